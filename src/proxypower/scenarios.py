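"""Literature-derived simulation scenarios.

Two published GABA-MRS results are re-examined through the proxy model:

* ``jia`` — a 7T behavioral-training study reporting a significant
  GABA/tCr increase measured with short-TE MRS.  Assuming the null is
  actually true, the observed group-mean difference back-translates to a
  differential bias ``delta``; the scenario sweeps the false-positive
  rate against ``delta`` over plausible (VR, R_sigma) combinations.
* ``blicher`` — a 3T ALS study that failed to find a GABA/tCr difference
  previously reported elsewhere.  Assuming the previously observed effect
  is real, the scenario sweeps the false-negative rate against ``Delta``,
  showing the study was likely underpowered at the empirical short-TE
  correlation.

All constants are published values in GABA/tCr institutional units; no
unit conversion is attempted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

from .mc_engine import CSV_COLUMNS, DEFAULT_REPS, SweepResult, estimate_rate
from .model_core import ReducedParams

__all__ = [
    "ScenarioConfig", "JIA", "BLICHER", "estimate_delta",
    "run_jia_scenario", "run_blicher_scenario", "scenario_dataframe",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScenarioConfig:
    """A named bundle of published constants plus sweep grids.

    ``vr_grid`` includes the scenario's maximum admissible variance ratio
    (``VR_max``) as its last entry; ``VR_max`` is a published constant of
    each scenario, not a derived quantity.
    """

    name: str
    sigma_P: float
    rho: float
    n_a: int
    n_b: int
    alpha: float
    Delta_assumed: float
    vr_grid: tuple[float, ...]
    r_sigma_grid: tuple[float, ...]
    mean_a: float | None = None
    mean_b: float | None = None

    def __post_init__(self) -> None:
        if self.sigma_P <= 0:
            raise ValueError(f"sigma_P must be > 0, got {self.sigma_P}")
        if not self.vr_grid or not self.r_sigma_grid:
            raise ValueError("vr_grid and r_sigma_grid must be non-empty")

    @property
    def vr_max(self) -> float:
        return self.vr_grid[-1]

    @property
    def mean_diff(self) -> float:
        if self.mean_a is None or self.mean_b is None:
            raise ValueError(f"scenario {self.name!r} has no published group means")
        return self.mean_b - self.mean_a


#: 7T behavioral-training FPR scenario.  sigma_P = 1.55 follows the value
#: stated with the group means; an alternative figure annotation gives 1.15
#: (JIA_ALT_SIGMA_P), but only 1.55 reproduces the reported FPR of 0.15 at
#: (VR = 0.5, R_sigma = 2) under the noncentral-t oracle.
JIA = ScenarioConfig(
    name="jia", sigma_P=1.55, rho=0.72, n_a=25, n_b=25, alpha=0.05,
    Delta_assumed=0.0, vr_grid=(0.5, 1.0, 1.9), r_sigma_grid=(0.5, 1.0, 2.0),
    mean_a=6.8, mean_b=7.6,
)

JIA_ALT_SIGMA_P = 1.15

#: 3T ALS FNR scenario.  The assumed true effect Delta = -0.05 comes from a
#: previously reported 16% GABA reduction in ALS patients.
BLICHER = ScenarioConfig(
    name="blicher", sigma_P=0.06, rho=0.58, n_a=9, n_b=10, alpha=0.05,
    Delta_assumed=-0.05, vr_grid=(0.5, 1.0, 1.3), r_sigma_grid=(1.0,),
)

SCENARIOS = {"jia": JIA, "blicher": BLICHER}


def estimate_delta(mean_diff: float, rho: float, R_sigma: float = 1.0,
                   VR: float = 1.0) -> float:
    """Back-estimate the differential bias from an observed proxy difference.

    Assuming the null (Delta = 0) is true, the observed proxy group-mean
    difference must be carried entirely by the contamination term, giving

        delta = mean_diff / sqrt(1 - rho^2) * sqrt(R_sigma / VR)

    which inverts E(P_B) - E(P_A) = x2 * delta.

    Raises
    ------
    ValueError
        At rho = 1 the bias is unidentifiable (the proxy carries no
        contamination), and outside [0, 1) rho is invalid.
    """
    if not 0.0 <= rho < 1.0:
        raise ValueError(
            f"rho must be in [0, 1); bias is unidentifiable at rho=1 (got {rho})"
        )
    if VR <= 0 or R_sigma <= 0:
        raise ValueError(f"VR and R_sigma must be > 0, got VR={VR}, R_sigma={R_sigma}")
    return mean_diff / math.sqrt(1.0 - rho * rho) * math.sqrt(R_sigma / VR)


def run_jia_scenario(
    config: ScenarioConfig = JIA,
    delta_grid=None,
    reps: int = DEFAULT_REPS,
    seed: int = 0,
) -> SweepResult:
    """False-positive rate versus delta over the (VR, R_sigma) grid.

    ``delta`` is held fixed while (VR, R_sigma) vary: the back-estimated
    bias is treated as the observed quantity, and the sweep probes how
    sensitive the FPR is to the unverifiable variance ratios.  The proxy
    SD is the published one (sigma_bio = sigma_P / sqrt(VR)).
    """
    if delta_grid is None:
        delta_grid = (estimate_delta(config.mean_diff, config.rho),)
    rows = []
    i = 0
    for vr in config.vr_grid:
        for r_sigma in config.r_sigma_grid:
            for delta in delta_grid:
                params = ReducedParams(
                    rho=config.rho, VR=vr, R_sigma=r_sigma,
                    Delta=config.Delta_assumed, delta=delta,
                    scale_mode="sigma_P", scale_value=config.sigma_P,
                    n_a=config.n_a, n_b=config.n_b, alpha=config.alpha,
                )
                rows.append(estimate_rate(params, reps=reps, seed=seed + i))
                i += 1
    grid = {"VR": config.vr_grid, "R_sigma": config.r_sigma_grid,
            "delta": tuple(delta_grid)}
    return SweepResult(rows=tuple(rows), grid_spec=grid)


def run_blicher_scenario(
    config: ScenarioConfig = BLICHER,
    Delta_grid=None,
    reps: int = DEFAULT_REPS,
    seed: int = 0,
    rho_grid=(0.58, 1.0),
) -> SweepResult:
    """False-negative rate versus Delta for the empirical and perfect rho.

    A correlation of 1 cannot be obtained at the scenario's maximum
    variance ratio, so the (rho = 1, VR = VR_max) cell is skipped with a
    logged notice.
    """
    if Delta_grid is None:
        Delta_grid = (config.Delta_assumed,)
    rows = []
    i = 0
    for rho in rho_grid:
        for vr in config.vr_grid:
            if rho == 1.0 and vr == config.vr_max:
                logger.info(
                    "skipping rho=1 at VR_max=%s: a correlation of 1 cannot "
                    "be obtained at the maximum variance ratio", vr,
                )
                continue
            for Delta in Delta_grid:
                params = ReducedParams(
                    rho=rho, VR=vr, R_sigma=1.0,
                    Delta=Delta, delta=0.0,
                    scale_mode="sigma_P", scale_value=config.sigma_P,
                    n_a=config.n_a, n_b=config.n_b, alpha=config.alpha,
                )
                # FNR even at Delta = 0 (where it equals 1 - alpha): this
                # sweep reports power loss across the whole effect grid
                rows.append(estimate_rate(params, reps=reps, seed=seed + i,
                                          rate_type="FNR"))
                i += 1
    grid = {"rho": tuple(rho_grid), "VR": config.vr_grid,
            "Delta": tuple(Delta_grid)}
    return SweepResult(rows=tuple(rows), grid_spec=grid)


def scenario_dataframe(result: SweepResult, name: str) -> pd.DataFrame:
    """Sweep rows as a DataFrame with scenario name and analytic companion."""
    from .analytic import rejection_probability

    df = result.to_dataframe()
    df["analytic_rate"] = [
        1.0 - rejection_probability(r.params) if r.rate_type == "FNR"
        else rejection_probability(r.params)
        for r in result.rows
    ]
    df.insert(0, "scenario", name)
    return df[["scenario"] + CSV_COLUMNS + ["analytic_rate"]]
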