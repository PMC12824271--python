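"""Monte Carlo estimation of false-positive and false-negative rates.

Each replicate draws one two-group experiment from the generative model and
applies a two-sided Welch t-test to the *proxy* samples only — the test is
performed on the convenient measurement while the hypothesis concerns the
gold-standard means.  Two regimes are distinguished:

* false-positive regime: ``Delta = 0`` (the null is true); the FPR is the
  fraction of replicates that reject.  A nonzero differential bias ``delta``
  inflates it above the nominal level.
* false-negative regime: ``Delta != 0`` with ``delta = 0``; the FNR is the
  fraction that fail to reject.

Replicates are fully vectorized (one Welch test per matrix row) and batched
to bound memory at large replicate counts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .inference import welch_test_matrix
from .model_core import ReducedParams, sample_paired

__all__ = ["RateEstimate", "SweepResult", "estimate_rate", "run_sweep",
           "read_rates", "DEFAULT_REPS", "CSV_COLUMNS"]

#: Replicates per parameter set when none are requested.
DEFAULT_REPS = 500_000

#: Fixed column order of the CSV/DataFrame emitted for sweeps.
CSV_COLUMNS = [
    "rate_type", "rho", "VR", "R_sigma", "Delta", "delta",
    "scale_mode", "scale_value", "n_a", "n_b", "alpha",
    "reps", "seed", "rate", "mc_se",
]

_BATCH = 100_000


@dataclass(frozen=True)
class RateEstimate:
    """An FPR or FNR estimate with Monte Carlo standard error and provenance.

    ``mc_se`` is the binomial normal-approximation standard error
    sqrt(rate * (1 - rate) / reps).  For rates of exactly 0 or 1 this is
    zero, so ``rule_of_three`` additionally reports the 3/reps upper bound
    on the true rate (or its complement).
    """

    rate_type: str
    rate: float
    mc_se: float
    reps: int
    params: ReducedParams
    seed: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError(f"rate must be in [0, 1], got {self.rate}")
        if self.reps < 1:
            raise ValueError(f"reps must be >= 1, got {self.reps}")

    @property
    def rule_of_three(self) -> float | None:
        if self.rate in (0.0, 1.0):
            return 3.0 / self.reps
        return None

    def to_row(self) -> dict:
        p = self.params
        return {
            "rate_type": self.rate_type, "rho": p.rho, "VR": p.VR,
            "R_sigma": p.R_sigma, "Delta": p.Delta, "delta": p.delta,
            "scale_mode": p.scale_mode, "scale_value": p.scale_value,
            "n_a": p.n_a, "n_b": p.n_b, "alpha": p.alpha,
            "reps": self.reps, "seed": self.seed,
            "rate": self.rate, "mc_se": self.mc_se,
        }


@dataclass(frozen=True)
class SweepResult:
    """RateEstimates over a Cartesian grid of swept parameters."""

    rows: tuple[RateEstimate, ...]
    grid_spec: dict[str, tuple]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_row() for r in self.rows], columns=CSV_COLUMNS)

    def to_csv(self, path) -> None:
        # repr gives shortest round-tripping float representation
        self.to_dataframe().to_csv(path, index=False, float_format=lambda v: repr(float(v)))


def read_rates(path) -> pd.DataFrame:
    """Read a rates CSV back with exact float round-tripping.

    The default pandas float parser can be off by one ulp; the
    ``round_trip`` parser recovers the written values exactly.
    """
    return pd.read_csv(path, float_precision="round_trip")


def _regime(params: ReducedParams, allow_mixed: bool) -> str:
    if params.Delta != 0.0 and params.delta != 0.0 and not allow_mixed:
        raise ValueError(
            "Delta != 0 and delta != 0 simultaneously mixes the false-positive "
            "and false-negative regimes; pass allow_mixed=True to force it"
        )
    return "FNR" if params.Delta != 0.0 else "FPR"


def estimate_rate(
    params: ReducedParams,
    reps: int = DEFAULT_REPS,
    seed: int = 0,
    allow_mixed: bool = False,
    rate_type: str | None = None,
) -> RateEstimate:
    """Estimate the FPR (Delta = 0) or FNR (Delta != 0) by Monte Carlo.

    Runs ``reps`` independent experiments — each a fresh draw from the
    gold/proxy model followed by a Welch t-test on the proxy samples at
    ``params.alpha`` — and reports the rejection fraction (FPR) or
    non-rejection fraction (FNR).  Deterministic given (params, reps, seed).

    ``rate_type`` overrides the regime inference, e.g. to report the FNR
    at the Delta = 0 point of an effect-size sweep (where it equals
    1 - alpha).

    Raises
    ------
    ValueError
        If both ``Delta`` and ``delta`` are nonzero without
        ``allow_mixed`` (the two regimes are never mixed), or ``reps < 1``.
    """
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    if rate_type is None:
        rate_type = _regime(params, allow_mixed)
    elif rate_type not in ("FPR", "FNR"):
        raise ValueError(f"rate_type must be 'FPR' or 'FNR', got {rate_type!r}")

    gold = params.gold_params()
    contam = params.contam_params()
    coeffs = params.coefficients()
    rng = np.random.default_rng(seed)

    n_reject = 0
    done = 0
    while done < reps:
        batch = min(_BATCH, reps - done)
        sample = sample_paired(
            gold, contam, coeffs, params.n_a, params.n_b, rng, reps=batch
        )
        _, _, reject = welch_test_matrix(sample.p_a, sample.p_b, params.alpha)
        n_reject += int(reject.sum())
        done += batch

    if rate_type == "FPR":
        rate = n_reject / reps
    else:
        rate = (reps - n_reject) / reps
    mc_se = float(np.sqrt(rate * (1.0 - rate) / reps))
    return RateEstimate(
        rate_type=rate_type, rate=rate, mc_se=mc_se,
        reps=reps, params=params, seed=seed,
    )


def run_sweep(
    grid_spec: Mapping[str, Sequence],
    base_params: ReducedParams,
    reps: int = DEFAULT_REPS,
    seed: int = 0,
    allow_mixed: bool = False,
) -> SweepResult:
    """Estimate rates over the Cartesian product of the grid axes.

    ``grid_spec`` maps ReducedParams field names to value sequences.  Axes
    are ordered lexicographically by name; the point at index ``i`` (in
    that ordering) uses seed ``seed + i``, so every grid cell is
    independently reproducible.

    Raises
    ------
    ValueError
        If any grid point yields invalid parameters; the message names the
        offending coordinates.
    """
    axes = sorted(grid_spec)
    value_lists = [tuple(grid_spec[a]) for a in axes]
    rows = []
    for i, combo in enumerate(itertools.product(*value_lists)):
        point = dict(zip(axes, combo))
        try:
            p = replace(base_params, **point)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"invalid grid point {point}: {exc}") from exc
        rows.append(estimate_rate(p, reps=reps, seed=seed + i,
                                  allow_mixed=allow_mixed))
    return SweepResult(rows=tuple(rows),
                       grid_spec={a: tuple(grid_spec[a]) for a in axes})
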