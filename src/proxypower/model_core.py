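"""Generative model of paired gold-standard and proxy measurements.

A gold-standard measurement ``G`` is the latent biological signal ``S`` plus
independent measurement error::

    G = S + eps,        S ~ N(mu_bio, sigma_bio^2),  eps ~ N(0, sigma_Gerr^2)

A proxy measurement ``P`` mixes the *same* latent signal with an independent
contamination component ``zeta``::

    P = x1 * S + x2 * zeta,   zeta ~ N(mu_contam, sigma_contam^2)

Two groups are modelled: controls (A) and cases (B).  Cases carry a true
effect ``Delta`` on the biological mean and, optionally, a *differential
bias* ``delta`` on the contamination mean — a shift present in one group
only (e.g. macromolecule differences between patients and controls bleeding
into a short-TE GABA estimate).

The user-facing parameterization is ``(rho, VR, R_sigma)``: the proxy/gold
correlation, the variance ratio var(P)/var(G), and the contamination-to-
biological variance ratio sigma_contam^2/sigma_bio^2.  With negligible
gold-standard measurement error these map to the mixing coefficients

    x1 = rho * sqrt(VR),      x2 = sqrt(VR * (1 - rho^2) / R_sigma)

which satisfy x1^2 + x2^2 * R_sigma = VR and corr(P, G) = rho.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GoldParams",
    "ContamParams",
    "MixingCoefficients",
    "ReducedParams",
    "PairedSample",
    "coefficients_from_reduced",
    "sample_paired",
]


@dataclass(frozen=True)
class GoldParams:
    """Parameters of the gold-standard measurement model.

    Attributes
    ----------
    mu_bio : float
        Mean of the latent biological signal (mM, or unitless for
        relative concentrations).
    sigma_bio : float
        SD of the biological signal, >= 0.
    sigma_Gerr : float
        SD of the gold-standard measurement error, >= 0.  Defaults to 0:
        the reduced parameterization treats the gold standard as exact,
        and all headline rates are functions of the proxy variables only.
    Delta : float
        True effect: difference of case minus control biological means.
    """

    mu_bio: float = 0.0
    sigma_bio: float = 1.0
    sigma_Gerr: float = 0.0
    Delta: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_bio < 0:
            raise ValueError(f"sigma_bio must be >= 0, got {self.sigma_bio}")
        if self.sigma_Gerr < 0:
            raise ValueError(f"sigma_Gerr must be >= 0, got {self.sigma_Gerr}")


@dataclass(frozen=True)
class ContamParams:
    """Parameters of the contamination component of the proxy.

    ``delta`` is the differential bias: a shift of the contamination mean
    present in the case group only.
    """

    mu_contam: float = 0.0
    sigma_contam: float = 1.0
    delta: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_contam < 0:
            raise ValueError(
                f"sigma_contam must be >= 0, got {self.sigma_contam}"
            )


@dataclass(frozen=True)
class MixingCoefficients:
    """Non-negative weights of signal (x1) and contamination (x2) in the proxy."""

    x1: float
    x2: float

    def __post_init__(self) -> None:
        if self.x1 < 0 or self.x2 < 0:
            raise ValueError(
                f"mixing coefficients must be >= 0, got x1={self.x1}, x2={self.x2}"
            )


@dataclass(frozen=True)
class ReducedParams:
    """User-facing parameterization of a simulated two-group experiment.

    Parameters
    ----------
    rho : float
        Target correlation between proxy and gold standard, in [0, 1].
    VR : float
        Variance ratio var(P)/var(G), > 0.
    R_sigma : float
        Contamination-to-biological variance ratio, > 0.
    Delta : float
        True effect on the biological mean (case minus control).
    delta : float
        Differential bias on the contamination mean (case group only).
    scale_mode : {"sigma_bio", "sigma_P"}
        Whether ``scale_value`` is the biological SD (theoretical
        simulations) or the proxy SD (literature simulations, where only
        the observed proxy spread is known).
    scale_value : float
        The SD named by ``scale_mode``, > 0.
    n_a, n_b : int
        Group sizes (controls, cases), >= 1.
    alpha : float
        Nominal two-sided test level, in (0, 1).
    """

    rho: float
    VR: float = 1.0
    R_sigma: float = 1.0
    Delta: float = 0.0
    delta: float = 0.0
    scale_mode: str = "sigma_bio"
    scale_value: float = 1.0
    n_a: int = 25
    n_b: int = 25
    alpha: float = 0.05
    mu_bio: float = 0.0
    mu_contam: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must be in [0, 1], got {self.rho}")
        if self.VR <= 0:
            raise ValueError(f"VR must be > 0, got {self.VR}")
        if self.R_sigma <= 0:
            raise ValueError(f"R_sigma must be > 0, got {self.R_sigma}")
        if self.scale_mode not in ("sigma_bio", "sigma_P"):
            raise ValueError(
                f"scale_mode must be 'sigma_bio' or 'sigma_P', got {self.scale_mode!r}"
            )
        if self.scale_value <= 0:
            raise ValueError(f"scale_value must be > 0, got {self.scale_value}")
        if self.n_a < 1 or self.n_b < 1:
            raise ValueError(
                f"group sizes must be positive, got n_a={self.n_a}, n_b={self.n_b}"
            )
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")

    @property
    def sigma_bio(self) -> float:
        """Biological SD; derived as sigma_P / sqrt(VR) in sigma_P mode."""
        if self.scale_mode == "sigma_bio":
            return self.scale_value
        return self.scale_value / math.sqrt(self.VR)

    @property
    def sigma_P(self) -> float:
        """Proxy SD; sqrt(VR) * sigma_bio."""
        if self.scale_mode == "sigma_P":
            return self.scale_value
        return math.sqrt(self.VR) * self.scale_value

    @property
    def sigma_contam(self) -> float:
        return math.sqrt(self.R_sigma) * self.sigma_bio

    def coefficients(self) -> MixingCoefficients:
        return coefficients_from_reduced(self.rho, self.VR, self.R_sigma)

    def gold_params(self) -> GoldParams:
        return GoldParams(
            mu_bio=self.mu_bio, sigma_bio=self.sigma_bio,
            sigma_Gerr=0.0, Delta=self.Delta,
        )

    def contam_params(self) -> ContamParams:
        return ContamParams(
            mu_contam=self.mu_contam, sigma_contam=self.sigma_contam,
            delta=self.delta,
        )


@dataclass(frozen=True)
class PairedSample:
    """One simulated experiment: gold and proxy arrays sharing latent S draws."""

    g_a: np.ndarray
    g_b: np.ndarray
    p_a: np.ndarray
    p_b: np.ndarray

    def __post_init__(self) -> None:
        if self.g_a.shape != self.p_a.shape or self.g_b.shape != self.p_b.shape:
            raise ValueError("gold and proxy arrays must have matching shapes")


def coefficients_from_reduced(
    rho: float, VR: float, R_sigma: float
) -> MixingCoefficients:
    """Map (rho, VR, R_sigma) to mixing coefficients (x1, x2).

    Uses the non-negative roots

        x1 = rho * sqrt(VR)
        x2 = sqrt(VR * (1 - rho^2) / R_sigma)

    which satisfy x1^2 + x2^2 * R_sigma = VR and x1 / sqrt(VR) = rho
    (the correlation when gold-standard measurement error is negligible).
    At rho = 1 the contamination weight is exactly 0 and R_sigma is
    irrelevant.

    Raises
    ------
    ValueError
        If rho is outside [0, 1] or VR or R_sigma is not positive.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"rho must be in [0, 1], got {rho}")
    if VR <= 0:
        raise ValueError(f"VR must be > 0, got {VR}")
    if R_sigma <= 0:
        raise ValueError(f"R_sigma must be > 0, got {R_sigma}")
    x1 = rho * math.sqrt(VR)
    if rho == 1.0:
        x2 = 0.0
    else:
        x2 = math.sqrt(VR * (1.0 - rho * rho) / R_sigma)
    return MixingCoefficients(x1=x1, x2=x2)


def _standard_blocks(rng: np.random.Generator, shape_a, shape_b):
    """Draw the six standardized normal blocks in a fixed order.

    The order (S_A, S_B, eps_A, eps_B, zeta_A, zeta_B) is part of the
    reproducibility contract: scaling and shifting these blocks afterwards
    makes test decisions bit-identical under changes of the means, of VR at
    fixed sigma_bio, and of R_sigma when delta = 0.
    """
    zs_a = rng.standard_normal(shape_a)
    zs_b = rng.standard_normal(shape_b)
    ze_a = rng.standard_normal(shape_a)
    ze_b = rng.standard_normal(shape_b)
    zz_a = rng.standard_normal(shape_a)
    zz_b = rng.standard_normal(shape_b)
    return zs_a, zs_b, ze_a, ze_b, zz_a, zz_b


def sample_paired(
    gold: GoldParams,
    contam: ContamParams,
    coeffs: MixingCoefficients,
    n_a: int,
    n_b: int,
    rng,
    reps: int | None = None,
) -> PairedSample:
    """Sample correlated gold-standard and proxy datasets for both groups.

    The same latent ``S`` realizations enter the gold-standard and proxy
    values, which is what induces the proxy-gold correlation.

    Parameters
    ----------
    rng : int or numpy.random.Generator
        Seed or generator.  Identical state gives bit-identical output.
    reps : int, optional
        If given, arrays have shape ``(reps, n)``: ``reps`` independent
        experiments drawn in one vectorized pass.

    Returns
    -------
    PairedSample
    """
    if n_a < 1 or n_b < 1:
        raise ValueError(f"group sizes must be positive, got n_a={n_a}, n_b={n_b}")
    if reps is not None and reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    generator = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    shape_a = (n_a,) if reps is None else (reps, n_a)
    shape_b = (n_b,) if reps is None else (reps, n_b)
    zs_a, zs_b, ze_a, ze_b, zz_a, zz_b = _standard_blocks(generator, shape_a, shape_b)

    s_a = gold.mu_bio + gold.sigma_bio * zs_a
    s_b = gold.mu_bio + gold.Delta + gold.sigma_bio * zs_b
    g_a = s_a + gold.sigma_Gerr * ze_a
    g_b = s_b + gold.sigma_Gerr * ze_b
    zeta_a = contam.mu_contam + contam.sigma_contam * zz_a
    zeta_b = contam.mu_contam + contam.delta + contam.sigma_contam * zz_b
    p_a = coeffs.x1 * s_a + coeffs.x2 * zeta_a
    p_b = coeffs.x1 * s_b + coeffs.x2 * zeta_b
    return PairedSample(g_a=g_a, g_b=g_b, p_a=p_a, p_b=p_b)
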