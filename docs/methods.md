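# Methods

## Model and assumptions

Two groups are compared: controls (A) and cases (B). Each subject carries a
latent biological signal `S ~ N(μ_bio, σ²_bio)` (cases shifted by the true
effect `Δ`). The gold-standard measurement adds independent error,
`G = S + ε`, `ε ~ N(0, σ²_Gerr)`. The proxy measurement is a linear blend of
the same latent signal and an independent contamination component,
`P = x₁S + x₂ζ`, `ζ ~ N(μ_contam, σ²_contam)`, with the case group's
contamination mean shifted by a differential bias `δ`. All components are
normal and independent across subjects and of each other (conditional on
`S`); paired or repeated-measures designs, more than two groups, and
non-normal signal or contamination distributions are out of scope.

Hypothesis tests are two-sided independent Welch's t-tests on the *proxy*
samples at level `α`, while the hypotheses concern the gold-standard means
(`H₀: Δ = 0`). The false-positive regime sets `Δ = 0`, `δ ≠ 0`; the
false-negative regime sets `Δ ≠ 0`, `δ = 0`. The engine refuses to mix the
two unless explicitly overridden, since a mixed setting has no
interpretation as either rate.

## Reduced parameterization

Users specify `(ρ, VR, R_σ)` — proxy–gold correlation, variance ratio
var(P)/var(G), and contamination-to-biological variance ratio
σ²_contam/σ²_bio — instead of `(x₁, x₂)` directly. The non-negative roots

    x₁ = ρ·√VR,   x₂ = √(VR·(1 − ρ²)/R_σ)

satisfy `x₁² + x₂²R_σ = VR` and give corr(P, G) = ρ when the gold-standard
measurement error is negligible. `σ_Gerr` defaults to 0 throughout the
reduced pathway: all headline rates are functions of the proxy samples
only, and the variance-ratio identity is exact in this limit. The field is
retained on `GoldParams` so the exact (non-limiting) correlation can be
studied. At `ρ = 1`, `x₂` is set to exactly 0 and `R_σ` becomes irrelevant;
negative mixing weights are excluded as they have no interpretation here.

Two scale conventions coexist. Theoretical sweeps fix `σ_bio` (default
1 mM). Literature scenarios know only the observed proxy SD, so
`scale_mode="sigma_P"` supplies `σ_P` and derives `σ_bio = σ_P/√VR`; the
variance ratio must then be swept because it is unidentifiable from proxy
data alone.

## Sampling and reproducibility

Each replicate draws six standardized normal blocks in a fixed order
(S_A, S_B, ε_A, ε_B, ζ_A, ζ_B), then scales and shifts them. Consequences,
each an exact (bit-identical at fixed seed) invariance of the rejection
decisions rather than a statistical one:

* changing `μ_bio` or `μ_contam` shifts both groups' proxies by the same
  constant — decisions unchanged (rates are independent of the means);
* changing `VR` at fixed `σ_bio` multiplies every proxy value by √VR —
  decisions unchanged (the t statistic is scale-free);
* changing `R_σ` when `δ = 0` leaves `x₂σ_contam = √(VR(1−ρ²))·σ_bio`
  unchanged — decisions unchanged (the FNR regime never depends on `R_σ`).

Monte Carlo runs are vectorized (one Welch test per row of a
replicates × n matrix, batched at 100,000 rows to bound memory) and fully
determined by `(params, reps, seed)`. Grid sweeps assign seed
`base + point_index` to each cell, ordered lexicographically by axis name,
so any cell can be recomputed in isolation. The default replicate count is
500,000; tests and the acceptance script use 20,000–100,000, which puts the
binomial standard error of any rate below 0.0016 at 100,000 replicates.

## Analytic oracle

The closed form treats the proxy two-sample t statistic as noncentral t
with noncentrality `λ = d·√(n_a n_b/(n_a+n_b))`,
`d = (x₁Δ + x₂δ)/σ_P`, and pooled degrees of freedom `n_a + n_b − 2`
(group variances are equal by construction). The rejection probability is
`P(|T′| > t_crit)`; the FPR is this probability at `Δ = 0` (exactly `α`
when `δ = 0` too) and the FNR its complement at `Δ ≠ 0`. Two approximations
are accepted, standard in power analysis: the population `σ_P` stands in
for the estimated one beyond what noncentral t captures, and the pooled df
replaces the Welch–Satterthwaite df. The latter bites at small, strongly
unequal group sizes (e.g. 0.598 analytic vs 0.604 simulated FNR at
n = 9/10); the Monte Carlo engine is the ground truth there, and the test
suite restricts the strict 3·SE agreement check to near-equal group sizes
accordingly.

## Literature scenarios

**7T behavioral-training FPR scenario (`jia`).** Published constants:
n = 25 per group, α = 0.05, proxy SD σ_P = 1.55, proxy group means 6.8 and
7.6 (GABA/tCr institutional units), correlation ρ = 0.72. Assuming the null
is true, the observed difference must be contamination, giving the
back-estimation formula `δ = (E(P_B) − E(P_A))/√(1 − ρ²) · √(R_σ/VR)`
(≈ 1.2 at R_σ = VR = 1), which inverts `E(P_B) − E(P_A) = x₂δ`. Because
only σ_P (not σ_bio) and neither `VR` nor `R_σ` are observable, the FPR is
swept over VR ∈ {0.5, 1, 1.9} and R_σ ∈ {0.5, 1, 2} with δ held fixed.
Two published values of σ_P circulate for this study (1.55 with the group
means, 1.15 in a figure annotation); 1.55 is the default because only it
reproduces the reported FPR of 0.15 at (VR = 0.5, R_σ = 2) under the
noncentral-t oracle — the alternative remains available via
`--sigma-p 1.15`. The maximum variance ratio 1.9 is carried as a published
constant of the scenario, not derived.

**3T ALS FNR scenario (`blicher`).** Published constants: n = 9 cases /
10 controls, α = 0.05, σ_P = 0.06, empirical correlation ρ = 0.58, assumed
true effect Δ = −0.05 (from a previously reported ~16% GABA reduction),
δ = 0. FNR is computed for ρ ∈ {0.58, 1} and VR ∈ {0.5, 1, 1.3}; the
(ρ = 1, VR = 1.3) cell is skipped with a logged notice because a perfect
correlation cannot coexist with the maximum variance ratio. The sweep
reports FNR (the non-rejection fraction) across the whole Δ grid,
including Δ = 0 where it equals 1 − α. Note: the published rate set for
this scenario is internally consistent with 10 subjects per group rather
than the stated 9/10 (all five values reproduce within 0.007 at n = 10/10,
while at n = 9/10 the (ρ = 1, VR = 1) cell is 0.604 rather than 0.59); the
package keeps the stated 9/10.

## Macromolecule contamination

To gauge plausible magnitudes of `δ`, the absolute proton concentrations of
the three macromolecule resonances overlying GABA (19.8 mM at 2.99 ppm,
120.8 mM at 2.04 ppm, 49.0 mM at 2.26 ppm) are converted to GABA/tCr
institutional units via

    C_M,inst = C_M,abs · (C_GABA,inst/C_GABA,abs) · (N_p,M/N_p,GABA)
               · exp(−TE/T2_M)/exp(−TE/T2_GABA)

with C_GABA,inst = 7.6, C_GABA,abs = 2.1 mM, proton-count factor ½ (every
GABA moiety has two protons), TE = 36 ms, T2_GABA = 63 ms and T2_M of
20.0/14.3/19.8 ms — yielding 10.5, 31.2 and 25.5. A `fraction` convenience
multiplies these by a fractional between-group change to show the implied
bias; no claim about any particular study is attached to it. T1/inversion
weighting is not modelled.

## What the simulations do and do not show

The generator emulates exactly the stated normal model: independent
subjects, equal group variances, a single contamination channel with a
clean mean shift. Real spectroscopy data add features the model omits —
non-normal and heteroscedastic concentration distributions, ratio
denominators (tCr) that correlate the proxy with its reference,
fitting-algorithm coupling between overlapping resonances, and
subject-level artifacts (motion, shim) that are unlikely to be mean shifts.
Passing tests therefore validate the arithmetic of the model and the
qualitative mechanisms (bias inflates FPR, decorrelation inflates FNR, more
subjects amplify a bias's FPR), not the calibration of any specific
published study.

## Numerical choices

* Rejection uses strict `p < α`; ties have probability zero under the
  continuous model.
* Rates of exactly 0 or 1 report the rule-of-three bound 3/reps alongside
  the (zero) binomial standard error.
* CSV output formats floats with shortest round-trip `repr`;
  `read_rates` reads them back with the exact (`round_trip`) parser, since
  the default pandas parser can be one ulp off.
* Degenerate inputs (zero SDs) are legal and produce constant samples; the
  Welch test refuses only when both samples have zero variance.
* Grid range specs (`start:stop:step`) round grid values to 12 decimals to
  keep printed coordinates clean.
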