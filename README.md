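# proxypower

**How wrong can a t-test be when it is run on a proxy measurement instead of
the gold standard?** `proxypower` answers this with a generative model of
paired gold-standard/proxy measurements and Monte Carlo simulation of
two-sided Welch's t-tests, quantifying the false-positive rate (FPR) and
false-negative rate (FNR) as functions of the proxy–gold correlation and of
any *differential bias* between groups.

The motivating application is GABA quantification by magnetic resonance
spectroscopy, where MEGA-edited measurements (the gold standard) are often
replaced by short-TE estimates (the proxy) that overlap broad macromolecule
resonances — but the model is generic to any gold-standard-vs-proxy design:
surrogate endpoints, screening instruments, cheaper assays.

## The model

Gold-standard measurements are the latent biological signal plus independent
error; proxy measurements mix the *same* latent signal with an independent
contamination component:

```
G = S + ε            S_A ~ N(μ_bio, σ²_bio),  S_B ~ N(μ_bio + Δ, σ²_bio)
P = x₁·S + x₂·ζ      ζ_A ~ N(μ_contam, σ²_contam),  ζ_B ~ N(μ_contam + δ, σ²_contam)
```

`Δ` is the true case-minus-control effect; `δ` is a differential bias
carried by the contamination in one group only (e.g. macromolecule changes
in patients bleeding into the GABA estimate). The user-facing
parameterization is `(ρ, VR, R_σ)` — the proxy–gold correlation, the
variance ratio var(P)/var(G), and the contamination-to-biological variance
ratio — which maps to the mixing weights

```
x₁ = ρ·√VR          x₂ = √(VR·(1 − ρ²)/R_σ)
```

Welch's t-test is applied to the proxy samples while the hypothesis
concerns the gold-standard means. With `Δ = 0` and `δ > 0` the simulation
measures FPR inflation; with `Δ ≠ 0` and `δ = 0` it measures FNR (power
loss). A noncentral-*t* closed form (noncentrality
`λ = (x₁Δ + x₂δ)/σ_P · √(n_a n_b/(n_a+n_b))`) serves as an independent
analytic cross-check of every simulated rate.

## Worked example

FNR for a 1 mM true effect at *perfect* proxy–gold correlation,
25 subjects per group:

```sh
$ proxypower fnr --rho 1 --Delta 1.0 --sigma-bio 1 --n 25 --alpha 0.05 --reps 20000 --seed 1
rate_type,rho,VR,R_sigma,Delta,delta,scale_mode,scale_value,n_a,n_b,alpha,reps,seed,rate,mc_se
FNR,1.0,1.0,1.0,1.0,0.0,sigma_bio,1.0,25,25,0.05,20000,1,0.0666,0.001763015031132747
```

Even a perfectly correlated proxy misses this effect ~7% of the time; drop
the correlation to 0.7 (`--rho 0.7`) and the miss rate triples to ~32%.
The same library call is `estimate_rate(ReducedParams(rho=1.0, Delta=1.0),
reps=20000, seed=1)`.

The macromolecule table shows why a differential bias of the size the
literature scenarios use is plausible:

```sh
$ proxypower mm-contam
label  C_M_abs  T2_M  C_M_inst
M2.99     19.8  20.0      10.5
M2.04    120.8  14.3      31.2
M2.26     49.0  19.8      25.5
```

The three macromolecule resonances overlying GABA have institutional
(GABA/tCr-unit) concentrations of 10.5–31.2 — so a few-percent
between-group change in any of them rivals the bias δ ≈ 1.2 back-estimated
in the 7T training scenario.

Other entry points: `proxypower sweep` (Cartesian parameter grids),
`proxypower alpha-sweep`, and `proxypower scenario {jia,blicher}` for the
two literature-derived scenarios (a 7T behavioral-training FPR analysis and
a 3T ALS FNR analysis). Every run writes a `.config.json` sidecar with the
resolved parameters, seed and library versions; identical flags and seed
reproduce output byte-for-byte.

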