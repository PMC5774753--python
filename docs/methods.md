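# Methods

`chronopewma` measures how radiocarbon dating uncertainty affects a count
time-series regression method — the Poisson Exponentially Weighted Moving
Average (PEWMA) state-space model — by simulation. This note records the
models, the numerical choices, and the places where the design was genuinely
open, so results produced with the package can be interpreted correctly.

## The PEWMA model and its likelihood

The observed counts y_t are conditionally Poisson with latent mean
μ_t = μ*_{t−1} · exp(r_t + x_t·δ), where the belief about the previous level
μ*_{t−1} is Gamma(a_{t−1}, b_{t−1}). Between steps the belief is discounted,
(a, b) ← (ωa, ωb) with ω ∈ (0, 1]: the mean a/b is unchanged but the belief's
effective sample size shrinks by ω, which is equivalent to a multiplicative
Beta(ωa, (1−ω)a) shock on the level. Smaller ω forgets older observations
faster — that is how the model encodes autocorrelated, non-stationary count
dynamics. Because the Gamma prior is conjugate to the Poisson likelihood, the
one-step-ahead predictive is negative binomial in closed form
(size ωa, success probability ωb/(ωb + m_t), with exposure
m_t = exp(r_t + x_t·δ)), and the full predictive log-likelihood is a single
O(n) filter pass. The filter's correctness is anchored to an independent
numerical oracle: on small cases, each predictive mass is compared with direct
quadrature of the Poisson-Gamma mixture integral (agreement to 1e-8 is a test
invariant; in practice it is ~1e-14).

Maximum likelihood jointly estimates ω (logit-transformed onto (0.01, 1)) and
δ (unbounded) by a compiled Nelder-Mead simplex from five deterministic ω
starts {0.2, 0.4, 0.6, 0.8, 0.99} with δ = 0. A derivative-free search was
chosen because the experiment engine performs 10^4–10^5 fits per run and the
likelihood has flat ridges in ω; spot checks against scipy's L-BFGS-B find the
same optima to <1e-6. Defaults: a0 = mean of the counts, b0 = 1 (prior mean
equals sample mean, unit prior weight); all predictive terms included
(`skip=0` — an option exists to exclude initial terms); base rate r_t = 0.

Model comparison uses the small-sample corrected information criterion
AICc = ((−2L) + 2k) · N/(N − k − 1), with k the number of covariate columns
(0 for the constant-only benchmark, 1 for the environmental-covariate model).
Note that this formula scales the whole −2L term, so for |L| ≈ 600 the
covariate model must beat the benchmark by roughly 2ΔL ≳ 2 + (−2L₀)/(N−1) ≈ 8,
considerably stricter than the plain-AIC threshold of 2. The "constant-only"
benchmark is the filter with an empty covariate matrix: the Gamma level is the
constant, and no separate intercept column is used in either model.

## Chronological machinery

Calibration follows the standard gridded Gaussian-measurement posterior:
on an annual calendar grid over the curve span,
p(θ) ∝ N(y; μ(θ), σ_lab² + σ_curve(θ)²), normalized to sum to one. The
varying total σ enters the Gaussian normalisation, so poorly known stretches
of the curve are down-weighted. A 1-yr grid is the package default.
Back-calibration (manufacturing a synthetic assay from a known calendar age)
is piecewise-linear interpolation of μ(θ); no extrapolation is permitted
anywhere.

Ordered bootstrap draws of anchor ages use a systematic-sweep Gibbs sampler:
each date is redrawn from its calibrated density truncated between its current
neighbours, with a minimum gap of one grid cell, so every draw is strictly
ordered (positions increase toward the past; cal BP ages increase with
position). Defaults: 100 burn-in sweeps, thinning 1, inverse-CDF sampling of
the piecewise-constant cell densities, initial state = per-date modes repaired
by sequential clamping. Whether the original procedure enforced strict or
weak ordering is unknowable from the text; strict ordering was chosen because
age-depth models require non-inverted anchors. Age-depth models are monotone
cubic Hermite interpolants (Fritsch-Carlson / PCHIP): exact at anchors,
monotone everywhere, no extrapolation.

## The synthetic study

One experiment fixes: span 12000–13000 cal BP, annual environmental grid of
1000 points (start-year inclusive), signal slope 0.01 units/yr, AR(1) noise
with lag-1 autocorrelation 0.7 initialized from stationarity, 200 covariate
samples (5-yr stride), laboratory error ±50 14C yr, generator discount
ω = 0.6, 1000 top-level pairs × 2000 bootstrap sub-pairs. Free parameters:
innovation sd ∈ {1, 0.1, 0.01} (SNR labels {1, 10, 100} are categorical
aliases, not exact variance ratios), dated horizons ∈ {5, 15, 25} (evenly
spaced, endpoints included), and target correlation ∈ {0, 0.25, 0.5, 0.75}.
Synthetic assays take the back-calibrated curve value exactly; σ_lab enters
only through calibration, so calibration is the isolated error source.

Counts are generated by the filter run in reverse: discount the belief, draw
μ ~ Gamma(ωa, ωb), emit y ~ Poisson(μ·e^{x δ}), update conjugately. The
belief starts at mean `baseline_mean` (default 10) with unit weight.
Covariates are standardized before entering the regression term, so δ is
scale-free.

**Correlation targeting.** The experiments are indexed by a covariate-count
correlation, not by δ, so δ is found by monotone bisection until the median
Pearson correlation over 200 replicate simulations hits the target (±0.02),
with common random numbers across evaluations. The replicates are drawn from
the conditional-Poisson reference process y ~ Poisson(baseline·e^{δx}), i.e.
with the latent level held at baseline. This choice is deliberate: the
discounted-Gamma level at ω = 0.6 is a multiplicative unit-root process whose
log-sd over a 200-step series is ≈ 2.8 at baseline 10, so a correlation
measured on full-process counts saturates near zero for every δ and the
target grid would be unreachable. Measured on the conditional process the
map is well-defined, monotone, and nearly independent of the particular
covariate realization (δ ≈ 0.08, 0.19, 0.38 for targets 0.25, 0.5, 0.75 at
baseline 10). δ is calibrated per top-level pair on that pair's covariate.

**What the generator does and does not emulate.** The reverse filter
reproduces the PEWMA model exactly, including its non-stationarity: the
latent level wanders over orders of magnitude in 200 steps at ω = 0.6, and
roughly half of replicate paths drift toward extinction while the grand mean
stays at baseline. Real archaeological count series are rarely this volatile.
Two consequences matter when reading hit rates produced by this package:
(i) a covariate with a strong monotone trend (the low-noise environmental
ramp) can be matched by the latent level's own stochastic drift, so per-pair
outcomes at low environmental noise are close to all-or-nothing and δ̂ is not
sign-identified there; (ii) detection genuinely driven by the covariate
operates through its fast (step-to-step) variation, which the discounted
belief cannot anticipate. Passing tests therefore demonstrate the behaviour
of the PEWMA method on data generated by its own model — they do not certify
hit rates for empirical series whose volatility is milder than the model's.

**Hit rule and denominators.** A sub-pair is a hit when the covariate model's
AICc is strictly below the benchmark's minus an optional buffer (default 0;
a positive buffer is recommended for real analyses). The benchmark does not
depend on the bootstrap draw and is fitted once per top-level pair.
Non-convergent fits mark the sub-pair invalid and are excluded from the hit
fraction's denominator (counts reported; a pair with >10% invalid sub-pairs
is flagged). Bootstrapped environmental values are linearly interpolated onto
the count series' calendar timestamps (edge values clamped), then
standardized — the simplest alignment rule consistent with re-timestamping.

**Seeding.** All randomness derives from one master seed through
`numpy.random.SeedSequence(master, spawn_key=(pair, stream))` counters, so any
sub-computation is reproducible in isolation and experiments are bit-stable
under resumption.

**Summaries.** Hit-rate distributions are summarized on a 0.05-wide histogram
over [0, 1]: the primary mode is the midpoint of the highest-count bin (ties
toward the lower bin); secondary modes are non-adjacent bins exceeding half
the primary count (contiguous runs collapsed to their highest member);
variance and quantiles accompany them.

## Calibration curve source

The package reads the standard `.14c` three-column dialect and the
experiments accept any such file. The default curve is synthetic:
μ(θ) = θ − 1850 + 55·sin(2πθ/310) with constant 40 yr 1σ error on a 5-yr grid
over 11800–13200 cal BP. The offset, error level, wiggle steepness (mild
reversals and plateaus), and the resulting ~70 yr calibrated-density widths
are chosen to resemble the early-Younger-Dryas portion of the international
calibration curve; the file-format reader makes substituting the real curve a
one-flag change (`--curve path/to/intcal.14c`).

## Problem sizes

The full study design (36 experiments × 2,000,000 analyses each) is
cluster-scale. The package's own evaluation uses the same machinery at
reduced replication — 100 top-level pairs × 200 bootstraps per experiment for
the false-positive and power measurements, and a handful of smoke-scale runs
elsewhere — which resolves hit-rate modes to the 0.05 histogram bin used for
reporting. Scaling back up is a configuration change (`n_top`, `n_boot`).

## Known limitations

- The generator's latent volatility is intrinsic to the PEWMA model at
  ω = 0.6; experiments at low environmental noise are dominated by
  stochastic-trend alignment rather than per-step covariate signal (see
  above), which compresses hit-rate distributions toward {0, 1} there.
- Estimating the magnitude of an underlying correlation (rather than
  detecting it), radiocarbon error on the dependent series (a config hook
  exists), resolution matching, reservoir/ΔR corrections, and outlier-aware
  deposition models are all out of scope.
- Negative target correlations are not supported; lagged covariate effects
  are expressed by shifting covariate columns upstream, not as a feature.
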