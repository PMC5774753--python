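# chronopewma

Count time-series regression under radiocarbon dating uncertainty.

Archaeological and palaeoenvironmental records are time-series, but their
observations are rarely dated exactly: radiocarbon dates must be calibrated,
and calibration produces irregular, often multimodal uncertainties spanning
decades to centuries. `chronopewma` implements a regression method suited to
archaeological count data — the Poisson Exponentially Weighted Moving Average
(PEWMA) state-space model — together with the simulation machinery needed to
measure how calibrated-date uncertainty affects its true- and false-positive
behaviour. It is written for archaeologists and palaeo-scientists who want to
test hypotheses of the form "did environmental conditions drive this count
record?" while propagating chronological uncertainty honestly.

## The model

The counts y_t follow a Poisson distribution whose latent mean evolves as a
discounted conjugate process:

    y_t | μ_t          ~ Poisson(μ_t)
    μ_t = μ*_{t−1} · exp(r_t + x_t δ),   μ*_{t−1} ~ Gamma(a_{t−1}, b_{t−1})
    (a, b) ← (ω a, ω b)   between steps,  ω ∈ (0, 1]

The discount factor ω forgets older observations exponentially (equivalently,
the level receives a Beta(ωa, (1−ω)a) multiplicative shock), which encodes
autocorrelated, non-stationary dynamics; covariates x_t enter log-linearly
with coefficients δ. Conjugacy makes the one-step-ahead predictive negative
binomial in closed form, so the exact likelihood is a single filter pass, and
(ω, δ) are estimated by maximum likelihood. Models are compared with the
small-sample corrected criterion AICc = ((−2L) + 2k) · N/(N − k − 1).

The simulation framework reproduces a full study design: synthetic
environmental series (linear signal + AR(1) noise) are dated with synthetic
radiocarbon assays, calibrated against a calibration curve, bootstrap-resampled
under the stratigraphic ordering constraint with a Gibbs sampler, turned into
monotone age-depth models, and regressed (as re-dated covariates) against
PEWMA-generated count series; a covariate model "hit" is an AICc win over a
constant-only benchmark.

## Worked example

```python
import numpy as np
from chronopewma import (
    EnvParams, simulate_env_series, sample_covariate,
    PewmaParams, simulate_counts, fit_pewma,
)

env = simulate_env_series(EnvParams(innovation_sd=0.1), seed=17)   # 12000-13000 cal BP
cov = sample_covariate(env, 200)                                   # 5-yr covariate grid
true = PewmaParams(omega=0.6, delta=np.array([0.5]))
counts = simulate_counts(cov, true, baseline_mean=10.0, seed=201)

x = (cov.values - cov.values.mean()) / cov.values.std()
fit_cov = fit_pewma(counts, x)
fit_bench = fit_pewma(counts)
print(f"omega={fit_cov.params.omega:.3f} delta={fit_cov.params.delta[0]:.3f}")
print(f"AICc covariate={fit_cov.aicc:.1f} benchmark={fit_bench.aicc:.1f}")
```

```
omega=0.578 delta=0.550
AICc covariate=1370.9 benchmark=1373.5
```

The fit recovers the generating discount factor (0.6) and regression
coefficient (0.5), and the covariate model's AICc beats the constant-only
benchmark by ~2.6 — the environmental driver is detected, though at
this effect size the margin over the benchmark is modest.

A full experiment from the shell (scaled down for illustration):

```bash
chronopewma run-experiment --corr 0.25 --innovation-sd 0.1 --n-dates 5 \
    --n-top 20 --n-boot 50 --seed 7 --out-dir results/
```

prints a JSON summary of the per-pair hit-rate distribution (primary and
secondary histogram modes, variance, quantiles). `chronopewma run-grid`
expands the full 3 noise × 3 date-count × 4 correlation factorial;
`simulate-env`, `calibrate-dates`, and `sample-ages` expose the individual
pipeline stages. By default experiments use a built-in synthetic calibration
curve emulating the 12000–13000 cal BP window; pass `--curve mycurve.14c` to
use a real calibration curve file.

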