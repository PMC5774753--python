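"""PEWMA filtering, maximum-likelihood fitting, and AICc model comparison.

The Poisson Exponentially Weighted Moving Average (PEWMA) model treats an
observed count series y_t as conditionally Poisson with latent mean
μ_t = μ*_{t−1} · exp(r_t + x_t·δ), where the belief about the previous mean
μ*_{t−1} is Gamma(a_{t−1}, b_{t−1}) and is discounted between steps by a
factor ω ∈ (0, 1] — equivalently, the mean receives a Beta-distributed
multiplicative shock each step.  Smaller ω forgets older observations faster,
which is how the model encodes autocorrelated, non-stationary count dynamics.

Because the Gamma prior is conjugate to the Poisson likelihood, the one-step
predictive distribution is negative binomial in closed form and the whole
predictive log-likelihood is a single O(n) filter pass; ω and δ are estimated
by maximising it.  Model comparison uses the small-sample corrected AIC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _filter
from .errors import DegenerateDataError

__all__ = [
    "CountSeries",
    "PewmaParams",
    "PewmaFit",
    "pewma_loglik",
    "fit_pewma",
    "aicc",
    "read_count_series",
    "write_count_series",
]

#: deterministic multi-start grid for the discount factor
OMEGA_STARTS = (0.2, 0.4, 0.6, 0.8, 0.99)


@dataclass(frozen=True)
class CountSeries:
    """Nonnegative-integer event counts with calendar timestamps (time order)."""

    timestamps: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        ts = np.asarray(self.timestamps, dtype=float)
        y = np.asarray(self.counts)
        if ts.shape != y.shape or ts.ndim != 1:
            raise ValueError("timestamps and counts must be equal-length 1-D arrays")
        yf = np.asarray(y, dtype=float)
        if np.any(~np.isfinite(yf)) or np.any(yf < 0) or np.any(yf != np.round(yf)):
            raise DegenerateDataError("counts must be finite nonnegative integers")
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "counts", yf.astype(np.int64))

    def __len__(self) -> int:
        return self.counts.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cal_bp": self.timestamps, "count": self.counts})


@dataclass(frozen=True)
class PewmaParams:
    """PEWMA model parameters: discount factor, regression coefficients, drift."""

    omega: float
    delta: np.ndarray = field(default_factory=lambda: np.zeros(0))
    base_rate: float = 0.0

    def __post_init__(self):
        if not 0.0 < self.omega <= 1.0:
            raise ValueError("omega must be in (0, 1]")
        d = np.atleast_1d(np.asarray(self.delta, dtype=float))
        if np.any(~np.isfinite(d)):
            raise ValueError("delta must be finite")
        object.__setattr__(self, "delta", d)


@dataclass(frozen=True)
class PewmaFit:
    """Result of a maximum-likelihood PEWMA fit."""

    params: PewmaParams
    loglik: float
    n_obs: int
    k: int
    aicc: float
    states: pd.DataFrame = field(repr=False, compare=False)
    converged: bool = True

    def summary(self) -> dict:
        out = {
            "omega": self.params.omega,
            "loglik": self.loglik,
            "n_obs": self.n_obs,
            "k": self.k,
            "aicc": self.aicc,
            "converged": self.converged,
        }
        for j, dj in enumerate(self.params.delta):
            out[f"delta_{j}"] = float(dj)
        return out


def _as_matrix(covariates, n: int) -> np.ndarray:
    """Validate/shape a covariate matrix aligned one-to-one with the counts."""
    if covariates is None:
        return np.zeros((n, 0))
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2 or X.shape[0] != n:
        raise DegenerateDataError(
            f"covariates must align with counts: expected {n} rows, got {X.shape}"
        )
    if np.any(~np.isfinite(X)):
        raise DegenerateDataError("covariates must be finite")
    return X


def default_init(counts: np.ndarray) -> tuple[float, float]:
    """Default Gamma initialisation: prior mean = sample mean, unit prior weight."""
    a0 = float(np.mean(counts))
    if a0 <= 0:
        raise DegenerateDataError("all counts are zero; the latent mean is degenerate")
    return a0, 1.0


def pewma_loglik(
    counts,
    covariates=None,
    params: PewmaParams | None = None,
    init: tuple[float, float] | None = None,
    skip: int = 0,
) -> tuple[float, pd.DataFrame]:
    """Predictive log-likelihood and filtered state trajectory.

    ``counts`` may be a :class:`CountSeries` or a plain integer array; the
    covariate matrix (if any) must have one row per count.  ``init`` is the
    Gamma prior (a0, b0); by default the prior mean equals the sample mean
    with unit prior weight.  ``skip`` excludes that many initial predictive
    terms from the sum (the states are still filtered through them).
    """
    y = counts.counts if isinstance(counts, CountSeries) else CountSeries(
        np.arange(np.asarray(counts).size), counts
    ).counts
    X = _as_matrix(covariates, y.size)
    if params is None:
        params = PewmaParams(omega=1.0)
    delta = params.delta
    if delta.size != X.shape[1]:
        if delta.size == 0 and X.shape[1] > 0:
            delta = np.zeros(X.shape[1])
        else:
            raise DegenerateDataError(
                f"delta has {delta.size} coefficients for {X.shape[1]} covariate columns"
            )
    a0, b0 = default_init(y) if init is None else (float(init[0]), float(init[1]))
    if a0 <= 0 or b0 <= 0:
        raise ValueError("init (a0, b0) must both be > 0")
    yf = y.astype(np.float64)
    ll = _filter.filter_loglik(
        yf, X, delta, params.omega, params.base_rate, a0, b0, int(skip)
    )
    a_tr, b_tr = _filter.filter_states(yf, X, delta, params.omega, params.base_rate, a0, b0)
    states = pd.DataFrame({"a": a_tr, "b": b_tr, "latent_mean": a_tr / b_tr})
    return float(ll), states


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike information criterion.

    ``((−2·L) + 2·k) · n / (n − k − 1)``, where k counts the covariates and n
    the observations; lower is better.  Requires n − k − 1 > 0.
    """
    if n - k - 1 <= 0:
        raise ValueError(f"AICc needs n - k - 1 > 0, got n={n}, k={k}")
    return ((-2.0 * loglik) + 2.0 * k) * n / (n - k - 1)


def fit_pewma(
    counts,
    covariates=None,
    skip: int = 0,
    base_rate: float = 0.0,
    init: tuple[float, float] | None = None,
    omega_starts=OMEGA_STARTS,
    ftol: float = 1e-10,
    xtol: float = 1e-6,
    max_iter: int = 600,
) -> PewmaFit:
    """Maximum-likelihood PEWMA fit.

    Jointly maximises the predictive log-likelihood over the discount factor
    ω — logit-transformed onto (0.01, 1) — and the regression coefficients δ,
    by Nelder–Mead simplex search from each of the deterministic ω starts
    (δ = 0).  The best optimum is returned with its AICc, where k is the
    number of covariate columns.  A fit that met the convergence tolerance
    from no start is returned with ``converged=False``.
    """
    series = counts if isinstance(counts, CountSeries) else CountSeries(
        np.arange(np.asarray(counts).size), counts
    )
    y = series.counts
    if y.size < 10:
        raise DegenerateDataError(f"series too short to fit ({y.size} < 10)")
    X = _as_matrix(covariates, y.size)
    a0, b0 = default_init(y) if init is None else (float(init[0]), float(init[1]))
    starts_u = np.array([_filter.u_from_omega(w) for w in omega_starts])
    yf = y.astype(np.float64)
    theta, neg_ll, converged = _filter.multistart_fit(
        yf, X, float(base_rate), a0, b0, int(skip), starts_u, ftol, xtol, int(max_iter)
    )
    omega = _filter.omega_from_u(theta[0])
    delta = np.asarray(theta[1:], dtype=float)
    params = PewmaParams(omega=omega, delta=delta, base_rate=base_rate)
    ll = -float(neg_ll)
    k = X.shape[1]
    a_tr, b_tr = _filter.filter_states(yf, X, delta, omega, base_rate, a0, b0)
    states = pd.DataFrame({"a": a_tr, "b": b_tr, "latent_mean": a_tr / b_tr})
    return PewmaFit(
        params=params,
        loglik=ll,
        n_obs=int(y.size),
        k=k,
        aicc=aicc(ll, k, int(y.size)),
        states=states,
        converged=bool(converged),
    )


def read_count_series(path) -> CountSeries:
    """Read a (timestamp, count) series from delimited text ('#' comments)."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    if df.shape[1] < 2:
        raise DegenerateDataError(f"{path}: expected two columns (timestamp, count)")
    return CountSeries(df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy())


def write_count_series(series: CountSeries, path) -> None:
    series.to_frame().to_csv(path, index=False)
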