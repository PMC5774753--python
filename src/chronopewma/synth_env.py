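"""Synthetic palaeoenvironmental series: linear signal + AR(1) noise.

The study conditions are a gently rising environmental signal over
12000–13000 cal BP — slope 0.01 units per year — with stationary AR(1) noise
(lag-1 autocorrelation 0.7) whose innovation standard deviation is one of
{1, 0.1, 0.01}.  Those three noise levels are referred to by their categorical
signal-to-noise labels SNR ∈ {1, 10, 100}.

Positions increase toward the past: an observation at calendar age θ cal BP
has position θ − span_young, so position 0 is the young end of the span and
the deepest (oldest) sample has the largest position.  Series arrays run in
time order, oldest observation first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError
from .radiocarbon import CalibrationCurve, RadiocarbonDate, back_calibrate

__all__ = [
    "EnvParams",
    "EnvSeries",
    "SNR_LABELS",
    "simulate_env_series",
    "sample_covariate",
    "place_dated_horizons",
    "make_synthetic_c14_dates",
    "write_env_series",
    "read_env_series",
]

#: categorical aliases: SNR label -> AR-innovation standard deviation
SNR_LABELS = {1: 1.0, 10: 0.1, 100: 0.01}


@dataclass(frozen=True)
class EnvParams:
    """Generator settings for one synthetic environmental series.

    ``span`` is (young, old) in cal BP; the series holds ``n_points``
    observations on an annual grid starting at the old end (start-year
    inclusive).  ``slope`` is in signal units per elapsed year, ``phi`` the
    AR(1) lag-1 autocorrelation, ``innovation_sd`` the standard deviation of
    the AR innovations.
    """

    span: tuple[float, float] = (12000.0, 13000.0)
    slope: float = 0.01
    phi: float = 0.7
    innovation_sd: float = 1.0
    n_points: int = 1000

    def __post_init__(self):
        if not abs(self.phi) < 1:
            raise ValueError("phi must satisfy |phi| < 1 (stationarity)")
        if self.innovation_sd < 0:
            raise ValueError("innovation_sd must be >= 0")
        if not np.isfinite(self.slope):
            raise ValueError("slope must be finite")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        lo, hi = min(self.span), max(self.span)
        if not hi > lo:
            raise ValueError("span must be a nonempty interval")
        object.__setattr__(self, "span", (float(lo), float(hi)))


@dataclass(frozen=True)
class EnvSeries:
    """A proxy series with exactly known (true) calendar timestamps.

    ``true_ages`` are cal BP in time order (decreasing: oldest first);
    ``positions`` are the corresponding depths, decreasing along the arrays.
    ``provenance`` records how the series was made (seed, stride, parents).
    """

    true_ages: np.ndarray
    values: np.ndarray
    params: EnvParams
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        ages = np.asarray(self.true_ages, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if ages.shape != vals.shape or ages.ndim != 1:
            raise ValueError("true_ages and values must be equal-length 1-D arrays")
        d = np.diff(ages)
        if ages.size > 1 and not (np.all(d < 0) or np.all(d > 0)):
            raise ValueError("true_ages must be strictly monotone")
        object.__setattr__(self, "true_ages", ages)
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.true_ages.size

    @property
    def positions(self) -> np.ndarray:
        """Depth coordinate: years above the young end of the span."""
        return self.true_ages - self.params.span[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cal_bp": self.true_ages,
                "position": self.positions,
                "value": self.values,
            }
        )


def simulate_env_series(params: EnvParams, seed: int = 0) -> EnvSeries:
    """Simulate one environmental series: linear ramp plus stationary AR(1).

    values[t] = slope · (elapsed years since the old end) + e[t] with
    e[t] = phi · e[t−1] + N(0, innovation_sd²), e[0] drawn from the stationary
    distribution N(0, innovation_sd² / (1 − phi²)) so short series carry no
    start-up transient.  With ``innovation_sd = 0`` the output is the pure
    ramp and is identical for every seed.
    """
    rng = np.random.default_rng(seed)
    _, old = params.span
    ages = old - np.arange(params.n_points, dtype=float)  # annual, oldest first
    signal = params.slope * (old - ages)
    if params.innovation_sd == 0.0:
        noise = np.zeros(params.n_points)
    else:
        stat_sd = params.innovation_sd / np.sqrt(1.0 - params.phi**2)
        innov = rng.normal(0.0, params.innovation_sd, size=params.n_points)
        noise = np.empty(params.n_points)
        noise[0] = rng.normal(0.0, stat_sd)
        for t in range(1, params.n_points):
            noise[t] = params.phi * noise[t - 1] + innov[t]
    return EnvSeries(
        ages, signal + noise, params, provenance={"seed": int(seed), "kind": "full"}
    )


def sample_covariate(env: EnvSeries, n_samples: int) -> EnvSeries:
    """Evenly strided subsample of an environmental series.

    The stride is the nearest integer to ``(len − 1)/(n_samples − 1)`` (at
    least 1); when that ratio is an integer both endpoints are included,
    otherwise the subsample starts at the first observation and the applied
    stride is recorded in provenance.  Sampled values and true ages are taken
    from the source arrays unchanged.
    """
    n = len(env)
    if not 2 <= n_samples <= n:
        raise ValueError(f"n_samples must be in [2, {n}], got {n_samples}")
    stride = max(1, int(round((n - 1) / (n_samples - 1))))
    idx = np.arange(n_samples) * stride
    if idx[-1] > n - 1:  # rounding overshoot: fall back to the floor stride
        stride = (n - 1) // (n_samples - 1)
        idx = np.arange(n_samples) * stride
    prov = dict(env.provenance)
    prov.update(
        {
            "kind": "covariate",
            "stride": int(stride),
            "exact_stride": bool((n - 1) % (n_samples - 1) == 0),
        }
    )
    return EnvSeries(env.true_ages[idx], env.values[idx], env.params, provenance=prov)


def place_dated_horizons(
    span: tuple[float, float], n_dates: int
) -> tuple[np.ndarray, np.ndarray]:
    """Evenly spaced dated horizons across a span, endpoints included.

    Returns ``(positions, true_ages)`` ordered young → old (ascending cal BP),
    the order in which the chronological bootstrap consumes them.  Positions
    use the same depth convention as :class:`EnvSeries` (years above the young
    end of the span).
    """
    if n_dates < 2:
        raise ValueError("n_dates must be >= 2")
    lo, hi = float(min(span)), float(max(span))
    ages = np.linspace(lo, hi, n_dates)
    positions = ages - lo
    return positions, ages


def make_synthetic_c14_dates(
    curve: CalibrationCurve,
    true_ages,
    lab_error: float = 50.0,
    positions=None,
) -> list[RadiocarbonDate]:
    """Manufacture synthetic radiocarbon assays from known calendar ages.

    Each assay's measured age is the back-calibrated curve value at the true
    calendar age — the measurement itself is not perturbed, so calibration is
    the only source of chronological error — and every assay carries the same
    laboratory error (default ±50 radiocarbon years).
    """
    ages = np.asarray(true_ages, dtype=float)
    if positions is None:
        positions = np.arange(ages.size, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if positions.shape != ages.shape:
        raise ValueError("positions must match true_ages in length")
    dates = []
    for age, pos in zip(ages, positions):
        c14 = back_calibrate(curve, age)  # raises DomainError outside span
        dates.append(RadiocarbonDate(c14_age=c14, lab_error=float(lab_error), position=float(pos)))
    return dates


def write_env_series(env: EnvSeries, path) -> None:
    """Write a series as delimited text with a '#'-prefixed provenance header."""
    import json

    with open(path, "wt", encoding="utf-8") as fh:
        meta = {
            "span": list(env.params.span),
            "slope": env.params.slope,
            "phi": env.params.phi,
            "innovation_sd": env.params.innovation_sd,
            "n_points": env.params.n_points,
            **env.provenance,
        }
        fh.write(f"# chronopewma env-series {json.dumps(meta)}\n")
        env.to_frame().to_csv(fh, index=False)


def read_env_series(path) -> EnvSeries:
    """Read a series written by :func:`write_env_series` (provenance restored)."""
    import json

    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline()
    prefix = "# chronopewma env-series "
    if not header.startswith(prefix):
        raise ValueError(f"{path}: missing env-series provenance header")
    meta = json.loads(header[len(prefix):])
    params = EnvParams(
        span=tuple(meta.pop("span")),
        slope=meta.pop("slope"),
        phi=meta.pop("phi"),
        innovation_sd=meta.pop("innovation_sd"),
        n_points=meta.pop("n_points"),
    )
    df = pd.read_csv(path, comment="#")
    return EnvSeries(
        df["cal_bp"].to_numpy(float), df["value"].to_numpy(float), params,
        provenance=meta,
    )
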