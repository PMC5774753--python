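"""Radiocarbon calibration, back-calibration, and chronological bootstrap.

Calendar ages are expressed in calendar years before present (cal BP,
present = 1950 CE) and radiocarbon ages in conventional radiocarbon years BP.
A calibration curve maps calendar age θ to the radiocarbon age μ(θ) expected
for a sample of that age, with a 1σ curve error σ_curve(θ).  Calibrating a
laboratory measurement y ± σ_lab produces a probability density over calendar
ages; back-calibration is the deterministic reverse lookup μ(θ*) used to
manufacture synthetic assays from known calendar ages.

Positions (depths) increase toward the past: a sample with a larger position
is stratigraphically older and must receive an older (larger) cal BP age.
The order-constrained Gibbs sampler and the monotone age-depth interpolant
enforce that superposition constraint for every bootstrap draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .errors import (
    CurveParseError,
    DomainError,
    IncompatibleDateError,
    InfeasibleOrderingError,
    InsufficientDataError,
)

__all__ = [
    "CalibrationCurve",
    "RadiocarbonDate",
    "CalibratedDensity",
    "AgeModel",
    "read_calibration_curve",
    "write_calibration_curve",
    "synthesize_curve",
    "back_calibrate",
    "calibrate",
    "sample_ordered_calendar_ages",
    "build_age_model",
    "apply_age_model",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CalibrationCurve:
    """Gridded calendar-age → radiocarbon-age mapping with 1σ curve error.

    Arrays are stored ascending in cal BP regardless of input order.
    """

    cal_age_grid: np.ndarray
    c14_age: np.ndarray
    curve_error: np.ndarray

    def __post_init__(self):
        cal = np.asarray(self.cal_age_grid, dtype=float)
        c14 = np.asarray(self.c14_age, dtype=float)
        err = np.asarray(self.curve_error, dtype=float)
        if not (cal.shape == c14.shape == err.shape) or cal.ndim != 1:
            raise ValueError("curve arrays must be 1-D and of equal length")
        if cal.size < 2:
            raise InsufficientDataError(
                f"calibration curve needs >= 2 grid points, got {cal.size}"
            )
        order = np.argsort(cal, kind="stable")
        cal, c14, err = cal[order], c14[order], err[order]
        if np.any(np.diff(cal) <= 0):
            raise ValueError("cal_age_grid must be strictly monotone")
        if np.any(err < 0):
            raise ValueError("curve_error must be nonnegative")
        object.__setattr__(self, "cal_age_grid", cal)
        object.__setattr__(self, "c14_age", c14)
        object.__setattr__(self, "curve_error", err)

    @property
    def span(self) -> tuple[float, float]:
        """(youngest, oldest) cal BP covered by the curve."""
        return float(self.cal_age_grid[0]), float(self.cal_age_grid[-1])

    def __len__(self) -> int:
        return self.cal_age_grid.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cal_bp": self.cal_age_grid,
                "c14_bp": self.c14_age,
                "sigma": self.curve_error,
            }
        )


@dataclass(frozen=True)
class RadiocarbonDate:
    """One conventional radiocarbon measurement attached to a series position."""

    c14_age: float
    lab_error: float
    position: float = 0.0

    def __post_init__(self):
        if not np.isfinite(self.c14_age):
            raise ValueError("c14_age must be finite")
        if not self.lab_error > 0:
            raise ValueError("lab_error must be > 0")
        if self.position < 0:
            raise ValueError("position must be nonnegative")


@dataclass(frozen=True)
class CalibratedDensity:
    """Normalized posterior probability over a calendar-age grid for one date.

    ``mass[j]`` is the probability of the grid cell centred on
    ``cal_age_grid[j]``; the cells are equal width and the masses sum to 1.
    """

    cal_age_grid: np.ndarray
    mass: np.ndarray

    def __post_init__(self):
        grid = np.asarray(self.cal_age_grid, dtype=float)
        mass = np.asarray(self.mass, dtype=float)
        if grid.shape != mass.shape or grid.ndim != 1 or grid.size < 1:
            raise ValueError("grid and mass must be equal-length 1-D arrays")
        if np.any(mass < 0):
            raise ValueError("mass must be nonnegative")
        total = mass.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mass must sum to 1 +/- 1e-9, got {total!r}")
        object.__setattr__(self, "cal_age_grid", grid)
        object.__setattr__(self, "mass", mass)

    @property
    def grid_step(self) -> float:
        if self.cal_age_grid.size == 1:
            return 1.0
        return float(self.cal_age_grid[1] - self.cal_age_grid[0])

    @property
    def mean(self) -> float:
        return float(np.sum(self.cal_age_grid * self.mass))

    @property
    def mode(self) -> float:
        return float(self.cal_age_grid[int(np.argmax(self.mass))])

    @property
    def sd(self) -> float:
        m = self.mean
        return float(np.sqrt(np.sum(self.mass * (self.cal_age_grid - m) ** 2)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cal_bp": self.cal_age_grid, "probability": self.mass})


@dataclass(frozen=True)
class AgeModel:
    """Monotone position → calendar-age interpolant through dated anchors."""

    anchor_positions: np.ndarray
    anchor_ages: np.ndarray
    interpolant: PchipInterpolator = field(repr=False, compare=False, default=None)

    def __call__(self, positions) -> np.ndarray:
        return apply_age_model(self, positions)


# ---------------------------------------------------------------------------
# curve I/O and synthesis
# ---------------------------------------------------------------------------

#: recognised column orders for three-column ".14c" style files
_DIALECTS = {
    "calbp_c14_sigma": (0, 1, 2),
}


def read_calibration_curve(path, dialect: str = "calbp_c14_sigma") -> CalibrationCurve:
    """Read a calibration curve from a ``.14c``-style delimited text file.

    Lines starting with ``#`` are comments; records may be comma- or
    whitespace-separated with at least three numeric columns
    (cal BP, conventional 14C age BP, 1σ curve error).  Any further columns
    (Δ14C and its error in the standard distribution files) are ignored.
    The returned curve is sorted ascending in cal BP whatever the file order.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    cols = _DIALECTS[dialect]
    cal, c14, err = [], [], []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.replace(",", " ").split()
            if len(fields) < 3:
                raise CurveParseError(
                    path, lineno, f"expected >= 3 columns, got {len(fields)}"
                )
            try:
                values = [float(fields[c]) for c in cols]
            except ValueError as exc:
                raise CurveParseError(path, lineno, f"malformed numeric field: {exc}")
            cal.append(values[0])
            c14.append(values[1])
            err.append(values[2])
    if len(cal) < 2:
        raise InsufficientDataError(
            f"{path}: calibration curve needs >= 2 usable records, got {len(cal)}"
        )
    return CalibrationCurve(np.array(cal), np.array(c14), np.array(err))


def write_calibration_curve(curve: CalibrationCurve, path, comment: str = "") -> None:
    """Write a curve in the comma-separated three-column ``.14c`` dialect."""
    with open(path, "wt", encoding="utf-8") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("# cal BP, 14C age BP, sigma\n")
        for cal, c14, err in zip(curve.cal_age_grid, curve.c14_age, curve.curve_error):
            fh.write(f"{float(cal)!r},{float(c14)!r},{float(err)!r}\n")


def synthesize_curve(
    span: tuple[float, float],
    base_offset: float = 0.0,
    wiggle_amplitude: float = 0.0,
    wiggle_period: float = 500.0,
    error_level: float = 0.0,
    step: float = 5.0,
) -> CalibrationCurve:
    """Deterministic sinusoidal-wiggle calibration curve for simulations.

    ``μ(θ) = θ − base_offset + wiggle_amplitude · sin(2πθ / wiggle_period)``
    with constant 1σ curve error ``error_level``.  A wiggle steep enough that
    ``wiggle_amplitude · 2π / wiggle_period > 1`` produces reversals — several
    calendar ages sharing one radiocarbon age — which is the feature of real
    curves that makes calibrated densities irregular and multimodal.
    """
    lo, hi = float(min(span)), float(max(span))
    if not hi > lo:
        raise ValueError("span must be a nonempty interval")
    if not step > 0:
        raise ValueError("step must be > 0")
    if error_level < 0:
        raise ValueError("error_level must be >= 0")
    if wiggle_amplitude != 0.0 and wiggle_period == 0.0:
        raise ValueError("wiggle_period must be nonzero when wiggle_amplitude != 0")
    n = int(round((hi - lo) / step)) + 1
    grid = lo + step * np.arange(n)
    if wiggle_amplitude == 0.0:
        wiggle = np.zeros_like(grid)
    else:
        wiggle = wiggle_amplitude * np.sin(2.0 * np.pi * grid / wiggle_period)
    c14 = grid - base_offset + wiggle
    err = np.full_like(grid, float(error_level))
    return CalibrationCurve(grid, c14, err)


# ---------------------------------------------------------------------------
# calibration and back-calibration
# ---------------------------------------------------------------------------


def back_calibrate(curve: CalibrationCurve, cal_age: float) -> float:
    """Radiocarbon age on the curve at a known calendar age (reverse lookup).

    Piecewise-linear interpolation of μ(θ); no extrapolation outside the span.
    """
    lo, hi = curve.span
    cal_age = float(cal_age)
    if not (lo <= cal_age <= hi):
        raise DomainError(
            f"cal_age {cal_age} outside curve span [{lo}, {hi}] (no extrapolation)"
        )
    return float(np.interp(cal_age, curve.cal_age_grid, curve.c14_age))


def calibrate(
    curve: CalibrationCurve, date: RadiocarbonDate, grid_step: float = 1.0
) -> CalibratedDensity:
    """Calibrate one radiocarbon date to a density over calendar ages.

    Standard gridded Gaussian-measurement posterior: on a calendar grid over
    the curve span with spacing ``grid_step``,

        mass(θ) ∝ N(y; μ(θ), σ_lab² + σ_curve(θ)²),

    normalized to sum to one.  The varying total standard deviation enters the
    Gaussian normalisation, so stretches where the curve is poorly known are
    correctly down-weighted.
    """
    if not grid_step > 0:
        raise ValueError("grid_step must be > 0")
    lo, hi = curve.span
    n = int(np.floor((hi - lo) / grid_step)) + 1
    grid = lo + grid_step * np.arange(n)
    mu = np.interp(grid, curve.cal_age_grid, curve.c14_age)
    sig_curve = np.interp(grid, curve.cal_age_grid, curve.curve_error)
    var = date.lab_error**2 + sig_curve**2
    # log-density for numerical stability far out in the tails
    logd = -0.5 * (date.c14_age - mu) ** 2 / var - 0.5 * np.log(var)
    logd -= logd.max()
    unnorm = np.exp(logd)
    total = unnorm.sum()
    # an absolute floor on the *unscaled* total mass: if even the best grid
    # point is > ~37 sigma away the date is simply incompatible with the span
    peak = -0.5 * (date.c14_age - mu) ** 2 / var
    if np.exp(peak.max()) * total < 1e-300 or not np.isfinite(total) or total <= 0:
        raise IncompatibleDateError(
            f"date {date.c14_age} +/- {date.lab_error} 14C BP has no support on "
            f"curve span [{lo}, {hi}] cal BP"
        )
    return CalibratedDensity(grid, unnorm / total)


# ---------------------------------------------------------------------------
# order-constrained Gibbs bootstrap
# ---------------------------------------------------------------------------


def _edge_cdf(density: CalibratedDensity) -> tuple[np.ndarray, np.ndarray]:
    """Cell-edge grid and CDF treating the density as piecewise constant."""
    h = density.grid_step
    edges = np.concatenate(
        [density.cal_age_grid - 0.5 * h, [density.cal_age_grid[-1] + 0.5 * h]]
    )
    cdf = np.concatenate([[0.0], np.cumsum(density.mass)])
    cdf[-1] = 1.0
    return edges, cdf


def _truncated_draw(edges, cdf, lo, hi, u) -> float:
    """Inverse-CDF draw from the piecewise-constant density restricted to [lo, hi].

    Returns NaN when the restriction carries (numerically) no mass.
    """
    flo = np.interp(lo, edges, cdf)
    fhi = np.interp(hi, edges, cdf)
    if fhi - flo <= 1e-300:
        return np.nan
    target = flo + u * (fhi - flo)
    age = np.interp(target, cdf, edges)
    # guard against flat CDF stretches landing an epsilon outside the bounds
    return float(min(max(age, lo), hi))


def sample_ordered_calendar_ages(
    densities: list[CalibratedDensity],
    n_draws: int,
    burn_in: int = 100,
    thin: int = 1,
    seed: int = 0,
) -> np.ndarray:
    """Draw jointly ordered calendar-age vectors from per-date densities.

    The densities must be supplied in position order (shallow → deep, i.e.
    young → old); every returned vector is strictly increasing in cal BP, so
    stratigraphic superposition is preserved in each bootstrap replicate.

    A systematic-sweep Gibbs sampler updates each date in turn from its
    calibrated density truncated to the open interval between its current
    neighbours, keeping a minimum gap of one grid cell.  The chain starts from
    the per-date density modes repaired to an ordered configuration by
    sequential clamping.  Returns an ``(n_draws, k)`` array.
    """
    if not densities:
        raise ValueError("densities must be nonempty")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if thin < 1:
        raise ValueError("thin must be >= 1")
    k = len(densities)
    rng = np.random.default_rng(seed)
    gap = max(d.grid_step for d in densities)
    supports_lo = np.array([d.cal_age_grid[0] for d in densities])
    supports_hi = np.array([d.cal_age_grid[-1] for d in densities])
    edges_cdfs = [_edge_cdf(d) for d in densities]

    # feasibility: the tightest ordered configuration respecting supports
    lower = np.empty(k)
    lower[0] = supports_lo[0]
    for i in range(1, k):
        lower[i] = max(supports_lo[i], lower[i - 1] + gap)
        if lower[i] > supports_hi[i]:
            raise InfeasibleOrderingError(
                f"no strictly ordered configuration exists: date {i} cannot be "
                f"placed at or above {lower[i]:.1f} cal BP within its support "
                f"[{supports_lo[i]:.1f}, {supports_hi[i]:.1f}]"
            )

    # initial state: modes, sequentially clamped into an ordered configuration
    state = np.array([d.mode for d in densities], dtype=float)
    for i in range(k):
        lo = lower[i] if i == 0 else max(lower[i], state[i - 1] + gap)
        state[i] = min(max(state[i], lo), supports_hi[i])
    # a final backward pass in case clamping forward pushed a date past a
    # tight upper neighbourhood (cannot happen when lower[] is feasible, but
    # keeps the invariant explicit)
    for i in range(k - 2, -1, -1):
        state[i] = min(state[i], state[i + 1] - gap)

    draws = np.empty((n_draws, k))
    total_sweeps = burn_in + n_draws * thin
    kept = 0
    for sweep in range(total_sweeps):
        for i in range(k):
            lo = state[i - 1] + gap if i > 0 else supports_lo[i] - 0.5 * gap
            hi = state[i + 1] - gap if i < k - 1 else supports_hi[i] + 0.5 * gap
            edges, cdf = edges_cdfs[i]
            age = _truncated_draw(edges, cdf, lo, hi, rng.random())
            if not np.isnan(age):
                state[i] = age
            # NaN: the truncation interval carries no mass, keep current value
        if sweep >= burn_in and (sweep - burn_in) % thin == 0:
            draws[kept] = state
            kept += 1
    assert kept == n_draws
    return draws


# ---------------------------------------------------------------------------
# age-depth models
# ---------------------------------------------------------------------------


def build_age_model(anchor_positions, anchor_ages) -> AgeModel:
    """Monotone cubic age-depth model through dated anchors.

    Uses the Fritsch–Carlson monotonicity-preserving cubic Hermite
    construction (PCHIP): exact at the anchors and monotone everywhere in
    between, so one bootstrap draw of anchor ages yields one internally
    consistent chronology with no age inversions.
    """
    pos = np.asarray(anchor_positions, dtype=float)
    ages = np.asarray(anchor_ages, dtype=float)
    if pos.ndim != 1 or pos.shape != ages.shape or pos.size < 2:
        raise ValueError("need >= 2 anchors with matching positions and ages")
    if np.any(np.diff(pos) <= 0):
        raise ValueError("anchor positions must be strictly increasing (no ties)")
    if np.any(np.diff(ages) < 0):
        raise ValueError("anchor ages must be ordered consistently with positions")
    interp = PchipInterpolator(pos, ages, extrapolate=False)
    return AgeModel(pos, ages, interp)


def apply_age_model(model: AgeModel, positions) -> np.ndarray:
    """Evaluate an age-depth model; queries outside the anchor span are errors."""
    q = np.asarray(positions, dtype=float)
    lo, hi = model.anchor_positions[0], model.anchor_positions[-1]
    if np.any(q < lo) or np.any(q > hi):
        raise DomainError(
            f"position outside anchor span [{lo}, {hi}] (no extrapolation)"
        )
    return np.asarray(model.interpolant(q), dtype=float)
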