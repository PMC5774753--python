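"""The hit-rate simulation study: top-level pairs, chronological bootstrap,
AICc benchmark comparisons, and hit-rate distributions.

One *top-level pair* is a simulated environmental series and the count series
it generated.  The environmental series is dated the way real archives are:
evenly spaced horizons are back-calibrated into synthetic radiocarbon assays,
calibrated, and bootstrap-resampled under the stratigraphic ordering
constraint; each resampled set of anchor ages yields a monotone age-depth
model and hence one re-timestamped *sub-pair*.  For every sub-pair, a PEWMA
regression with the (re-dated, interpolated, standardized) environmental
covariate competes on AICc against a constant-only PEWMA benchmark; a win is
a *hit*.  The fraction of hits over a pair's bootstrap ensemble is its hit
rate, and the distribution of hit rates over pairs is the experiment's
result: at zero underlying correlation it measures the false-positive rate,
at positive correlation the power.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ChronoPewmaError
from .pewma import CountSeries, PewmaParams, aicc, fit_pewma
from .radiocarbon import (
    CalibrationCurve,
    build_age_model,
    calibrate,
    read_calibration_curve,
    sample_ordered_calendar_ages,
    synthesize_curve,
)
from .simulate import SimDesign, calibrate_delta, simulate_counts, standardize
from .synth_env import (
    EnvParams,
    EnvSeries,
    make_synthetic_c14_dates,
    place_dated_horizons,
    sample_covariate,
    simulate_env_series,
)

__all__ = [
    "ExperimentConfig",
    "SubPairResult",
    "TopPairResult",
    "HitRateDistribution",
    "resolve_curve",
    "decide_hit",
    "run_sub_pair",
    "run_top_pair",
    "run_experiment",
    "run_grid",
    "expand_grid",
    "summarize",
    "scheduled_analyses",
]

#: default synthetic stand-in for the early-Younger-Dryas calibration-curve
#: segment: ~1850 14C yr offset, wiggles steep enough for mild reversals and
#: plateaus, constant 40 yr 1σ curve error, 5-yr grid, padded past the span.
DEFAULT_FIXTURE = (
    "fixture:span=11800:13200,offset=1850,amplitude=55,period=310,error=40,step=5"
)


@dataclass(frozen=True)
class ExperimentConfig:
    """Free and fixed parameters of one experiment.

    Free parameters (the study grid): ``corr`` target covariate-count
    correlation, ``innovation_sd`` environmental noise level, ``n_dates``
    dated horizons.  Fixed parameters default to the study conditions:
    1000 top-level pairs x 2000 bootstrap sub-pairs over 12000-13000 cal BP,
    slope 0.01/yr, AR(1) autocorrelation 0.7, discount factor 0.6, 200 count
    observations, +/-50 yr laboratory error.
    """

    corr: float = 0.0
    innovation_sd: float = 1.0
    n_dates: int = 5
    n_top: int = 1000
    n_boot: int = 2000
    aic_buffer: float = 0.0
    curve_source: str = DEFAULT_FIXTURE
    seed: int = 0
    # fixed study conditions
    span: tuple[float, float] = (12000.0, 13000.0)
    slope: float = 0.01
    phi: float = 0.7
    omega: float = 0.6
    n_env_points: int = 1000
    n_samples: int = 200
    lab_error: float = 50.0
    baseline_mean: float = 10.0
    grid_step: float = 1.0
    chrono_uncertainty: bool = True
    #: hook for future work: radiocarbon error on the dependent series
    date_dependent_series: bool = False

    def __post_init__(self):
        if self.n_top < 1 or self.n_boot < 1:
            raise ValueError("n_top and n_boot must be >= 1")
        if self.aic_buffer < 0:
            raise ValueError("aic_buffer must be >= 0")
        if self.date_dependent_series:
            raise NotImplementedError(
                "radiocarbon uncertainty on the dependent series is a config "
                "hook only; it is not implemented"
            )

    def label(self) -> str:
        return (
            f"corr{self.corr:g}_sd{self.innovation_sd:g}_dates{self.n_dates}"
            f"_top{self.n_top}_boot{self.n_boot}"
        )


@dataclass(frozen=True)
class SubPairResult:
    """AICc comparison of one bootstrap sub-pair."""

    aicc_cov: float
    aicc_bench: float
    hit: bool
    valid: bool = True


@dataclass(frozen=True)
class TopPairResult:
    """Hit fraction of one top-level pair over its bootstrap ensemble."""

    hit_fraction: float
    n_valid: int
    n_invalid: int
    delta: float
    flagged: bool  # > 10% of sub-pairs invalid


@dataclass(frozen=True)
class HitRateDistribution:
    """Per-top-level-pair hit fractions for one experiment."""

    hit_fractions: np.ndarray
    config: ExperimentConfig
    n_invalid: np.ndarray = field(default=None, compare=False)
    flagged: np.ndarray = field(default=None, compare=False)

    def __post_init__(self):
        hf = np.asarray(self.hit_fractions, dtype=float)
        if np.any(hf < 0) or np.any(hf > 1):
            raise ValueError("hit fractions must lie in [0, 1]")
        object.__setattr__(self, "hit_fractions", hf)

    def __len__(self) -> int:
        return self.hit_fractions.size

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"pair": np.arange(len(self)), "hit_fraction": self.hit_fractions}
        )
        if self.n_invalid is not None:
            df["n_invalid"] = self.n_invalid
        if self.flagged is not None:
            df["flagged"] = self.flagged
        return df


# ---------------------------------------------------------------------------
# curve sources
# ---------------------------------------------------------------------------


def resolve_curve(curve_source: str) -> CalibrationCurve:
    """Resolve a curve source: a ``.14c`` file path or a ``fixture:`` spec.

    Fixture specs look like
    ``fixture:span=11800:13200,offset=1850,amplitude=55,period=310,error=40,step=5``
    (any field may be omitted; ``fixture:default`` gives the package default,
    ``fixture:identity`` an identity curve with zero error over the default
    span).
    """
    if not curve_source.startswith("fixture:"):
        return read_calibration_curve(curve_source)
    spec = curve_source[len("fixture:") :]
    if spec == "default":
        spec = DEFAULT_FIXTURE[len("fixture:") :]
    params = {
        "span": (11800.0, 13200.0),
        "offset": 0.0,
        "amplitude": 0.0,
        "period": 500.0,
        "error": 0.0,
        "step": 5.0,
    }
    if spec != "identity":
        for item in spec.split(","):
            if not item:
                continue
            key, _, value = item.partition("=")
            key = key.strip()
            if key not in params:
                raise ValueError(f"unknown fixture field {key!r} in {curve_source!r}")
            if key == "span":
                lo, _, hi = value.partition(":")
                params["span"] = (float(lo), float(hi))
            else:
                params[key] = float(value)
    return synthesize_curve(
        span=params["span"],
        base_offset=params["offset"],
        wiggle_amplitude=params["amplitude"],
        wiggle_period=params["period"],
        error_level=params["error"],
        step=params["step"],
    )


# ---------------------------------------------------------------------------
# seeding: counter-based derivation from one master seed
# ---------------------------------------------------------------------------

_STREAM_ENV = 0
_STREAM_DELTA = 1
_STREAM_COUNTS = 2
_STREAM_GIBBS = 3


def derive_seed(master_seed: int, pair_index: int, stream: int) -> int:
    """Deterministic child seed for (pair, stream); any sub-computation is
    reproducible in isolation from the master seed and its counters."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(int(pair_index), int(stream)))
    return int(ss.generate_state(1)[0])


# ---------------------------------------------------------------------------
# sub-pair and top-pair analyses
# ---------------------------------------------------------------------------


def align_covariate(counts: CountSeries, env_boot: EnvSeries) -> np.ndarray:
    """Interpolate a (re-timestamped) environmental series onto the count grid.

    Linear interpolation in calendar age; count timestamps outside the
    bootstrap age range take the nearest edge value.  Returns standardized
    covariate values aligned one-to-one with the counts.
    """
    ages = env_boot.true_ages
    vals = env_boot.values
    order = np.argsort(ages)
    x = np.interp(counts.timestamps, ages[order], vals[order])
    return standardize(x)


def decide_hit(aicc_cov: float, aicc_bench: float, aic_buffer: float = 0.0) -> bool:
    """Hit rule: the covariate model must beat the benchmark by more than the
    buffer; a tie is not a hit."""
    return bool(aicc_cov < aicc_bench - aic_buffer)


def run_sub_pair(
    counts: CountSeries,
    env_boot: EnvSeries,
    aic_buffer: float = 0.0,
    bench_aicc: float | None = None,
) -> SubPairResult:
    """AICc contest between the covariate model and the constant-only benchmark.

    The bootstrapped environmental values are interpolated onto the count
    series' calendar timestamps, standardized, and fitted as the single
    covariate.  A hit requires ``aicc_cov < aicc_bench - aic_buffer``
    (strict: a tie is not a hit).  The benchmark does not depend on the
    bootstrap draw, so callers running many sub-pairs of one top-level pair
    may pass its AICc in.
    """
    x = align_covariate(counts, env_boot)
    fit_cov = fit_pewma(counts, x)
    if bench_aicc is None:
        fit_bench = fit_pewma(counts)
        if not fit_bench.converged:
            return SubPairResult(np.nan, np.nan, False, valid=False)
        bench_aicc = fit_bench.aicc
    if not fit_cov.converged:
        return SubPairResult(np.nan, float(bench_aicc), False, valid=False)
    hit = decide_hit(fit_cov.aicc, bench_aicc, aic_buffer)
    return SubPairResult(float(fit_cov.aicc), float(bench_aicc), hit)


def _simulate_pair(config: ExperimentConfig, pair_index: int):
    """Simulate one top-level pair: environment, covariate, delta, counts."""
    env_params = EnvParams(
        span=config.span,
        slope=config.slope,
        phi=config.phi,
        innovation_sd=config.innovation_sd,
        n_points=config.n_env_points,
    )
    env = simulate_env_series(env_params, derive_seed(config.seed, pair_index, _STREAM_ENV))
    cov = sample_covariate(env, config.n_samples)
    design = SimDesign(
        omega=config.omega,
        target_corr=config.corr,
        baseline_mean=config.baseline_mean,
        n_obs=config.n_samples,
    )
    delta = calibrate_delta(
        cov, design, seed=derive_seed(config.seed, pair_index, _STREAM_DELTA)
    )
    counts = simulate_counts(
        cov,
        PewmaParams(omega=config.omega, delta=np.array([delta])),
        baseline_mean=config.baseline_mean,
        seed=derive_seed(config.seed, pair_index, _STREAM_COUNTS),
    )
    return env, cov, delta, counts


def run_top_pair(
    config: ExperimentConfig, pair_seed: int, curve: CalibrationCurve | None = None
) -> TopPairResult:
    """One top-level pair: simulate, date, bootstrap, and tally hits.

    ``pair_seed`` is the pair's index; all randomness derives deterministically
    from ``(config.seed, pair_seed)``.  With ``chrono_uncertainty=False`` the
    environmental series keeps its true timestamps in every sub-pair, so the
    hit fraction collapses to exactly 0 or 1.
    """
    if curve is None:
        curve = resolve_curve(config.curve_source)
    env, cov, delta, counts = _simulate_pair(config, pair_seed)

    positions, horizon_ages = place_dated_horizons(config.span, config.n_dates)
    if config.chrono_uncertainty:
        dates = make_synthetic_c14_dates(
            curve, horizon_ages, lab_error=config.lab_error, positions=positions
        )
        densities = [calibrate(curve, d, grid_step=config.grid_step) for d in dates]
        draws = sample_ordered_calendar_ages(
            densities,
            n_draws=config.n_boot,
            seed=derive_seed(config.seed, pair_seed, _STREAM_GIBBS),
        )
    else:
        draws = np.tile(horizon_ages, (config.n_boot, 1))

    bench = fit_pewma(counts)
    bench_aicc = bench.aicc if bench.converged else None

    hits = 0
    n_valid = 0
    n_invalid = 0
    cov_positions = cov.positions
    prov = dict(cov.provenance)
    prov["kind"] = "bootstrap"
    for draw in draws:
        try:
            model = build_age_model(positions, draw)
            boot_ages = np.asarray(model.interpolant(cov_positions), dtype=float)
            env_boot = EnvSeries(boot_ages, cov.values, cov.params, provenance=prov)
            result = run_sub_pair(
                counts, env_boot, aic_buffer=config.aic_buffer, bench_aicc=bench_aicc
            )
        except (ChronoPewmaError, ValueError):
            result = SubPairResult(np.nan, np.nan, False, valid=False)
        if result.valid:
            n_valid += 1
            hits += int(result.hit)
        else:
            n_invalid += 1
    frac = hits / n_valid if n_valid else 0.0
    return TopPairResult(
        hit_fraction=frac,
        n_valid=n_valid,
        n_invalid=n_invalid,
        delta=float(delta),
        flagged=bool(n_invalid > 0.1 * config.n_boot),
    )


# ---------------------------------------------------------------------------
# experiments and grids
# ---------------------------------------------------------------------------


def scheduled_analyses(config: ExperimentConfig) -> int:
    """Number of sub-pair PEWMA analyses one experiment enumerates."""
    return config.n_top * config.n_boot


def run_experiment(
    config: ExperimentConfig,
    out_dir: str | Path | None = None,
    progress: bool = False,
) -> HitRateDistribution:
    """Run all top-level pairs of one experiment.

    With ``out_dir`` set, per-pair results stream to
    ``<out_dir>/<label>.csv`` as they complete and the full configuration is
    written alongside as JSON; an interrupted run resumes from the rows
    already on disk.
    """
    curve = resolve_curve(config.curve_source)
    done: dict[int, dict] = {}
    out_path = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        out_path = out_dir / f"{config.label()}.csv"
        (out_dir / f"{config.label()}.config.json").write_text(
            json.dumps(asdict(config), indent=2, default=str)
        )
        if out_path.exists():
            prev = pd.read_csv(out_path)
            done = {int(r.pair): dict(r._asdict()) for r in prev.itertuples(index=False)}
        else:
            out_path.write_text("pair,hit_fraction,n_valid,n_invalid,delta,flagged\n")

    rows = []
    for pair in range(config.n_top):
        if pair in done:
            rows.append(done[pair])
            continue
        res = run_top_pair(config, pair, curve=curve)
        row = {
            "pair": pair,
            "hit_fraction": res.hit_fraction,
            "n_valid": res.n_valid,
            "n_invalid": res.n_invalid,
            "delta": res.delta,
            "flagged": res.flagged,
        }
        rows.append(row)
        if out_path is not None:
            with open(out_path, "at", encoding="utf-8") as fh:
                fh.write(
                    f"{pair},{res.hit_fraction!r},{res.n_valid},"
                    f"{res.n_invalid},{res.delta!r},{res.flagged}\n"
                )
        if progress:
            print(f"[{config.label()}] pair {pair + 1}/{config.n_top}: "
                  f"hit fraction {res.hit_fraction:.3f}")
    df = pd.DataFrame(rows).sort_values("pair")
    return HitRateDistribution(
        hit_fractions=df["hit_fraction"].to_numpy(float),
        config=config,
        n_invalid=df["n_invalid"].to_numpy(int),
        flagged=df["flagged"].to_numpy(bool),
    )


def expand_grid(
    corrs=(0.0, 0.25, 0.5, 0.75),
    innovation_sds=(1.0, 0.1, 0.01),
    n_dates=(5, 15, 25),
    **common,
) -> list[ExperimentConfig]:
    """Full factorial of the free parameters (3 noise x 3 dates x 4 corr = 36)."""
    return [
        ExperimentConfig(corr=c, innovation_sd=sd, n_dates=nd, **common)
        for sd, nd, c in itertools.product(innovation_sds, n_dates, corrs)
    ]


def run_grid(
    grid: list[ExperimentConfig],
    out_dir: str | Path | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Run a list of experiments; one row per top-level pair, all parameters
    carried alongside.  Duplicate configurations are rejected."""
    if not grid:
        raise ValueError("grid must be nonempty")
    if len(set(grid)) != len(grid):
        raise ValueError("duplicate configs in grid")
    frames = []
    for config in grid:
        dist = run_experiment(config, out_dir=out_dir, progress=progress)
        df = dist.to_frame()
        for key, value in asdict(config).items():
            df[key] = [value] * len(df) if isinstance(value, tuple) else value
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def summarize(dist, bin_width: float = 0.05) -> dict:
    """Histogram summary of a hit-rate distribution: modes, variance, quantiles.

    The primary mode is the midpoint of the highest-count histogram bin on
    [0, 1] (ties broken toward the lower bin).  Secondary modes are reported
    where a bin not adjacent to the primary bin exceeds half the primary bin
    count; contiguous runs of such bins report their highest member.
    """
    hf = dist.hit_fractions if isinstance(dist, HitRateDistribution) else np.asarray(dist, float)
    if hf.size == 0:
        raise ValueError("distribution must be nonempty")
    nbins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, nbins + 1)
    counts, _ = np.histogram(hf, bins=edges)
    mids = 0.5 * (edges[:-1] + edges[1:])
    primary_idx = int(np.argmax(counts))  # argmax takes the first = lower bin on ties
    primary_count = counts[primary_idx]

    candidates = [
        i
        for i in range(nbins)
        if abs(i - primary_idx) > 1 and counts[i] > 0.5 * primary_count
    ]
    secondary = []
    run: list[int] = []
    for i in candidates + [None]:
        if run and (i is None or i != run[-1] + 1):
            best = max(run, key=lambda j: (counts[j], -j))
            secondary.append(float(mids[best]))
            run = []
        if i is not None:
            run.append(i)

    qs = (0.025, 0.25, 0.5, 0.75, 0.975)
    return {
        "n": int(hf.size),
        "mean": float(hf.mean()),
        "variance": float(hf.var()),
        "primary_mode": float(mids[primary_idx]),
        "secondary_modes": secondary,
        "quantiles": {str(q): float(np.quantile(hf, q)) for q in qs},
        "bin_width": float(bin_width),
        "bin_counts": counts.tolist(),
    }
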