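"""Noise injection, parameter sweeps, and the qualitative trend suite.

The sweep engine reruns the forward or reverse simulator across a grid of
values for one named parameter and summarizes each run into scalar metrics
(compartment peaks and AUCs, peak bioluminescence, threshold first-crossing
time).  The trend suite bundles the sweeps that characterize the system's
sensitivity — sensor load ``n0``, exchange/binding rates ``k21r``/``k1`` on
the reverse side; dose ``omega0``, elimination ``k10``, distribution
``k12``, uptake ``k1wi``/``k3wi``, vascular permeability ``ps`` and
perfusion ``W0`` on the forward side — and asserts the qualitative
directions the model is expected to show.

Metrics are always computed on noiseless trajectories; Gaussian noise is a
separate step (:func:`add_gaussian_noise`) applied only when manufacturing
fitting targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError, IntegrationError
from .forward import default_grid, peak_metrics, simulate_forward
from .params import ParamSet, load_defaults
from .reverse import simulate_reverse

__all__ = ["NoiseSpec", "SweepSpec", "add_gaussian_noise", "run_sweep",
           "paper_figure_suite", "TrendAssertionError",
           "FORWARD_SWEEP_METRICS", "REVERSE_SWEEP_METRICS"]

FORWARD_SWEEP_METRICS = ("peak_w2", "peak_w4", "peak_w5", "peak_time_w4",
                         "peak_time_w5", "auc_w5")
REVERSE_SWEEP_METRICS = ("peak_I", "first_crossing_time", "auc_I")

_REVERSE_PARAMS = {"k12r", "k21r", "k1", "n0", "mu", "alphaL", "alphaM",
                   "atp", "kr", "kp", "gamma_r", "gamma_p", "hill_K",
                   "hill_h", "I0"}


class TrendAssertionError(AssertionError):
    """A sweep failed its expected qualitative trend; names the sweep."""


@dataclass(frozen=True)
class NoiseSpec:
    """Zero-mean Gaussian measurement noise on a concentration series."""

    variance: float = 0.05   # [uM^2-scale]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ConfigurationError("noise variance must be >= 0")


@dataclass(frozen=True)
class SweepSpec:
    """One-parameter sweep over the simulator."""

    param: str
    values: Sequence[float]
    base: Optional[ParamSet] = None
    metrics: Optional[Sequence[str]] = None
    seed: int = 0
    grid: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.size == 0 or np.any(np.diff(vals) <= 0):
            raise ConfigurationError(
                "sweep values must be nonempty and strictly increasing")
        base = self.base if self.base is not None else load_defaults()
        base._locate(self.param)  # raises ConfigurationError if unknown


def add_gaussian_noise(series, spec: NoiseSpec):
    """Add i.i.d. zero-mean Gaussian noise of the spec's variance.

    Seed-reproducible; zero variance returns the input unchanged.
    """
    series = np.asarray(series, dtype=float)
    if not np.all(np.isfinite(series)):
        raise InputError("series must be finite")
    if spec.variance == 0:
        return series.copy()
    rng = np.random.default_rng(spec.seed)
    return series + rng.normal(0.0, np.sqrt(spec.variance), size=series.shape)


def _forward_metrics(p: ParamSet, grid: np.ndarray) -> dict:
    f = p.forward
    init = np.array([f.omega0 / f.VD, 0.0, 0.0, 0.0, 0.0])
    traj = simulate_forward(f, init=init, grid=grid)
    pm = peak_metrics(traj)
    return {
        "peak_w2": pm["w2"]["peak"], "peak_w4": pm["w4"]["peak"],
        "peak_w5": pm["w5"]["peak"], "peak_time_w4": pm["w4"]["peak_time"],
        "peak_time_w5": pm["w5"]["peak_time"], "auc_w5": pm["w5"]["auc"],
    }


def _reverse_metrics(p: ParamSet, grid: np.ndarray,
                     norm_ref: Optional[float] = None) -> dict:
    traj = simulate_reverse(p.reverse, p.signaling, grid=grid,
                            norm_ref=norm_ref)
    cross = traj.first_crossing_time()
    return {
        "peak_I": float(traj.intensity.max()),
        "first_crossing_time": np.inf if cross is None else cross,
        "auc_I": float(np.trapezoid(traj.intensity, traj.time)),
    }


def run_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Run a one-parameter sweep; returns a tidy table.

    Columns: ``sweep_param, sweep_value, metric, value``.  One row per swept
    value per metric.  A value whose simulation fails is flagged with NaN
    metrics and an ``error`` column entry; the sweep continues.

    For reverse sweeps the threshold first-crossing metric uses a normalized
    scale calibrated once at the *base* configuration's peak intensity, so
    that every swept value is decoded against the same absolute threshold
    (a never-crossed threshold yields +inf).
    """
    base = spec.base if spec.base is not None else load_defaults()
    grid = spec.grid if spec.grid is not None else default_grid()
    is_reverse = spec.param in _REVERSE_PARAMS
    metrics = tuple(spec.metrics) if spec.metrics is not None else (
        REVERSE_SWEEP_METRICS if is_reverse else FORWARD_SWEEP_METRICS)
    norm_ref = None
    if is_reverse:
        norm_ref = float(simulate_reverse(base.reverse, base.signaling,
                                          grid=grid).intensity.max())
    rows = []
    for value in spec.values:
        p = base.with_value(spec.param, float(value))
        try:
            got = _reverse_metrics(p, grid, norm_ref) if is_reverse \
                else _forward_metrics(p, grid)
            err = ""
        except IntegrationError as exc:
            got = {}
            err = str(exc)
        for metric in metrics:
            rows.append({"sweep_param": spec.param,
                         "sweep_value": float(value),
                         "metric": metric,
                         "value": got.get(metric, np.nan),
                         "error": err})
    df = pd.DataFrame(rows)
    if (df["error"] == "").all():
        df = df.drop(columns="error")
    return df


def _metric_series(table: pd.DataFrame, metric: str) -> np.ndarray:
    sel = table[table["metric"] == metric].sort_values("sweep_value")
    return sel["value"].to_numpy()


def _check_monotone(name: str, vals: np.ndarray, direction: str,
                    slack: float = 1e-9) -> None:
    diffs = np.diff(vals)
    if direction == "increasing":
        ok = bool(np.all(diffs > -slack) and vals[-1] > vals[0])
    else:
        ok = bool(np.all(diffs < slack) and vals[-1] < vals[0])
    if not ok:
        raise TrendAssertionError(
            f"sweep {name!r}: expected {direction} trend, got {vals}")


def _check_interior_peak(name: str, times: np.ndarray, t_end: float) -> None:
    if not np.all((times > 0) & (times < t_end)):
        raise TrendAssertionError(
            f"sweep {name!r}: expected interior-time maxima, "
            f"got peak times {times}")


#: (sweep name, metric, expected direction or 'interior_peak')
TREND_EXPECTATIONS = (
    ("n0", "peak_I", "increasing"),
    ("k21r", "peak_I", "increasing"),
    ("k1", "peak_I", "increasing"),
    ("omega0", "peak_w5", "increasing"),
    ("k10", "peak_w5", "decreasing"),
    ("k12", "peak_time_w4", "interior_peak"),
    ("k1wi", "peak_w5", "increasing"),
    ("k3wi", "peak_w5", "increasing"),
    ("ps", "peak_w5", "increasing"),
    ("W0", "peak_w5", "increasing"),
)


def sweep_values(base: ParamSet, name: str, n_points: int = 5,
                 span: tuple[float, float] = (0.25, 4.0)) -> np.ndarray:
    """Geometric value grid bracketing the default symmetrically."""
    ref = base.get(name)
    if ref is None or ref <= 0:
        raise ConfigurationError(f"cannot build a sweep around {name}={ref}")
    return ref * np.geomspace(span[0], span[1], n_points)


def paper_figure_suite(base: Optional[ParamSet] = None, n_points: int = 5,
                       assert_trends: bool = True,
                       grid: Optional[np.ndarray] = None) -> dict:
    """Run the ten characteristic sensitivity sweeps and check their trends.

    Peak bioluminescence should rise with ``n0``, ``k21r`` and ``k1``; peak
    intracellular drug should rise with ``omega0``, ``k1wi``, ``k3wi``,
    ``ps`` and ``W0`` and fall with ``k10``; the EES and intracellular
    curves should rise and then fall (interior-time maxima) across the
    ``k12`` sweep.  Returns ``{sweep name: tidy table}``; with
    ``assert_trends`` a violated trend raises :class:`TrendAssertionError`
    naming the sweep.
    """
    base = base if base is not None else load_defaults()
    grid = grid if grid is not None else default_grid()
    tables: dict[str, pd.DataFrame] = {}
    for name, metric, direction in TREND_EXPECTATIONS:
        spec = SweepSpec(name, sweep_values(base, name, n_points), base=base,
                         grid=grid)
        table = run_sweep(spec)
        tables[name] = table
        if not assert_trends:
            continue
        vals = _metric_series(table, metric)
        if np.any(np.isnan(vals)):
            raise TrendAssertionError(f"sweep {name!r}: simulation failures")
        if direction == "interior_peak":
            _check_interior_peak(name, vals, t_end=float(grid[-1]))
            _check_interior_peak(
                name, _metric_series(table, "peak_time_w5"),
                t_end=float(grid[-1]))
        else:
            _check_monotone(name, vals, direction)
    return tables
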