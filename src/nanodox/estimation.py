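"""Parameter estimation: trajectory-matching NLS and an MLP surrogate.

Two estimators recover simulator parameters from observed (noisy)
trajectories, mirroring how the bio-cyber interface identifies its own
model:

* :class:`NLSTrajectoryEstimator` — nonlinear least squares.  The objective
  is the sum of squared deviations between the simulated observable (tumor
  plasma ``w2`` for the forward model, bioluminescence intensity ``I`` for
  the reverse model) and the observed series at ``M`` sample times, minimized
  over the free parameters within bounds.
* :class:`MLPSurrogate` — a single-hidden-layer perceptron (10 log-sigmoid
  hidden units by default, identity output) trained on a simulated corpus of
  (noisy trajectory, NLS-fitted parameters) pairs, so that at deployment a
  parameter estimate costs one forward pass instead of an iterative fit.
  Features and regression targets are min-max scaled to [0, 1]; the training
  objective adds an L2 weight penalty (sum of squared errors plus
  ``lambda * sum of squared weights``) in the spirit of Bayesian
  regularization.

Both follow the scikit-learn estimator protocol (``get_params``/
``set_params``, ``fit``, ``predict``, fitted attributes with a trailing
underscore) and compose with sklearn model-selection tooling.  The
module-level functions (:func:`nls_fit`, :func:`train_surrogate`, ...) are
thin wrappers kept for scripting convenience.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.neural_network import MLPRegressor

from .errors import ConfigurationError, InputError, IntegrationError
from .forward import simulate_forward
from .params import ParamSet, load_defaults
from .reverse import simulate_reverse

__all__ = [
    "FitProblem", "FitResult", "SurrogateModel", "TrainingSet",
    "NLSTrajectoryEstimator", "MLPSurrogate",
    "minmax_scale", "minmax_unscale", "mlp_predict", "regularized_loss",
    "rmse", "nls_fit", "make_training_set", "train_surrogate",
    "compare_estimators",
    "FORWARD_FREE_DEFAULT", "REVERSE_FREE_DEFAULT",
]

#: default free parameters: the sensitive knobs of each direction
FORWARD_FREE_DEFAULT = ("k12", "k21", "k10", "omega0")
REVERSE_FREE_DEFAULT = ("k12r", "k21r", "k1", "n0")


# --------------------------------------------------------------------------
# small numeric primitives
# --------------------------------------------------------------------------

def minmax_scale(y, y_min, y_max):
    """Scale features to [0, 1]: ``y* = (y - y_min) / (y_max - y_min)``."""
    y = np.asarray(y, dtype=float)
    y_min = np.asarray(y_min, dtype=float)
    y_max = np.asarray(y_max, dtype=float)
    if np.any(y_max <= y_min):
        raise ConfigurationError("min-max bounds are degenerate (min >= max)")
    return (y - y_min) / (y_max - y_min)


def minmax_unscale(y_star, y_min, y_max):
    """Invert :func:`minmax_scale` using the stored bounds."""
    y_star = np.asarray(y_star, dtype=float)
    y_min = np.asarray(y_min, dtype=float)
    y_max = np.asarray(y_max, dtype=float)
    if np.any(y_max <= y_min):
        raise ConfigurationError("min-max bounds are degenerate (min >= max)")
    return y_min + y_star * (y_max - y_min)


def rmse(pred, truth) -> float:
    """Root-mean-square error between two equal-length vectors."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape or pred.size == 0:
        raise InputError("pred and truth must be nonempty and equal-shaped")
    return float(np.sqrt(np.mean((pred - truth) ** 2)))


def regularized_loss(pred, target, weights: Sequence[np.ndarray],
                     lam: float) -> float:
    """Sum of squared errors plus an L2 weight penalty.

    ``sum((pred - target)^2) + lam * sum(w^2)``; with ``lam = 0`` this is the
    plain sum of squared errors.
    """
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.shape != target.shape:
        raise InputError("pred and target must have the same shape")
    if lam < 0:
        raise InputError("lambda must be >= 0")
    sse = float(np.sum((pred - target) ** 2))
    penalty = sum(float(np.sum(np.asarray(w, dtype=float) ** 2))
                  for w in weights)
    return sse + lam * penalty


# --------------------------------------------------------------------------
# surrogate network container and forward pass
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SurrogateModel:
    """A trained single-hidden-layer surrogate with its scaling bounds.

    The forward pass is
    ``z_k = f1(b_k + sum_j w_kj * f2(b_j + sum_i w_ji * y*_i))`` with
    ``f2`` the log-sigmoid and ``f1`` the identity; ``y*`` is the min-max
    scaled feature vector and the output is unscaled back to parameter units
    through the stored label bounds.
    """

    w_in: np.ndarray          # (hidden, n_features)
    b_in: np.ndarray          # (hidden,)
    w_out: np.ndarray         # (n_outputs, hidden)
    b_out: np.ndarray         # (n_outputs,)
    x_min: np.ndarray         # per-feature scaling bounds
    x_max: np.ndarray
    y_min: np.ndarray         # per-label scaling bounds
    y_max: np.ndarray
    param_names: tuple = ()
    activation: str = "logsig"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        m, n = self.w_in.shape
        k = self.w_out.shape[0]
        ok = (self.b_in.shape == (m,) and self.w_out.shape == (k, m)
              and self.b_out.shape == (k,) and self.x_min.shape == (n,)
              and self.x_max.shape == (n,) and self.y_min.shape == (k,)
              and self.y_max.shape == (k,))
        if not ok:
            raise ConfigurationError("inconsistent surrogate weight shapes")
        if np.any(self.x_max <= self.x_min) or np.any(self.y_max <= self.y_min):
            raise ConfigurationError("degenerate surrogate scaling bounds")

    @property
    def hidden_units(self) -> int:
        return self.w_in.shape[0]

    def weights(self) -> list[np.ndarray]:
        return [self.w_in, self.w_out]

    def to_json(self, path: str | Path) -> None:
        doc = {
            "w_in": self.w_in.tolist(), "b_in": self.b_in.tolist(),
            "w_out": self.w_out.tolist(), "b_out": self.b_out.tolist(),
            "x_min": self.x_min.tolist(), "x_max": self.x_max.tolist(),
            "y_min": self.y_min.tolist(), "y_max": self.y_max.tolist(),
            "param_names": list(self.param_names),
            "activation": self.activation, "meta": self.meta,
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path: str | Path) -> "SurrogateModel":
        doc = json.loads(Path(path).read_text())
        return cls(
            w_in=np.array(doc["w_in"]), b_in=np.array(doc["b_in"]),
            w_out=np.array(doc["w_out"]), b_out=np.array(doc["b_out"]),
            x_min=np.array(doc["x_min"]), x_max=np.array(doc["x_max"]),
            y_min=np.array(doc["y_min"]), y_max=np.array(doc["y_max"]),
            param_names=tuple(doc.get("param_names", ())),
            activation=doc.get("activation", "logsig"),
            meta=doc.get("meta", {}),
        )


def _logsig(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def mlp_predict(y, net: SurrogateModel):
    """Evaluate the surrogate on one feature vector or a batch.

    Scaling of inputs and unscaling of outputs happen internally using the
    bounds stored with the network.
    """
    y = np.asarray(y, dtype=float)
    single = y.ndim == 1
    Y = np.atleast_2d(y)
    if Y.shape[1] != net.w_in.shape[1]:
        raise InputError(
            f"feature dimension {Y.shape[1]} does not match network input "
            f"size {net.w_in.shape[1]}")
    Ys = minmax_scale(Y, net.x_min, net.x_max)
    hidden = _logsig(Ys @ net.w_in.T + net.b_in)
    z = hidden @ net.w_out.T + net.b_out       # identity output activation
    out = minmax_unscale(z, net.y_min, net.y_max)
    return out[0] if single else out


# --------------------------------------------------------------------------
# nonlinear least squares
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FitProblem:
    """An observed series plus the free-parameter specification."""

    t: np.ndarray                       # observation grid [min], M points
    observed: np.ndarray                # observed series at t
    free: tuple                          # free parameter names (s1..sn)
    bounds: dict                        # name -> (lower, upper)
    x0: dict                            # name -> initial guess
    model: str = "forward"              # {"forward", "reverse"}
    base: Optional[ParamSet] = None     # fixed-parameter context
    observable: Optional[str] = None    # default: w2 / intensity by model
    ode_rtol: float = 1e-8
    ode_atol: float = 1e-10

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        y = np.asarray(self.observed, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "observed", y)
        if self.model not in ("forward", "reverse"):
            raise ConfigurationError(f"unknown model {self.model!r}")
        if t.ndim != 1 or t.shape != y.shape:
            raise InputError("t and observed must be 1-D and equal length")
        if not np.all(np.isfinite(y)):
            raise InputError("observed series must be finite")
        if len(t) < len(self.free):
            raise InputError("need at least as many observations as free "
                             "parameters (M >= n)")
        for name in self.free:
            lo, hi = self.bounds[name]
            if not lo < hi:
                raise ConfigurationError(f"bounds for {name} must satisfy "
                                         "lower < upper")


@dataclass(frozen=True)
class FitResult:
    """Outcome of one NLS fit."""

    params: dict                  # fitted values, name -> value
    residual_norm: float          # sqrt(sum of squared residuals)
    rmse: float
    nfev: int
    wall_time: float              # seconds
    success: bool
    message: str = ""


def make_simulator(problem: FitProblem) -> Callable[[np.ndarray], np.ndarray]:
    """Map a free-parameter vector to the model observable on the grid.

    For forward problems the commanded concentration ``omega0`` acts as the
    injected dose, so the plasma initial condition is ``omega0 / VD``.
    """
    base = problem.base if problem.base is not None else load_defaults()
    observable = problem.observable or (
        "w2" if problem.model == "forward" else "intensity")
    names = problem.free
    grid = problem.t
    # the solver needs t=0 in the grid to anchor the initial condition
    sim_grid = grid if grid[0] == 0.0 else np.concatenate([[0.0], grid])
    skip = 0 if grid[0] == 0.0 else 1

    def simulator(x: np.ndarray) -> np.ndarray:
        p = base
        for name, value in zip(names, x):
            p = p.with_value(name, float(value))
        if problem.model == "forward":
            f = p.forward
            init = np.array([f.omega0 / f.VD, 0.0, 0.0, 0.0, 0.0])
            traj = simulate_forward(f, init=init, grid=sim_grid,
                                    rtol=problem.ode_rtol,
                                    atol=problem.ode_atol)
            series = traj.column(observable)
        else:
            traj = simulate_reverse(p.reverse, p.signaling, grid=sim_grid,
                                    rtol=problem.ode_rtol,
                                    atol=problem.ode_atol)
            series = getattr(traj, observable)
        return series[skip:]

    return simulator


class NLSTrajectoryEstimator(BaseEstimator, RegressorMixin):
    """Scikit-learn style nonlinear least-squares trajectory fitter.

    ``fit(t, y)`` finds the free simulator parameters minimizing
    ``sum_i (model(t_i, S) - y_i)^2`` within bounds, starting from a fixed
    initial guess (deterministic given identical inputs).

    Parameters
    ----------
    model : {"forward", "reverse"}
        Which simulator the observable comes from.
    free : sequence of str, optional
        Free parameter names; defaults to the direction's sensitive set.
    base : ParamSet, optional
        Fixed-parameter context (defaults to the tabulated registry).
    bounds, x0 : dict, optional
        Per-name bounds and starting values.  Defaults: bounds span
        x0/bound_factor .. x0*bound_factor around the registry value, and
        x0 is the registry value itself.
    """

    def __init__(self, model: str = "forward", free: Optional[Sequence] = None,
                 base: Optional[ParamSet] = None, bounds: Optional[dict] = None,
                 x0: Optional[dict] = None, observable: Optional[str] = None,
                 bound_factor: float = 10.0, ode_rtol: float = 1e-8,
                 ode_atol: float = 1e-10, max_nfev: Optional[int] = None,
                 ftol: float = 1e-14, xtol: float = 1e-14):
        self.model = model
        self.free = free
        self.base = base
        self.bounds = bounds
        self.x0 = x0
        self.observable = observable
        self.bound_factor = bound_factor
        self.ode_rtol = ode_rtol
        self.ode_atol = ode_atol
        self.max_nfev = max_nfev
        self.ftol = ftol
        self.xtol = xtol

    # -- problem assembly --------------------------------------------------

    def _problem(self, t, y) -> FitProblem:
        base = self.base if self.base is not None else load_defaults()
        free = tuple(self.free) if self.free is not None else (
            FORWARD_FREE_DEFAULT if self.model == "forward"
            else REVERSE_FREE_DEFAULT)
        x0 = dict(self.x0) if self.x0 is not None else {}
        bounds = dict(self.bounds) if self.bounds is not None else {}
        for name in free:
            ref = x0.get(name, base.get(name))
            x0.setdefault(name, ref)
            bounds.setdefault(name, (ref / self.bound_factor,
                                     ref * self.bound_factor))
        return FitProblem(t=np.asarray(t, dtype=float).ravel(),
                          observed=np.asarray(y, dtype=float).ravel(),
                          free=free, bounds=bounds, x0=x0, model=self.model,
                          base=base, observable=self.observable,
                          ode_rtol=self.ode_rtol, ode_atol=self.ode_atol)

    def fit(self, X, y):
        """Fit free parameters to an observed series.

        ``X`` is the observation time grid (M,) or (M, 1); ``y`` the observed
        series.
        """
        problem = self._problem(X, y)
        result = nls_fit(problem, max_nfev=self.max_nfev,
                         ftol=self.ftol, xtol=self.xtol)
        self.problem_ = problem
        self.result_ = result
        self.params_ = result.params
        self.rmse_ = result.rmse
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        """Simulated observable at the fitted parameters on grid ``X``."""
        if not hasattr(self, "result_"):
            raise InputError("estimator is not fitted")
        grid = np.asarray(X, dtype=float).ravel()
        prob = FitProblem(t=grid, observed=np.zeros_like(grid),
                          free=self.problem_.free, bounds=self.problem_.bounds,
                          x0=self.problem_.x0, model=self.problem_.model,
                          base=self.problem_.base,
                          observable=self.problem_.observable,
                          ode_rtol=self.problem_.ode_rtol,
                          ode_atol=self.problem_.ode_atol)
        sim = make_simulator(prob)
        x = np.array([self.params_[n] for n in self.problem_.free])
        return sim(x)


def nls_fit(problem: FitProblem,
            simulator: Optional[Callable] = None,
            max_nfev: Optional[int] = None,
            ftol: float = 1e-14, xtol: float = 1e-14) -> FitResult:
    """Solve a :class:`FitProblem` by bounded nonlinear least squares.

    ``simulator`` may override the model handle (it must map a free-parameter
    vector to the observable series on the problem grid).  Non-convergence
    returns a result flagged ``success=False`` carrying the best-so-far
    parameters rather than raising.
    """
    sim = simulator if simulator is not None else make_simulator(problem)
    names = problem.free
    x0 = np.array([problem.x0[n] for n in names], dtype=float)
    lo = np.array([problem.bounds[n][0] for n in names], dtype=float)
    hi = np.array([problem.bounds[n][1] for n in names], dtype=float)
    obs = problem.observed

    def residuals(x):
        try:
            return sim(x) - obs
        except IntegrationError:
            # a diverged candidate: large residuals steer the solver away
            return np.full_like(obs, 1e6)

    t0 = time.perf_counter()
    try:
        # diff_step well above the ODE tolerance floor keeps the
        # finite-difference jacobian clean near the optimum
        sol = least_squares(residuals, x0, bounds=(lo, hi), method="trf",
                            x_scale=np.maximum(np.abs(x0), 1e-12),
                            diff_step=1e-6,
                            ftol=ftol, xtol=xtol, gtol=1e-14,
                            max_nfev=max_nfev)
        success = bool(sol.status > 0)
        x, cost, nfev, message = sol.x, sol.cost, sol.nfev, sol.message
    except Exception as exc:  # pragma: no cover - defensive
        x, cost, nfev, message, success = x0, np.inf, 0, str(exc), False
    wall = time.perf_counter() - t0
    res = residuals(x)
    return FitResult(
        params={n: float(v) for n, v in zip(names, x)},
        residual_norm=float(np.linalg.norm(res)),
        rmse=rmse(res + obs, obs),
        nfev=int(nfev), wall_time=wall, success=success, message=str(message),
    )


# --------------------------------------------------------------------------
# training-set generation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainingSet:
    """Simulated corpus for surrogate training.

    ``X`` holds the noisy observable series (one row per scenario), ``Y_true``
    the sampled ground-truth parameters, ``Y_fit`` the NLS estimates used as
    regression labels.
    """

    X: np.ndarray
    Y_true: np.ndarray
    Y_fit: np.ndarray
    param_names: tuple
    ranges: dict
    t: np.ndarray
    noise_var: float
    seed: int
    fit_times: np.ndarray
    n_failed: int = 0


def default_fit_grid(n: int = 50, t_end: float = 2000.0) -> np.ndarray:
    """Default M-point observation grid for fitting experiments."""
    return np.linspace(0.0, t_end, n)


def make_training_set(
    n_scenarios: int,
    ranges: Optional[dict] = None,
    grid: Optional[np.ndarray] = None,
    noise_var: float = 0.05,
    seed: int = 0,
    model: str = "forward",
    base: Optional[ParamSet] = None,
    ode_rtol: float = 1e-6,
    max_nfev: int = 200,
) -> TrainingSet:
    """Sample scenarios, simulate, add noise, and fit each one by NLS.

    Per scenario the true parameters are drawn uniformly within ``ranges``
    (default: registry value x0.5 .. x2 for the direction's sensitive set),
    the model is simulated, zero-mean Gaussian noise of variance
    ``noise_var`` is added, and the noisy series is fitted.  Failed fits are
    dropped (and counted).  Everything is reproducible from ``seed``.
    """
    if n_scenarios < 1:
        raise InputError("n_scenarios must be >= 1")
    base = base if base is not None else load_defaults()
    names = tuple(ranges) if ranges else (
        FORWARD_FREE_DEFAULT if model == "forward" else REVERSE_FREE_DEFAULT)
    if ranges is None:
        ranges = {n: (base.get(n) * 0.5, base.get(n) * 2.0) for n in names}
    grid = grid if grid is not None else default_fit_grid()
    rng = np.random.default_rng(seed)

    lo = np.array([ranges[n][0] for n in names])
    hi = np.array([ranges[n][1] for n in names])
    X, Y_true, Y_fit, times = [], [], [], []
    n_failed = 0
    probe = FitProblem(t=grid, observed=np.zeros_like(grid), free=names,
                       bounds=ranges, x0={n: 0.5 * (ranges[n][0] + ranges[n][1])
                                          for n in names},
                       model=model, base=base, ode_rtol=ode_rtol,
                       ode_atol=ode_rtol * 1e-2)
    sim = make_simulator(probe)
    for _ in range(n_scenarios):
        truth = lo + (hi - lo) * rng.random(len(names))
        clean = sim(truth)
        noisy = clean + rng.normal(0.0, np.sqrt(noise_var), size=clean.shape)
        problem = FitProblem(t=grid, observed=noisy, free=names,
                             bounds=ranges, x0=probe.x0, model=model,
                             base=base, ode_rtol=ode_rtol,
                             ode_atol=ode_rtol * 1e-2)
        result = nls_fit(problem, simulator=sim, max_nfev=max_nfev,
                         ftol=1e-10, xtol=1e-10)
        if not result.success:
            n_failed += 1
            continue
        X.append(noisy)
        Y_true.append(truth)
        Y_fit.append([result.params[n] for n in names])
        times.append(result.wall_time)
    if not X:
        raise ConfigurationError("every scenario fit failed")
    return TrainingSet(np.array(X), np.array(Y_true), np.array(Y_fit),
                       names, dict(ranges), grid, noise_var, seed,
                       np.array(times), n_failed)


# --------------------------------------------------------------------------
# surrogate training
# --------------------------------------------------------------------------

class MLPSurrogate(BaseEstimator, RegressorMixin):
    """Single-hidden-layer log-sigmoid surrogate regressor.

    ``fit(X, Y)`` min-max scales features and labels to [0, 1], trains a
    10-hidden-unit perceptron (L-BFGS, L2 weight penalty ``lam``), and stores
    the weights in a :class:`SurrogateModel`; ``predict`` runs the package's
    own forward pass (:func:`mlp_predict`) on the stored weights.
    """

    def __init__(self, hidden_units: int = 10, lam: float = 1e-3,
                 epochs: int = 2000, seed: int = 0,
                 label_bounds: Optional[dict] = None,
                 param_names: Optional[Sequence[str]] = None):
        self.hidden_units = hidden_units
        self.lam = lam
        self.epochs = epochs
        self.seed = seed
        self.label_bounds = label_bounds
        self.param_names = param_names

    def fit(self, X, Y):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if X.ndim != 2 or X.shape[0] != Y.shape[0] or X.shape[0] == 0:
            raise InputError("X and Y must be nonempty with matching rows")
        x_min, x_max = X.min(axis=0), X.max(axis=0)
        if np.any(x_max <= x_min):
            raise ConfigurationError(
                "degenerate dataset: at least one feature is constant")
        names = tuple(self.param_names) if self.param_names else tuple(
            f"s{i + 1}" for i in range(Y.shape[1]))
        if self.label_bounds is not None:
            y_min = np.array([self.label_bounds[n][0] for n in names])
            y_max = np.array([self.label_bounds[n][1] for n in names])
        else:
            y_min, y_max = Y.min(axis=0), Y.max(axis=0)
        if np.any(y_max <= y_min):
            raise ConfigurationError("degenerate labels: constant target")

        Xs = minmax_scale(X, x_min, x_max)
        Ys = minmax_scale(Y, y_min, y_max)
        reg = MLPRegressor(
            hidden_layer_sizes=(self.hidden_units,), activation="logistic",
            solver="lbfgs", alpha=self.lam, max_iter=self.epochs,
            random_state=self.seed, tol=1e-9)
        import warnings

        from sklearn.exceptions import ConvergenceWarning

        with warnings.catch_warnings():
            # hitting the lbfgs iteration cap is an accepted stopping rule
            warnings.simplefilter("ignore", ConvergenceWarning)
            reg.fit(Xs, Ys if Ys.shape[1] > 1 else Ys.ravel())
        w_in = reg.coefs_[0].T
        w_out = reg.coefs_[1].T
        b_in = reg.intercepts_[0]
        b_out = np.atleast_1d(reg.intercepts_[1])
        if w_out.ndim == 1:
            w_out = w_out[None, :]
        self.net_ = SurrogateModel(
            w_in=w_in, b_in=b_in, w_out=w_out, b_out=b_out,
            x_min=x_min, x_max=x_max, y_min=np.asarray(y_min, dtype=float),
            y_max=np.asarray(y_max, dtype=float), param_names=names,
            meta={"lam": self.lam, "seed": self.seed,
                  "hidden_units": self.hidden_units,
                  "n_train": int(X.shape[0]),
                  "loss": float(reg.loss_)})
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        if not hasattr(self, "net_"):
            raise InputError("surrogate is not fitted")
        return mlp_predict(np.asarray(X, dtype=float), self.net_)


def train_surrogate(dataset: TrainingSet, hidden_units: int = 10,
                    lam: float = 1e-3, epochs: int = 2000, seed: int = 0,
                    holdout: float = 0.25) -> tuple[SurrogateModel, dict]:
    """Train the surrogate on a :class:`TrainingSet` with a held-out split.

    Labels are the NLS estimates (the surrogate learns to reproduce the
    fitting map); the report carries held-out RMSE per parameter on both the
    [0, 1] scale and raw parameter units.
    """
    n = dataset.X.shape[0]
    n_hold = max(1, int(round(holdout * n))) if holdout > 0 else 0
    if n - n_hold < 2:
        raise ConfigurationError("dataset too small for the requested split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    hold, train = order[:n_hold], order[n_hold:]

    est = MLPSurrogate(hidden_units=hidden_units, lam=lam, epochs=epochs,
                       seed=seed, label_bounds=dataset.ranges,
                       param_names=dataset.param_names)
    est.fit(dataset.X[train], dataset.Y_fit[train])
    net = est.net_

    report: dict = {"n_train": int(len(train)), "n_holdout": int(len(hold)),
                    "param_names": list(dataset.param_names)}
    if n_hold:
        pred = mlp_predict(dataset.X[hold], net)
        truth = dataset.Y_fit[hold]
        ps = minmax_scale(pred, net.y_min, net.y_max)
        ts = minmax_scale(truth, net.y_min, net.y_max)
        report["holdout_rmse_scaled"] = {
            name: rmse(ps[:, j], ts[:, j])
            for j, name in enumerate(dataset.param_names)}
        report["holdout_rmse_raw"] = {
            name: rmse(pred[:, j], truth[:, j])
            for j, name in enumerate(dataset.param_names)}
    return net, report


# --------------------------------------------------------------------------
# NLS vs surrogate comparison
# --------------------------------------------------------------------------

def compare_estimators(test_set: TrainingSet, net: SurrogateModel,
                       base: Optional[ParamSet] = None) -> dict:
    """Compare NLS and surrogate estimates against ground truth.

    The test scenarios must come from seeds disjoint from training.  NLS
    estimates and wall times are the ones recorded while building the test
    set; surrogate inference is timed per scenario here.  RMSEs are reported
    per parameter in raw units and on the [0, 1] scale of the network's
    label bounds (comparable across parameters).
    """
    names = test_set.param_names
    truth = test_set.Y_true
    nls_pred = test_set.Y_fit

    sur_pred = np.empty_like(nls_pred)
    sur_times = np.empty(truth.shape[0])
    for i, x in enumerate(test_set.X):
        t0 = time.perf_counter()
        sur_pred[i] = mlp_predict(x, net)
        sur_times[i] = time.perf_counter() - t0

    def per_param(pred):
        scaled_p = minmax_scale(np.clip(pred, net.y_min, net.y_max),
                                net.y_min, net.y_max)
        scaled_t = minmax_scale(truth, net.y_min, net.y_max)
        return (
            {n: rmse(pred[:, j], truth[:, j]) for j, n in enumerate(names)},
            {n: rmse(scaled_p[:, j], scaled_t[:, j])
             for j, n in enumerate(names)},
            rmse(scaled_p.ravel(), scaled_t.ravel()),
        )

    nls_raw, nls_scaled, nls_overall = per_param(nls_pred)
    sur_raw, sur_scaled, sur_overall = per_param(sur_pred)
    return {
        "param_names": list(names),
        "n_scenarios": int(truth.shape[0]),
        "nls": {"rmse_raw": nls_raw, "rmse_scaled": nls_scaled,
                "rmse_overall_scaled": nls_overall,
                "mean_wall_time_s": float(np.mean(test_set.fit_times))},
        "surrogate": {"rmse_raw": sur_raw, "rmse_scaled": sur_scaled,
                      "rmse_overall_scaled": sur_overall,
                      "mean_wall_time_s": float(np.mean(sur_times))},
    }
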