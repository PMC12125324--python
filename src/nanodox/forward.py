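"""Forward five-compartment doxorubicin transport model.

Compartments (concentrations, model units consistent with uM):

* ``w1`` systemic plasma, ``w3`` body tissue — a closed two-compartment
  exchange with first-order elimination ``k10`` from plasma;
* ``w2`` tumor plasma — coupled to systemic plasma by perfusion ``Fpv_t``
  and to the tumor EES by the permeability–surface-area product ``ps``;
* ``w4`` tumor extracellular-extravascular space (EES);
* ``w5`` tumor intracellular space — fed by a saturable (Michaelis–Menten)
  plus passive uptake flux with linear efflux.

Two right-hand-side variants are provided.  ``mass_consistent`` (the
default) balances the transvascular and cellular-uptake fluxes so that mass
is conserved when elimination and perfusion are switched off; it is the mode
used for all quantitative work.  ``as_printed`` reproduces the published
equation set verbatim, including its sign conventions, and is retained for
documentation and symbolic-fidelity testing only — with both transvascular
terms negative the EES level can never rise from zero, so it is excluded
from positivity and conservation guarantees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .errors import ConfigurationError, InputError, IntegrationError
from .params import ForwardParams, ParamSet

__all__ = [
    "ForwardState", "ForwardTrajectory", "forward_rhs", "simulate_forward",
    "two_compartment_closed_form", "peak_metrics", "default_grid",
    "STATE_NAMES",
]

STATE_NAMES = ("w1", "w3", "w2", "w4", "w5")
_MODES = ("as_printed", "mass_consistent")


@dataclass(frozen=True)
class ForwardState:
    """Concentrations of the five forward compartments at one time."""

    w1: float = 0.0
    w3: float = 0.0
    w2: float = 0.0
    w4: float = 0.0
    w5: float = 0.0
    time: float = 0.0

    def as_vector(self) -> np.ndarray:
        return np.array([self.w1, self.w3, self.w2, self.w4, self.w5])


@dataclass(frozen=True)
class ForwardTrajectory:
    """A solved forward trajectory on a fixed output grid."""

    time: np.ndarray                 # [min], strictly increasing
    states: np.ndarray               # shape (len(time), 5), columns STATE_NAMES
    equation_mode: str = "mass_consistent"
    solver: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.time) <= 0):
            raise InputError("trajectory time grid must be strictly increasing")

    def column(self, name: str) -> np.ndarray:
        return self.states[:, STATE_NAMES.index(name)]

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.states, columns=list(STATE_NAMES))
        df.insert(0, "time_min", self.time)
        return df


def uptake_flux(w4: float, w5: float, p: ForwardParams) -> float:
    """Shared cellular-uptake flux J_up acting on unbound EES drug.

    ``J_up = k3wi * (k1wi*w4e + k2wi*w4e/(kiwi + w4e) - k5wi*w5)`` with
    ``w4e = w4 * UDOXe``: passive (linear) entry, saturable carrier entry,
    and linear efflux from the intracellular pool.
    """
    w4e = w4 * p.UDOXe
    return p.k3wi * (p.k1wi * w4e + p.k2wi * w4e / (p.kiwi + w4e)
                     - p.k5wi * w5)


def forward_rhs(state, p: ForwardParams, mode: str = "mass_consistent"):
    """Right-hand side of the forward model.

    ``state`` is a :class:`ForwardState` or a length-5 vector ordered as
    ``(w1, w3, w2, w4, w5)``; the returned derivative vector uses the same
    ordering.  See the module docstring for the two modes.
    """
    if mode not in _MODES:
        raise ConfigurationError(f"unknown mode {mode!r}; expected {_MODES}")
    if isinstance(state, ForwardState):
        state = state.as_vector()
    w1, w3, w2, w4, w5 = np.asarray(state, dtype=float)
    if p.Vp_t is None or p.Fpv_t is None:
        raise ConfigurationError(
            "forward_rhs requires derived quantities (Vp_t, Fpv_t); "
            "call derive_quantities first")

    dw1 = -(p.k12 + p.k10) * w1 + p.k21 * w3
    dw3 = p.k12 * w1 - p.k21 * w3

    if mode == "mass_consistent":
        transvascular = p.ps * (w4 * p.UDOXe - w2 * p.UDOX)
        dw2 = transvascular / p.Vp_t + p.Fpv_t * (w1 - w2)
        jup = uptake_flux(w4, w5, p)
        dw4 = -transvascular / p.Ve_t - jup / p.Ve_t
        dw5 = jup
    else:  # as_printed: published signs and groupings, kept verbatim
        dw2 = (-(p.ps / p.Vp_t) * (w2 * p.UDOX)
               + (p.ps / p.Vp_t) * (w4 * p.UDOXe)
               - p.Fpv_t * w2 + p.Fpv_t * w1)
        w4e = w4 * p.UDOXe
        dw4 = (-(p.ps / p.Ve_t) * (w2 * p.UDOX)
               - (p.ps / p.Ve_t) * w4e
               - p.k3wi * ((p.k1wi * w4e + p.k2wi * w4e) / (p.kiwi + w4e)
                           - p.k5wi * w5))
        dw5 = p.k3wi * (p.k1wi * w4 + p.k2wi * w4 / (p.kiwi + w4)
                        - p.k5wi * w5)
    return np.array([dw1, dw3, dw2, dw4, dw5])


def default_grid(t_end: float = 2000.0, n: int = 2001) -> np.ndarray:
    """Default output grid: ``n`` evenly spaced points on [0, t_end] minutes."""
    return np.linspace(0.0, t_end, n)


def simulate_forward(
    p: ForwardParams | ParamSet,
    init: ForwardState | Sequence[float] | None = None,
    grid: Optional[np.ndarray] = None,
    mode: str = "mass_consistent",
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> ForwardTrajectory:
    """Integrate the forward model on a fixed output grid.

    With ``init=None`` the plasma compartment starts at the derived
    ``w1_init = D/VD`` and all other compartments at zero.
    """
    if isinstance(p, ParamSet):
        p = p.forward
    if mode not in _MODES:
        raise ConfigurationError(f"unknown mode {mode!r}; expected {_MODES}")
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise InputError("grid must be a strictly increasing 1-D array")
    if init is None:
        if p.w1_init is None:
            raise ConfigurationError("w1_init not derived; call derive_quantities")
        y0 = np.array([p.w1_init, 0.0, 0.0, 0.0, 0.0])
    elif isinstance(init, ForwardState):
        y0 = init.as_vector()
    else:
        y0 = np.asarray(init, dtype=float)
    if np.any(y0 < 0):
        raise InputError("initial concentrations must be nonnegative")

    sol = solve_ivp(
        lambda t, y: forward_rhs(y, p, mode),
        (grid[0], grid[-1]), y0, t_eval=grid,
        method=method, rtol=rtol, atol=atol,
    )
    if not sol.success:
        last = sol.t[-1] if sol.t.size else grid[0]
        raise IntegrationError(f"forward integration failed: {sol.message}",
                               last_time=float(last))
    meta = {"method": method, "rtol": rtol, "atol": atol,
            "n_steps": int(sol.t.size), "nfev": int(sol.nfev)}
    return ForwardTrajectory(grid, sol.y.T, equation_mode=mode, solver=meta)


def two_compartment_closed_form(k12: float, k21: float, k10: float,
                                w1_0: float, t):
    """Analytic biexponential solution of the (w1, w3) subsystem.

    The linear system ``dw1 = -(k12+k10) w1 + k21 w3``,
    ``dw3 = k12 w1 - k21 w3`` with ``w3(0)=0`` has eigenvalues given by the
    quadratic ``lam^2 + (k12+k10+k21) lam + k10 k21 = 0``; this routine
    returns the explicit eigen-solution and serves as the integration
    oracle for the numerical solver.
    """
    if min(k12, k21, k10) < 0 or w1_0 < 0:
        raise InputError("rate constants and w1_0 must be >= 0")
    t = np.asarray(t, dtype=float)
    a = k12 + k10
    s = a + k21                      # -(trace)
    prod = k10 * k21                 # determinant of -A
    disc = math.sqrt(max(s * s - 4.0 * prod, 0.0))
    lam1 = -(s + disc) / 2.0
    lam2 = -(s - disc) / 2.0
    if abs(lam1 - lam2) < 1e-14 * max(1.0, abs(lam1)):
        # defective (repeated eigenvalue) corner: fall back to expm
        from scipy.linalg import expm

        A = np.array([[-a, k21], [k12, -k21]])
        pts = np.atleast_1d(t)
        out = np.array([expm(A * ti) @ [w1_0, 0.0] for ti in pts])
        w1, w3 = out[:, 0], out[:, 1]
    else:
        # w1(t) = c1 e^{lam1 t} + c2 e^{lam2 t}; w3 from the first equation
        # via w3 = (dw1 + a w1)/k21 when k21 > 0, else direct integration.
        c2 = w1_0 * (lam1 + a) / (lam1 - lam2)
        c1 = w1_0 - c2
        e1 = np.exp(lam1 * t)
        e2 = np.exp(lam2 * t)
        w1 = c1 * e1 + c2 * e2
        if k21 > 0:
            w3 = (c1 * (lam1 + a) * e1 + c2 * (lam2 + a) * e2) / k21
        else:
            # with k21 = 0: w3(t) = k12 * w1_0 * (1 - e^{-a t}) / a
            if a > 0:
                w3 = k12 * w1_0 * (1.0 - np.exp(-a * t)) / a
            else:
                w3 = np.zeros_like(t)
    if np.ndim(t) == 0:
        return float(np.squeeze(w1)), float(np.squeeze(w3))
    return w1, w3


def peak_metrics(traj: ForwardTrajectory) -> dict:
    """Per-compartment peak value, peak time, and trapezoidal AUC."""
    if traj.time.size == 0:
        raise InputError("empty trajectory")
    out = {}
    for name in STATE_NAMES:
        series = traj.column(name)
        i = int(np.argmax(series))
        out[name] = {
            "peak": float(series[i]),
            "peak_time": float(traj.time[i]),
            "auc": float(np.trapezoid(series, traj.time)),
        }
    return out
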