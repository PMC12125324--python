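"""Reverse signaling path: bio-nanosensor to bio-cyber interface.

A bio-nanosensor releases ``n0`` uM of information molecules into the tumor
intracellular compartment ``v2``; the molecules exchange with systemic
plasma ``v1`` (rates ``k12r``/``k21r``), are eliminated at ``k10`` and bind
receptors at ``k1``.  The receptor-bound signal ``g_r = k1 v1`` is
conditioned into a transcription factor ``m = mu * g_r`` that drives
luciferase expression through a two-stage (mRNA, protein) gene-expression
model with Hill-type activation:

    dM/dt = kr * H(m) - gamma_r * M,   H(m) = m^h / (K^h + m^h)
    dL/dt = kp * M    - gamma_p * L

Luciferase L reacts with ATP (held at concentration X) and produces light
with Michaelis-Menten intensity ``I = alphaL * L * X / (X + alphaM)``.  The
interface normalizes I(t) to its own maximum and decodes a bit stream by
thresholding: ``c_r(t) = 1`` iff normalized ``I(t) >= I0``.

The luciferase gene-expression stage is the standard two-stage activation
model; its Hill constants default to ``h=1`` and ``K=0.01`` (the order of
magnitude of the transcription-factor signal produced by the default
reverse constants) and are fully configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from .errors import InputError, IntegrationError
from .params import ParamSet, ReverseParams, SignalingParams

__all__ = [
    "ReverseState", "ReverseTrajectory", "reverse_rhs", "receptor_signal",
    "gene_expression_rhs", "bioluminescence_intensity", "threshold_decision",
    "simulate_reverse",
]


@dataclass(frozen=True)
class ReverseState:
    """Reverse-path state at one time: sensor molecules, mRNA, luciferase."""

    v1: float = 0.0      # plasma information-molecule concentration [uM]
    v2: float = 0.0      # tumor intracellular concentration [uM]
    M_rna: float = 0.0   # luciferase mRNA level
    L: float = 0.0       # luciferase concentration
    time: float = 0.0

    def as_vector(self) -> np.ndarray:
        return np.array([self.v1, self.v2, self.M_rna, self.L])


@dataclass(frozen=True)
class ReverseTrajectory:
    """Solved reverse chain with derived signal, intensity and bit series."""

    time: np.ndarray
    v1: np.ndarray
    v2: np.ndarray
    M_rna: np.ndarray
    L: np.ndarray
    g_r: np.ndarray          # receptor-bound signal k1 * v1
    m: np.ndarray            # transcription factor mu * g_r
    intensity: np.ndarray    # raw bioluminescence I(t) [a.u.]
    intensity_norm: np.ndarray  # I(t) / max I(t) (zeros if I == 0)
    bits: np.ndarray         # decoded c_r(t) in {0, 1}
    solver: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.time) <= 0):
            raise InputError("trajectory time grid must be strictly increasing")

    def first_crossing_time(self) -> Optional[float]:
        """Earliest grid time with decoded bit 1, or None if never crossed."""
        idx = np.flatnonzero(self.bits == 1)
        return float(self.time[idx[0]]) if idx.size else None

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "time_min": self.time, "v1": self.v1, "v2": self.v2,
            "g_r": self.g_r, "m": self.m, "mrna": self.M_rna, "lu": self.L,
            "intensity": self.intensity, "bit": self.bits,
        })


def reverse_rhs(state, p: ReverseParams):
    """Two-compartment sensor-molecule kinetics.

    ``dv1 = k21r v2 - (k12r + k10 + k1) v1``; ``dv2 = k12r v1 - k21r v2``.
    Accepts a :class:`ReverseState` or a vector whose first two entries are
    ``(v1, v2)``; returns ``(dv1, dv2)``.
    """
    if isinstance(state, ReverseState):
        v1, v2 = state.v1, state.v2
    else:
        v1, v2 = np.asarray(state, dtype=float)[:2]
    dv1 = p.k21r * v2 - (p.k12r + p.k10 + p.k1) * v1
    dv2 = p.k12r * v1 - p.k21r * v2
    return np.array([dv1, dv2])


def receptor_signal(v1, p: ReverseParams):
    """Receptor-bound signal and conditioned transcription factor.

    ``g_r = k1 * v1`` and ``m = mu * g_r``; both linear and homogeneous in
    ``v1``.  Works on scalars or arrays.
    """
    v1 = np.asarray(v1, dtype=float)
    if np.any(v1 < 0):
        raise InputError("v1 must be >= 0")
    g_r = p.k1 * v1
    m = p.mu * g_r
    if g_r.ndim == 0:
        return float(g_r), float(m)
    return g_r, m


def hill_activation(m, sp: SignalingParams):
    """Hill transcription activation ``H(m) = m^h / (K^h + m^h)``; H(0)=0."""
    m = np.asarray(m, dtype=float)
    mh = np.power(m, sp.hill_h)
    out = mh / (sp.hill_K ** sp.hill_h + mh)
    return float(out) if out.ndim == 0 else out


def gene_expression_rhs(M_rna: float, L: float, m: float,
                        sp: SignalingParams) -> np.ndarray:
    """mRNA/protein derivatives for the luciferase expression stage."""
    if min(M_rna, L, m) < 0:
        raise InputError("levels must be >= 0")
    dM = sp.kr * hill_activation(m, sp) - sp.gamma_r * M_rna
    dL = sp.kp * M_rna - sp.gamma_p * L
    return np.array([dM, dL])


def bioluminescence_intensity(L, sp: SignalingParams):
    """Michaelis-Menten light output ``I = alphaL * L * X / (X + alphaM)``."""
    L = np.asarray(L, dtype=float)
    if np.any(L < 0):
        raise InputError("luciferase concentration must be >= 0")
    out = sp.alphaL * L * sp.atp / (sp.atp + sp.alphaM)
    return float(out) if out.ndim == 0 else out


def threshold_decision(I, I0: float):
    """Decode intensity into a bit: 1 iff ``I >= I0`` (boundary maps to 1)."""
    I = np.asarray(I, dtype=float)
    if np.any(I < 0) or I0 < 0:
        raise InputError("intensities must be >= 0")
    out = (I >= I0).astype(int)
    return int(out) if out.ndim == 0 else out


def simulate_reverse(
    p: ReverseParams | ParamSet,
    sp: SignalingParams | None = None,
    grid: Optional[np.ndarray] = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    norm_ref: Optional[float] = None,
) -> ReverseTrajectory:
    """Integrate the full reverse chain and decode the bit series.

    Initial conditions follow the sensing scenario: ``v2(0) = n0`` (the
    sensor has just released its molecules intracellularly), ``v1(0) = 0``,
    and no pre-existing mRNA or luciferase.  The decoded bit series applies
    the threshold ``I0`` to the *normalized* intensity.

    ``norm_ref`` sets the reference intensity of the normalized scale.  By
    default each trajectory is normalized to its own maximum (the way the
    readout curves are usually plotted); a detector comparing different
    sensor loads against one fixed threshold should instead pass the peak
    intensity of its calibration configuration, so that the threshold has a
    fixed absolute meaning.
    """
    if isinstance(p, ParamSet):
        if sp is None:
            sp = p.signaling
        p = p.reverse
    if sp is None:
        sp = SignalingParams()
    if grid is None:
        grid = np.linspace(0.0, 2000.0, 2001)
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise InputError("grid must be a strictly increasing 1-D array")

    def rhs(t, y):
        v1, v2, M, L = y
        dv1, dv2 = reverse_rhs((v1, v2), p)
        m = p.mu * p.k1 * v1
        dM = sp.kr * hill_activation(m, sp) - sp.gamma_r * M
        dL = sp.kp * M - sp.gamma_p * L
        return (dv1, dv2, dM, dL)

    y0 = np.array([0.0, p.n0, 0.0, 0.0])
    sol = solve_ivp(rhs, (grid[0], grid[-1]), y0, t_eval=grid,
                    method=method, rtol=rtol, atol=atol)
    if not sol.success:
        last = sol.t[-1] if sol.t.size else grid[0]
        raise IntegrationError(f"reverse integration failed: {sol.message}",
                               last_time=float(last))
    v1, v2, M, L = sol.y
    g_r, m = receptor_signal(np.clip(v1, 0.0, None), p)
    intensity = bioluminescence_intensity(np.clip(L, 0.0, None), sp)
    ref = float(intensity.max()) if norm_ref is None else float(norm_ref)
    norm = intensity / ref if ref > 0 else np.zeros_like(intensity)
    bits = threshold_decision(norm, sp.I0)
    meta = {"method": method, "rtol": rtol, "atol": atol,
            "nfev": int(sol.nfev)}
    return ReverseTrajectory(grid, v1, v2, M, L, g_r, m, intensity, norm,
                             bits, solver=meta)
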