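"""Forward bio-cyber transduction: command decoding and liposomal DOX release.

A 3-bit command received by the bio-cyber interface selects the physical
stimulus applied to the liposome store: ``011`` activates the thermal source
(thermo-sensitive liposomes), ``111`` the optical source (photo-sensitive
liposomes).  Release from a stimulated liposome population follows
first-order kinetics, so the instantaneous released concentration is

    omega(t) = omega_R * delta * exp(-delta * t),

the time derivative of ``omega_R (1 - exp(-delta t))``, and the cumulative
amount delivered while the stimulation window of length ``R_IN`` is open is

    g_f = xi * omega_R * (1 - exp(-delta * R_IN)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .params import ReleaseParams

__all__ = ["Stimulus", "decode_command", "release_rate", "cumulative_release",
           "window_close_rate"]

_CODE_MAP = {"011": "thermal", "111": "photo"}


@dataclass(frozen=True)
class Stimulus:
    """A decoded release stimulus: kind, rate constant and window length."""

    kind: str                 # {"thermal", "photo", "none"}
    delta: float = 0.0        # release rate constant [1/min]
    window: float = 0.0       # R_IN [min]

    def __post_init__(self) -> None:
        if self.kind not in ("thermal", "photo", "none"):
            raise InputError(f"unknown stimulus kind {self.kind!r}")
        if self.kind != "none" and not self.delta > 0:
            raise InputError("delta must be > 0 for an active stimulus")


def decode_command(bits: str, p: ReleaseParams | None = None) -> Stimulus:
    """Decode a 3-bit command string into a release stimulus.

    Only two codes are mapped (``011`` thermal, ``111`` photo); every other
    3-bit code is a deliberate no-op (``Stimulus('none')``) — an unmapped
    command must not trigger a release.
    """
    if not isinstance(bits, str) or len(bits) != 3 or set(bits) - {"0", "1"}:
        raise InputError(
            f"command must be a 3-character string over {{0,1}}, got {bits!r}")
    p = p if p is not None else ReleaseParams()
    kind = _CODE_MAP.get(bits, "none")
    if kind == "none":
        return Stimulus("none", 0.0, p.R_IN)
    delta = p.delta_t if kind == "thermal" else p.delta_l
    return Stimulus(kind, delta, p.R_IN)


def release_rate(t, p: ReleaseParams, s: Stimulus):
    """Instantaneous released DOX concentration omega(t) [conc/min].

    Integrates to ``omega_R`` over [0, inf).  Accepts scalar or array times.
    """
    if s.kind == "none":
        raise InputError("release_rate requires an active stimulus")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InputError("time must be >= 0")
    out = p.omegaR * s.delta * np.exp(-s.delta * t)
    return float(out) if out.ndim == 0 else out


def cumulative_release(p: ReleaseParams, s: Stimulus) -> float:
    """Total DOX amount g_f delivered over the stimulation window.

    ``g_f = xi * omega_R * (1 - exp(-delta * R_IN))``; monotone nondecreasing
    in the window length and saturating at ``xi * omega_R``.
    """
    if s.kind == "none":
        return 0.0
    window = s.window
    # expm1 keeps accuracy for short windows (delta * R_IN << 1)
    return p.xi * p.omegaR * (-math.expm1(-s.delta * window))


def window_close_rate(p: ReleaseParams, s: Stimulus) -> float:
    """Diagnostic: instantaneous population release rate at window close.

    This is ``xi * omega(R_IN)``, reported for monitoring only; the delivered
    dose handed to the pharmacokinetic stage is :func:`cumulative_release`.
    """
    if s.kind == "none":
        return 0.0
    return p.xi * release_rate(s.window, p, s)
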