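"""Time-unit handling for kinetic rate constants.

The simulation time base is minutes throughout the package; transport and
kinetic constants quoted per hour or per second are converted once, at load
time, so every right-hand side works on a single consistent scale.
"""

from __future__ import annotations

from .errors import ConfigurationError

#: minutes contained in one unit of each supported time base
_MINUTES_PER_UNIT = {
    "per_second": 1.0 / 60.0,
    "per_minute": 1.0,
    "per_hour": 60.0,
}

_ALIASES = {
    "s^-1": "per_second",
    "1/s": "per_second",
    "per_s": "per_second",
    "min^-1": "per_minute",
    "1/min": "per_minute",
    "per_min": "per_minute",
    "h^-1": "per_hour",
    "1/h": "per_hour",
    "per_h": "per_hour",
}


def canonical_time_unit(unit: str) -> str:
    u = unit.strip().lower()
    u = _ALIASES.get(u, u)
    if u not in _MINUTES_PER_UNIT:
        raise ConfigurationError(
            f"unknown time unit {unit!r}; expected one of "
            f"{sorted(_MINUTES_PER_UNIT)} (or aliases {sorted(_ALIASES)})"
        )
    return u


def convert_rate(value: float, from_unit: str, to_unit: str) -> float:
    """Rescale a first-order rate constant between time bases.

    A rate of ``r`` per *from_unit* equals ``r / minutes(from_unit)`` per
    minute, so conversion multiplies by ``minutes(to_unit)/minutes(from_unit)``.
    Round-tripping is the identity to machine precision.
    """
    f = canonical_time_unit(from_unit)
    t = canonical_time_unit(to_unit)
    return value * _MINUTES_PER_UNIT[t] / _MINUTES_PER_UNIT[f]
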