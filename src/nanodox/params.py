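"""Typed parameter registry for the bio-cyber drug-delivery simulator.

Four parameter groups cover the whole framework:

* :class:`ForwardParams` — the five-compartment doxorubicin (DOX) transport
  model: systemic plasma w1, body tissue w3, tumor plasma w2, tumor
  extracellular-extravascular space (EES) w4 and tumor intracellular space w5.
* :class:`ReverseParams` — the bio-nanosensor two-compartment kinetics that
  carry molecular information back toward the bio-cyber interface.
* :class:`ReleaseParams` — stimulated liposomal release of the encapsulated
  drug (thermal or photo trigger).
* :class:`SignalingParams` — receptor signal conditioning, luciferase gene
  expression, Michaelis–Menten bioluminescence and the decision threshold.

All rate constants are stored normalized to the simulation time base of
minutes; constants quoted per hour in the literature are divided by 60 at
load time.  Serialized profiles carry explicit ``{value, unit}`` tags so a
constant can never silently change time base on the way in or out.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Optional

from .errors import ConfigurationError
from .units import canonical_time_unit, convert_rate

__all__ = [
    "ForwardParams",
    "ReverseParams",
    "ReleaseParams",
    "SignalingParams",
    "ParamSet",
    "load_defaults",
    "derive_quantities",
    "convert_rate",
]


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigurationError(msg)


@dataclass(frozen=True)
class ForwardParams:
    """Five-compartment forward transport parameters (time base: minutes)."""

    # systemic two-compartment kinetics
    k12: float = 9.4e-3      # plasma -> body tissue [1/min]
    k21: float = 7.052e-5    # body tissue -> plasma [1/min]
    k10: float = 2.1e-3      # systemic elimination [1/min]
    # tumor transvascular / perfusion exchange
    ps: float = 4.9e-3       # permeability-surface-area product [1/min scale]
    UDOX: float = 1.0        # unbound DOX fraction in plasma
    UDOXe: float = 1.0       # unbound DOX fraction in the EES
    # cellular uptake (saturable + passive), values used as tabulated
    k1wi: float = 2.257
    k2wi: float = 0.0452
    k3wi: float = 2.806e-4
    k5wi: float = 10.0
    kiwi: float = 5.29e-4
    # tumor geometry / composition
    Vv_t: float = 0.092      # fractional vascular volume
    Ve_t: float = 0.454      # fractional EES volume
    Vt_t: float = 0.454      # EES volume fraction (tabulated alongside Ve_t)
    Hct_t: float = 0.19      # tumor microvascular hematocrit
    rho_t: float = 1.06      # tissue density [g/ml]
    # perfusion
    W0: Optional[float] = 0.02   # blood perfusion [ml g^-1 min^-1]
    BV: Optional[float] = None   # blood volume fraction term; derived 0.063*rho_t
    Fpv_t: Optional[float] = None  # perfusion rate W0/BV [1/min]
    Vp_t: Optional[float] = None   # fractional plasma volume; derived Vv_t*(1-Hct_t)
    # dosing
    D: float = 0.7           # injected dose
    VD: float = 100.0        # distribution volume
    omega0: float = 0.7      # commanded/injected drug concentration
    w1_init: Optional[float] = None  # initial plasma concentration D/VD

    def __post_init__(self) -> None:
        for name in ("k12", "k21", "k10", "ps", "k1wi", "k2wi", "k3wi",
                     "k5wi", "kiwi"):
            _require(getattr(self, name) >= 0, f"{name} must be >= 0")
        _require(0 <= self.Hct_t < 1, "Hct_t must lie in [0, 1)")
        _require(0 < self.Ve_t <= 1, "Ve_t must lie in (0, 1]")
        _require(0 <= self.UDOX <= 1 and 0 <= self.UDOXe <= 1,
                 "unbound fractions must lie in [0, 1]")
        _require(self.VD > 0, "VD must be > 0")
        if self.Vp_t is not None:
            _require(0 < self.Vp_t <= 1, "Vp_t must lie in (0, 1]")


@dataclass(frozen=True)
class ReverseParams:
    """Bio-nanosensor two-compartment kinetics (time base: minutes)."""

    k12r: float = 0.103e-2   # plasma -> tumor intracellular influx [1/min]
    k21r: float = 0.373      # tumor intracellular -> plasma efflux [1/min]
    k1: float = 0.1e-2       # ligand-receptor binding constant [1/min]
    k10: float = 2.1e-3      # elimination [1/min]
    n0: float = 8.0          # initial bio-nanosensor molecule conc. [uM]
    mu: float = 1.0          # cellular-surface signal conditioning factor

    def __post_init__(self) -> None:
        for name in ("k12r", "k21r", "k1", "k10", "n0", "mu"):
            _require(getattr(self, name) >= 0, f"{name} must be >= 0")


@dataclass(frozen=True)
class ReleaseParams:
    """Stimulated liposomal DOX release (time base: minutes)."""

    xi: float = 100.0        # total number of liposomes (dimensionless count)
    omegaR: float = 0.007    # releasable DOX concentration per liposome unit
    delta_t: float = 0.0078  # thermal release rate constant [1/min]
    delta_l: float = 1.04e-4  # photo (UV) release rate constant [1/min]
    R_IN: float = 60.0       # stimulation window [min]

    def __post_init__(self) -> None:
        _require(self.xi >= 0 and float(self.xi).is_integer(),
                 "xi must be a nonnegative integer count")
        _require(self.delta_t > 0 and self.delta_l > 0,
                 "release rate constants must be > 0")
        _require(self.R_IN >= 0 and self.omegaR >= 0,
                 "R_IN and omegaR must be >= 0")


@dataclass(frozen=True)
class SignalingParams:
    """Receptor signal, gene expression and bioluminescence readout.

    Transcription/translation and degradation rates are quoted per hour in
    the literature and stored here already divided by 60.
    """

    alphaL: float = 0.044        # catalytic (luciferase turnover) constant
    alphaM: float = 15.0         # Michaelis-Menten constant [uM]
    atp: float = 40.0            # ATP concentration X, held constant
    kr: float = 10.0 / 60.0      # transcription rate [1/min] (10 h^-1)
    kp: float = 150.0 / 60.0     # translation rate [1/min] (150 h^-1)
    gamma_r: float = 10.05 / 60.0  # mRNA degradation [1/min] (10.05 h^-1)
    gamma_p: float = 4.15 / 60.0   # protein degradation [1/min] (4.15 h^-1)
    hill_K: float = 0.01         # half-saturation of TF activation
    hill_h: float = 1.0          # Hill coefficient
    I0: float = 0.7              # decision threshold on normalized I [a.u.]

    def __post_init__(self) -> None:
        _require(self.alphaM > 0, "alphaM must be > 0")
        _require(self.gamma_r > 0 and self.gamma_p > 0,
                 "degradation rates must be > 0")
        _require(self.hill_h >= 1, "hill_h must be >= 1")
        _require(self.hill_K > 0, "hill_K must be > 0")
        _require(self.I0 >= 0, "I0 must be >= 0")


# units for serialization; "1" marks a dimensionless quantity
_UNITS = {
    "forward": {
        "k12": "per_minute", "k21": "per_minute", "k10": "per_minute",
        "ps": "per_minute", "UDOX": "1", "UDOXe": "1",
        "k1wi": "1", "k2wi": "1", "k3wi": "1", "k5wi": "1", "kiwi": "1",
        "Vv_t": "1", "Ve_t": "1", "Vt_t": "1", "Hct_t": "1",
        "rho_t": "g/ml", "W0": "ml/g/min", "BV": "1",
        "Fpv_t": "per_minute", "Vp_t": "1",
        "D": "dose", "VD": "volume", "omega0": "uM", "w1_init": "uM",
    },
    "reverse": {
        "k12r": "per_minute", "k21r": "per_minute", "k1": "per_minute",
        "k10": "per_minute", "n0": "uM", "mu": "1",
    },
    "release": {
        "xi": "count", "omegaR": "uM", "delta_t": "per_minute",
        "delta_l": "per_minute", "R_IN": "min",
    },
    "signaling": {
        "alphaL": "1", "alphaM": "uM", "atp": "uL",
        "kr": "per_minute", "kp": "per_minute",
        "gamma_r": "per_minute", "gamma_p": "per_minute",
        "hill_K": "uM", "hill_h": "1", "I0": "a.u.",
    },
}

# derived forward fields and the inputs that invalidate them when changed
_DERIVED_DEPENDENCIES = {
    "Vp_t": ("Vv_t", "Hct_t"),
    "BV": ("rho_t",),
    "Fpv_t": ("W0", "BV", "rho_t"),
    "w1_init": ("D", "VD"),
}


@dataclass(frozen=True)
class ParamSet:
    """The full named parameter registry for one simulation setup."""

    forward: ForwardParams = field(default_factory=ForwardParams)
    reverse: ReverseParams = field(default_factory=ReverseParams)
    release: ReleaseParams = field(default_factory=ReleaseParams)
    signaling: SignalingParams = field(default_factory=SignalingParams)

    # -- flat-name access -------------------------------------------------

    def _locate(self, name: str) -> tuple[str, str]:
        for group in ("forward", "reverse", "release", "signaling"):
            if name in _UNITS[group]:
                return group, name
        raise ConfigurationError(self._unknown_key_message(name))

    def _unknown_key_message(self, name: str) -> str:
        import difflib

        candidates = [k for g in _UNITS.values() for k in g]
        close = difflib.get_close_matches(name, candidates, n=3)
        hint = f"; did you mean {', '.join(close)}?" if close else ""
        return f"unknown parameter {name!r}{hint}"

    def get(self, name: str) -> float:
        group, key = self._locate(name)
        return getattr(getattr(self, group), key)

    def with_value(self, name: str, value: float) -> "ParamSet":
        """Return a copy with one named parameter replaced.

        Setting an input of a derived forward quantity (e.g. ``W0`` for
        ``Fpv_t``) invalidates and recomputes the derived value; setting a
        derived quantity directly acts as an explicit override.
        """
        group, key = self._locate(name)
        sub = getattr(self, group)
        sub = replace(sub, **{key: value})
        if group == "forward" and key not in _DERIVED_DEPENDENCIES:
            stale = {d: None for d, deps in _DERIVED_DEPENDENCIES.items()
                     if key in deps}
            if stale:
                sub = replace(sub, **stale)
        new = replace(self, **{group: sub})
        return derive_quantities(new) if group == "forward" else new

    def names(self) -> list[str]:
        return [k for g in _UNITS.values() for k in g]

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        out: dict = {}
        for group in ("forward", "reverse", "release", "signaling"):
            sub = getattr(self, group)
            out[group] = {
                f.name: {"value": getattr(sub, f.name),
                         "unit": _UNITS[group][f.name]}
                for f in fields(sub)
            }
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, doc: dict) -> "ParamSet":
        groups = {}
        classes = {"forward": ForwardParams, "reverse": ReverseParams,
                   "release": ReleaseParams, "signaling": SignalingParams}
        for group, klass in classes.items():
            kwargs = {}
            for key, entry in doc.get(group, {}).items():
                if key not in _UNITS[group]:
                    raise ConfigurationError(
                        f"unknown parameter {group}.{key!r}")
                if not isinstance(entry, dict) or "value" not in entry \
                        or "unit" not in entry:
                    raise ConfigurationError(
                        f"parameter {group}.{key} must be tagged as "
                        "{value, unit}; bare numbers are rejected")
                value = entry["value"]
                if value is not None:
                    value = _normalize(value, entry["unit"],
                                       _UNITS[group][key], f"{group}.{key}")
                kwargs[key] = value
            groups[group] = klass(**kwargs)
        return cls(**groups)

    @classmethod
    def from_json(cls, path: str | Path) -> "ParamSet":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _normalize(value: float, unit: str, expected: str, label: str) -> float:
    """Convert a tagged value to the registry's canonical unit."""
    if expected == "per_minute":
        return convert_rate(value, canonical_time_unit(unit), "per_minute")
    if unit != expected:
        raise ConfigurationError(
            f"{label}: unit {unit!r} does not match expected {expected!r}")
    return value


def derive_quantities(p: ParamSet) -> ParamSet:
    """Fill in derived forward quantities; idempotent.

    ``Vp_t = Vv_t (1 - Hct_t)``; ``BV = (6.3/100) rho_t`` when not overridden;
    ``Fpv_t = W0 / BV`` unless an explicit ``Fpv_t`` override is present;
    ``w1_init = D / VD``.
    """
    f = p.forward
    updates: dict = {}
    if f.Vp_t is None:
        updates["Vp_t"] = f.Vv_t * (1.0 - f.Hct_t)
    if f.BV is None:
        updates["BV"] = (6.3 / 100.0) * f.rho_t
    if f.Fpv_t is None:
        bv = updates.get("BV", f.BV)
        if f.W0 is None:
            raise ConfigurationError(
                "Fpv_t cannot be derived: provide W0 (with BV or rho_t) "
                "or an explicit Fpv_t override")
        updates["Fpv_t"] = f.W0 / bv
    if f.w1_init is None:
        updates["w1_init"] = f.D / f.VD
    if not updates:
        return p
    return replace(p, forward=replace(f, **updates))


_PROFILES = ("forward_default", "reverse_default")


def load_defaults(profile: str = "forward_default") -> ParamSet:
    """Load the default parameter registry for a named profile.

    Both profiles currently share the same tabulated registry (the forward
    and reverse constants live side by side); two names are kept so callers
    state which direction they are configuring.
    """
    if profile not in _PROFILES:
        raise ConfigurationError(
            f"unknown profile {profile!r}; expected one of {_PROFILES}")
    return derive_quantities(ParamSet())
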