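"""Solvent descriptors and reference-electrode scale conversions.

The model's only view of a solvent is the pair (epsilon, n): the static
dielectric constant and the refractive index at 25 C.  The registry ships
standard literature values for the five training solvents; every value is
overridable by registering a replacement, so tabulated values from other
sources can be dropped in verbatim.

Reference electrodes are represented by their potential on the absolute
scale; converting a window reported vs. Fc0/Fc+ or Li/Li+ to absolute is
plain addition of the registered offset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from redoxsolv.thermocycle import E_REF_SHE

__all__ = [
    "SolventSpec",
    "ReferenceElectrode",
    "TRAINING_SOLVENTS",
    "get_solvent",
    "register_solvent",
    "list_solvents",
    "get_reference",
    "register_reference",
    "descriptor_vector",
    "onsager_descriptors",
    "to_absolute",
    "to_relative",
]


@dataclass(frozen=True)
class SolventSpec:
    """A solvent as the model sees it: a name and the (epsilon, n) pair."""

    name: str
    epsilon: float
    refractive_index: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.epsilon) and self.epsilon > 1.0):
            raise ValueError(f"dielectric constant must be finite and > 1, got {self.epsilon}")
        if not (math.isfinite(self.refractive_index) and self.refractive_index >= 1.0):
            raise ValueError(
                f"refractive index must be finite and >= 1, got {self.refractive_index}"
            )


@dataclass(frozen=True)
class ReferenceElectrode:
    """A reference couple pinned to the absolute potential scale.

    ``offset_volts`` is the electrode's potential on the absolute scale with
    the sign such that  absolute = relative + offset_volts.  For SHE this is
    +4.48 V (the negation of E_REF = -4.48 V in the potential equation).
    """

    name: str
    offset_volts: float
    solvent_scope: str | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.offset_volts):
            raise ValueError("reference offset must be finite")


# Static dielectric constants and refractive indices at 25 C, standard
# literature values (CRC Handbook).  User-overridable via register_solvent.
_SOLVENTS: dict[str, SolventSpec] = {}
_ALIASES: dict[str, str] = {}

#: Fixed solvent order of the five-solvent prediction vector.
TRAINING_SOLVENTS = ("ACN", "H2O", "THF", "DMSO", "DMF")


def register_solvent(spec: SolventSpec, aliases: tuple[str, ...] = ()) -> None:
    """Add or replace a solvent; never mutates other entries."""
    _SOLVENTS[spec.name.upper()] = spec
    for a in aliases:
        _ALIASES[a.upper()] = spec.name.upper()


def _populate_defaults() -> None:
    register_solvent(SolventSpec("ACN", 35.9, 1.344), aliases=("acetonitrile", "MeCN"))
    register_solvent(SolventSpec("H2O", 78.4, 1.333), aliases=("water",))
    register_solvent(SolventSpec("THF", 7.4, 1.407), aliases=("tetrahydrofuran",))
    register_solvent(SolventSpec("DMSO", 46.8, 1.479), aliases=("dimethyl sulfoxide", "dimethylsulfoxide"))
    register_solvent(SolventSpec("DMF", 36.7, 1.430), aliases=("dimethylformamide", "N,N-dimethylformamide"))


_populate_defaults()


def get_solvent(name: str) -> SolventSpec:
    """Look up a solvent by name or common alias, case-insensitively."""
    key = name.upper()
    key = _ALIASES.get(key, key)
    try:
        return _SOLVENTS[key]
    except KeyError:
        known = ", ".join(sorted(_SOLVENTS))
        raise KeyError(f"unknown solvent {name!r}; registered solvents: {known}") from None


def list_solvents() -> list[SolventSpec]:
    return [_SOLVENTS[k] for k in sorted(_SOLVENTS)]


# Reference electrodes.  SHE comes from the cycle arithmetic; Fc0/Fc+ and
# Li/Li+ offsets are literature conventions (Fc0/Fc+ ~ +0.40 V vs SHE in
# ACN; Li/Li+ ~ -3.04 V vs SHE) and should be overridden when a different
# convention is required — they are documented defaults, not measurements.
_REFERENCES: dict[str, ReferenceElectrode] = {}


def register_reference(ref: ReferenceElectrode) -> None:
    _REFERENCES[ref.name.upper()] = ref


register_reference(ReferenceElectrode("SHE", -E_REF_SHE))
register_reference(ReferenceElectrode("FC", -E_REF_SHE + 0.40, solvent_scope="ACN"))
register_reference(ReferenceElectrode("LI", -E_REF_SHE - 3.04))


def get_reference(name: str) -> ReferenceElectrode:
    key = name.upper().replace("0/FC+", "").replace("/LI+", "")
    try:
        return _REFERENCES[key]
    except KeyError:
        known = ", ".join(sorted(_REFERENCES))
        raise KeyError(f"unknown reference electrode {name!r}; registered: {known}") from None


# Descriptor scaling bounds: min-max over a range generously covering the
# registry (epsilon 1..100, n 1..1.8) so added synthetic solvents reuse the
# same fixed transform.
_EPS_RANGE = (1.0, 100.0)
_N_RANGE = (1.0, 1.8)


def descriptor_vector(s: SolventSpec, scheme: str = "minmax") -> np.ndarray:
    """Deterministic 2-vector of model inputs from (epsilon, n).

    ``minmax`` linearly rescales each of (epsilon, n) to [0, 1] over fixed
    bounds; ``onsager`` uses the reaction-field functions
    (eps-1)/(eps+2) and (n^2-1)/(n^2+2).  Both are strictly increasing in
    each argument and vanish at the vacuum point (1, 1).
    """
    if scheme == "minmax":
        e = (s.epsilon - _EPS_RANGE[0]) / (_EPS_RANGE[1] - _EPS_RANGE[0])
        n = (s.refractive_index - _N_RANGE[0]) / (_N_RANGE[1] - _N_RANGE[0])
        return np.array([e, n], dtype=np.float64)
    if scheme == "onsager":
        return onsager_descriptors(s)
    raise ValueError(f"unknown descriptor scheme {scheme!r}")


def onsager_descriptors(s: SolventSpec) -> np.ndarray:
    e = (s.epsilon - 1.0) / (s.epsilon + 2.0)
    n2 = s.refractive_index ** 2
    return np.array([e, (n2 - 1.0) / (n2 + 2.0)], dtype=np.float64)


def to_absolute(potential: float, ref: ReferenceElectrode | str) -> float:
    """Convert a potential reported vs ``ref`` to the absolute scale (volts)."""
    if isinstance(ref, str):
        ref = get_reference(ref)
    return potential + ref.offset_volts


def to_relative(potential_abs: float, ref: ReferenceElectrode | str) -> float:
    """Inverse of :func:`to_absolute`; round-trips exactly."""
    if isinstance(ref, str):
        ref = get_reference(ref)
    return potential_abs - ref.offset_volts
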