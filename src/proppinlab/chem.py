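"""Shared mass-spectrometry chemistry: residue masses, modifications, linker and lipid.

Monoisotopic residue masses come from the standard table shipped with
pyteomics.  The BS3 linker and DOPE lipid default to the bookkeeping values
used for protein–lipid adduct identification (linker bridge 140.074 Da,
DOPE 743.36 Da); both are plain configuration and can be overridden, e.g.
with the elemental monoisotopic DOPE mass (~743.55 Da for C41H78NO8P) if a
different accounting is wanted.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

from pyteomics import mass as _pmass

#: Mass of a proton (Da).
PROTON_MASS = 1.007276
#: Monoisotopic mass of water (Da), the condensation term of a peptide bond chain.
WATER_MASS = 18.010565

MOD_CARBAMIDOMETHYL = "carbamidomethyl"
MOD_OXIDATION = "oxidation"

_STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

_DEFAULT_RESIDUE_MASSES = MappingProxyType(
    {aa: _pmass.std_aa_mass[aa] for aa in _STANDARD_RESIDUES}
)
_DEFAULT_MOD_DELTAS = MappingProxyType(
    {MOD_CARBAMIDOMETHYL: 57.021464, MOD_OXIDATION: 15.994915}
)
_DEFAULT_MOD_TARGETS = MappingProxyType(
    {MOD_CARBAMIDOMETHYL: frozenset("C"), MOD_OXIDATION: frozenset("M")}
)


@dataclass(frozen=True)
class ResidueMassTable:
    """Monoisotopic residue masses plus modification deltas.

    ``residues`` maps each one-letter residue code to its residue
    (water-free) monoisotopic mass in Da; a peptide's neutral mass is the
    sum of its residue masses plus one water.
    """

    residues: Mapping[str, float] = field(default_factory=lambda: _DEFAULT_RESIDUE_MASSES)
    water: float = WATER_MASS
    proton: float = PROTON_MASS
    mod_deltas: Mapping[str, float] = field(default_factory=lambda: _DEFAULT_MOD_DELTAS)
    mod_targets: Mapping[str, frozenset] = field(default_factory=lambda: _DEFAULT_MOD_TARGETS)

    def __post_init__(self) -> None:
        missing = [aa for aa in _STANDARD_RESIDUES if aa not in self.residues]
        if missing:
            raise ValueError(f"residue mass table missing entries for {missing}")
        bad = [aa for aa, m in self.residues.items() if not m > 0]
        if bad:
            raise ValueError(f"non-positive residue masses for {bad}")

    def residue_mass(self, residue: str, position: int | None = None) -> float:
        try:
            return self.residues[residue]
        except KeyError:
            where = f" at position {position}" if position is not None else ""
            raise ValueError(f"unknown residue symbol {residue!r}{where}") from None


@dataclass(frozen=True)
class Linker:
    """A homobifunctional amine-reactive cross-linker (default BS3).

    ``linker_mass`` is the mass of the bridge as counted in adduct
    arithmetic; one proton is released per reacted amine, i.e. two per
    complete bridge.  BS3 reacts with lysine side chains, protein
    N-termini and, at lower efficiency, S/T/Y hydroxyls.
    """

    name: str = "BS3"
    linker_mass: float = 140.074
    reactive_residues: frozenset = frozenset("KSTY")
    reacts_nterm: bool = True
    protons_released_per_bond: int = 1

    def __post_init__(self) -> None:
        if not self.linker_mass > 0:
            raise ValueError("linker_mass must be > 0")


@dataclass(frozen=True)
class Lipid:
    """An amine-headgroup lipid cross-linkable by BS3 (default DOPE)."""

    name: str = "DOPE"
    mass: float = 743.36

    def __post_init__(self) -> None:
        if not self.mass > 0:
            raise ValueError("lipid mass must be > 0")
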