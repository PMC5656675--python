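"""BS3 cross-link candidate enumeration and precursor mass matching.

Covers in-silico tryptic digestion, neutral monoisotopic peptide masses,
lipid-adduct (peptide + DOPE via BS3) and di-peptide cross-link candidate
masses, ppm-tolerance matching of observed precursor masses, classification
of homo-oligomer links, and b/y fragment annotation.  Spectrum-level
scoring (pLink/MaxQuant style) is intentionally out of scope: matching is
at the precursor level only.

Adduct arithmetic: bridging releases one proton per reacted amine, so a
lipid adduct adds ``lipid + linker - 2*proton`` to a peptide and a
di-peptide link weighs ``mass_A + mass_B + linker - 2*proton``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from pyteomics import parser as _pparser

from .chem import Linker, Lipid, ResidueMassTable

#: Trypsin: cleave C-terminal to K/R except before proline.
TRYPSIN_RULE = r"[KR](?!P)"

_DEFAULT_TABLE = ResidueMassTable()


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with a coordinate offset for site numbering.

    ``numbering_offset`` is the protein coordinate of sequence position 1;
    it may be <= 0 so expression-tag residues keep negative site labels
    (e.g. a tag serine at "S-2").
    """

    id: str
    sequence: str
    numbering_offset: int = 1

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        for i, aa in enumerate(seq):
            if aa not in _DEFAULT_TABLE.residues:
                raise ValueError(
                    f"protein {self.id!r}: unknown residue {aa!r} at position {i + 1}"
                )

    def coord(self, index0: int) -> int:
        """Protein coordinate of 0-based sequence index."""
        return self.numbering_offset + index0


@dataclass(frozen=True)
class Peptide:
    """A tryptic digestion product in protein coordinates."""

    parent_id: str
    sequence: str
    start: int  # protein coordinate of first residue (inclusive)
    end: int  # protein coordinate of last residue (inclusive)
    missed_cleavages: int
    mass: float  # neutral monoisotopic, Da
    is_protein_nterm: bool = False
    is_protein_cterm: bool = False
    modifications: tuple = ()  # ((position_1based, mod_name), ...)

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("peptide coordinates inconsistent with length")
        if not self.mass > 0:
            raise ValueError("peptide mass must be > 0")
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be >= 0")

    def overlaps(self, other: "Peptide") -> bool:
        return self.start <= other.end and other.start <= self.end


def peptide_mass(
    sequence: str,
    table: ResidueMassTable = _DEFAULT_TABLE,
    modifications: Sequence[tuple] = (),
) -> float:
    """Neutral monoisotopic mass: residue masses + water + mod deltas.

    ``modifications`` is a sequence of (position_1based, mod_name); a
    modification whose target residue is absent at that position raises.
    """
    if not sequence:
        raise ValueError("cannot compute the mass of an empty sequence")
    total = table.water
    for i, aa in enumerate(sequence):
        total += table.residue_mass(aa, position=i + 1)
    for pos, name in modifications:
        if name not in table.mod_deltas:
            raise ValueError(f"unknown modification {name!r}")
        if not 1 <= pos <= len(sequence):
            raise ValueError(f"modification position {pos} outside peptide")
        residue = sequence[pos - 1]
        if residue not in table.mod_targets[name]:
            raise ValueError(
                f"modification {name!r} cannot sit on residue {residue!r} at {pos}"
            )
        total += table.mod_deltas[name]
    return total


def _count_missed(sequence: str) -> int:
    return sum(
        1
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    )


def digest(
    protein: ProteinRecord,
    max_missed: int = 0,
    min_len: int = 1,
    max_len: int | None = None,
    table: ResidueMassTable = _DEFAULT_TABLE,
) -> list[Peptide]:
    """Tryptic digest: cleave after K/R except before P.

    Returns all peptides with up to ``max_missed`` internal missed
    cleavages inside the [min_len, max_len] length window, in protein
    coordinates honouring the record's numbering offset.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    if not 1 <= min_len <= (max_len or min_len):
        raise ValueError("need 1 <= min_len <= max_len")
    seq = protein.sequence
    peptides = []
    for start0, pep in _pparser.icleave(seq, TRYPSIN_RULE, missed_cleavages=max_missed):
        if len(pep) < min_len or (max_len is not None and len(pep) > max_len):
            continue
        peptides.append(
            Peptide(
                parent_id=protein.id,
                sequence=pep,
                start=protein.coord(start0),
                end=protein.coord(start0 + len(pep) - 1),
                missed_cleavages=_count_missed(pep),
                mass=peptide_mass(pep, table),
                is_protein_nterm=start0 == 0,
                is_protein_cterm=start0 + len(pep) == len(seq),
            )
        )
    return peptides


def lipid_adduct_delta(
    lipid: Lipid = Lipid(),
    linker: Linker = Linker(),
    table: ResidueMassTable = _DEFAULT_TABLE,
) -> float:
    """Mass added to a peptide by one lipid bridged via the linker.

    lipid + linker - 2 protons (one proton released from each reacted
    amine).  With the default DOPE/BS3 accounting this is 881.42 Da.
    """
    return lipid.mass + linker.linker_mass - 2 * table.proton


@dataclass(frozen=True)
class CrossLinkCandidate:
    """A theoretical lipid-adduct or di-peptide cross-link precursor."""

    kind: str  # "lipid" | "dipeptide"
    peptide_a: Peptide
    sites_a: tuple  # ((coord, residue_or_'nterm'), ...)
    mass: float  # theoretical neutral, Da
    peptide_b: Peptide | None = None
    sites_b: tuple | None = None
    lipid: Lipid | None = None
    linker: Linker = Linker()

    def __post_init__(self) -> None:
        if self.kind not in ("lipid", "dipeptide"):
            raise ValueError(f"unknown candidate kind {self.kind!r}")
        if self.kind == "dipeptide" and self.peptide_b is None:
            raise ValueError("di-peptide candidate needs a second peptide")


def reactive_sites(peptide: Peptide, linker: Linker = Linker()) -> list[tuple]:
    """Linker-reactive sites of a peptide, as (protein coordinate, label).

    K/S/T/Y side chains react; a C-terminal lysine is excluded unless the
    peptide ends the protein, because a cross-linked lysine blocks tryptic
    cleavage and could not have produced that terminus.  The protein
    N-terminal alpha-amine is a site of its own.
    """
    sites = []
    if linker.reacts_nterm and peptide.is_protein_nterm:
        sites.append((peptide.start, "nterm"))
    last = len(peptide.sequence) - 1
    for i, aa in enumerate(peptide.sequence):
        if aa not in linker.reactive_residues:
            continue
        if aa == "K" and i == last and not peptide.is_protein_cterm:
            continue  # cleaved C-terminal K cannot carry a link
        sites.append((peptide.start + i, aa))
    return sites


def enumerate_lipid_candidates(
    peptides: Iterable[Peptide],
    lipid: Lipid = Lipid(),
    linker: Linker = Linker(),
    table: ResidueMassTable = _DEFAULT_TABLE,
) -> list[CrossLinkCandidate]:
    """One candidate per (peptide, reactive site) with the lipid-adduct mass."""
    delta = lipid_adduct_delta(lipid, linker, table)
    out = []
    for pep in peptides:
        for site in reactive_sites(pep, linker):
            out.append(
                CrossLinkCandidate(
                    kind="lipid",
                    peptide_a=pep,
                    sites_a=(site,),
                    mass=pep.mass + delta,
                    lipid=lipid,
                    linker=linker,
                )
            )
    return out


def enumerate_dipeptide_candidates(
    peptides: Sequence[Peptide],
    linker: Linker = Linker(),
    mass_window: tuple | None = None,
    table: ResidueMassTable = _DEFAULT_TABLE,
) -> list[CrossLinkCandidate]:
    """All unordered peptide pairs (including homodimeric self-pairs) with
    at least one reactive site on each side.

    Candidate mass = mass_A + mass_B + linker - 2 protons; ``mass_window``
    is an optional (low, high) filter in Da.
    """
    linkable = [(p, tuple(reactive_sites(p, linker))) for p in peptides]
    linkable = [(p, s) for p, s in linkable if s]
    out = []
    for i, (pa, sa) in enumerate(linkable):
        for pb, sb in linkable[i:]:
            mass = pa.mass + pb.mass + linker.linker_mass - 2 * table.proton
            if mass_window is not None and not (
                mass_window[0] <= mass <= mass_window[1]
            ):
                continue
            out.append(
                CrossLinkCandidate(
                    kind="dipeptide",
                    peptide_a=pa,
                    sites_a=sa,
                    peptide_b=pb,
                    sites_b=sb,
                    mass=mass,
                    linker=linker,
                )
            )
    return out


def classify_crosslink(candidate: CrossLinkCandidate) -> str:
    """Classify a di-peptide link of a homo-oligomer.

    Identical or coordinate-overlapping peptides can only arise from two
    protein copies -> "inter".  Disjoint peptides are "ambiguous" (intra
    and inter are indistinguishable at precursor level).  Peptides from
    different proteins are labelled "heteromeric".  Symmetric in A/B.
    """
    if candidate.kind != "dipeptide":
        raise ValueError("classification applies to di-peptide candidates")
    a, b = candidate.peptide_a, candidate.peptide_b
    if a.parent_id != b.parent_id:
        return "heteromeric"
    return "inter" if a.overlaps(b) else "ambiguous"


@dataclass(frozen=True)
class MatchResult:
    """An observed precursor matched to a candidate within tolerance."""

    observed_mass: float  # neutral, Da
    candidate: CrossLinkCandidate
    ppm: float
    classification: str  # intra | inter | lipid | ambiguous | heteromeric


def match_precursors(
    observed: Sequence[float],
    candidates: Sequence[CrossLinkCandidate],
    tol_ppm: float,
) -> list[list[MatchResult]]:
    """Match each observed neutral mass against all candidates at ppm tolerance.

    Returns, per observed mass, every candidate with
    |obs - theo| / theo * 1e6 <= tol_ppm, sorted by |ppm| then by lower
    candidate mass; an empty list where nothing matches.
    """
    if not tol_ppm > 0:
        raise ValueError("tol_ppm must be > 0")
    observed = np.asarray(observed, dtype=float)
    if observed.size and not np.all(observed > 0):
        raise ValueError("observed masses must be > 0")
    theo = np.array([c.mass for c in candidates])
    order = np.argsort(theo)
    theo_sorted = theo[order]
    results: list[list[MatchResult]] = []
    for obs in observed:
        lo = obs / (1 + tol_ppm * 1e-6)
        hi = obs / (1 - tol_ppm * 1e-6)
        i0 = int(np.searchsorted(theo_sorted, lo, side="left"))
        i1 = int(np.searchsorted(theo_sorted, hi, side="right"))
        hits = []
        for idx in order[i0:i1]:
            cand = candidates[idx]
            ppm = (obs - cand.mass) / cand.mass * 1e6
            if abs(ppm) <= tol_ppm:
                cls = "lipid" if cand.kind == "lipid" else classify_crosslink(cand)
                hits.append(MatchResult(float(obs), cand, float(ppm), cls))
        hits.sort(key=lambda m: (abs(m.ppm), m.candidate.mass))
        results.append(hits)
    return results


def crosslink_fragment_delta(
    partner_mass: float, linker: Linker = Linker(), table: ResidueMassTable = _DEFAULT_TABLE
) -> float:
    """Fixed mass carried by the linked residue when fragmenting one chain
    of a di-peptide link: intact partner chain + linker - 2 protons."""
    return partner_mass + linker.linker_mass - 2 * table.proton


def fragment_masses(
    peptide: Peptide | str,
    ion_types: Sequence[str] = ("b", "y"),
    max_charge: int = 1,
    table: ResidueMassTable = _DEFAULT_TABLE,
    link: tuple | None = None,
) -> list[tuple]:
    """b/y fragment m/z values of one peptide chain.

    ``link`` is an optional (position_1based, delta_da) pair: fragments
    containing that residue carry the delta (a lipid adduct or the intact
    partner chain of a di-peptide link).  Returns (label, m/z) tuples with
    labels like "b2", "y3^2".  m/z = (neutral + z*proton)/z.
    """
    bad = set(ion_types) - {"b", "y"}
    if bad:
        raise ValueError(f"unsupported ion types {sorted(bad)}; only b and y")
    if max_charge < 1:
        raise ValueError("max_charge must be >= 1")
    seq = peptide.sequence if isinstance(peptide, Peptide) else peptide
    if len(seq) < 2:
        raise ValueError("fragmentation needs at least 2 residues")
    res = [table.residue_mass(aa, position=i + 1) for i, aa in enumerate(seq)]
    prefix = np.concatenate([[0.0], np.cumsum(res)])
    n = len(seq)
    link_pos, link_delta = link if link is not None else (None, 0.0)
    out = []
    for i in range(1, n):
        for ion in ion_types:
            if ion == "b":
                neutral = prefix[i]
                if link_pos is not None and link_pos <= i:
                    neutral += link_delta
            else:  # y_i covers the last i residues
                neutral = prefix[n] - prefix[n - i] + table.water
                if link_pos is not None and link_pos > n - i:
                    neutral += link_delta
            for z in range(1, max_charge + 1):
                label = f"{ion}{i}" if z == 1 else f"{ion}{i}^{z}"
                out.append((label, (neutral + z * table.proton) / z))
    return out
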