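"""Readers and writers for the package's plain-text formats.

Trace CSV dialect: "#key=value" metadata lines (total_lipid_mM,
accessible_fraction, protein_uM, label, seed) followed by a header row and
time_s,fluorescence_au columns.  Numbers are serialized with enough digits
to round-trip.  FASTA goes through Biopython; MGF through pyteomics.
"""
from __future__ import annotations

import csv
import io as _stdio
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyteomics import mgf as _pmgf

from .chem import PROTON_MASS
from .kinetics import KobsPoint, LipidCondition, StoppedFlowTrace
from .native_ms import Assignments, OligomerResult, PeakList
from .xlink import MatchResult, ProteinRecord


class FormatError(ValueError):
    """A file does not satisfy the expected dialect."""


# ---------------------------------------------------------------- FASTA


def read_fasta(path) -> list[ProteinRecord]:
    """Read protein records; an ``offset=N`` key in the header sets the
    numbering offset (coordinate of the first residue)."""
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
        offset = 1
        for token in rec.description.split():
            if token.startswith("offset="):
                offset = int(token.split("=", 1)[1])
        records.append(
            ProteinRecord(
                id=rec.id, sequence=str(rec.seq).upper(), numbering_offset=offset
            )
        )
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: list[ProteinRecord], path) -> None:
    seqs = [
        SeqRecord(
            Seq(r.sequence),
            id=r.id,
            description=f"offset={r.numbering_offset}",
        )
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


# ---------------------------------------------------------- trace CSV

_TRACE_KEYS = ("total_lipid_mM", "accessible_fraction", "protein_uM", "label", "seed")


def write_trace_csv(trace: StoppedFlowTrace, path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"#total_lipid_mM={trace.condition.total_lipid:.10g}\n")
        fh.write(f"#accessible_fraction={trace.condition.accessible_fraction:.10g}\n")
        fh.write(f"#protein_uM={trace.protein_conc:.10g}\n")
        fh.write(f"#label={trace.label}\n")
        fh.write(f"#seed={'' if trace.seed is None else trace.seed}\n")
        writer = csv.writer(fh)
        writer.writerow(["time_s", "fluorescence_au"])
        for t, f in zip(trace.times, trace.fluorescence):
            writer.writerow([f"{t:.10g}", f"{f:.10g}"])


def read_trace_csv(path) -> StoppedFlowTrace:
    meta: dict[str, str] = {}
    body = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                meta[key] = value
            else:
                body.append(line)
    for key in _TRACE_KEYS:
        if key not in meta:
            raise FormatError(f"{path}: missing metadata key #{key}")
    frame = pd.read_csv(_stdio.StringIO("".join(body)))
    if list(frame.columns) != ["time_s", "fluorescence_au"]:
        raise FormatError(f"{path}: expected columns time_s,fluorescence_au")
    times = frame["time_s"].to_numpy(float)
    if not np.all(np.diff(times) > 0):
        raise FormatError(f"{path}: times are not strictly increasing")
    cond = LipidCondition(
        total_lipid=float(meta["total_lipid_mM"]),
        accessible_fraction=float(meta["accessible_fraction"]),
        label=meta["label"],
    )
    seed = int(meta["seed"]) if meta["seed"] else None
    return StoppedFlowTrace(
        times=times,
        fluorescence=frame["fluorescence_au"].to_numpy(float),
        condition=cond,
        protein_conc=float(meta["protein_uM"]),
        label=meta["label"],
        seed=seed,
    )


# ------------------------------------------------------------ k_obs CSV


def write_kobs_table(points: list[KobsPoint], path) -> None:
    frame = pd.DataFrame(
        {
            "accessible_lipid_mM": [p.accessible_lipid for p in points],
            "kobs1_per_s": [p.k_obs1 for p in points],
            "se_per_s": [p.se for p in points],
        }
    )
    frame.to_csv(path, index=False, float_format="%.10g")


def read_kobs_table(path) -> list[KobsPoint]:
    frame = pd.read_csv(path)
    expected = ["accessible_lipid_mM", "kobs1_per_s", "se_per_s"]
    if list(frame.columns) != expected:
        raise FormatError(f"{path}: expected columns {expected}")
    return [
        KobsPoint(accessible_lipid=row[0], k_obs1=row[1], se=row[2])
        for row in frame.itertuples(index=False)
    ]


# ----------------------------------------------------------- matches TSV


def _site_str(sites) -> str:
    return ";".join(f"{label}{coord}" if label != "nterm" else f"nterm{coord}"
                    for coord, label in sites)


def write_matches_tsv(match_lists: list[list[MatchResult]], path) -> None:
    rows = []
    for hits in match_lists:
        for m in hits:
            c = m.candidate
            rows.append(
                {
                    "kind": c.kind,
                    "peptide_a": c.peptide_a.sequence,
                    "site_a": _site_str(c.sites_a),
                    "peptide_b": c.peptide_b.sequence
                    if c.peptide_b is not None
                    else (c.lipid.name if c.lipid else ""),
                    "site_b": _site_str(c.sites_b) if c.sites_b else "",
                    "theo_mass_da": f"{c.mass:.6f}",
                    "obs_mass_da": f"{m.observed_mass:.6f}",
                    "ppm": f"{m.ppm:.3f}",
                    "classification": m.classification,
                }
            )
    pd.DataFrame(
        rows,
        columns=[
            "kind",
            "peptide_a",
            "site_a",
            "peptide_b",
            "site_b",
            "theo_mass_da",
            "obs_mass_da",
            "ppm",
            "classification",
        ],
    ).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------- native MS


def read_peaklist(path) -> PeakList:
    """Two-column m/z-intensity text (whitespace or comma separated)."""
    data = np.loadtxt(path, delimiter=None, ndmin=2)
    if data.shape[1] == 1:
        data = np.loadtxt(path, delimiter=",", ndmin=2)
    if data.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns (mz, intensity)")
    return PeakList(mz=data[:, 0], intensity=data[:, 1])


def write_peaklist(peaks: PeakList, path) -> None:
    np.savetxt(path, np.column_stack([peaks.mz, peaks.intensity]), fmt="%.8g")


def write_oligomer_tsv(results: list[OligomerResult], path) -> None:
    pd.DataFrame(
        {
            "order": [r.order for r in results],
            "mass_da": [f"{r.mass:.2f}" for r in results],
            "sd_da": [f"{r.mass_sd:.2f}" for r in results],
            "n_peaks": [r.n_peaks for r in results],
            "rel_intensity_pct": [f"{r.rel_intensity:.2f}" for r in results],
        }
    ).to_csv(path, sep="\t", index=False)


# ----------------------------------------------------- precursor masses


def read_mass_list(path) -> list[tuple[float, float]]:
    """Two-column text of (neutral_mass_da, intensity)."""
    data = np.loadtxt(path, ndmin=2)
    if data.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns (mass, intensity)")
    return [(float(m), float(i)) for m, i in data[:, :2]]


def write_mass_list(masses, path) -> None:
    """Write (mass, intensity) pairs; bare masses get unit intensity."""
    rows = []
    for m in masses:
        if np.isscalar(m):
            rows.append((float(m), 1.0))
        else:
            rows.append((float(m[0]), float(m[1])))
    np.savetxt(path, np.asarray(rows), fmt="%.8f")


def read_mgf_masses(path) -> list[tuple[float, float]]:
    """Neutral precursor masses from an MGF file.

    PEPMASS is the precursor m/z; with charge z the neutral mass is
    z * (m/z - proton).  Spectra without a charge are skipped.
    """
    out = []
    with _pmgf.MGF(str(path)) as reader:
        for spectrum in reader:
            params = spectrum["params"]
            pepmass = params["pepmass"]
            mz = pepmass[0] if isinstance(pepmass, (tuple, list)) else float(pepmass)
            charge = params.get("charge")
            if charge is None:
                continue
            z = int(charge[0])
            intensity = (
                float(pepmass[1])
                if isinstance(pepmass, (tuple, list)) and len(pepmass) > 1 and pepmass[1]
                else 1.0
            )
            out.append((z * (mz - PROTON_MASS), intensity))
    return out
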