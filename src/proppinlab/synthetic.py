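"""Ground-truthed synthetic data for every analysis stage.

Each generator is deterministic under a fixed seed and returns a
``SyntheticTruth`` alongside the data so recovery tests can compare
estimates against the generating parameters without any downloaded data.
The generators emulate the statistical structure the analyses assume —
multi-exponential FRET traces with Gaussian noise and optional slow
aggregation drift, precursor lists with ppm-level mass error plus uniform
decoys, and Gaussian-peak native spectra of oligomer charge series — not
real chromatography, isotope envelopes or instrument response.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .chem import Linker, Lipid, ResidueMassTable
from .kinetics import (
    LipidCondition,
    ObservableModel,
    RateParameters,
    StoppedFlowTrace,
    simulate_trace,
)
from .native_ms import PeakList, mz_for
from .xlink import (
    CrossLinkCandidate,
    ProteinRecord,
    digest,
    enumerate_dipeptide_candidates,
    enumerate_lipid_candidates,
)

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SyntheticTruth:
    """Generator-side ground truth serialized next to every dataset."""

    generator: str
    seed: int
    params: dict
    noise: dict

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        return cls(**json.loads(text))

    def write(self, path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def read(cls, path) -> "SyntheticTruth":
        return cls.from_json(Path(path).read_text())


def _child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic sub-seeds (< 2**31) for independent streams."""
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def gen_trace_series(
    params: RateParameters,
    concentrations: Sequence[float],
    obs: ObservableModel = ObservableModel(),
    noise_sd: float = 0.01,
    replicates: int = 1,
    seed: int = 0,
    duration: float = 10.0,
    n_points: int = 500,
    accessible_fraction: float = 0.6,
    protein_conc: float = 0.25,
) -> tuple[list[StoppedFlowTrace], SyntheticTruth]:
    """Simulate a stopped-flow series over accessible-lipid concentrations.

    ``concentrations`` are accessible lipid in mM (the abscissa of the
    pseudo-first-order analysis); the stored conditions back-compute total
    lipid from ``accessible_fraction``.  One trace per (concentration,
    replicate), each with its own deterministic noise sub-seed.
    """
    concentrations = list(concentrations)
    if len(concentrations) < 2:
        raise ValueError("need >= 2 concentrations")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    seeds = iter(_child_seeds(seed, len(concentrations) * replicates))
    traces = []
    for conc in concentrations:
        cond = LipidCondition.from_accessible(
            conc, accessible_fraction=accessible_fraction
        )
        for rep in range(replicates):
            traces.append(
                simulate_trace(
                    params,
                    obs,
                    cond,
                    duration=duration,
                    n_points=n_points,
                    noise_sd=noise_sd,
                    seed=next(seeds),
                    protein_conc=protein_conc,
                    label=f"L{conc:g}_rep{rep}",
                )
            )
    truth = SyntheticTruth(
        generator="gen_trace_series",
        seed=seed,
        params={
            "k_on": params.k_on,
            "k_off": params.k_off,
            "k_oli": params.k_oli,
            "k_dis": params.k_dis,
            "k_off_app": params.k_off + params.k_oli + params.k_dis,
            "concentrations_mM": concentrations,
            "replicates": replicates,
            "duration_s": duration,
            "n_points": n_points,
            "accessible_fraction": accessible_fraction,
            "protein_uM": protein_conc,
        },
        noise={"noise_sd": noise_sd, "drift_phases": list(obs.drift_phases)},
    )
    return traces, truth


def random_protein(
    length: int, seed: int = 0, kr_floor: float = 0.08, id: str = "synthetic"
) -> ProteinRecord:
    """Random protein with uniform residue frequencies and a combined K/R
    frequency floor so that a tryptic digest yields peptides."""
    rng = np.random.default_rng(seed)
    while True:
        seq = "".join(rng.choice(list(_AA), size=length))
        kr = (seq.count("K") + seq.count("R")) / length
        if kr >= kr_floor:
            return ProteinRecord(id=id, sequence=seq)


def gen_xl_dataset(
    protein: ProteinRecord,
    n_lipid_sites: int,
    n_dipeptide_links: int,
    ppm_noise_sd: float = 3.0,
    n_decoys: int = 0,
    seed: int = 0,
    max_missed: int = 1,
    min_len: int = 4,
    max_len: int = 40,
    lipid: Lipid = Lipid(),
    linker: Linker = Linker(),
    table: ResidueMassTable = ResidueMassTable(),
) -> tuple[list[float], list[CrossLinkCandidate], SyntheticTruth]:
    """Draw true lipid-adduct and di-peptide cross-link precursors plus decoys.

    Observed masses are the chosen candidates' theoretical masses under
    Gaussian ppm error, plus ``n_decoys`` uniform masses over the
    candidate mass range.  Returns (observed masses, true candidates,
    truth); the truth records the linked sites and true masses.
    """
    peptides = digest(protein, max_missed=max_missed, min_len=min_len, max_len=max_len)
    lipid_cands = enumerate_lipid_candidates(peptides, lipid, linker, table)
    dipep_cands = enumerate_dipeptide_candidates(peptides, linker, table=table)
    if n_lipid_sites > len(lipid_cands):
        raise ValueError(
            f"requested {n_lipid_sites} lipid sites but only "
            f"{len(lipid_cands)} candidates exist"
        )
    if n_dipeptide_links > len(dipep_cands):
        raise ValueError(
            f"requested {n_dipeptide_links} di-peptide links but only "
            f"{len(dipep_cands)} candidates exist"
        )
    rng = np.random.default_rng(seed)
    chosen: list[CrossLinkCandidate] = []
    if n_lipid_sites:
        idx = rng.choice(len(lipid_cands), size=n_lipid_sites, replace=False)
        chosen += [lipid_cands[i] for i in sorted(idx)]
    if n_dipeptide_links:
        idx = rng.choice(len(dipep_cands), size=n_dipeptide_links, replace=False)
        chosen += [dipep_cands[i] for i in sorted(idx)]
    observed = [
        c.mass * (1 + rng.normal(0.0, ppm_noise_sd) * 1e-6) for c in chosen
    ]
    all_masses = [c.mass for c in lipid_cands + dipep_cands]
    lo, hi = min(all_masses), max(all_masses)
    observed += list(rng.uniform(lo, hi, size=n_decoys))
    truth = SyntheticTruth(
        generator="gen_xl_dataset",
        seed=seed,
        params={
            "protein_id": protein.id,
            "true_masses": [c.mass for c in chosen],
            "true_kinds": [c.kind for c in chosen],
            "true_sites": [
                [list(s) for s in c.sites_a]
                + ([list(s) for s in c.sites_b] if c.sites_b else [])
                for c in chosen
            ],
            "n_decoys": n_decoys,
            "decoy_range_da": [lo, hi],
        },
        noise={"ppm_noise_sd": ppm_noise_sd},
    )
    return observed, chosen, truth


def gen_native_spectrum(
    monomer_mass: float,
    abundances: dict,
    charge_center: float = 15.0,
    charge_spread: float = 1.5,
    peak_width_th: float = 2.0,
    noise_floor: float = 0.0,
    height_noise_frac: float = 0.02,
    seed: int = 0,
    mz_step: float | None = None,
) -> tuple[PeakList, SyntheticTruth]:
    """Synthesize a native mass spectrum of an oligomer mixture.

    ``abundances`` maps oligomer order to relative abundance (monomer
    100).  Each order contributes Gaussian peaks of width
    ``peak_width_th`` (sd, Th) at its charge-series positions for integer
    charges within charge_center +/- 2*charge_spread, weighted by a
    Gaussian charge envelope.  Peak heights carry multiplicative Gaussian
    noise of fraction ``height_noise_frac``; ``noise_floor`` adds
    half-normal baseline noise.
    """
    if not abundances or all(v <= 0 for v in abundances.values()):
        raise ValueError("need at least one positive abundance")
    if any(v < 0 for v in abundances.values()):
        raise ValueError("abundances must be >= 0")
    rng = np.random.default_rng(seed)
    z_lo = max(1, int(np.ceil(charge_center - 2 * charge_spread)))
    z_hi = int(np.floor(charge_center + 2 * charge_spread))
    charges = list(range(z_lo, z_hi + 1))
    positions, heights = [], []
    for order in sorted(abundances):
        ab = abundances[order]
        if ab <= 0:
            continue
        for z in charges:
            w = np.exp(-((z - charge_center) ** 2) / (2 * charge_spread**2))
            h = ab * w
            if height_noise_frac > 0:
                h *= 1 + rng.normal(0.0, height_noise_frac)
            positions.append(mz_for(order, monomer_mass, z))
            heights.append(max(h, 0.0))
    lo = min(positions) - 20 * peak_width_th
    hi = max(positions) + 20 * peak_width_th
    step = mz_step if mz_step is not None else peak_width_th / 5.0
    mz = np.arange(lo, hi, step)
    intensity = np.zeros_like(mz)
    for pos, h in zip(positions, heights):
        intensity += h * np.exp(-((mz - pos) ** 2) / (2 * peak_width_th**2))
    if noise_floor > 0:
        intensity += np.abs(rng.normal(0.0, noise_floor, size=mz.shape))
    truth = SyntheticTruth(
        generator="gen_native_spectrum",
        seed=seed,
        params={
            "monomer_mass_da": monomer_mass,
            "abundances": {str(k): v for k, v in abundances.items()},
            "charges": charges,
            "charge_center": charge_center,
            "charge_spread": charge_spread,
            "peak_width_th": peak_width_th,
        },
        noise={
            "height_noise_frac": height_noise_frac,
            "noise_floor": noise_floor,
        },
    )
    return PeakList(mz=mz, intensity=intensity), truth
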