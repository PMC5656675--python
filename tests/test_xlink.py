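"""Tryptic digestion, cross-link candidate masses, matching and fragments."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from proppinlab.chem import Linker, Lipid, ResidueMassTable, PROTON_MASS, WATER_MASS
from proppinlab.xlink import (
    CrossLinkCandidate,
    Peptide,
    ProteinRecord,
    classify_crosslink,
    crosslink_fragment_delta,
    digest,
    enumerate_dipeptide_candidates,
    enumerate_lipid_candidates,
    fragment_masses,
    lipid_adduct_delta,
    match_precursors,
    peptide_mass,
    reactive_sites,
)

TABLE = ResidueMassTable()
AA = "ACDEFGHIKLMNPQRSTVWY"


def make_peptide(seq, start=1, parent="p", nterm=False, cterm=False, missed=0):
    return Peptide(
        parent_id=parent,
        sequence=seq,
        start=start,
        end=start + len(seq) - 1,
        missed_cleavages=missed,
        mass=peptide_mass(seq),
        is_protein_nterm=nterm,
        is_protein_cterm=cterm,
    )


class TestDigest:
    def test_kr_cleavage_with_proline_exception(self):
        prot = ProteinRecord("p", "AKRPGKG")
        assert [p.sequence for p in digest(prot)] == ["AK", "RPGK", "G"]

    @given(st.text(alphabet=AA, min_size=1, max_size=60))
    @settings(max_examples=100, derandomize=True)
    def test_zero_missed_peptides_tile_the_protein(self, seq):
        prot = ProteinRecord("p", seq)
        peptides = digest(prot, max_missed=0)
        assert "".join(p.sequence for p in peptides) == seq
        # coordinates are contiguous and start at the numbering offset
        assert peptides[0].start == 1
        for a, b in zip(peptides, peptides[1:]):
            assert b.start == a.end + 1

    def test_numbering_offset_propagates(self):
        prot = ProteinRecord("p", "GR", numbering_offset=-3)
        (pep,) = digest(prot)
        assert (pep.start, pep.end) == (-3, -2)

    def test_missed_cleavage_enumeration(self):
        prot = ProteinRecord("p", "AKGKC")
        seqs = {p.sequence for p in digest(prot, max_missed=1)}
        assert seqs == {"AK", "GK", "C", "AKGK", "GKC"}
        counts = {p.sequence: p.missed_cleavages for p in digest(prot, max_missed=1)}
        assert counts["AKGK"] == 1 and counts["AK"] == 0

    def test_terminal_flags(self):
        prot = ProteinRecord("p", "AKGKC")
        peps = {p.sequence: p for p in digest(prot)}
        assert peps["AK"].is_protein_nterm and not peps["AK"].is_protein_cterm
        assert peps["C"].is_protein_cterm and not peps["C"].is_protein_nterm

    def test_unknown_residue_named_by_position(self):
        with pytest.raises(ValueError, match="position 3"):
            ProteinRecord("p", "GGXG")


class TestPeptideMass:
    def test_glycine(self):
        assert peptide_mass("G") == pytest.approx(57.02146 + 18.010565, abs=1e-4)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            peptide_mass("")

    def test_carbamidomethyl_additivity(self):
        assert peptide_mass("C", modifications=[(1, "carbamidomethyl")]) == pytest.approx(
            peptide_mass("C") + 57.021464
        )

    def test_modification_on_wrong_residue_rejected(self):
        with pytest.raises(ValueError, match="oxidation"):
            peptide_mass("GAG", modifications=[(2, "oxidation")])

    @given(st.text(alphabet=AA, min_size=1, max_size=30))
    @settings(max_examples=50, derandomize=True)
    def test_mass_is_residue_sum_plus_water(self, seq):
        expected = sum(TABLE.residues[aa] for aa in seq) + WATER_MASS
        assert peptide_mass(seq) == pytest.approx(expected, abs=1e-9)


class TestLipidAdduct:
    def test_paper_accounting_two_decimal_places(self):
        assert round(lipid_adduct_delta(), 2) == 881.42

    def test_zero_mass_lipid_forbidden(self):
        with pytest.raises(ValueError):
            Lipid(mass=0.0)

    def test_delta_independent_of_peptide(self):
        delta = lipid_adduct_delta()
        for seq in ("GK", "STYK", "AAAA"):
            pep = make_peptide(seq)
            (cand,) = enumerate_lipid_candidates([pep])[:1] or [None]
            if cand is not None:
                assert cand.mass - pep.mass == pytest.approx(delta, abs=1e-9)


class TestLipidCandidates:
    def test_cleaved_cterminal_lysine_blocked(self):
        pep = make_peptide("STK", cterm=False)
        sites = {label for _, label in reactive_sites(pep)}
        assert sites == {"S", "T"}

    def test_protein_cterminal_lysine_allowed(self):
        pep = make_peptide("STK", cterm=True)
        assert {label for _, label in reactive_sites(pep)} == {"S", "T", "K"}

    def test_internal_missed_cleavage_lysine_is_a_site(self):
        pep = make_peptide("AKGK", missed=1)
        assert [(c, l) for c, l in reactive_sites(pep)] == [(2, "K")]

    def test_unreactive_peptide_yields_no_candidates(self):
        pep = make_peptide("AGGAVILR")
        assert enumerate_lipid_candidates([pep]) == []

    def test_protein_nterm_is_a_site(self):
        pep = make_peptide("AGGR", nterm=True)
        assert reactive_sites(pep) == [(1, "nterm")]


class TestDipeptideCandidates:
    def test_mass_formula(self):
        pa, pb = make_peptide("GK", missed=0, cterm=True), make_peptide("STAR", start=10)
        cands = enumerate_dipeptide_candidates([pa, pb])
        pair = [c for c in cands if c.peptide_a is pa and c.peptide_b is pb][0]
        assert pair.mass == pytest.approx(
            pa.mass + pb.mass + 140.074 - 2 * PROTON_MASS, abs=1e-9
        )

    def test_homodimeric_self_pair_allowed(self):
        pep = make_peptide("STAR")
        cands = enumerate_dipeptide_candidates([pep])
        assert len(cands) == 1
        assert cands[0].peptide_a is cands[0].peptide_b

    def test_pair_count_all_linkable(self):
        peps = [make_peptide(s, start=10 * i + 1) for i, s in enumerate(["SA", "TA", "YA", "SG"])]
        n = len(peps)
        assert len(enumerate_dipeptide_candidates(peps)) == n * (n + 1) // 2


class TestClassify:
    def test_overlapping_peptides_are_intermolecular(self):
        a = make_peptide("SAAAAAAAAAT", start=100)
        b = make_peptide("SAAAAAAAAAT", start=105)
        cand = CrossLinkCandidate("dipeptide", a, ((100, "S"),), a.mass + b.mass, b, ((105, "S"),))
        assert classify_crosslink(cand) == "inter"

    def test_identical_peptides_are_intermolecular(self):
        a = make_peptide("SAAAAAAAAAGT", start=390)
        cand = CrossLinkCandidate("dipeptide", a, ((390, "S"),), 2 * a.mass, a, ((390, "S"),))
        assert classify_crosslink(cand) == "inter"

    def test_disjoint_peptides_are_ambiguous(self):
        a = make_peptide("SAAAAAAAAAT", start=50)
        b = make_peptide("TAAAAAAAAAS", start=200)
        cand = CrossLinkCandidate("dipeptide", a, ((50, "S"),), a.mass + b.mass, b, ((210, "S"),))
        assert classify_crosslink(cand) == "ambiguous"

    def test_different_proteins_heteromeric(self):
        a = make_peptide("SA", parent="x")
        b = make_peptide("TA", parent="y")
        cand = CrossLinkCandidate("dipeptide", a, ((1, "S"),), a.mass + b.mass, b, ((1, "T"),))
        assert classify_crosslink(cand) == "heteromeric"

    @given(
        st.integers(min_value=1, max_value=200),
        st.integers(min_value=5, max_value=15),
        st.integers(min_value=1, max_value=200),
        st.integers(min_value=5, max_value=15),
    )
    @settings(max_examples=100, derandomize=True)
    def test_symmetry(self, sa, la, sb, lb):
        a = make_peptide("S" + "A" * (la - 1), start=sa)
        b = make_peptide("T" + "A" * (lb - 1), start=sb)
        ab = CrossLinkCandidate("dipeptide", a, ((sa, "S"),), a.mass + b.mass, b, ((sb, "T"),))
        ba = CrossLinkCandidate("dipeptide", b, ((sb, "T"),), a.mass + b.mass, a, ((sa, "S"),))
        assert classify_crosslink(ab) == classify_crosslink(ba)


def brute_force_matches(observed, candidates, tol_ppm):
    """O(n*m) oracle for the sorted/searchsorted matcher."""
    out = []
    for obs in observed:
        hits = [
            i
            for i, c in enumerate(candidates)
            if abs((obs - c.mass) / c.mass * 1e6) <= tol_ppm
        ]
        out.append(set(hits))
    return out


class TestMatchPrecursors:
    def test_exact_mass_matches_at_zero_ppm(self):
        pep = make_peptide("STAR")
        (cand,) = enumerate_lipid_candidates([pep])[:1]
        (hits,) = match_precursors([cand.mass], [cand], tol_ppm=5.0)
        assert len(hits) == 1 and hits[0].ppm == pytest.approx(0.0, abs=1e-9)

    def test_mass_beyond_tolerance_not_matched(self):
        pep = make_peptide("STAR")
        (cand,) = enumerate_lipid_candidates([pep])[:1]
        off = cand.mass * (1 + 2 * 5.0 * 1e-6)
        (hits,) = match_precursors([off], [cand], tol_ppm=5.0)
        assert hits == []

    def test_nonpositive_observed_mass_rejected(self):
        pep = make_peptide("STAR")
        cands = enumerate_lipid_candidates([pep])
        with pytest.raises(ValueError):
            match_precursors([-5.0], cands, tol_ppm=5.0)

    def test_agrees_with_brute_force_oracle(self):
        from proppinlab.synthetic import gen_xl_dataset, random_protein

        protein = random_protein(300, seed=5)
        observed, chosen, _ = gen_xl_dataset(
            protein, n_lipid_sites=30, n_dipeptide_links=20,
            ppm_noise_sd=3.0, n_decoys=200, seed=5,
        )
        from proppinlab.xlink import digest as _digest
        peptides = _digest(protein, max_missed=1, min_len=4, max_len=40)
        candidates = enumerate_lipid_candidates(peptides) + enumerate_dipeptide_candidates(peptides)
        results = match_precursors(observed, candidates, tol_ppm=10.0)
        oracle = brute_force_matches(observed, candidates, tol_ppm=10.0)
        for hits, expected in zip(results, oracle):
            got = {candidates.index(h.candidate) for h in hits}
            assert got == expected
        # every true precursor (first 50 observed) recovered
        for hits in results[:50]:
            assert hits, "a true cross-link mass found no candidate"

    def test_hits_sorted_by_absolute_ppm(self):
        peps = [make_peptide("SAAG"), make_peptide("SAGA"), make_peptide("SGAA")]
        cands = enumerate_lipid_candidates(peps)  # identical masses
        obs = cands[0].mass * (1 + 1e-6)
        (hits,) = match_precursors([obs], cands, tol_ppm=5.0)
        ppms = [abs(h.ppm) for h in hits]
        assert ppms == sorted(ppms)


class TestFragments:
    def test_y1_of_gk(self):
        frags = dict(fragment_masses("GK", ion_types=("y",)))
        assert frags["y1"] == pytest.approx(147.1128, abs=1e-3)

    def test_complement_sum_identity(self):
        """b_i + y_(n-i) singly charged = peptide neutral + 2 protons."""
        seq = "MSTYAKGACDER"
        neutral = peptide_mass(seq)
        frags = dict(fragment_masses(seq))
        n = len(seq)
        for i in range(1, n):
            assert frags[f"b{i}"] + frags[f"y{n - i}"] == pytest.approx(
                neutral + 2 * PROTON_MASS, abs=1e-9
            )

    def test_lipid_adduct_shifts_site_containing_ions(self):
        seq = "GASTK"
        delta = lipid_adduct_delta()
        plain = dict(fragment_masses(seq))
        linked = dict(fragment_masses(seq, link=(3, delta)))  # site on S3
        n = len(seq)
        for i in range(1, n):
            b_shift = linked[f"b{i}"] - plain[f"b{i}"]
            assert b_shift == pytest.approx(delta if i >= 3 else 0.0, abs=1e-9)
            y_shift = linked[f"y{i}"] - plain[f"y{i}"]
            assert y_shift == pytest.approx(delta if i > n - 3 else 0.0, abs=1e-9)

    def test_dipeptide_partner_carried_as_fixed_delta(self):
        partner = make_peptide("STAR")
        delta = crosslink_fragment_delta(partner.mass)
        assert delta == pytest.approx(partner.mass + 140.074 - 2 * PROTON_MASS)

    def test_unknown_ion_type_rejected(self):
        with pytest.raises(ValueError):
            fragment_masses("GK", ion_types=("a",))

    def test_doubly_charged_ions(self):
        frags = dict(fragment_masses("GKGK", max_charge=2))
        single, double = frags["y2"], frags["y2^2"]
        neutral = single - PROTON_MASS
        assert double == pytest.approx((neutral + 2 * PROTON_MASS) / 2, abs=1e-9)


class TestCandidateMassAdditivity:
    @given(st.text(alphabet=AA, min_size=2, max_size=20))
    @settings(max_examples=50, derandomize=True)
    def test_lipid_candidate_mass_additivity(self, seq):
        pep = make_peptide(seq, cterm=True)
        for cand in enumerate_lipid_candidates([pep]):
            expected = pep.mass + Lipid().mass + Linker().linker_mass - 2 * PROTON_MASS
            assert cand.mass == pytest.approx(expected, abs=1e-6)
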