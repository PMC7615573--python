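"""NG86 site counting, branch polarization, and the candidate screen."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from woolgen.dnds import (
    SENSE_CODONS,
    CodonAlignment,
    GeneDnDs,
    count_sites_ng86,
    coverage_filter,
    lookup_known_variants,
    polarize_focal_changes,
    screen_candidates,
)

from conftest import build_matrix


def _translate(codon):
    """Independent oracle via Bio.Seq.translate."""
    return str(Seq(codon).translate())


class TestNg86Sites:
    def test_all_sense_codons_match_enumeration_oracle(self):
        for codon in SENSE_CODONS:
            syn = 0
            for i in range(3):
                for b in "ACGT":
                    if b == codon[i]:
                        continue
                    mut = codon[:i] + b + codon[i + 1 :]
                    # stops are nonsynonymous by convention
                    if _translate(mut) != "*" and _translate(mut) == _translate(codon):
                        syn += 1
            n, s = count_sites_ng86(codon)
            assert s == pytest.approx(syn / 3), codon
            assert n + s == pytest.approx(3.0), codon

    def test_met_has_no_synonymous_sites(self):
        assert count_sites_ng86("ATG") == (3.0, 0.0)

    def test_phe_third_position(self):
        n, s = count_sites_ng86("TTT")
        assert s == pytest.approx(1 / 3)
        assert n == pytest.approx(8 / 3)

    def test_ambiguous_and_stop_codons_contribute_nothing(self):
        assert count_sites_ng86("TNA") is None
        assert count_sites_ng86("TAA") is None


def _aln(gene_id, focal_seq, other_seq, samples=("Woolly", "c1", "c2", "c3", "o1", "o2")):
    seqs = {s: other_seq for s in samples}
    seqs["Woolly"] = focal_seq
    return CodonAlignment(gene_id, seqs)


class TestAlignmentValidation:
    def test_internal_stop_flags_gene(self):
        aln = _aln("g", "ATGTAAGCT", "ATGTAAGCT")
        assert not aln.valid and "stop" in aln.invalid_reason

    def test_terminal_stop_allowed(self):
        aln = _aln("g", "ATGGCTTAA", "ATGGCTTAA")
        assert aln.valid

    def test_frame_violation_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            CodonAlignment("g", {"a": "ATGA"})

    def test_callable_fraction_counts_clean_codons(self):
        aln = CodonAlignment("g", {"a": "ATGNNNGCT"})
        assert aln.callable_fraction("a") == pytest.approx(2 / 3)


class TestPolarization:
    def test_identical_sequences_have_no_changes(self):
        aln = _aln("g", "ATGGCTTGC", "ATGGCTTGC")
        res = polarize_focal_changes(aln, "Woolly", ["c1", "c2", "c3"], ["o1", "o2"])
        assert res.nd == 0 and res.sd == 0
        assert res.n_sites + res.s_sites == pytest.approx(3 * 3)

    def test_hand_built_one_nonsyn_two_syn(self):
        # TTT->TTC syn (Phe), CTG->CTA syn (Leu), ATG->ATA nonsyn (Met->Ile)
        anc = "TTT" + "CTG" + "ATG"
        foc = "TTC" + "CTA" + "ATA"
        aln = _aln("g", foc, anc)
        res = polarize_focal_changes(aln, "Woolly", ["c1", "c2", "c3"], ["o1", "o2"])
        assert res.nd == pytest.approx(1.0)
        assert res.sd == pytest.approx(2.0)

    def test_change_shared_with_comparator_assigned_to_neither(self):
        anc, derived = "ATGGCT", "ATGGAT"  # GCT->GAT nonsyn
        seqs = {s: anc for s in ("c2", "c3", "o1", "o2")}
        seqs["Woolly"] = derived
        seqs["c1"] = derived  # comparator shares the change
        aln = CodonAlignment("g", seqs)
        res = polarize_focal_changes(aln, "Woolly", ["c1", "c2", "c3"], ["o1", "o2"])
        assert res.nd == 0  # background not uniform -> codon skipped
        assert res.comparator_nd["c1"] == 0

    def test_focal_absent_raises(self):
        aln = CodonAlignment("g", {"x": "ATG"})
        with pytest.raises(KeyError, match="focal"):
            polarize_focal_changes(aln, "Woolly", ["x"], [])

    def test_multi_hit_codon_averages_pathways(self):
        # TTT -> GCT differs at positions 0 and 1; both orders evaluated
        aln = _aln("g", "GCT", "TTT")
        res = polarize_focal_changes(aln, "Woolly", ["c1", "c2", "c3"], ["o1", "o2"])
        assert res.nd + res.sd == pytest.approx(2.0)
        assert res.nd == pytest.approx(2.0)  # both pathways all-nonsyn

    def test_site_conservation_per_gene(self):
        rng = np.random.default_rng(0)
        codons = [SENSE_CODONS[i] for i in rng.integers(0, 61, 50)]
        seq = "".join(codons)
        aln = _aln("g", seq, seq)
        res = polarize_focal_changes(aln, "Woolly", ["c1", "c2", "c3"], ["o1", "o2"])
        assert res.n_sites + res.s_sites == pytest.approx(3 * res.n_codons_evaluated)
        assert res.n_codons_evaluated == 50


class TestCoverageFilter:
    def test_fully_callable_retained(self):
        aln = _aln("g", "ATGGCT", "ATGGCT")
        kept, excluded = coverage_filter([aln], list(aln.seqs))
        assert [a.gene_id for a in kept] == ["g"]
        assert len(excluded) == 0

    def test_half_callable_dropped_with_reason(self):
        seqs = {"a": "ATGGCT", "b": "NNNGCT"}
        aln = CodonAlignment("g", seqs)
        kept, excluded = coverage_filter([aln], ["a", "b"])
        assert not kept
        assert "low coverage" in excluded["reason"].iloc[0]

    def test_known_fraction_fixture_exact_retained_set(self):
        alns = []
        for i, frac in enumerate([1.0, 0.9, 0.8, 0.7, 0.5, 1.0, 0.85, 0.3, 0.95, 0.79]):
            n = 100
            n_bad = round((1 - frac) * n)
            seq = "NNN" * n_bad + "ATG" * (n - n_bad)
            alns.append(CodonAlignment(f"g{i}", {"a": seq}))
        kept, _ = coverage_filter(alns, ["a"], min_callable_fraction=0.8)
        assert [a.gene_id for a in kept] == ["g0", "g1", "g2", "g5", "g6", "g8"]


def _gene(gene_id, nd, comp=(0.0, 0.0, 0.0), sd=0.0, n_sites=300.0, s_sites=100.0):
    return GeneDnDs(
        gene_id, nd, sd, n_sites, s_sites, 100,
        {"c1": comp[0], "c2": comp[1], "c3": comp[2]},
    )


class TestScreen:
    def _genes(self):
        # filler gene pins dS_genome: Sd=10 over S_sites=1000 -> contributes
        # most of dS; total Sd=10, total S_sites=3100 -> ds = 10/3100
        filler = _gene("filler", nd=0.0, sd=10.0, n_sites=3000.0, s_sites=1000.0)
        ds = 10.0 / (1000.0 + 100.0 * 3)
        # omega = (nd/300)/ds -> nd = omega * 300 * ds
        mk = lambda gid, om, comp: _gene(gid, om * 300.0 * ds, comp)
        return filler, mk, ds

    def test_rule_fixtures(self):
        filler, mk, ds = self._genes()
        genes = [
            filler,
            mk("cand", 2.0, (0, 0, 0)),
            mk("weak", 1.4, (0, 0, 0)),
            mk("shared", 3.0, (1, 0, 0)),
        ]
        res = screen_candidates(genes, threshold=1.5)
        assert res.candidates == ["cand"]
        reasons = dict(zip(res.excluded["gene_id"], res.excluded["reason"]))
        assert reasons["weak"] == "below threshold"
        assert reasons["shared"] == "comparator nonzero dN"
        assert res.ds_genome == pytest.approx(ds)

    def test_invariant_to_gene_order(self):
        filler, mk, _ = self._genes()
        genes = [filler, mk("a", 2.0, (0, 0, 0)), mk("b", 3.0, (0, 0, 0))]
        r1 = screen_candidates(genes)
        r2 = screen_candidates(genes[::-1])
        assert r1.candidates == r2.candidates
        assert r1.table["gene_id"].tolist() == r2.table["gene_id"].tolist()

    def test_strict_inequality_excludes_boundary(self):
        # power-of-two site counts make omega == 1.5 exact in binary
        filler = _gene("filler", nd=0.0, sd=4.0, n_sites=3000.0, s_sites=1024.0)
        edge = _gene("edge", nd=1.5, sd=0.0, n_sites=256.0, s_sites=0.0)
        genes = [filler, edge]
        assert screen_candidates(genes).candidates == ["edge"]
        assert screen_candidates(genes, strict_inequality=True).candidates == []

    def test_zero_ds_genome_raises(self):
        genes = [_gene("g", nd=2.0, sd=0.0)]
        with pytest.raises(ValueError, match="dS is zero"):
            screen_candidates(genes)

    def test_synthetic_screen_detects_selected_genes(self):
        from woolgen.simulate import (
            SCREEN_COMPARATORS,
            SCREEN_FOCAL,
            SCREEN_OUTGROUPS,
            default_gene_omegas,
            simulate_codon_evolution,
        )

        omegas = default_gene_omegas(80, seed=3)
        alns, _ = simulate_codon_evolution(omegas, 120, 9)
        kept, low = coverage_filter(
            alns, [SCREEN_FOCAL] + SCREEN_COMPARATORS + SCREEN_OUTGROUPS
        )
        genes = [
            polarize_focal_changes(a, SCREEN_FOCAL, SCREEN_COMPARATORS, SCREEN_OUTGROUPS)
            for a in kept
        ]
        res = screen_candidates(genes, low_coverage=low)
        selected = {g for g, w in omegas.items() if w > 1}
        cand = set(res.candidates)
        assert len(cand & selected) / len(selected) >= 0.5
        neutral = {g for g, w in omegas.items() if w <= 1}
        assert len(cand & neutral) / len(neutral) < 0.10


class TestLookupKnownVariants:
    def test_fifteen_row_fixture_exact_report(self):
        # haploid focal over 10 sites; 5 variants probe absent positions
        calls = np.array(
            [[0], [1], [-1], [0], [1], [0], [0], [1], [0], [1]]
        )
        refs = list("ACGTACGTAC")
        alts = list("CGTACGTACG")
        m = build_matrix(calls, ["focal"], ploidy=[1], ref=refs, alt=alts)
        rows = []
        expected = []
        for i in range(10):
            anc, der = refs[i], alts[i]
            rows.append(("gene%d" % i, "1", (i + 1) * 1000, anc, der))
            if calls[i, 0] == -1:
                expected.append("missing")
            elif calls[i, 0] == 0:
                expected.append("ancestral")
            else:
                expected.append("derived")
        for i in range(5):  # positions with no data
            rows.append(("ghost%d" % i, "1", 999_000 + i, "A", "C"))
            expected.append("missing")
        table = pd.DataFrame(
            rows, columns=["gene", "chrom", "pos", "ancestral", "derived"]
        )
        out = lookup_known_variants(m, "s0", table)
        assert out["state"].tolist() == expected

    def test_derived_orientation_flipped_vs_ref(self):
        # ancestral allele is the ALT of the genotype matrix
        m = build_matrix([[0]], ["p"], ploidy=[1], ref=["A"], alt=["C"])
        table = pd.DataFrame(
            [("g", "1", 1000, "C", "A")],
            columns=["gene", "chrom", "pos", "ancestral", "derived"],
        )
        out = lookup_known_variants(m, "s0", table)
        assert out["state"].iloc[0] == "derived"  # carries A = derived
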