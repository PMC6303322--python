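"""TSS resolution, candidate enumeration, round-based picking and oligos."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import reverse_complement

import screenforge as sf
from screenforge.design import (
    CRISPRA_WINDOW,
    CRISPRI_WINDOW,
    LocusTooShortError,
    OLIGO_FLANK_3,
    OLIGO_FLANK_5,
    PickingRound,
)


class TestResolveTss:
    @staticmethod
    def _tables():
        def tbl(genes):
            return pd.DataFrame(
                {"gene": genes, "chrom": ["chr1"] * len(genes),
                 "position": range(1000, 1000 + len(genes)), "strand": ["+"] * len(genes)}
            )

        return tbl(["A", "B"]), tbl(["A", "C"]), tbl(["A", "C", "D"])

    def test_priority_order(self):
        cage, ens, ncbi = self._tables()
        recs, missing = sf.resolve_tss(cage, ens, ncbi, ["A", "B", "C", "D", "E"])
        assert recs["A"].source == "FANTOM_CAGE"
        assert recs["B"].source == "FANTOM_CAGE"
        assert recs["C"].source == "Ensembl"
        assert recs["D"].source == "NCBI"
        assert missing == ["E"]  # reported, not dropped


class TestEnumerateCandidates:
    def test_all_a_locus_has_no_candidates(self):
        assert sf.enumerate_candidates("A" * 701, 350) == []

    def test_planted_sites_recovered_on_both_strands(self):
        # A/T background cannot host a PAM; plant one site per strand
        L = 350
        locus = list("AT" * 351)[:701]
        # plus strand: PAM-proximal base at offset +50 -> PAM at L+51
        locus[L + 51 : L + 54] = list("TGG")
        # minus strand: genomic CC at w, protospacer PAM-proximal base at w+3;
        # choose offset -100 -> w = L - 100 - 3
        w = L - 103
        locus[w : w + 2] = list("CC")
        seq = "".join(locus)
        cands = sf.enumerate_candidates(seq, L)
        by_strand = {c.strand: c for c in cands}
        assert len(cands) == 2
        assert by_strand["+"].tss_offset == 50
        assert by_strand["+"].sequence == seq[L + 31 : L + 51]
        assert by_strand["-"].tss_offset == -100
        assert by_strand["-"].sequence == reverse_complement(seq[w + 3 : w + 23])
        assert by_strand["-"].pam.endswith("GG")

    def test_window_boundary_inclusive(self):
        L = 400
        for offset, expect in ((300, True), (301, False)):
            locus = list("AT" * 400)[:801]
            locus[L + offset + 1 : L + offset + 4] = list("TGG")
            cands = sf.enumerate_candidates("".join(locus), L)
            assert (len(cands) == 1) is expect

    def test_minus_strand_gene_flips_offset_sign(self):
        L = 350
        locus = list("AT" * 351)[:701]
        locus[L + 51 : L + 54] = list("TGG")
        plus = sf.enumerate_candidates("".join(locus), L, gene_strand="+")
        minus = sf.enumerate_candidates("".join(locus), L, gene_strand="-")
        assert plus[0].tss_offset == 50
        assert minus[0].tss_offset == -50

    def test_locus_too_short_names_required_span(self):
        with pytest.raises(LocusTooShortError, match="330"):
            sf.enumerate_candidates("A" * 500, 100)


class TestPickingPolicy:
    def test_default_round1_windows(self):
        assert sf.PickingPolicy.default("CRISPRi").rounds[0].window == CRISPRI_WINDOW == (25, 75)
        assert sf.PickingPolicy.default("CRISPRa").rounds[0].window == CRISPRA_WINDOW == (-150, -75)

    def test_tightening_rounds_rejected(self):
        with pytest.raises(ValueError, match="tighten"):
            sf.PickingPolicy(
                modality="CRISPRi",
                rounds=(PickingRound((25, 75), 5, 0.5), PickingRound((25, 75), 1, 0.5)),
            )

    def test_crispri_optimal_candidate_is_round1_eligible(self):
        cand = sf.SgRnaCandidate(
            sequence="ACGT" * 5, pam="AGG", strand="+", tss_offset=50,
            on_target_score=0.9, perfect_match_sites=1,
        )
        assert sf.PickingPolicy.default("CRISPRi").rounds[0].eligible(cand)


def _candidate(seq, offset, score, pm):
    return sf.SgRnaCandidate(sequence=seq, pam="AGG", strand="+", tss_offset=offset,
                             on_target_score=score, perfect_match_sites=pm)


class TestPickSgrnas:
    def test_quota_from_round1_ordered_by_score(self):
        cands = [
            _candidate(f"AAAAAAAAAAAAAAAAAA{'ACGT'[i % 4]}{'ACGT'[i // 4]}", 30 + i,
                       0.9 - 0.05 * i, 0)
            for i in range(8)
        ]
        res = sf.pick_sgrnas({"G": cands}, sf.PickingPolicy.default("CRISPRi"))
        assert len(res.picks) == 6
        assert all(p.round_index == 1 for p in res.picks)
        scores = [p.sgrna.on_target_score for p in res.picks]
        assert scores == sorted(scores, reverse=True)
        assert [p.set_assignment for p in res.picks] == ["A"] * 3 + ["B"] * 3
        assert res.shortfall == {}

    def test_round2_fills_after_round1_exhausted(self):
        r1 = [_candidate("A" * 19 + b, 50, 0.8, 0) for b in "CT"]
        r2 = [_candidate("C" * 19 + b, 200, 0.9, 0) for b in "ACGT"] + [
            _candidate("G" * 19 + b, 250, 0.7, 1) for b in "ACGT"
        ]
        res = sf.pick_sgrnas({"G": r1 + r2}, sf.PickingPolicy.default("CRISPRi"))
        rounds = [p.round_index for p in res.picks]
        assert rounds == [1, 1, 2, 2, 2, 2]

    def test_shortfall_flagged_not_raised(self):
        cands = [_candidate("A" * 19 + b, 50, 0.8, 0) for b in "CGTA"]
        res = sf.pick_sgrnas({"G": cands}, sf.PickingPolicy.default("CRISPRi"))
        assert res.shortfall == {"G": 4}
        assert len(res.picks) == 4

    def test_every_pick_satisfies_its_round_and_fails_earlier_rounds(self):
        fx = sf.make_design_fixture(6, {1: 2, 2: 2, 3: 2, 4: 2}, seed=2)
        cands = {
            g: sf.annotate_candidates(
                sf.enumerate_candidates(fx.loci[g], fx.tss_index[g]),
                fx.scores, fx.offtargets,
            )
            for g in fx.loci
        }
        res = sf.pick_sgrnas(cands, fx.policy)
        for p in res.picks:
            assert fx.policy.rounds[p.round_index - 1].eligible(p.sgrna)
            for earlier in fx.policy.rounds[: p.round_index - 1]:
                assert not earlier.eligible(p.sgrna)


class TestAssignRounds:
    def test_self_consistency_on_round1_rich_library(self):
        fx = sf.make_design_fixture(4, {1: 6}, seed=3)
        cands = {
            g: sf.annotate_candidates(
                sf.enumerate_candidates(fx.loci[g], fx.tss_index[g]),
                fx.scores, fx.offtargets,
            )
            for g in fx.loci
        }
        res = sf.pick_sgrnas(cands, fx.policy)
        ra = sf.assign_rounds([p.sgrna for p in res.picks], fx.policy)
        assert ra.fraction(1) == 1.0

    def test_round2_only_candidate_labelled_round2(self):
        cand = _candidate("A" * 20, 200, 0.9, 0)  # outside the round-1 window
        ra = sf.assign_rounds([cand], sf.PickingPolicy.default("CRISPRi"))
        assert ra.labels == [2]

    def test_fractions_partition_to_one(self):
        policy = sf.PickingPolicy.default("CRISPRi")
        lib = [
            _candidate("A" * 20, 50, 0.9, 0),        # round 1
            _candidate("C" * 20, 200, 0.9, 0),       # round 2
            _candidate("G" * 20, 200, 0.9, 20),      # no round (too many sites)
            sf.SgRnaCandidate(sequence="T" * 20, pam="AGG", strand="+",
                              tss_offset=50),        # unannotated
        ]
        ra = sf.assign_rounds(lib, policy)
        assert sum(ra.fractions.values()) == pytest.approx(1.0)
        assert ra.fractions["none"] == 0.25
        assert ra.fractions["unassignable"] == 0.25


class TestAddControls:
    def test_controls_have_no_perfect_match_sites(self):
        genome = sf.SequenceGenomeIndex(["ACGT" * 300])
        controls = sf.add_controls(genome, n=25, seed=4)
        assert len(controls) == 25
        assert (controls["perfect_match_sites"] == 0).all()
        for seq in controls["sgrna_sequence"]:
            assert genome.perfect_match_sites(seq) == 0

    def test_seed_determinism_and_default_n(self):
        genome = lambda seq: 0
        a = sf.add_controls(genome, seed=5)
        b = sf.add_controls(genome, seed=5)
        assert len(a) == 992
        assert a.equals(b)

    def test_attempt_budget_exhaustion(self):
        everything_matches = lambda seq: 1
        with pytest.raises(RuntimeError, match="attempts"):
            sf.add_controls(everything_matches, n=2, seed=0, max_attempts=10)

    def test_genome_index_counts_both_strands(self):
        proto = "ACGTACGTACGTACGTACGT"
        site = proto + "TGG"
        genome = sf.SequenceGenomeIndex(["TTTT" + site + "TTTT"])
        assert genome.perfect_match_sites(proto) == 1
        # the same site read from the other strand
        genome_rc = sf.SequenceGenomeIndex([reverse_complement("TTTT" + site + "TTTT")])
        assert genome_rc.perfect_match_sites(proto) == 1


class TestAssembleOligos:
    def test_printed_primer_example(self):
        oligo = sf.assemble_oligos(["ACGTACGTACGTACGTACGT"], primer_set=1)[0]
        assert oligo == (
            "AGGCACTTGCTCGTACGACG" "CGTCTCACACCG" "ACGTACGTACGTACGTACGT"
            "GTTTCGAGACG" "TTAAGGTGCCGGGCCCACAT"
        )
        assert len(oligo) == 83

    def test_bsmbi_sites_one_per_strand(self):
        for ps in range(1, 7):
            oligo = sf.assemble_oligos(["ACGTACGTACGTACGTACGT"], ps)[0]
            assert oligo.count("CGTCTC") == 1
            assert reverse_complement(oligo).count("CGTCTC") == 1

    def test_anchor_extraction_recovers_protospacer(self):
        rng = np.random.default_rng(6)
        bases = np.array(list("ACGT"))
        protos = ["".join(bases[rng.integers(0, 4, 20)]) for _ in range(50)]
        for proto, oligo in zip(protos, sf.assemble_oligos(protos, 3)):
            pos = oligo.find("CACCG")
            assert oligo[pos + 5 : pos + 25] == proto

    def test_unknown_primer_set(self):
        with pytest.raises(ValueError, match="primer set"):
            sf.assemble_oligos(["A" * 20], 7)


class TestP1Fraction:
    def test_single_promoter(self):
        t = pd.DataFrame({"promoter_rank": [1], "reads": [100]})
        assert sf.p1_fraction(t) == 1.0

    def test_motivating_case(self):
        # a p1 peak carrying 58 of 100 reads -> fraction 0.58
        t = pd.DataFrame({"promoter_rank": [1, 2, 3], "reads": [58, 30, 12]})
        assert sf.p1_fraction(t) == pytest.approx(0.58)

    def test_zero_p1(self):
        t = pd.DataFrame({"promoter_rank": [1, 2], "reads": [0, 10]})
        assert sf.p1_fraction(t) == 0.0

    def test_zero_total_rejected(self):
        t = pd.DataFrame({"promoter_rank": [1], "reads": [0]})
        with pytest.raises(ValueError, match="zero total"):
            sf.p1_fraction(t)
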