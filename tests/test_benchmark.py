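"""AUC / dAUC / ROC metrics against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

import screenforge as sf


def brute_force_depletion_auc(values: pd.Series, subset: set) -> float:
    """Oracle: trapezoid over the explicit curve points (i/N, c_i/|S|)."""
    df = pd.DataFrame({"v": values.astype(float), "g": values.index.astype(str)})
    order = list(df.sort_values(["v", "g"]).index)
    N, S = len(order), len(subset)
    xs, ys = [0.0], [0.0]
    c = 0
    for i, item in enumerate(order, start=1):
        c += item in subset
        xs.append(i / N)
        ys.append(c / S)
    return sum(
        (xs[i] - xs[i - 1]) * (ys[i] + ys[i - 1]) / 2 for i in range(1, len(xs))
    )


def pairwise_roc_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """Oracle: all-pairs concordance with ties counted one half."""
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestDepletionAuc:
    def test_subset_of_everything_is_diagonal(self):
        v = pd.Series([3.0, 1.0, 2.0, 0.0], index=list("abcd"))
        assert sf.depletion_auc(v, set("abcd")) == pytest.approx(0.5)

    @pytest.mark.parametrize(
        "ranks, expected",
        [({1, 3}, 0.625), ({1, 2}, 0.75)],
    )
    def test_hand_trapezoids_n4(self, ranks, expected):
        v = pd.Series([0.0, 1.0, 2.0, 3.0], index=["r1", "r2", "r3", "r4"])
        subset = {f"r{r}" for r in ranks}
        assert sf.depletion_auc(v, subset) == pytest.approx(expected)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(17)
        for _ in range(300):
            N = int(rng.integers(3, 50))
            vals = rng.choice([-2.0, -1.0, 0.0, 1.0], size=N)  # ties on purpose
            v = pd.Series(vals, index=[f"i{j:02d}" for j in range(N)])
            k = int(rng.integers(1, N + 1))
            subset = set(rng.choice(v.index, size=k, replace=False))
            assert sf.depletion_auc(v, subset) == pytest.approx(
                brute_force_depletion_auc(v, subset), abs=1e-12
            )

    def test_complement_symmetry_without_ties(self):
        rng = np.random.default_rng(23)
        v = pd.Series(rng.normal(size=40), index=[f"i{j}" for j in range(40)])
        subset = set(v.index[:13])
        a = sf.depletion_auc(v, subset)
        b = sf.depletion_auc(-v, subset)
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_empty_subset_rejected(self):
        v = pd.Series([1.0], index=["a"])
        with pytest.raises(ValueError):
            sf.depletion_auc(v, set())

    def test_subset_item_without_value_rejected(self):
        v = pd.Series([1.0], index=["a"])
        with pytest.raises(ValueError, match="without a value"):
            sf.depletion_auc(v, {"a", "ghost"})


class TestDauc:
    def test_identical_sets_give_zero(self, ko_lfc, ko_screen, ko_gene_sets):
        ess, _ = ko_gene_sets
        rep = sf.dauc(ko_lfc, ko_screen.reference.gene_map(), ess, ess)
        assert rep.dauc == pytest.approx(0.0, abs=1e-12)

    def test_toy_composition(self):
        v = pd.Series([0.0, 1.0, 2.0, 3.0], index=["s1", "s2", "s3", "s4"])
        gene_map = {"E": ["s1", "s2"], "N1": ["s1"], "N2": ["s3"]}
        # essential sgRNAs at ranks {1,2} -> 0.75; nonessential at {1,3} -> 0.625
        ess = sf.GeneSet.from_iterable("e", ["E"], role="essential")
        ness = sf.GeneSet.from_iterable("n", ["N1", "N2"], role="nonessential")
        rep = sf.dauc(v, gene_map, ess, ness)
        assert rep.dauc == pytest.approx(0.125)

    def test_sign_flip_maps_auc_to_complement(self, ko_lfc, ko_screen, ko_gene_sets):
        ess, ness = ko_gene_sets
        gm = ko_screen.reference.gene_map()
        fwd = sf.dauc(ko_lfc, gm, ess, ness)
        rev = sf.dauc(-ko_lfc, gm, ess, ness)
        n = len(ko_lfc)
        assert fwd.auc_essential + rev.auc_essential == pytest.approx(1.0, abs=1 / n)

    def test_unresolvable_set_rejected(self, ko_lfc, ko_screen):
        gm = ko_screen.reference.gene_map()
        ghost = sf.GeneSet.from_iterable("g", ["NOT_A_GENE"], role="essential")
        with pytest.raises(ValueError, match="zero scored"):
            sf.dauc(ko_lfc, gm, ghost, ghost)


class TestGeneRocAuc:
    def test_perfect_separation(self):
        scores = pd.Series({"p1": -3.0, "p2": -2.0, "n1": 0.0, "n2": 1.0})
        pos = sf.GeneSet.from_iterable("p", ["p1", "p2"], role="essential")
        neg = sf.GeneSet.from_iterable("n", ["n1", "n2"], role="nonessential")
        assert sf.gene_roc_auc(scores, pos, neg) == 1.0

    def test_three_of_four_pairs_concordant(self):
        # depletion magnitudes: positives {3,1}, negatives {2,0}
        scores = pd.Series({"p1": -3.0, "p2": -1.0, "n1": -2.0, "n2": 0.0})
        pos = sf.GeneSet.from_iterable("p", ["p1", "p2"], role="essential")
        neg = sf.GeneSet.from_iterable("n", ["n1", "n2"], role="nonessential")
        assert sf.gene_roc_auc(scores, pos, neg) == pytest.approx(0.75)

    def test_all_ties_give_half(self):
        scores = pd.Series({"p1": 1.0, "p2": 1.0, "n1": 1.0})
        pos = sf.GeneSet.from_iterable("p", ["p1", "p2"], role="essential")
        neg = sf.GeneSet.from_iterable("n", ["n1"], role="nonessential")
        assert sf.gene_roc_auc(scores, pos, neg) == pytest.approx(0.5)

    def test_matches_pairwise_concordance_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(200):
            n_pos = int(rng.integers(1, 30))
            n_neg = int(rng.integers(1, 30))
            vals = rng.choice(np.arange(-4, 5) / 2, size=n_pos + n_neg)
            genes = [f"p{i}" for i in range(n_pos)] + [f"n{i}" for i in range(n_neg)]
            scores = pd.Series(vals, index=genes)
            pos = sf.GeneSet.from_iterable("p", genes[:n_pos], role="essential")
            neg = sf.GeneSet.from_iterable("n", genes[n_pos:], role="nonessential")
            expected = pairwise_roc_auc(-vals[:n_pos], -vals[n_pos:])
            assert sf.gene_roc_auc(scores, pos, neg) == pytest.approx(expected, abs=1e-12)

    def test_overlapping_sets_rejected(self):
        scores = pd.Series({"a": 1.0, "b": 2.0})
        s1 = sf.GeneSet.from_iterable("x", ["a", "b"], role="essential")
        s2 = sf.GeneSet.from_iterable("y", ["b"], role="nonessential")
        with pytest.raises(ValueError, match="overlap"):
            sf.gene_roc_auc(scores, s1, s2)


class TestSubsampleRoc:
    def test_full_draw_equals_full_library_roc(self, ko_lfc, ko_screen, ko_gene_sets):
        ess, ness = ko_gene_sets
        gm = ko_screen.reference.gene_map()
        gene_means = ko_lfc.groupby(ko_screen.reference.id_to_gene()).mean()
        full = sf.gene_roc_auc(gene_means, ess, ness)
        rep = sf.subsample_roc(ko_lfc, gm, n=4, iterations=1, positives=ess,
                               negatives=ness, seed=3)
        assert rep.mean_roc_auc == pytest.approx(full, abs=1e-12)
        assert rep.sd_roc_auc == 0.0

    def test_seed_determinism(self, ko_lfc, ko_screen, ko_gene_sets):
        ess, ness = ko_gene_sets
        gm = ko_screen.reference.gene_map()
        a = sf.subsample_roc(ko_lfc, gm, 2, 5, ess, ness, seed=9)
        b = sf.subsample_roc(ko_lfc, gm, 2, 5, ess, ness, seed=9)
        assert a == b

    def test_mean_roc_nondecreasing_in_n(self, ko_lfc, ko_screen, ko_gene_sets):
        """More guides per gene should not hurt performance (within 2 sd)."""
        ess, ness = ko_gene_sets
        gm = ko_screen.reference.gene_map()
        reports = [
            sf.subsample_roc(ko_lfc, gm, n, 20, ess, ness, seed=13) for n in (1, 2, 4)
        ]
        for lo, hi in zip(reports, reports[1:]):
            assert hi.mean_roc_auc >= lo.mean_roc_auc - 2 * max(lo.sd_roc_auc, 1e-6)


class TestFilteredDdauc:
    def test_fraction_one_is_identity(self, ko_lfc, ko_screen, ko_gene_sets):
        ess, ness = ko_gene_sets
        gm = ko_screen.reference.gene_map()
        scheme = pd.Series(np.arange(len(ko_lfc), dtype=float), index=ko_lfc.index)
        rep = sf.filtered_ddauc(ko_lfc, gm, scheme, ess, ness, fraction=1.0)
        assert rep.ddauc == pytest.approx(0.0, abs=1e-12)

    def test_oracle_scheme_improves_dauc(self, ko_lfc, ko_screen, ko_gene_sets):
        """Scoring by true efficacy concentrates active guides: ddAUC > 0."""
        ess, ness = ko_gene_sets
        gm = ko_screen.reference.gene_map()
        truth = ko_screen.truth.sgrnas.set_index("sgrna_id")
        scheme = truth.loc[ko_lfc.index, "efficacy"]
        rep = sf.filtered_ddauc(ko_lfc, gm, scheme, ess, ness, fraction=0.10)
        assert rep.ddauc > 0
        assert rep.n_retained == int(np.ceil(0.1 * len(ko_lfc)))

    def test_random_scheme_is_neutral_in_expectation(self, ko_lfc, ko_screen, ko_gene_sets):
        ess, ness = ko_gene_sets
        gm = ko_screen.reference.gene_map()
        rng = np.random.default_rng(7)
        dd = []
        for _ in range(20):
            scheme = pd.Series(rng.normal(size=len(ko_lfc)), index=ko_lfc.index)
            dd.append(sf.filtered_ddauc(ko_lfc, gm, scheme, ess, ness, fraction=0.25).ddauc)
        assert abs(np.mean(dd)) < 0.05

    def test_bad_fraction_rejected(self, ko_lfc, ko_screen, ko_gene_sets):
        ess, ness = ko_gene_sets
        with pytest.raises(ValueError):
            sf.filtered_ddauc(ko_lfc, ko_screen.reference.gene_map(),
                              ko_lfc, ess, ness, fraction=0.0)


class TestStopGeneSet:
    @staticmethod
    def _tables():
        def tbl(rows):
            return pd.DataFrame(rows, columns=["gene", "log2", "pvalue"])

        return {
            "lineA": tbl([("STOP1", -1.0, 1e-6), ("STOP2", -0.5, 1e-5),
                          ("GO1", 1.0, 1e-9), ("WEAK", -0.2, 1e-3),
                          ("BOUND", -0.3, 1e-4), ("PARTIAL", -1.0, 1e-8)]),
            "lineB": tbl([("STOP1", -2.0, 1e-7), ("STOP2", -0.4, 1e-6),
                          ("GO1", 2.0, 1e-9), ("WEAK", -0.1, 1e-2),
                          ("BOUND", -0.3, 1e-4), ("PARTIAL", np.nan, np.nan)]),
            "lineC": tbl([("STOP1", 0.5, 0.5), ("STOP2", 0.1, 0.9),
                          ("GO1", 1.5, 1e-3), ("WEAK", 0.0, 1.0),
                          ("BOUND", -0.2, 0.2), ("PARTIAL", -0.5, 1e-6)]),
        }

    def test_planted_stop_genes_recovered(self):
        gs = sf.build_stop_gene_set(self._tables(), held_out="lineC")
        assert gs.members == {"STOP1", "STOP2"}
        assert gs.role == "stop"

    def test_boundary_pvalue_excluded(self):
        # BOUND has p exactly 1e-4 in both other lines: strict inequality
        gs = sf.build_stop_gene_set(self._tables(), held_out="lineC")
        assert "BOUND" not in gs.members

    def test_gene_missing_in_one_line_excluded(self):
        # PARTIAL would qualify on values but is n/a in lineB
        gs = sf.build_stop_gene_set(self._tables(), held_out="lineC")
        assert "PARTIAL" not in gs.members

    def test_too_few_other_lines(self):
        t = self._tables()
        del t["lineA"]
        with pytest.raises(ValueError, match="2 non-held-out"):
            sf.build_stop_gene_set(t, held_out="lineC")
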