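"""Over-representation statistics: expectations, folds, tails, tables."""

import numpy as np
import pytest
from scipy.stats import hypergeom, poisson

import flightsel as fs
from flightsel.enrichment import round_display


class TestExpectedAndFold:
    @pytest.mark.parametrize(
        "k,n_bg,n,o,e_disp,fe_disp",
        [
            (34, 914, 38, 7, 1.4, 5.0),
            (50, 1231, 54, 8, 2.2, 3.6),
            (21, 1229, 21, 3, 0.4, 8.4),
        ],
    )
    def test_display_values(self, k, n_bg, n, o, e_disp, fe_disp):
        e = fs.expected_count(k, n_bg, n)
        assert round_display(e, 1) == e_disp
        assert round_display(fs.fold_enrichment(o, k, n_bg, n), 1) == fe_disp

    def test_rounded_expectation_would_fail(self):
        # fold enrichment must divide by the unrounded expectation:
        # 3 / round(0.359, 1) = 7.5, not the correct 8.4
        e = fs.expected_count(21, 1229, 21)
        assert round_display(3 / round_display(e, 1), 1) == 7.5
        assert round_display(fs.fold_enrichment(3, 21, 1229, 21), 1) == 8.4

    def test_zero_category(self):
        assert fs.expected_count(0, 914, 38) == 0.0
        assert fs.fold_enrichment(0, 0, 914, 38) == 0.0

    def test_observed_equals_expected(self):
        assert np.isclose(fs.fold_enrichment(2, 50, 1000, 40), 1.0)


class TestFisher:
    def test_oxphos_candidate_table(self):
        assert round(fs.fisher_one_tailed(1, 13, 954, 39, "over"), 2) == 0.42

    def test_wing_grouping_table(self):
        assert round(fs.fisher_one_tailed(1, 28, 954, 39, "over"), 2) == 0.69

    def test_zero_observed_over_is_one(self):
        assert fs.fisher_one_tailed(0, 14, 1285, 56, "over") == 1.0

    def test_tails_share_observed_table(self):
        over = fs.fisher_one_tailed(3, 20, 500, 30, "over")
        under = fs.fisher_one_tailed(3, 20, 500, 30, "under")
        assert over + under >= 1.0

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            fs.fisher_one_tailed(10, 5, 100, 20)


class TestEase:
    def test_singleton_scores_one(self):
        assert fs.ease_score(1, 20, 1000, 50) == 1.0

    def test_zero_observed_scores_one(self):
        assert fs.ease_score(0, 20, 1000, 50) == 1.0

    def test_never_smaller_than_fisher(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            n_bg = int(rng.integers(50, 500))
            k = int(rng.integers(1, n_bg // 3))
            n = int(rng.integers(1, n_bg // 3))
            o = int(rng.integers(0, min(k, n) + 1))
            assert fs.ease_score(o, k, n_bg, n) >= fs.fisher_one_tailed(o, k, n_bg, n) - 1e-12

    def test_matches_summation_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            n_bg = int(rng.integers(30, 200))
            k = int(rng.integers(1, n_bg // 2))
            n = int(rng.integers(1, n_bg // 2))
            o = int(rng.integers(1, min(k, n) + 1))
            # direct tail sum on the decremented observed cell
            expect = sum(
                hypergeom.pmf(x, n_bg, k, n) for x in range(o - 1, min(k, n) + 1)
            )
            assert abs(fs.ease_score(o, k, n_bg, n) - expect) < 1e-9


class TestBinomial:
    @pytest.mark.parametrize(
        "o,k,n_bg,n,printed",
        [
            (3, 11, 1209, 53, 0.013),
            (2, 9, 894, 35, 0.048),
            (1, 1, 1209, 53, 0.043),
        ],
    )
    def test_printed_values(self, o, k, n_bg, n, printed):
        assert round(fs.binomial_overrep(o, k, n_bg, n), 3) == printed

    def test_dominates_poisson_tail_for_rare_categories(self):
        # sanity bound: binomial tail close to its Poisson approximation
        for o, k, n_bg, n in [(2, 5, 2000, 50), (3, 8, 5000, 100)]:
            b = fs.binomial_overrep(o, k, n_bg, n)
            p = poisson.sf(o - 1, n * k / n_bg)
            assert abs(b - p) < 0.01


class TestEnrichTable:
    def make_annotations(self, planted_genes):
        genes = {f"g{i}": set() for i in range(100)}
        for i in range(20, 40):
            genes[f"g{i}"].add("catA")
        for g in planted_genes:
            genes[g].add("planted")
        for i in range(40, 50):
            genes[f"g{i}"].add("planted")
        return fs.AnnotationTable(gene_categories=genes)

    def test_planted_category_ranks_first(self):
        candidates = {f"g{i}" for i in range(10)}
        ann = self.make_annotations([f"g{i}" for i in range(8)])
        rows = fs.enrich_table(candidates, {f"g{i}" for i in range(100)}, ann)
        assert rows[0].category == "planted"
        assert rows[0].p < rows[-1].p or len(rows) == 1

    def test_candidates_equal_background(self):
        ann = self.make_annotations([])
        bg = {f"g{i}" for i in range(100)}
        rows = fs.enrich_table(bg, bg, ann)
        assert all(np.isclose(r.fold, 1.0) for r in rows)
        assert all(r.p == 1.0 for r in rows)

    def test_absent_category_has_p_one(self):
        ann = self.make_annotations([])
        candidates = {f"g{i}" for i in range(60, 70)}  # no catA/planted members
        rows = fs.enrich_table(candidates, {f"g{i}" for i in range(100)}, ann)
        for r in rows:
            if r.observed == 0:
                assert r.p == 1.0

    def test_counts_conserved(self):
        ann = self.make_annotations([f"g{i}" for i in range(5)])
        candidates = {f"g{i}" for i in range(10)}
        rows = fs.enrich_table(candidates, {f"g{i}" for i in range(100)}, ann)
        for r in rows:
            assert r.k == len(ann.genes_in(r.category))
            assert r.observed == len(ann.genes_in(r.category) & candidates)

    def test_candidate_outside_background_rejected(self):
        ann = self.make_annotations([])
        with pytest.raises(ValueError, match="outside"):
            fs.enrich_table({"zzz"}, {f"g{i}" for i in range(100)}, ann)
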