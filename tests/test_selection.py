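"""Selection tests: BH correction, LRT behaviour, direction symmetry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import flightsel as fs
from flightsel.model import BranchSiteOmega, CodonModelSpec
from flightsel.selection import lrt_pvalue

from .oracles import bh_step_up


class TestBH:
    def test_single_p(self):
        adj, sig = fs.bh_adjust([0.04], alpha=0.05)
        assert np.isclose(adj[0], 0.04) and sig[0]

    def test_all_ones(self):
        adj, sig = fs.bh_adjust([1.0] * 5)
        assert np.all(adj == 1.0) and not sig.any()

    def test_step_up_example(self):
        adj, sig = fs.bh_adjust([0.01, 0.02, 0.03, 0.8], alpha=0.05)
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.8])
        assert list(sig) == [True, True, True, False]

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_matches_hand_rolled_step_up(self, ps):
        adj, sig = fs.bh_adjust(ps)
        oadj, osig = bh_step_up(ps)
        assert np.allclose(adj, oadj, atol=1e-12)
        assert (sig == osig).all()

    def test_monotone_in_raw_p(self):
        rng = np.random.default_rng(0)
        ps = rng.uniform(size=20)
        _, sig = fs.bh_adjust(ps)
        lowered = ps.copy()
        lowered[3] = ps[3] / 10
        _, sig2 = fs.bh_adjust(lowered)
        # lowering one raw p never removes a flag elsewhere
        assert np.all(sig2 | ~sig)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fs.bh_adjust([0.5, 1.5])


class TestLRTPValue:
    def test_zero_statistic_gives_one(self):
        assert lrt_pvalue(0.0) == 1.0
        assert lrt_pvalue(-1e-9) == 1.0  # clamped

    def test_mixture_is_half_chi2(self):
        assert np.isclose(lrt_pvalue(3.84, null="mixture"), 0.5 * lrt_pvalue(3.84))


class TestBranchRates:
    def test_direction_symmetry(self, rates_tree, equal_freqs):
        model = CodonModelSpec(
            kappa=2.0, freqs=equal_freqs, omega=fs.BranchClassOmega((0.05, 0.09, 0.02))
        )
        aln = fs.simulate_codon_alignment(rates_tree, model, 400, seed=17)
        fwd = fs.branch_rates_test(aln, rates_tree, seed=0)
        swapped = rates_tree.merge_classes({1: 2, 2: 1})
        rev = fs.branch_rates_test(aln, swapped, seed=0)
        assert abs(fwd.lrt - rev.lrt) < 1e-4
        assert fwd.direction != rev.direction

    def test_malformed_classes_rejected(self, three_taxon_tree, equal_freqs):
        aln = fs.simulate_codon_alignment(
            three_taxon_tree,
            CodonModelSpec(kappa=2.0, freqs=equal_freqs, omega=fs.SingleOmega(0.1)),
            10, seed=0,
        )
        with pytest.raises(ValueError, match="classes"):
            fs.branch_rates_test(aln, three_taxon_tree)

    def test_recovery_with_direction(self, rates_tree_full, equal_freqs):
        model = CodonModelSpec(
            kappa=2.0, freqs=equal_freqs, omega=fs.BranchClassOmega((0.05, 0.15, 0.02))
        )
        aln = fs.simulate_codon_alignment(rates_tree_full, model, 800, seed=23)
        res = fs.branch_rates_test(aln, rates_tree_full, seed=0)
        assert res.direction == "flightless"
        assert res.omega_by_class["flightless"] > res.omega_by_class["flying"]
        assert res.p_raw < 0.05


class TestBranchSite:
    def test_requires_foreground(self, three_taxon_tree, equal_freqs):
        aln = fs.simulate_codon_alignment(
            three_taxon_tree,
            CodonModelSpec(kappa=2.0, freqs=equal_freqs, omega=fs.SingleOmega(0.1)),
            10, seed=0,
        )
        with pytest.raises(ValueError, match="foreground"):
            fs.branch_site_test(aln, three_taxon_tree)

    def test_power_exceeds_null_rate(self, panel_tree, equal_freqs):
        # episodic positive selection on the focal branch is detected more
        # often than in matched null simulations
        alt = CodonModelSpec(
            kappa=2.0, freqs=equal_freqs,
            omega=BranchSiteOmega(p0=0.7, p1=0.15, omega0=0.05, omega2=4.0),
        )
        null = CodonModelSpec(
            kappa=2.0, freqs=equal_freqs,
            omega=BranchSiteOmega(p0=0.7, p1=0.15, omega0=0.05, omega2=1.0),
        )
        hits = {}
        for name, model in (("alt", alt), ("null", null)):
            n = 0
            for s in range(8):
                aln = fs.simulate_codon_alignment(panel_tree, model, 300, seed=300 + s)
                r = fs.branch_site_test(aln, panel_tree, seed=s, n_restarts=1)
                n += r.p_raw < 0.05
            hits[name] = n
        assert hits["alt"] > hits["null"]

    def test_positive_call_requires_selection_signal(self, panel_tree, equal_freqs):
        null = CodonModelSpec(
            kappa=2.0, freqs=equal_freqs,
            omega=BranchSiteOmega(p0=0.7, p1=0.15, omega0=0.05, omega2=1.0),
        )
        aln = fs.simulate_codon_alignment(panel_tree, null, 200, seed=77)
        r = fs.branch_site_test(aln, panel_tree, seed=0, n_restarts=1)
        assert r.lnl_alt >= r.lnl_null - 1e-6
        if r.p_raw > 0.05:
            assert not r.positive_selection


class TestFamilyAnnotation:
    def test_family_bh_flags(self):
        results = [
            fs.GeneTestResult(
                gene=f"g{i}", kind="branch_rates", lnl_null=-10, lnl_alt=-9,
                df=1, p_raw=p,
                direction="flightless",
                omega_by_class={"flightless": 0.1, "flying": 0.02, "background": 0.05},
            )
            for i, p in enumerate([0.001, 0.2, 0.9])
        ]
        fs.annotate_family(results, alpha=0.05)
        assert results[0].significant and results[0].relaxed
        assert not results[1].significant and not results[1].relaxed
        assert all(r.p_bh >= r.p_raw for r in results)
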