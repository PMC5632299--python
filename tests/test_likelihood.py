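"""Pruning likelihood against independent oracles; fitting behaviour."""

import dendropy
import numpy as np
import pytest

import flightsel as fs
from flightsel.likelihood import PatternData, fit_model
from flightsel.model import BranchSiteOmega, CodonModelSpec, SingleOmega

from .oracles import brute_force_log_likelihood


def random_instance(seed, code):
    """Random small tree + model + alignment for oracle comparison."""
    rng = np.random.default_rng(seed)
    n_leaves = int(rng.integers(2, 5))
    names = [f"t{i}" for i in range(n_leaves)]
    frags = list(names)
    while len(frags) > 1:
        i, j = sorted(rng.choice(len(frags), 2, replace=False))
        b, a = frags.pop(j), frags.pop(i)
        la, lb = rng.uniform(0.02, 0.6, 2)
        frags.append(f"({a}:{la:.4f},{b}:{lb:.4f})")
    tree = fs.LabeledTree.from_newick(frags[0] + ";")
    # random branch classes so branch and branch-site structures are exercised
    classes = np.zeros(tree.n_nodes, dtype=np.int64)
    classes[1:] = rng.integers(0, 2, tree.n_nodes - 1)
    if not np.any(classes[1:] == 0):
        classes[1] = 0
    tree = tree.with_classes(classes)
    pi = rng.dirichlet(np.ones(code.n_states))
    kappa = float(rng.uniform(0.5, 8))
    kind = rng.integers(0, 3)
    if kind == 0:
        omega = SingleOmega(float(rng.uniform(0.02, 3)))
    elif kind == 1:
        omega = fs.BranchClassOmega((float(rng.uniform(0.02, 1)), float(rng.uniform(0.02, 3))))
    else:
        omega = BranchSiteOmega(
            p0=float(rng.uniform(0.3, 0.8)), p1=float(rng.uniform(0.05, 0.2)),
            omega0=float(rng.uniform(0.02, 0.9)), omega2=float(rng.uniform(1.0, 6)),
        )
    model = CodonModelSpec(kappa=kappa, freqs=pi, omega=omega, code=code)
    n_sites = int(rng.integers(1, 4))
    aln = fs.simulate_codon_alignment(tree, model, n_sites, seed=seed + 1)
    return aln, tree, model


class TestPruning:
    def test_single_taxon_is_log_frequencies(self, code, equal_freqs):
        aln = fs.CodonAlignment(taxa=["A"], codons=[["TTT", "GGG"]])
        tree = fs.LabeledTree.from_newick("A;")
        model = CodonModelSpec(kappa=2.0, freqs=equal_freqs, omega=SingleOmega(0.3))
        expect = sum(
            np.log(equal_freqs[code.index[c]]) for c in ("TTT", "GGG")
        )
        assert np.isclose(fs.log_likelihood(aln, tree, model), expect)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_enumeration(self, seed, code):
        aln, tree, model = random_instance(seed, code)
        pruned = fs.log_likelihood(aln, tree, model)
        brute = brute_force_log_likelihood(aln, tree, model)
        assert abs(pruned - brute) < 1e-8

    def test_degenerate_mixture_equals_single_class(self, three_taxon_tree, equal_freqs):
        # p0 = 1 collapses the branch-site mixture onto omega0
        aln = fs.simulate_codon_alignment(
            three_taxon_tree,
            CodonModelSpec(kappa=2.0, freqs=equal_freqs, omega=SingleOmega(0.2)),
            30,
            seed=4,
        )
        tree = three_taxon_tree.with_classes(
            np.array([0, 1, 0, 0, 0])[: three_taxon_tree.n_nodes]
        )
        mix = CodonModelSpec(
            kappa=2.0, freqs=equal_freqs,
            omega=BranchSiteOmega(p0=1.0 - 1e-12, p1=0.0, omega0=0.2, omega2=1.0),
        )
        single = CodonModelSpec(kappa=2.0, freqs=equal_freqs, omega=SingleOmega(0.2))
        assert np.isclose(
            fs.log_likelihood(aln, tree, mix), fs.log_likelihood(aln, tree, single), atol=1e-6
        )

    def test_root_position_invariance(self, equal_freqs):
        nwk = "((A:0.1,B:0.2):0.05,(C:0.3,D:0.15):0.07);"
        tree = fs.LabeledTree.from_newick(nwk)
        model = CodonModelSpec(kappa=2.0, freqs=equal_freqs, omega=SingleOmega(0.3))
        aln = fs.simulate_codon_alignment(tree, model, 40, seed=9)
        base = fs.log_likelihood(aln, tree, model)
        for target in ("A", "C"):
            dtree = dendropy.Tree.get(data=nwk, schema="newick")
            node = dtree.find_node_with_taxon_label(target).parent_node
            dtree.reroot_at_node(node, update_bipartitions=False)
            rerooted = fs.LabeledTree.from_dendropy(dtree)
            assert abs(fs.log_likelihood(aln, rerooted, model) - base) < 1e-8

    def test_taxa_mismatch_rejected(self, three_taxon_tree, equal_freqs):
        aln = fs.CodonAlignment(taxa=["A", "Z"], codons=[["TTT"], ["GGG"]])
        model = CodonModelSpec(kappa=2.0, freqs=equal_freqs, omega=SingleOmega(0.3))
        with pytest.raises(ValueError, match="Z"):
            fs.log_likelihood(aln, three_taxon_tree, model)


class TestFitting:
    def test_recovers_omega_on_long_gene(self, equal_freqs):
        tree = fs.LabeledTree.from_newick(
            "((A:0.25,B:0.25):0.1,(C:0.25,D:0.25):0.1);"
        )
        truth = CodonModelSpec(kappa=2.0, freqs=equal_freqs, omega=SingleOmega(0.2))
        aln = fs.simulate_codon_alignment(tree, truth, 2000, seed=21)
        res = fit_model(aln, tree, "M0", freqs=equal_freqs, n_restarts=1, seed=0)
        assert abs(res.model.omega.omega - 0.2) < 0.05
        assert abs(res.model.kappa - 2.0) < 0.5

    def test_null_never_beats_alternative(self, rates_tree, equal_freqs):
        model = CodonModelSpec(
            kappa=2.0, freqs=equal_freqs, omega=fs.BranchClassOmega((0.05, 0.05, 0.05))
        )
        aln = fs.simulate_codon_alignment(rates_tree, model, 200, seed=3)
        res = fs.branch_rates_test(aln, rates_tree, seed=0)
        assert res.lnl_alt >= res.lnl_null - 1e-6
        assert res.lrt >= 0

    def test_seeded_fits_are_deterministic(self, rates_tree, equal_freqs):
        model = CodonModelSpec(
            kappa=2.0, freqs=equal_freqs, omega=fs.BranchClassOmega((0.05, 0.08, 0.02))
        )
        aln = fs.simulate_codon_alignment(rates_tree, model, 300, seed=6)
        r1 = fit_model(aln, rates_tree, "branch", freqs=equal_freqs, seed=42, n_restarts=2)
        r2 = fit_model(aln, rates_tree, "branch", freqs=equal_freqs, seed=42, n_restarts=2)
        assert abs(r1.lnl - r2.lnl) < 1e-8
        assert r1.model.omega == r2.model.omega

    def test_added_parameter_never_decreases_lnl(self, rates_tree, equal_freqs):
        model = CodonModelSpec(
            kappa=2.0, freqs=equal_freqs, omega=fs.BranchClassOmega((0.05, 0.1, 0.02))
        )
        aln = fs.simulate_codon_alignment(rates_tree, model, 300, seed=8)
        m0 = fit_model(aln, rates_tree, "M0", freqs=equal_freqs, n_restarts=1, seed=0)
        tree2 = rates_tree.merge_classes({2: 1})
        b2 = fit_model(
            aln, tree2, "branch", freqs=equal_freqs, n_restarts=1, seed=0,
            init={"omega": m0.omega_by_class[0], "kappa": m0.model.kappa},
        )
        b3 = fit_model(
            aln, rates_tree, "branch", freqs=equal_freqs, n_restarts=1, seed=0,
            init={f"omega_{k}": w for k, w in b2.omega_by_class.items()} | {"kappa": b2.model.kappa},
        )
        assert b2.lnl >= m0.lnl - 1e-6
        assert b3.lnl >= b2.lnl - 1e-6
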