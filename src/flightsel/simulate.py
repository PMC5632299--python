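"""Synthetic data: codon alignments evolved under selection regimes,
flight-loss study scenarios, and annotation tables with planted enrichment.

Simulation is generative under exactly the model the likelihood engine
evaluates: per site, a root codon is drawn from the equilibrium
frequencies and each branch applies its transition matrix P(t) for the
branch's class-specific omega (for branch-site models, a site class is
drawn once per site and applies across the whole tree, with the
foreground omega only on foreground branches). This closes the
simulate-fit loop exactly, so parameter-recovery tests probe the
inference machinery rather than model mismatch.

Everything is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import CodonAlignment
from .annotations import AnnotationTable
from .genetics import GeneticCode, get_code
from .model import (
    BranchClassOmega,
    BranchSiteOmega,
    CodonModelSpec,
    RateMatrix,
    SingleOmega,
    class_rate_multipliers,
)
from .tree import LabeledTree

#: study-condition defaults: transition/transversion ratio and background
#: purifying dN/dS for nuclear-like genes; mitochondrial-like scenarios
#: use the lower flying/flightless pair.
DEFAULT_KAPPA = 2.0
DEFAULT_OMEGA_BACKGROUND = 0.05
DEFAULT_MITO_OMEGA = {"flying": 0.02, "flightless": 0.03}
DEFAULT_LENGTH_RANGE = (0.02, 0.2)


# --------------------------------------------------------------------------
# sequence simulation


def _sample_rows(p: np.ndarray, parent_states: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw one categorical sample per row of ``p[parent_states]``."""
    cum = np.cumsum(p, axis=1)
    cum[:, -1] = 1.0
    u = rng.random(parent_states.size)
    child = (cum[parent_states] < u[:, None]).sum(axis=1)
    return np.minimum(child, p.shape[1] - 1)


def simulate_codon_alignment(
    tree: LabeledTree,
    model: CodonModelSpec,
    n_sites: int,
    seed: int = 0,
) -> CodonAlignment:
    """Evolve an in-frame codon alignment along a labeled tree.

    Root codons are drawn from the model's equilibrium frequencies; each
    branch applies P(t) under the omega of its branch class (and, for
    branch-site models, of the site's class).
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    code = model.code
    pi = np.asarray(model.freqs, float)
    present = sorted(set(int(c) for c in tree.classes[1:]))
    om = model.omega
    if isinstance(om, SingleOmega):
        site_class = np.zeros(n_sites, dtype=int)
        omega_table = [{c: om.omega for c in present}]
    elif isinstance(om, BranchClassOmega):
        for c in present:
            if c >= len(om.omega_by_class):
                raise ValueError(f"no omega for branch class {c} on tree")
        site_class = np.zeros(n_sites, dtype=int)
        omega_table = [{c: om.omega_by_class[c] for c in present}]
    elif isinstance(om, BranchSiteOmega):
        probs = om.proportions
        site_class = rng.choice(4, size=n_sites, p=probs / probs.sum())
        omega_table = [
            {c: (bg if c == 0 else fg) for c in present} for bg, fg in om.class_omegas()
        ]
    else:
        raise TypeError(f"unknown omega structure {type(om).__name__}")

    if isinstance(om, BranchSiteOmega):
        class_list = list(zip(om.proportions, omega_table))
    else:
        class_list = [(1.0, omega_table[0])]
    multipliers = class_rate_multipliers(class_list, model.kappa, pi, code)

    matrices: dict[float, RateMatrix] = {}
    states = np.empty((tree.n_nodes, n_sites), dtype=np.int64)
    cum_pi = np.cumsum(pi)
    cum_pi[-1] = 1.0
    states[0] = np.searchsorted(cum_pi, rng.random(n_sites), side="right")
    for node in range(1, tree.n_nodes):
        t = float(tree.lengths[node])
        cls = int(tree.classes[node])
        parent = states[tree.parent[node]]
        out = np.empty(n_sites, dtype=np.int64)
        for sc in np.unique(site_class):
            w = omega_table[sc][cls]
            rm = matrices.get(w)
            if rm is None:
                rm = RateMatrix.build(model.kappa, w, pi, code)
                matrices[w] = rm
            idx = np.nonzero(site_class == sc)[0]
            t_eff = t * multipliers[sc][cls]
            if t_eff == 0:
                out[idx] = parent[idx]
            else:
                out[idx] = _sample_rows(rm.probs(t_eff), parent[idx], rng)
        states[node] = out

    leaves = tree.leaves
    taxa = [tree.names[i] for i in leaves]
    codons = [[code.codons[s] for s in states[i]] for i in leaves]
    return CodonAlignment(taxa=taxa, codons=codons, code=code)


# --------------------------------------------------------------------------
# study scenarios


@dataclass
class PanelSpec:
    """One focal lineage: a sub-tree with a single class-1 focal branch."""

    lineage: str
    flight_state: str
    tree: LabeledTree


@dataclass
class SimulationScenario:
    """A full flight-loss study design: panels, a rates tree, model defaults."""

    panels: list[PanelSpec]
    rates_tree: LabeledTree
    kappa: float = DEFAULT_KAPPA
    omega_background: float = DEFAULT_OMEGA_BACKGROUND
    genes: int = 50
    sites: int = 300
    seed: int = 0
    code: GeneticCode = field(default_factory=get_code)

    @property
    def flightless_panels(self) -> list[PanelSpec]:
        return [p for p in self.panels if p.flight_state != "flying"]

    @property
    def flying_panels(self) -> list[PanelSpec]:
        return [p for p in self.panels if p.flight_state == "flying"]


def _random_newick(names: list[str], rng: np.random.Generator, length_range) -> str:
    """Random binary topology by sequential joins; lengths uniform in range."""
    lo, hi = length_range
    frags = list(names)
    while len(frags) > 1:
        i, j = sorted(rng.choice(len(frags), size=2, replace=False))
        a = frags.pop(j)
        b = frags.pop(i)
        la, lb = rng.uniform(lo, hi, size=2)
        frags.append(f"({a}:{la:.6f},{b}:{lb:.6f})")
    return frags[0] + ";"


def _random_subtree(
    n_taxa: int, prefix: str, rng: np.random.Generator, length_range
) -> LabeledTree:
    names = [f"{prefix}_t{i}" for i in range(n_taxa)]
    return LabeledTree.from_newick(_random_newick(names, rng, length_range))


def _pick_focal_branch(tree: LabeledTree, rng: np.random.Generator) -> int:
    """An internal stem branch subtending a small clade (2-5 leaves)."""
    candidates = []
    for node in range(1, tree.n_nodes):
        if tree.children[node]:
            n_below = sum(1 for i in tree.subtree_nodes(node) if not tree.children[i])
            if 2 <= n_below <= 5:
                candidates.append(node)
    if not candidates:  # tiny trees: fall back to any non-root branch
        candidates = list(range(1, tree.n_nodes))
    return int(rng.choice(candidates))


def make_flight_scenario(
    n_flightless: int = 11,
    n_flying: int = 9,
    taxa_per_subtree: tuple[int, int] | int = (14, 19),
    seed: int = 0,
    *,
    n_female_flightless: int = 3,
    length_range: tuple[float, float] = DEFAULT_LENGTH_RANGE,
    rates_clades: int = 4,
    clade_size: int = 3,
    background_taxa: int = 8,
    genes: int = 50,
    sites: int = 300,
) -> SimulationScenario:
    """Build a synthetic flight-loss study design.

    Default panel counts mirror the study conditions: 11 flightless
    lineages (3 of them female-only flight loss) compared against 9
    flight-capable lineages, each tested on its own 14-19 taxon
    sub-tree with one focal branch. A separate rates tree carries
    ``rates_clades`` flightless clades (class 1) and as many matched
    flying clades (class 2) over background taxa, for the pooled-branch
    relaxed-selection comparison.
    """
    if n_flightless < 1 or n_flying < 1:
        raise ValueError("panel counts must be >= 1")
    lo, hi = (taxa_per_subtree, taxa_per_subtree) if isinstance(taxa_per_subtree, int) else taxa_per_subtree
    if not (4 <= lo <= hi <= 30):
        raise ValueError("taxa_per_subtree must lie within [4, 30]")
    rng = np.random.default_rng(seed)
    panels: list[PanelSpec] = []
    states = (
        ["female_flightless"] * min(n_female_flightless, n_flightless)
        + ["flightless"] * max(0, n_flightless - n_female_flightless)
        + ["flying"] * n_flying
    )
    for idx, state in enumerate(states):
        n_taxa = int(rng.integers(lo, hi + 1))
        label = f"{'FL' if state != 'flying' else 'FY'}{idx:02d}"
        tree = _random_subtree(n_taxa, label, rng, length_range)
        classes = np.zeros(tree.n_nodes, dtype=np.int64)
        classes[_pick_focal_branch(tree, rng)] = 1
        panels.append(PanelSpec(lineage=label, flight_state=state, tree=tree.with_classes(classes)))

    # rates tree: alternating flightless/flying clades over a backbone
    frags = []
    for c in range(rates_clades):
        for state, cls in (("red", 1), ("blue", 2)):
            names = [f"{state}{c}_t{i}" for i in range(clade_size)]
            sub = _random_newick(names, rng, length_range)[:-1]
            stem = rng.uniform(*length_range)
            frags.append(f"{sub}#{cls}:{stem:.6f}")
    frags += [f"bg_t{i}" for i in range(background_taxa)]
    rates_tree = LabeledTree.from_newick(_assemble_backbone(frags, rng, length_range))
    # propagate clade classes to internal branches of each labeled clade
    classes = rates_tree.classes.copy()
    for node in range(1, rates_tree.n_nodes):
        if classes[node] in (1, 2):
            for i in rates_tree.subtree_nodes(node):
                classes[i] = classes[node]
    rates_tree = rates_tree.with_classes(classes)
    return SimulationScenario(
        panels=panels, rates_tree=rates_tree, seed=seed, genes=genes, sites=sites
    )


def _assemble_backbone(frags: list[str], rng: np.random.Generator, length_range) -> str:
    lo, hi = length_range
    frags = list(frags)
    while len(frags) > 1:
        i, j = sorted(rng.choice(len(frags), size=2, replace=False))
        a = frags.pop(j)
        b = frags.pop(i)
        la, lb = rng.uniform(lo, hi, size=2)
        # every fragment needs a top-level length unless it already carries one
        if ":" not in a.rsplit(")", 1)[-1]:
            a = f"{a}:{la:.6f}"
        if ":" not in b.rsplit(")", 1)[-1]:
            b = f"{b}:{lb:.6f}"
        frags.append(f"({a},{b})")
    return frags[0] + ";"


# --------------------------------------------------------------------------
# annotation simulation


def simulate_annotations(
    background_genes: list[str],
    category_sizes: dict[str, int],
    planted: set[str] | None = None,
    enrichment_factor: float = 1.0,
    candidate_set: set[str] | None = None,
    seed: int = 0,
) -> AnnotationTable:
    """Annotation table with optional planted candidate enrichment.

    Non-planted categories sample their members uniformly from the
    background; planted categories over-sample candidate genes by
    ``enrichment_factor``. Category sizes in the output match
    ``category_sizes`` exactly.
    """
    planted = planted or set()
    candidate_set = candidate_set or set()
    if enrichment_factor < 1:
        raise ValueError("enrichment_factor must be >= 1")
    unknown = planted - set(category_sizes)
    if unknown:
        raise ValueError(f"planted categories not in size spec: {sorted(unknown)}")
    genes = list(background_genes)
    n = len(genes)
    rng = np.random.default_rng(seed)
    is_candidate = np.array([g in candidate_set for g in genes], dtype=float)
    table: dict[str, set[str]] = {g: set() for g in genes}
    for category in sorted(category_sizes):
        size = category_sizes[category]
        if size > n:
            raise ValueError(f"category {category!r} size {size} exceeds {n} genes")
        if category in planted and enrichment_factor > 1:
            weights = 1.0 + (enrichment_factor - 1.0) * is_candidate
            probs = weights / weights.sum()
            expected_hits = probs[is_candidate > 0].sum() * size
            if expected_hits > is_candidate.sum():
                raise ValueError(
                    f"enrichment factor {enrichment_factor} infeasible for "
                    f"category {category!r} of size {size}"
                )
            members = rng.choice(n, size=size, replace=False, p=probs)
        else:
            members = rng.choice(n, size=size, replace=False)
        for m in members:
            table[genes[int(m)]].add(category)
    return AnnotationTable(gene_categories=table)


# --------------------------------------------------------------------------
# gene-level scenario simulation


def simulate_rates_genes(
    scenario: SimulationScenario,
    n_relaxed: int = 5,
    n_neutral: int = 45,
    omega_flightless: float = 0.1,
    omega_flying: float = 0.02,
    freqs: np.ndarray | str = "equal",
    seed: int | None = None,
) -> list[tuple[str, CodonAlignment, bool]]:
    """Per-gene alignments on the scenario's rates tree.

    ``n_relaxed`` genes evolve with elevated (but still purifying)
    omega on flightless branches; the remaining genes have no
    flightless/flying difference. Returns (gene id, alignment,
    is_planted_relaxed) triples.
    """
    seed = scenario.seed if seed is None else seed
    code = scenario.code
    pi = np.full(code.n_states, 1.0 / code.n_states) if freqs == "equal" else np.asarray(freqs)
    out = []
    for g in range(n_relaxed + n_neutral):
        relaxed = g < n_relaxed
        if relaxed:
            omega = BranchClassOmega(
                (scenario.omega_background, omega_flightless, omega_flying)
            )
        else:
            omega = BranchClassOmega(
                (scenario.omega_background, scenario.omega_background, scenario.omega_background)
            )
        model = CodonModelSpec(kappa=scenario.kappa, freqs=pi, omega=omega, code=code)
        aln = simulate_codon_alignment(
            scenario.rates_tree, model, scenario.sites, seed=seed + 1000 + g
        )
        out.append((f"gene{g:04d}", aln, relaxed))
    return out
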