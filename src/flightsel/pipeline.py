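"""End-to-end orchestration: scenario simulation to result tables.

``cmd_simulate`` writes a synthetic flight-loss study to disk in the
standard formats (FASTA alignments, Newick trees with ``#k`` class
labels, trait and annotation TSVs, a JSON manifest of seeds), and
``cmd_run`` executes the selection tests, comparative filters, and
enrichment statistics over it, mirroring the four analyses of a
flight gain/loss study. Per-gene failures are logged and skipped; all
outputs are sorted by gene id and fully determined by the config seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .alignment import read_codon_alignment, write_codon_alignment
from .annotations import AnnotationTable
from .comparative import direction_sign_test
from .enrichment import enrich_table
from .selection import annotate_family, branch_rates_test
from .simulate import make_flight_scenario, simulate_annotations, simulate_rates_genes
from .tables import write_results_table
from .tree import LabeledTree

log = logging.getLogger("flightsel")


@dataclass
class RunConfig:
    """Configuration for a pipeline run (defaults follow the study design)."""

    out_dir: str = "results/run"
    data_dir: str | None = None
    alpha: float = 0.05
    tally_threshold: int = 3
    enrichment_method: str = "fisher"
    lrt_null: str = "chi2"
    seed: int = 0
    # scenario parameters (used by cmd_simulate)
    n_flightless: int = 11
    n_flying: int = 9
    taxa_per_subtree: tuple[int, int] = (14, 19)
    genes: int = 50
    sites: int = 300
    n_relaxed: int = 5
    rates_clades: int = 4
    clade_size: int = 3
    background_taxa: int = 8
    planted_category: str = "planted_cat"
    category_sizes: dict = field(default_factory=lambda: {"planted_cat": 30, **{f"cat{i:02d}": 30 for i in range(9)}})
    enrichment_factor: float = 5.0
    tests: tuple[str, ...] = ("rates", "tally", "sign", "enrich")

    def validate(self) -> "RunConfig":
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.tally_threshold < 1:
            raise ValueError("tally threshold must be >= 1")
        if self.enrichment_method not in ("fisher", "ease", "binomial"):
            raise ValueError(f"unknown enrichment method {self.enrichment_method!r}")
        if self.data_dir is not None and not Path(self.data_dir).exists():
            raise ValueError(f"data directory {self.data_dir} does not exist")
        return self

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def cmd_simulate(config: RunConfig) -> Path:
    """Write a synthetic scenario to ``config.out_dir``; returns that path.

    Layout: ``genes/<gene>.fasta`` (rates-tree alignments),
    ``rates_tree3.nwk`` / ``rates_tree2.nwk``, per-panel trees under
    ``panels/``, ``annotations.tsv``, and ``manifest.json`` recording
    every derived seed and the planted truth.
    """
    config.validate()
    out = Path(config.out_dir)
    (out / "genes").mkdir(parents=True, exist_ok=True)
    (out / "panels").mkdir(exist_ok=True)
    scenario = make_flight_scenario(
        n_flightless=config.n_flightless,
        n_flying=config.n_flying,
        taxa_per_subtree=config.taxa_per_subtree,
        seed=config.seed,
        rates_clades=config.rates_clades,
        clade_size=config.clade_size,
        background_taxa=config.background_taxa,
        genes=config.genes,
        sites=config.sites,
    )
    n_neutral = config.genes - config.n_relaxed
    triples = simulate_rates_genes(
        scenario, n_relaxed=config.n_relaxed, n_neutral=n_neutral, seed=config.seed
    )
    gene_seeds = {}
    planted_genes = []
    for i, (gene, aln, relaxed) in enumerate(triples):
        write_codon_alignment(aln, out / "genes" / f"{gene}.fasta")
        gene_seeds[gene] = config.seed + 1000 + i
        if relaxed:
            planted_genes.append(gene)
    (out / "rates_tree3.nwk").write_text(scenario.rates_tree.to_newick() + "\n")
    tree2 = scenario.rates_tree.merge_classes({2: 1})
    (out / "rates_tree2.nwk").write_text(tree2.to_newick() + "\n")
    for panel in scenario.panels:
        (out / "panels" / f"{panel.lineage}_{panel.flight_state}.nwk").write_text(
            panel.tree.to_newick() + "\n"
        )
    genes = sorted(gene_seeds)
    annotations = simulate_annotations(
        genes,
        config.category_sizes,
        planted={config.planted_category},
        enrichment_factor=config.enrichment_factor,
        candidate_set=set(planted_genes),
        seed=config.seed + 7,
    )
    annotations.write(out / "annotations.tsv")
    manifest = {
        "seed": config.seed,
        "config_hash": config.hash(),
        "gene_seeds": gene_seeds,
        "planted_relaxed_genes": planted_genes,
        "planted_category": config.planted_category,
        "panels": [
            {"lineage": p.lineage, "flight_state": p.flight_state, "n_taxa": len(p.tree.leaves)}
            for p in scenario.panels
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out


def cmd_run(config: RunConfig) -> dict:
    """Run the relaxed-selection stage and enrichment over a scenario directory.

    Reads ``config.data_dir`` (as written by ``cmd_simulate`` or laid
    out the same way for real data), fits the 3-rate vs 2-rate branch
    models per gene, applies BH across genes, reports direction sign
    tests and the enrichment table of the BH-significant
    higher-in-flightless genes, and writes all tables under
    ``config.out_dir``. Returns a summary dict with stage counts.
    """
    config.validate()
    if config.data_dir is None:
        raise ValueError("cmd_run requires data_dir")
    data = Path(config.data_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gene_files = sorted((data / "genes").glob("*.fasta")) if (data / "genes").exists() else []
    if not gene_files:
        raise ValueError(f"no genes found under {data}")
    tree3 = LabeledTree.from_newick(data / "rates_tree3.nwk")
    results = []
    failures = 0
    for path in gene_files:
        gene = path.stem
        try:
            aln = read_codon_alignment(path)
            res = branch_rates_test(aln, tree3, gene=gene, seed=config.seed)
            results.append(res)
            log.info(
                "gene %s lnL0=%.3f lnL1=%.3f p=%.4g", gene, res.lnl_null, res.lnl_alt, res.p_raw
            )
        except Exception:  # per-gene failures are logged, not fatal
            log.exception("gene %s failed", gene)
            failures += 1
    if not results:
        raise RuntimeError("all genes failed")
    annotate_family(results, alpha=config.alpha)
    results.sort(key=lambda r: r.gene)
    write_results_table(results, out / "branch_rates_tests.tsv")
    candidates = {r.gene for r in results if r.relaxed}
    background = {r.gene for r in results}
    sign = direction_sign_test([r.direction for r in results if r.direction])
    summary = {
        "config_hash": config.hash(),
        "tested": len(results),
        "converged": sum(r.converged for r in results),
        "significant": sum(r.significant for r in results),
        "relaxed_candidates": sorted(candidates),
        "failures": failures,
        "sign_test": sign,
    }
    ann_path = data / "annotations.tsv"
    if ann_path.exists() and candidates:
        annotations = AnnotationTable.read(ann_path)
        rows = enrich_table(candidates, background, annotations, method=config.enrichment_method)
        write_results_table(rows, out / "enrichment.tsv")
        summary["top_category"] = rows[0].category if rows else None
    (out / "run_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    log.info(
        "%d of %d genes significant after BH; %d relaxed-selection candidates",
        summary["significant"], summary["tested"], len(candidates),
    )
    return summary
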