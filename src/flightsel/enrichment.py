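"""Over-representation statistics for candidate gene sets.

Given a background of N genes, n candidates, K background genes in a
category and O candidates observed in it, the expected count is
E = (K/N) n and the fold enrichment O/E (computed on the unrounded E;
display values are rounded to one decimal). One-tailed p-values come
from the hypergeometric tail (Fisher's exact test), its EASE-penalised
variant (the observed-in-category cell reduced by one), or the binomial
tail with per-trial rate K/N. Raw p-values are reported without an
extra FDR layer: the gene-level tests feeding the candidate list are
already corrected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import binom, hypergeom

from .annotations import AnnotationTable


def _check_counts(o: int, k: int, n_bg: int, n_cand: int) -> None:
    if n_bg <= 0:
        raise ValueError("background size must be positive")
    if not (0 <= k <= n_bg and 0 <= n_cand <= n_bg):
        raise ValueError("inconsistent category/candidate sizes")
    if not (0 <= o <= min(k, n_cand)):
        raise ValueError(f"observed count {o} outside [0, min(K={k}, n={n_cand})]")


def round_display(x: float, decimals: int = 1) -> float:
    """Round half away from zero (table display convention)."""
    factor = 10**decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def expected_count(k: int, n_bg: int, n_cand: int) -> float:
    """Expected candidates in a category: (K / N) * n, full precision."""
    if n_bg <= 0:
        raise ValueError("background size must be positive")
    return k * n_cand / n_bg


def fold_enrichment(o: int, k: int, n_bg: int, n_cand: int) -> float:
    """Observed over expected count, using the unrounded expectation."""
    e = expected_count(k, n_bg, n_cand)
    if e == 0:
        if o > 0:
            return math.inf
        return 0.0
    return o / e


def fisher_one_tailed(
    o: int, k: int, n_bg: int, n_cand: int, direction: str = "over"
) -> float:
    """One-tailed Fisher's exact test on the candidate x category table.

    Over-representation: P(X >= O); under-representation: P(X <= O),
    X ~ Hypergeometric(N, K, n). Tails include the observed table.
    """
    _check_counts(o, k, n_bg, n_cand)
    if direction == "over":
        return float(hypergeom.sf(o - 1, n_bg, k, n_cand))
    if direction == "under":
        return float(hypergeom.cdf(o, n_bg, k, n_cand))
    raise ValueError(f"direction must be 'over' or 'under', got {direction!r}")


def ease_score(o: int, k: int, n_bg: int, n_cand: int) -> float:
    """EASE-penalised over-representation p-value.

    The observed-in-category cell is reduced by one before taking the
    hypergeometric upper tail (margins unchanged): p = P(X >= O - 1).
    A singleton hit (O = 1) therefore scores 1 by convention, and the
    EASE p is never smaller than the plain Fisher p.
    """
    _check_counts(o, k, n_bg, n_cand)
    if o == 0:
        return 1.0
    return float(hypergeom.sf(o - 2, n_bg, k, n_cand))


def binomial_overrep(o: int, k: int, n_bg: int, n_cand: int) -> float:
    """Binomial over-representation tail: P(X >= O), X ~ Bin(n, K/N)."""
    _check_counts(o, k, n_bg, n_cand)
    return float(binom.sf(o - 1, n_cand, k / n_bg))


_METHODS = {
    "fisher": fisher_one_tailed,
    "ease": ease_score,
    "binomial": binomial_overrep,
}


@dataclass
class EnrichmentRow:
    """One category's over-representation summary (a table row)."""

    category: str
    name: str
    k: int  # genes in category among background
    n_bg: int  # background size
    n_cand: int  # candidate size
    observed: int
    method: str = "fisher"

    def __post_init__(self) -> None:
        _check_counts(self.observed, self.k, self.n_bg, self.n_cand)

    @property
    def expected(self) -> float:
        return expected_count(self.k, self.n_bg, self.n_cand)

    @property
    def fold(self) -> float:
        return fold_enrichment(self.observed, self.k, self.n_bg, self.n_cand)

    @property
    def expected_display(self) -> float:
        return round_display(self.expected, 2 if self.expected < 0.05 else 1)

    @property
    def fold_display(self) -> float:
        return round_display(self.fold, 1)

    @property
    def p(self) -> float:
        return _METHODS[self.method](self.observed, self.k, self.n_bg, self.n_cand)


def enrich_table(
    candidates: set[str],
    background: set[str],
    annotations: AnnotationTable,
    method: str = "fisher",
) -> list[EnrichmentRow]:
    """Per-category over-representation rows for a candidate gene set.

    Categories are those with at least one annotated background gene;
    rows are sorted by ascending p then descending fold. Raw p-values
    only (no additional FDR correction).
    """
    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}")
    stray = candidates - background
    if stray:
        raise ValueError(f"candidates outside background: {sorted(stray)}")
    n_bg = len(background)
    n_cand = len(candidates)
    rows = []
    for category in sorted(annotations.categories):
        members = annotations.genes_in(category) & background
        k = len(members)
        if k == 0:
            continue
        o = len(members & candidates)
        rows.append(
            EnrichmentRow(
                category=category,
                name=annotations.display_name(category),
                k=k, n_bg=n_bg, n_cand=n_cand, observed=o, method=method,
            )
        )
    rows.sort(key=lambda r: (r.p, -r.fold, r.category))
    return rows


def grouped_term_test(
    candidates: set[str],
    background: set[str],
    group_genes: set[str],
    direction: str = "over",
) -> dict:
    """Fisher test for a user-defined union of related terms (e.g. wing-related).

    Returns the 2x2 ingredients and the one-tailed p in the requested
    direction — the same statistic as any single category, applied to a
    grouped gene list.
    """
    members = group_genes & background
    o = len(members & candidates)
    k = len(members)
    p = fisher_one_tailed(o, k, len(background), len(candidates), direction)
    return {
        "observed": o, "k": k, "n_bg": len(background), "n_cand": len(candidates),
        "pct_candidates": 100.0 * o / len(candidates) if candidates else 0.0,
        "pct_noncandidates": 100.0 * (k - o) / (len(background) - len(candidates))
        if len(background) > len(candidates) else 0.0,
        "p": p, "direction": direction,
    }
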