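"""TSV writers/readers for gene-test and enrichment result tables."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .enrichment import EnrichmentRow, round_display
from .selection import GeneTestResult

GENE_TEST_COLUMNS = [
    "gene", "kind", "lnl_null", "lnl_alt", "lrt", "df", "p_raw", "p_bh",
    "significant", "direction", "omegas",
]
ENRICHMENT_COLUMNS = [
    "category", "name", "K", "N", "n", "O", "E", "E_display", "FE", "FE_display",
    "p", "method",
]


def gene_results_frame(rows: list[GeneTestResult]) -> pd.DataFrame:
    records = []
    for r in rows:
        records.append(
            {
                "gene": r.gene,
                "kind": r.kind,
                "lnl_null": r.lnl_null,
                "lnl_alt": r.lnl_alt,
                "lrt": r.lrt,
                "df": r.df,
                "p_raw": r.p_raw,
                "p_bh": r.p_bh,
                "significant": r.significant,
                "direction": r.direction or "",
                "omegas": ";".join(
                    f"{k}={v:.6g}" for k, v in sorted(r.omega_by_class.items()) if v is not None
                ),
            }
        )
    return pd.DataFrame.from_records(records, columns=GENE_TEST_COLUMNS)


def enrichment_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    records = []
    for r in rows:
        records.append(
            {
                "category": r.category,
                "name": r.name,
                "K": r.k,
                "N": r.n_bg,
                "n": r.n_cand,
                "O": r.observed,
                "E": r.expected,
                "E_display": r.expected_display,
                "FE": r.fold,
                "FE_display": round_display(r.fold, 1),
                "p": r.p,
                "method": r.method,
            }
        )
    return pd.DataFrame.from_records(records, columns=ENRICHMENT_COLUMNS)


def write_results_table(rows: list, path: str | Path) -> pd.DataFrame:
    """Write gene-test or enrichment rows as TSV with a fixed column order.

    Floats are printed with six significant digits; enrichment tables
    also carry display columns rounded as in published tables (one
    decimal for expected counts and fold enrichments). An empty row
    list yields a header-only gene-test table.
    """
    if rows and isinstance(rows[0], EnrichmentRow):
        frame = enrichment_frame(rows)
    else:
        frame = gene_results_frame(rows)
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return frame


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
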