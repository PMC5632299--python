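"""Gene-to-category annotation tables (flat GO-style term assignments)."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class AnnotationTable:
    """Maps genes to sets of functional category identifiers.

    The on-disk form is a two-column TSV: ``gene<TAB>cat1;cat2;...``.
    A gene may be listed with an empty category field, meaning it is
    explicitly unannotated but still part of the universe.
    """

    gene_categories: dict[str, set[str]]
    category_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, cats in self.gene_categories.items():
            if not gene:
                raise ValueError("empty gene identifier")
            if not isinstance(cats, set):
                self.gene_categories[gene] = set(cats)

    @property
    def genes(self) -> set[str]:
        return set(self.gene_categories)

    @property
    def categories(self) -> set[str]:
        out: set[str] = set()
        for cats in self.gene_categories.values():
            out |= cats
        return out

    def genes_in(self, category: str) -> set[str]:
        return {g for g, cats in self.gene_categories.items() if category in cats}

    def display_name(self, category: str) -> str:
        return self.category_names.get(category, category)

    @classmethod
    def read(cls, path: str | Path) -> "AnnotationTable":
        gene_categories: dict[str, set[str]] = {}
        for line in Path(path).read_text().splitlines():
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            gene = parts[0].strip()
            cats = parts[1].strip() if len(parts) > 1 else ""
            catset = {c.strip() for c in cats.split(";") if c.strip()}
            if gene in gene_categories:
                raise ValueError(f"duplicate gene entry {gene!r}")
            gene_categories[gene] = catset
        return cls(gene_categories=gene_categories)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for gene in sorted(self.gene_categories):
                fh.write(gene + "\t" + ";".join(sorted(self.gene_categories[gene])) + "\n")
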