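"""In-frame codon alignments and their readers/writers.

Alignments are protein-coding nucleotide matrices indexed by codon column.
FASTA and relaxed sequential PHYLIP are accepted; sequences must be equal
length, a multiple of three, and free of unambiguous internal stop codons
under the active genetic code.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .genetics import GeneticCode, codon_state, get_code


@dataclass
class CodonAlignment:
    """An in-frame nucleotide alignment over codon sites.

    ``codons[i][s]`` is the 3-letter codon of taxon ``i`` at codon site
    ``s``; gaps/N/IUPAC letters are preserved verbatim.
    """

    taxa: list[str]
    codons: list[list[str]]
    code: GeneticCode = field(default_factory=get_code)

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.codons):
            raise ValueError("taxa/sequence count mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise ValueError(f"duplicate taxa: {', '.join(dupes)}")
        for t in self.taxa:
            if not t or re.search(r"\s", t):
                raise ValueError(f"invalid taxon name {t!r}")
        lengths = {len(row) for row in self.codons}
        if len(lengths) > 1:
            raise ValueError("ragged alignment: unequal sequence lengths")
        for taxon, row in zip(self.taxa, self.codons):
            for s, codon in enumerate(row):
                if len(codon) != 3:
                    raise ValueError(f"{taxon}: codon of length {len(codon)} at site {s}")
                try:
                    codon_state(codon, self.code)
                except ValueError:
                    raise ValueError(
                        f"internal stop codon {codon} in taxon {taxon!r} at codon site {s}"
                    ) from None

    @property
    def sites(self) -> int:
        return len(self.codons[0]) if self.codons else 0

    def sequence(self, taxon: str) -> str:
        return "".join(self.codons[self.taxa.index(taxon)])

    def encode(self) -> np.ndarray:
        """Integer state matrix (n_taxa, sites); -1 marks missing/ambiguous codons."""
        out = np.empty((len(self.taxa), self.sites), dtype=np.int32)
        for i, row in enumerate(self.codons):
            out[i] = [codon_state(c, self.code) for c in row]
        return out

    def site_patterns(self) -> tuple[np.ndarray, np.ndarray]:
        """Distinct site columns and their multiplicities."""
        states = self.encode()
        patterns, counts = np.unique(states, axis=1, return_counts=True)
        return patterns, counts


def _split_codons(name: str, seq: str) -> list[str]:
    seq = seq.upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise ValueError(f"{name}: length {len(seq)} not multiple of 3")
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def _parse_relaxed_phylip(text: str) -> list[tuple[str, str]]:
    tokens = text.split()
    if len(tokens) < 2:
        raise ValueError("not a PHYLIP file: missing header")
    try:
        ntax, nchar = int(tokens[0]), int(tokens[1])
    except ValueError as exc:
        raise ValueError("not a PHYLIP file: non-numeric header") from exc
    records = []
    pos = 2
    for _ in range(ntax):
        if pos >= len(tokens):
            raise ValueError("truncated PHYLIP file")
        name = tokens[pos]
        pos += 1
        chunks: list[str] = []
        need = nchar
        while need > 0:
            if pos >= len(tokens):
                raise ValueError(f"truncated sequence for {name!r}")
            chunk = tokens[pos]
            pos += 1
            chunks.append(chunk)
            need -= len(chunk)
        records.append((name, "".join(chunks)))
    return records


def read_codon_alignment(
    path: str | Path, genetic_code: str | int | GeneticCode = "standard"
) -> CodonAlignment:
    """Read a FASTA or relaxed sequential PHYLIP codon alignment.

    Raises ``ValueError`` on ragged rows, lengths not divisible by three,
    duplicate taxa, or an unambiguous stop codon (the error names the
    offending taxon and codon site).
    """
    code = genetic_code if isinstance(genetic_code, GeneticCode) else get_code(genetic_code)
    path = Path(path)
    text = path.read_text()
    first = text.lstrip()[:1]
    if first == ">":
        pairs = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    else:
        pairs = _parse_relaxed_phylip(text)
    if not pairs:
        raise ValueError(f"no sequences found in {path}")
    taxa = [name for name, _ in pairs]
    codons = [_split_codons(name, seq) for name, seq in pairs]
    return CodonAlignment(taxa=taxa, codons=codons, code=code)


def write_codon_alignment(alignment: CodonAlignment, path: str | Path, width: int = 60) -> None:
    """Write the alignment as FASTA (wrapped at ``width`` columns)."""
    with open(path, "w") as fh:
        for taxon in alignment.taxa:
            seq = alignment.sequence(taxon)
            fh.write(f">{taxon}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
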