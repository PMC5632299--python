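"""Genetic codes and codon-level bookkeeping.

The likelihood machinery works on the sense codons of a genetic code
(61 for the standard nuclear code). Stop codons are excluded from the
state space; single-nucleotide substitution structure (transition vs
transversion, synonymous vs nonsynonymous) is precomputed once per code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import product

import numpy as np
from Bio.Data import CodonTable

NUCLEOTIDES = "TCAG"
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

#: letters that make a codon position ambiguous (treated as missing data)
AMBIGUOUS = frozenset("NRYSWKMBDHV-?X.")

CODE_ALIASES = {
    "standard": 1,
    "nuclear": 1,
    "invertebrate-mito": 5,
    "invertebrate_mitochondrial": 5,
    "mito": 5,
}


def _is_transition(a: str, b: str) -> bool:
    return (a in PURINES and b in PURINES) or (a in PYRIMIDINES and b in PYRIMIDINES)


@dataclass(frozen=True)
class GeneticCode:
    """A genetic code restricted to its sense codons.

    Attributes
    ----------
    table_id : NCBI translation table identifier (1 = standard, 5 =
        invertebrate mitochondrial).
    codons : tuple of sense codons, in a fixed (TCAG-major) order.
    amino_acids : one-letter translation per sense codon.
    stop_codons : codons excluded from the state space.
    """

    table_id: int
    codons: tuple[str, ...]
    amino_acids: tuple[str, ...]
    stop_codons: frozenset[str]
    index: dict[str, int] = field(repr=False, compare=False, default_factory=dict)

    @property
    def n_states(self) -> int:
        return len(self.codons)

    def translate(self, codon: str) -> str:
        return self.amino_acids[self.index[codon]]

    def single_step_structure(self):
        """Return (diff_pos, transition, synonymous) arrays over codon pairs.

        ``diff_pos[i, j]`` is the single differing codon position (0..2) or
        -1 when the pair differs at zero or more than one position;
        ``transition`` / ``synonymous`` are boolean matrices, defined only
        where ``diff_pos >= 0``.
        """
        return _single_step_structure(self)


@lru_cache(maxsize=None)
def _single_step_structure(code: GeneticCode):
    n = code.n_states
    diff_pos = np.full((n, n), -1, dtype=np.int8)
    transition = np.zeros((n, n), dtype=bool)
    synonymous = np.zeros((n, n), dtype=bool)
    for i, ci in enumerate(code.codons):
        for j, cj in enumerate(code.codons):
            if i == j:
                continue
            diffs = [k for k in range(3) if ci[k] != cj[k]]
            if len(diffs) != 1:
                continue
            k = diffs[0]
            diff_pos[i, j] = k
            transition[i, j] = _is_transition(ci[k], cj[k])
            synonymous[i, j] = code.amino_acids[i] == code.amino_acids[j]
    diff_pos.setflags(write=False)
    transition.setflags(write=False)
    synonymous.setflags(write=False)
    return diff_pos, transition, synonymous


@lru_cache(maxsize=None)
def get_code(name_or_id: str | int = "standard") -> GeneticCode:
    """Look up a genetic code by name ("standard", "invertebrate-mito") or NCBI id."""
    if isinstance(name_or_id, str):
        key = name_or_id.strip().lower().replace(" ", "-")
        if key.isdigit():
            table_id = int(key)
        elif key in CODE_ALIASES:
            table_id = CODE_ALIASES[key]
        else:
            raise ValueError(f"unknown genetic code {name_or_id!r}")
    else:
        table_id = int(name_or_id)
    table = CodonTable.unambiguous_dna_by_id[table_id]
    stops = frozenset(table.stop_codons)
    codons = tuple(
        c for c in ("".join(p) for p in product(NUCLEOTIDES, repeat=3)) if c not in stops
    )
    aas = tuple(table.forward_table[c] for c in codons)
    return GeneticCode(
        table_id=table_id,
        codons=codons,
        amino_acids=aas,
        stop_codons=stops,
        index={c: i for i, c in enumerate(codons)},
    )


def codon_state(codon: str, code: GeneticCode) -> int:
    """Encode a codon as a sense-codon state index, or -1 for missing data.

    Any codon containing a gap, N or IUPAC ambiguity letter is treated as
    fully missing; an unambiguous stop codon raises ``ValueError``.
    """
    codon = codon.upper().replace("U", "T")
    if any(ch in AMBIGUOUS or ch not in "ACGT" for ch in codon):
        return -1
    if codon in code.stop_codons:
        raise ValueError(f"stop codon {codon}")
    return code.index[codon]
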