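"""Goldman–Yang codon substitution model: rate matrices and P(t).

The GY94 instantaneous rate from codon i to codon j is nonzero only for
single-nucleotide changes and proportional to the target codon frequency
pi_j, multiplied by kappa for transitions and by omega (dN/dS) for
nonsynonymous changes. Matrices are scaled to one expected substitution
per codon per unit branch length. The chain is time-reversible, so P(t)
is computed by eigendecomposition of the symmetrised generator, with a
scaling-and-squaring fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import expm

from .genetics import GeneticCode, get_code


def codon_frequencies(
    alignment, method: str = "F3x4", code: GeneticCode | None = None
) -> np.ndarray:
    """Equilibrium codon frequencies over the sense codons.

    ``equal``: uniform; ``F1x4``: products of overall nucleotide
    frequencies; ``F3x4``: products of position-specific nucleotide
    frequencies. Stop codons are excluded and the vector renormalised.
    Counts ignore gaps/ambiguity letters; a pseudocount guards against
    zero frequencies in short genes.
    """
    code = code or (alignment.code if alignment is not None else get_code())
    n = code.n_states
    if method == "equal":
        return np.full(n, 1.0 / n)
    counts = np.ones((3, 4))  # pseudocount per position x ACGT
    order = {"A": 0, "C": 1, "G": 2, "T": 3}
    for row in alignment.codons:
        for codon in row:
            for pos, ch in enumerate(codon.upper().replace("U", "T")):
                if ch in order:
                    counts[pos, order[ch]] += 1
    if method == "F1x4":
        tot = counts.sum(axis=0)
        pos_freqs = np.tile(tot / tot.sum(), (3, 1))
    elif method == "F3x4":
        pos_freqs = counts / counts.sum(axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown frequency method {method!r}")
    pi = np.array(
        [
            pos_freqs[0, order[c[0]]] * pos_freqs[1, order[c[1]]] * pos_freqs[2, order[c[2]]]
            for c in code.codons
        ]
    )
    return pi / pi.sum()


def build_rate_matrix(
    kappa: float, omega: float, freqs: np.ndarray, code: GeneticCode | None = None
) -> np.ndarray:
    """GY94 rate matrix over sense codons, scaled to unit mean rate."""
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    if omega < 0:
        raise ValueError("omega must be nonnegative")
    code = code or get_code()
    pi = np.asarray(freqs, dtype=float)
    if pi.shape != (code.n_states,) or np.any(pi < 0) or abs(pi.sum() - 1) > 1e-8:
        raise ValueError("invalid codon frequency vector")
    diff_pos, transition, synonymous = code.single_step_structure()
    single = diff_pos >= 0
    rate = np.where(transition, kappa, 1.0) * np.where(synonymous, 1.0, omega)
    q = np.where(single, rate * pi[None, :], 0.0)
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    scale = -np.dot(pi, np.diag(q))
    if scale <= 0:
        # omega=0 with no synonymous moves possible would be degenerate;
        # never reached for real codes, but guard anyway
        raise ValueError("degenerate rate matrix: zero mean rate")
    return q / scale


def mean_rate(
    kappa: float, omega: float, freqs: np.ndarray, code: GeneticCode | None = None
) -> float:
    """Mean substitution rate of the *unnormalised* GY94 generator.

    Linear in omega: the synonymous flow plus omega times the
    nonsynonymous flow. Used to put the site classes of a mixture on a
    common time scale (branch length = expected substitutions per codon
    averaged over site classes), so that classes with larger omega
    genuinely substitute faster.
    """
    code = code or get_code()
    pi = np.asarray(freqs, dtype=float)
    diff_pos, transition, synonymous = code.single_step_structure()
    single = diff_pos >= 0
    rate = np.where(transition, kappa, 1.0) * np.where(synonymous, 1.0, omega)
    q = np.where(single, rate * pi[None, :], 0.0)
    return float(pi @ q.sum(axis=1))


def class_rate_multipliers(
    classes: list[tuple[float, dict[int, float]]],
    kappa: float,
    freqs: np.ndarray,
    code: GeneticCode | None = None,
) -> list[dict[int, float]]:
    """Per-class, per-branch-class time multipliers for a site mixture.

    ``classes`` holds (probability, branch_class -> omega) entries. For
    each branch class the expected rate averaged over site classes is
    normalised to 1, so effective branch length for site class c is
    t * mu(omega_c) / sum_c' p_c' mu(omega_c'). Single-class models get
    multiplier 1 exactly.
    """
    if len(classes) == 1:
        return [{bc: 1.0 for bc in classes[0][1]}]
    mu_cache: dict[float, float] = {}

    def mu(w: float) -> float:
        if w not in mu_cache:
            mu_cache[w] = mean_rate(kappa, w, freqs, code)
        return mu_cache[w]

    branch_classes = set()
    for _, table in classes:
        branch_classes |= set(table)
    mean_by_bc = {
        bc: sum(prob * mu(table[bc]) for prob, table in classes) for bc in branch_classes
    }
    return [
        {bc: mu(table[bc]) / mean_by_bc[bc] for bc in branch_classes}
        for _, table in classes
    ]


@dataclass(frozen=True)
class RateMatrix:
    """A GY94 generator with its spectral decomposition cached.

    For a reversible Q with stationary distribution pi, the matrix
    B = diag(sqrt(pi)) Q diag(1/sqrt(pi)) is symmetric; with B = V L V',
    P(t) = diag(1/sqrt(pi)) V exp(L t) V' diag(sqrt(pi)).
    """

    q: np.ndarray
    pi: np.ndarray
    _decomp: tuple | None = field(default=None, compare=False, repr=False)

    @classmethod
    def build(
        cls, kappa: float, omega: float, freqs: np.ndarray, code: GeneticCode | None = None
    ) -> "RateMatrix":
        q = build_rate_matrix(kappa, omega, freqs, code)
        return cls(q=q, pi=np.asarray(freqs, dtype=float)).with_decomposition()

    def with_decomposition(self) -> "RateMatrix":
        sqrt_pi = np.sqrt(self.pi)
        b = (sqrt_pi[:, None] * self.q) / sqrt_pi[None, :]
        b = 0.5 * (b + b.T)  # enforce exact symmetry
        try:
            vals, vecs = np.linalg.eigh(b)
            left = vecs.T * sqrt_pi[None, :]
            right = vecs / sqrt_pi[:, None]
            decomp = (vals, right, left)
        except np.linalg.LinAlgError:  # pragma: no cover - ill-conditioning fallback
            decomp = None
        return replace(self, _decomp=decomp)

    def probs(self, t: float) -> np.ndarray:
        """Transition probability matrix P(t) = exp(Qt)."""
        if t < 0:
            raise ValueError("negative time")
        if t == 0:
            return np.eye(len(self.pi))
        if self._decomp is None:  # pragma: no cover
            p = expm(self.q * t)
        else:
            vals, right, left = self._decomp
            p = (right * np.exp(vals * t)[None, :]) @ left
        p = np.clip(p, 0.0, None)
        return p / p.sum(axis=1, keepdims=True)


def transition_probabilities(q: np.ndarray, t: float, pi: np.ndarray | None = None) -> np.ndarray:
    """P(t) = exp(Qt) for a (reversible) generator.

    With ``pi`` given, uses the symmetric eigendecomposition route;
    otherwise scipy's expm.
    """
    if t < 0:
        raise ValueError("negative time")
    if pi is not None:
        return RateMatrix(q=np.asarray(q, float), pi=np.asarray(pi, float)).with_decomposition().probs(t)
    p = expm(np.asarray(q, float) * t)
    p = np.clip(p, 0.0, None)
    return p / p.sum(axis=1, keepdims=True)


# --------------------------------------------------------------------------
# omega structures


@dataclass(frozen=True)
class SingleOmega:
    """One dN/dS ratio shared by every branch and site (M0)."""

    omega: float


@dataclass(frozen=True)
class BranchClassOmega:
    """One dN/dS ratio per branch class (multi-rate branch model)."""

    omega_by_class: tuple[float, ...]  # indexed by branch class


@dataclass(frozen=True)
class BranchSiteOmega:
    """Branch-site model A site-class mixture.

    Four site classes with proportions (p0, p1, p2a, p2b) where
    p2a = (1-p0-p1) p0/(p0+p1) and p2b = (1-p0-p1) p1/(p0+p1):

    =====  ==========  ==========
    class  background  foreground
    =====  ==========  ==========
    0      omega0      omega0
    1      1           1
    2a     omega0      omega2
    2b     1           omega2
    =====  ==========  ==========

    The null (A1) fixes omega2 = 1.
    """

    p0: float
    p1: float
    omega0: float
    omega2: float

    def __post_init__(self) -> None:
        if not (0 < self.p0 <= 1) or self.p1 < 0 or self.p0 + self.p1 > 1 + 1e-9:
            raise ValueError("invalid site-class proportions")
        if not (0 < self.omega0 <= 1):
            raise ValueError("omega0 must lie in (0, 1]")
        if self.omega2 < 1:
            raise ValueError("omega2 must be >= 1 under model A")

    @property
    def proportions(self) -> np.ndarray:
        p0, p1 = self.p0, self.p1
        rest = max(0.0, 1.0 - p0 - p1)
        p2a = rest * p0 / (p0 + p1)
        p2b = rest * p1 / (p0 + p1)
        return np.array([p0, p1, p2a, p2b])

    def class_omegas(self) -> list[tuple[float, float]]:
        """(background, foreground) omega per site class."""
        return [
            (self.omega0, self.omega0),
            (1.0, 1.0),
            (self.omega0, self.omega2),
            (1.0, self.omega2),
        ]


OmegaStructure = SingleOmega | BranchClassOmega | BranchSiteOmega


@dataclass(frozen=True)
class CodonModelSpec:
    """A complete codon model: kappa, codon frequencies, omega structure."""

    kappa: float
    freqs: np.ndarray
    omega: OmegaStructure
    code: GeneticCode = field(default_factory=get_code)

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
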