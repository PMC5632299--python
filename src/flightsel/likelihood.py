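"""Phylogenetic likelihood for codon models and maximum-likelihood fitting.

Likelihoods are computed by Felsenstein pruning over the sense-codon
state space, vectorised across distinct site patterns. Site-class
mixtures (the branch-site models) are handled by computing each class's
per-site likelihood with class-specific per-branch omegas and mixing
with the class proportions. Ambiguous codons enter as missing data
(partial-likelihood vectors of ones).

Fitting maximises the log-likelihood with bounded L-BFGS-B on log/logit
transformed parameters, with seeded multi-start jitter around heuristic
initial values.
"""

from __future__ import annotations

import math
from collections import OrderedDict
from dataclasses import dataclass

import numpy as np

#: sentinel zero scale shared by leaf partials (no rescaling applied)
_ZERO = 0.0
from scipy.optimize import minimize

from .alignment import CodonAlignment
from .model import (
    BranchClassOmega,
    BranchSiteOmega,
    CodonModelSpec,
    RateMatrix,
    SingleOmega,
    class_rate_multipliers,
    codon_frequencies,
)
from .tree import LabeledTree

OMEGA_BOUNDS = (1e-4, 999.0)
KAPPA_BOUNDS = (0.01, 100.0)
SCALE_BOUNDS = (1e-3, 1e3)
LENGTH_BOUNDS = (1e-7, 50.0)


# --------------------------------------------------------------------------
# likelihood evaluation


def _site_class_table(
    model: CodonModelSpec, branch_classes: np.ndarray
) -> list[tuple[float, dict[int, float]]]:
    """Expand the omega structure into (probability, class->omega) entries.

    For branch-site models every nonzero branch class is foreground.
    """
    present = sorted(set(int(c) for c in branch_classes))
    om = model.omega
    if isinstance(om, SingleOmega):
        return [(1.0, {c: om.omega for c in present})]
    if isinstance(om, BranchClassOmega):
        table = {}
        for c in present:
            if c >= len(om.omega_by_class):
                raise ValueError(f"no omega supplied for branch class {c}")
            table[c] = om.omega_by_class[c]
        return [(1.0, table)]
    if isinstance(om, BranchSiteOmega):
        probs = om.proportions
        out = []
        for prob, (bg, fg) in zip(probs, om.class_omegas()):
            if prob <= 0:
                continue
            out.append((float(prob), {c: (bg if c == 0 else fg) for c in present}))
        return out
    raise TypeError(f"unknown omega structure {type(om).__name__}")


class PatternData:
    """A codon alignment compiled against a tree for repeated evaluation."""

    def __init__(self, alignment: CodonAlignment, tree: LabeledTree):
        missing = set(alignment.taxa) - set(tree.leaf_names)
        if missing:
            raise ValueError(f"alignment taxa not in tree: {sorted(missing)}")
        self.tree = tree
        self.code = alignment.code
        patterns, counts = alignment.site_patterns()
        self.patterns = patterns  # (n_taxa, n_patterns)
        self.counts = counts.astype(float)
        self.n_states = alignment.code.n_states
        row_of = {t: i for i, t in enumerate(alignment.taxa)}
        self.leaf_row: dict[int, int | None] = {
            leaf: row_of.get(tree.names[leaf]) for leaf in tree.leaves
        }
        self.n_sites = alignment.sites
        # caches persist across evaluations: numeric gradients perturb one
        # parameter at a time, so most subtree partials can be reused
        self._rm_cache: dict = {}
        self._p_cache: dict = {}
        self._partial_cache: "OrderedDict" = OrderedDict()
        self._partial_cache_cap = 400
        self._leaf_cache: dict[int, np.ndarray] = {}

    def _leaf_partial(self, node: int) -> np.ndarray:
        lp = self._leaf_cache.get(node)
        if lp is not None:
            return lp
        row = self.leaf_row[node]
        npat = self.patterns.shape[1]
        lp = np.zeros((self.n_states, npat))
        if row is None:
            lp[:] = 1.0
        else:
            states = self.patterns[row]
            obs = states >= 0
            lp[:, ~obs] = 1.0
            lp[states[obs], np.nonzero(obs)[0]] = 1.0
        self._leaf_cache[node] = lp
        return lp

    def log_likelihood(
        self, model: CodonModelSpec, lengths: np.ndarray | None = None
    ) -> float:
        """Mixture log-likelihood via pruning with cross-class partial reuse.

        P matrices are cached by (omega, branch length) and node partial
        vectors by a subtree signature of the omegas applied below the
        node, so site classes that differ only on the foreground
        branches recompute only the root-ward path. Partials are
        rescaled per node to avoid underflow on deep trees; the log
        correction is carried separately.
        """
        tree = self.tree
        lengths = tree.lengths if lengths is None else lengths
        classes = _site_class_table(model, tree.classes[1:])
        multipliers = class_rate_multipliers(classes, model.kappa, model.freqs, self.code)
        pi = np.asarray(model.freqs, float)
        kappa = float(model.kappa)
        pi_key = hash(pi.tobytes())
        npat = self.patterns.shape[1]
        mixture = np.zeros(npat)
        log_offset = np.zeros(npat)
        first = True

        def probs_for(w: float, t: float) -> np.ndarray:
            key = (pi_key, kappa, w, t)
            p = self._p_cache.get(key)
            if p is None:
                rm = self._rm_cache.get((pi_key, kappa, w))
                if rm is None:
                    rm = RateMatrix.build(kappa, w, pi, self.code)
                    self._rm_cache[(pi_key, kappa, w)] = rm
                p = rm.probs(t)
                if len(self._p_cache) > 4000:
                    self._p_cache.clear()
                self._p_cache[key] = p
            return p

        for (prob, omega_of_class), mult in zip(classes, multipliers):
            # subtree signature: (omega, effective length) of the branch
            # above each node plus child signatures; identical signatures
            # mean the partial below that node is identical and reusable
            t_eff = {
                node: float(lengths[node]) * mult[int(tree.classes[node])]
                for node in range(1, tree.n_nodes)
            }
            sig: dict[int, tuple] = {}
            for node in tree.postorder():
                if tree.parent[node] >= 0:
                    edge = (omega_of_class[int(tree.classes[node])], t_eff[node])
                else:
                    edge = None
                sig[node] = (edge, tuple(sig[c] for c in tree.children[node]))

            def partial(node: int) -> tuple[np.ndarray, np.ndarray]:
                key = (node, pi_key, kappa, sig[node])
                cached = self._partial_cache.get(key)
                if cached is not None:
                    self._partial_cache.move_to_end(key)
                    return cached
                if not tree.children[node]:
                    out = (self._leaf_partial(node), _ZERO)
                else:
                    lp = np.ones((self.n_states, npat))
                    scale = np.zeros(npat)
                    for child in tree.children[node]:
                        w = omega_of_class[int(tree.classes[child])]
                        child_lp, child_scale = partial(child)
                        lp = lp * (probs_for(w, t_eff[child]) @ child_lp)
                        if child_scale is not _ZERO:
                            scale = scale + child_scale
                    peak = lp.max(axis=0)
                    low = peak < 1e-150
                    if np.any(low & (peak > 0)):
                        factor = np.where(low & (peak > 0), 1.0 / peak, 1.0)
                        lp = lp * factor
                        scale = scale - np.log(factor)
                    out = (lp, scale)
                self._partial_cache[key] = out
                while len(self._partial_cache) > self._partial_cache_cap:
                    self._partial_cache.popitem(last=False)
                return out

            root_lp, root_scale = partial(0)
            site_like = pi @ root_lp
            if first:
                log_offset = root_scale
                first = False
            # all classes share leaf data, so scales agree; fold any drift in
            site_like = site_like * np.exp(root_scale - log_offset)
            mixture += prob * site_like
        if np.any(mixture <= 0) or not np.all(np.isfinite(mixture)):
            bad = int(np.argmin(mixture))
            raise FloatingPointError(f"non-finite site likelihood at pattern {bad}")
        return float((np.log(mixture) + log_offset) @ self.counts)


def log_likelihood(
    alignment: CodonAlignment, tree: LabeledTree, model: CodonModelSpec
) -> float:
    """Log-likelihood of the alignment on the tree under the codon model."""
    return PatternData(alignment, tree).log_likelihood(model)


# --------------------------------------------------------------------------
# fitting


@dataclass
class LikelihoodResult:
    """Outcome of a maximum-likelihood fit."""

    lnl: float
    model: CodonModelSpec
    lengths: np.ndarray
    scale: float
    converged: bool
    n_restarts_used: int
    kind: str

    @property
    def omega_by_class(self) -> dict[int, float]:
        om = self.model.omega
        if isinstance(om, SingleOmega):
            return {0: om.omega}
        if isinstance(om, BranchClassOmega):
            return dict(enumerate(om.omega_by_class))
        return {}


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _logit(p: float) -> float:
    p = min(max(p, 1e-9), 1 - 1e-9)
    return math.log(p / (1 - p))


class _Parameterisation:
    """Maps an unconstrained vector to a CodonModelSpec (+ length scale)."""

    def __init__(self, kind, n_branch_classes, freqs, code, branch_lengths, fix):
        self.kind = kind
        self.n_branch_classes = n_branch_classes
        self.freqs = freqs
        self.code = code
        self.branch_lengths = branch_lengths
        self.fix = fix or {}
        names: list[str] = [] if "kappa" in self.fix else ["log_kappa"]
        if kind == "M0":
            names += ["log_omega"]
        elif kind == "branch":
            names += [f"log_omega_{k}" for k in range(n_branch_classes)]
        elif kind in ("branch_site_alt", "branch_site_null"):
            names += ["stick_s", "stick_r", "log_omega0"]
            if kind == "branch_site_alt":
                names += ["x_omega2"]
        else:
            raise ValueError(f"unknown model kind {kind!r}")
        if branch_lengths == "scale":
            names += ["log_scale"]
        self.names = names

    def bounds(self, n_lengths: int = 0):
        lo_w, hi_w = np.log(OMEGA_BOUNDS)
        b = []
        for name in self.names:
            if name == "log_kappa":
                b.append(tuple(np.log(KAPPA_BOUNDS)))
            elif name.startswith("log_omega0"):
                b.append((lo_w, 0.0))  # omega0 in (0, 1]
            elif name.startswith("log_omega"):
                b.append((lo_w, hi_w))
            elif name in ("stick_s", "stick_r"):
                b.append((-12.0, 12.0))
            elif name == "x_omega2":
                b.append((-15.0, math.log(OMEGA_BOUNDS[1] - 1.0)))
            elif name == "log_scale":
                b.append(tuple(np.log(SCALE_BOUNDS)))
        b += [tuple(np.log(LENGTH_BOUNDS))] * n_lengths
        return b

    def init_vector(self, init: dict) -> np.ndarray:
        v = []
        for name in self.names:
            if name == "log_kappa":
                v.append(math.log(init.get("kappa", 2.0)))
            elif name == "log_omega":
                v.append(math.log(init.get("omega", 0.2)))
            elif name.startswith("log_omega0"):
                v.append(math.log(init.get("omega0", 0.1)))
            elif name.startswith("log_omega_"):
                k = int(name.rsplit("_", 1)[1])
                v.append(math.log(init.get(f"omega_{k}", init.get("omega", 0.1))))
            elif name == "stick_s":
                p0, p1 = init.get("p0", 0.75), init.get("p1", 0.15)
                v.append(_logit(min(p0 + p1, 1 - 1e-6)))
            elif name == "stick_r":
                p0, p1 = init.get("p0", 0.75), init.get("p1", 0.15)
                v.append(_logit(p0 / (p0 + p1)))
            elif name == "x_omega2":
                v.append(math.log(max(init.get("omega2", 2.0) - 1.0, 1e-6)))
            elif name == "log_scale":
                v.append(math.log(init.get("scale", 1.0)))
        return np.array(v)

    def unpack(self, v: np.ndarray) -> tuple[CodonModelSpec, float]:
        vals = dict(zip(self.names, v))
        kappa = self.fix.get("kappa", math.exp(vals.get("log_kappa", math.log(2.0))))
        if self.kind == "M0":
            omega = SingleOmega(math.exp(vals["log_omega"]))
        elif self.kind == "branch":
            omega = BranchClassOmega(
                tuple(
                    math.exp(vals[f"log_omega_{k}"]) for k in range(self.n_branch_classes)
                )
            )
        else:
            s = _sigmoid(vals["stick_s"])
            r = _sigmoid(vals["stick_r"])
            p0 = max(s * r, 1e-9)
            p1 = max(s * (1 - r), 0.0)
            omega0 = math.exp(vals["log_omega0"])
            omega2 = 1.0 + math.exp(vals["x_omega2"]) if self.kind == "branch_site_alt" else 1.0
            omega = BranchSiteOmega(p0=p0, p1=p1, omega0=min(omega0, 1.0), omega2=omega2)
        scale = math.exp(vals.get("log_scale", 0.0)) if self.branch_lengths == "scale" else 1.0
        return CodonModelSpec(kappa=kappa, freqs=self.freqs, omega=omega, code=self.code), scale


def fit_model(
    alignment: CodonAlignment,
    tree: LabeledTree,
    kind: str = "M0",
    *,
    freqs: np.ndarray | str = "F3x4",
    fix: dict | None = None,
    init: dict | None = None,
    branch_lengths: str = "fixed",
    n_restarts: int = 3,
    seed: int = 0,
    jitter_sd: float = 0.3,
    data: PatternData | None = None,
) -> LikelihoodResult:
    """Maximise the codon-model likelihood.

    ``kind`` selects the omega structure: ``M0`` (single omega),
    ``branch`` (one omega per branch class), ``branch_site_alt`` /
    ``branch_site_null`` (model A with omega2 free / fixed at 1).
    ``branch_lengths``: ``fixed`` uses the tree's lengths as given,
    ``scale`` additionally fits one tree-wide multiplier, ``full``
    re-estimates every branch length. Deterministic given ``seed``.
    """
    data = data or PatternData(alignment, tree)
    pi = codon_frequencies(alignment, freqs, alignment.code) if isinstance(freqs, str) else np.asarray(freqs, float)
    n_classes = max(int(c) for c in tree.classes[1:]) + 1
    par = _Parameterisation(kind, n_classes, pi, alignment.code, branch_lengths, fix)
    n_len = tree.n_nodes - 1 if branch_lengths == "full" else 0
    base = par.init_vector(init or {})
    if branch_lengths == "full":
        base = np.concatenate([base, np.log(np.maximum(tree.lengths[1:], 1e-6))])
    bounds = par.bounds(n_len)
    base = np.clip(base, [b[0] for b in bounds], [b[1] for b in bounds])

    def objective(v: np.ndarray) -> float:
        model, scale = par.unpack(v[: len(par.names)])
        if branch_lengths == "full":
            lengths = np.concatenate([[0.0], np.exp(v[len(par.names) :])])
        else:
            lengths = tree.lengths * scale
        try:
            return -data.log_likelihood(model, lengths)
        except FloatingPointError:
            return 1e12

    rng = np.random.default_rng(seed)
    best = None
    used = 0
    for attempt in range(max(1, n_restarts)):
        start = base if attempt == 0 else base + rng.normal(0.0, jitter_sd, size=base.size)
        start = np.clip(start, [b[0] for b in bounds], [b[1] for b in bounds])
        res = minimize(
            objective,
            start,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 300, "ftol": 1e-9, "gtol": 1e-6},
        )
        used = attempt + 1
        if best is None or res.fun < best.fun - 1e-9:
            best = res
    model, scale = par.unpack(best.x[: len(par.names)])
    if branch_lengths == "full":
        lengths = np.concatenate([[0.0], np.exp(best.x[len(par.names) :])])
    else:
        lengths = tree.lengths * scale
    return LikelihoodResult(
        lnl=-float(best.fun),
        model=model,
        lengths=lengths,
        scale=scale,
        converged=bool(best.success),
        n_restarts_used=used,
        kind=kind,
    )
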