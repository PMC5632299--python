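"""Gene-level selection tests and multiple-testing control.

Two likelihood ratio tests are provided:

* ``branch_site_test`` — branch-site model A against its null A1
  (omega2 fixed at 1) on a designated foreground branch set; a
  significant result with fitted omega2 > 1 on a positive fraction of
  sites is evidence of episodic positive selection on the foreground.
* ``branch_rates_test`` — a 3-rate branch model (background, flightless,
  flying) against the 2-rate model pooling flightless+flying; a
  significant increase of omega in the flightless class, with both
  omegas below 1, is the relaxed-selection signature.

Raw p-values come from a chi-square with one degree of freedom (the
50:50 boundary mixture is available behind a flag); families of genes
are corrected by Benjamini-Hochberg at a family-wise alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .alignment import CodonAlignment
from .likelihood import PatternData, fit_model
from .model import BranchSiteOmega
from .tree import LabeledTree


@dataclass
class GeneTestResult:
    """Per-gene likelihood-ratio test outcome."""

    gene: str
    kind: str  # "branch_site" | "branch_rates"
    lnl_null: float
    lnl_alt: float
    df: int
    p_raw: float
    p_bh: float | None = None
    significant: bool = False
    direction: str | None = None
    omega_by_class: dict = field(default_factory=dict)
    converged: bool = True
    positive_selection: bool | None = None
    relaxed: bool | None = None

    @property
    def lrt(self) -> float:
        return max(0.0, 2.0 * (self.lnl_alt - self.lnl_null))


def lrt_pvalue(lrt: float, df: int = 1, null: str = "chi2") -> float:
    """P-value of a likelihood-ratio statistic.

    ``chi2``: standard chi-square reference. ``mixture``: the 50:50
    point-mass/chi-square boundary mixture (for a parameter tested at
    the edge of its space).
    """
    lrt = max(0.0, lrt)
    if null == "chi2":
        return float(chi2.sf(lrt, df)) if lrt > 0 else 1.0
    if null == "mixture":
        return float(0.5 * chi2.sf(lrt, df)) if lrt > 0 else 1.0
    raise ValueError(f"unknown null distribution {null!r}")


def branch_site_test(
    alignment: CodonAlignment,
    tree: LabeledTree,
    gene: str = "gene",
    *,
    seed: int = 0,
    null: str = "chi2",
    n_restarts: int = 2,
    freqs: str | np.ndarray = "F3x4",
    fit_scale: bool = True,
) -> GeneTestResult:
    """Branch-site test of positive selection on the foreground branches.

    Foreground branches are those with a nonzero class on ``tree``.
    Branch lengths are set once by an M0 fit of a tree-wide scale factor
    and then held fixed for the nested A1/A comparison; the alternative
    is additionally started from the null optimum so the nesting
    inequality holds up to optimizer tolerance.
    """
    if not np.any(tree.classes[1:] > 0):
        raise ValueError("no foreground branches on tree")
    data = PatternData(alignment, tree)
    base = fit_model(
        alignment, tree, "M0",
        freqs=freqs, branch_lengths="scale" if fit_scale else "fixed",
        n_restarts=1, seed=seed, data=data,
    )
    scaled = tree.copy()
    scaled.lengths = base.lengths
    data_scaled = PatternData(alignment, scaled)
    m0_omega = base.omega_by_class[0]
    init = {"kappa": base.model.kappa, "omega0": min(max(m0_omega, 1e-3), 0.9)}
    null_fit = fit_model(
        alignment, scaled, "branch_site_null",
        freqs=freqs, init=init, n_restarts=n_restarts, seed=seed, data=data_scaled,
    )
    nm = null_fit.model.omega
    alt_init = {
        "kappa": null_fit.model.kappa,
        "p0": nm.p0, "p1": nm.p1, "omega0": nm.omega0, "omega2": 1.5,
    }
    alt_fit = fit_model(
        alignment, scaled, "branch_site_alt",
        freqs=freqs, init=alt_init, n_restarts=n_restarts, seed=seed + 1, data=data_scaled,
    )
    lnl0, lnl1 = null_fit.lnl, max(alt_fit.lnl, null_fit.lnl)
    lrt = max(0.0, 2.0 * (lnl1 - lnl0))
    p = lrt_pvalue(lrt, 1, null)
    am: BranchSiteOmega = alt_fit.model.omega
    p2 = float(am.proportions[2] + am.proportions[3])
    result = GeneTestResult(
        gene=gene, kind="branch_site",
        lnl_null=lnl0, lnl_alt=lnl1, df=1, p_raw=p,
        omega_by_class={"omega0": am.omega0, "omega2": am.omega2, "p2": p2},
        converged=null_fit.converged and alt_fit.converged,
    )
    result.positive_selection = bool(p <= 0.05 and am.omega2 > 1.0 and p2 > 0.0)
    return result


def branch_rates_test(
    alignment: CodonAlignment,
    tree3: LabeledTree,
    tree2: LabeledTree | None = None,
    gene: str = "gene",
    *,
    seed: int = 0,
    n_restarts: int = 1,
    freqs: str | np.ndarray = "F3x4",
    fit_scale: bool = True,
    flightless_class: int = 1,
    flying_class: int = 2,
) -> GeneTestResult:
    """3-rate vs 2-rate branch-model LRT for a flightless/flying omega difference.

    ``tree3`` carries classes {0: background, 1: flightless, 2: flying};
    ``tree2`` (derived by pooling classes 1 and 2 when omitted) is the
    null in which both focal sets share one omega. ``direction`` reports
    which focal class has the higher fitted omega; the relaxed-selection
    call additionally requires both focal omegas in (0, 1).
    """
    classes = tree3.class_set()
    if not {flightless_class, flying_class} <= classes:
        raise ValueError(
            f"tree3 must carry classes {flightless_class} and {flying_class}; has {sorted(classes)}"
        )
    if tree2 is None:
        tree2 = tree3.merge_classes({flying_class: flightless_class})
    else:
        if not np.allclose(tree2.lengths, tree3.lengths):
            raise ValueError("tree2 and tree3 must share topology and branch lengths")
    data3 = PatternData(alignment, tree3)
    base = fit_model(
        alignment, tree3, "M0",
        freqs=freqs, branch_lengths="scale" if fit_scale else "fixed",
        n_restarts=1, seed=seed, data=data3,
    )
    w0 = base.omega_by_class[0]
    scaled3 = tree3.copy()
    scaled3.lengths = base.lengths
    scaled2 = tree2.copy()
    scaled2.lengths = base.lengths
    init = {"kappa": base.model.kappa, "omega": min(max(w0, 1e-3), 5.0)}
    null_fit = fit_model(
        alignment, scaled2, "branch",
        freqs=freqs, init=init, n_restarts=n_restarts, seed=seed,
        data=PatternData(alignment, scaled2),
    )
    alt_init = dict(init)
    for k, w in null_fit.omega_by_class.items():
        alt_init[f"omega_{k}"] = w
    pooled = null_fit.omega_by_class.get(flightless_class, w0)
    alt_init[f"omega_{flightless_class}"] = pooled
    alt_init[f"omega_{flying_class}"] = pooled
    alt_init["kappa"] = null_fit.model.kappa
    alt_fit = fit_model(
        alignment, scaled3, "branch",
        freqs=freqs, init=alt_init, n_restarts=n_restarts, seed=seed + 1,
        data=PatternData(alignment, scaled3),
    )
    lnl0, lnl1 = null_fit.lnl, max(alt_fit.lnl, null_fit.lnl)
    lrt = max(0.0, 2.0 * (lnl1 - lnl0))
    p = lrt_pvalue(lrt, 1, "chi2")
    omegas = alt_fit.omega_by_class
    w_fl, w_fly = omegas[flightless_class], omegas[flying_class]
    result = GeneTestResult(
        gene=gene, kind="branch_rates",
        lnl_null=lnl0, lnl_alt=lnl1, df=1, p_raw=p,
        direction="flightless" if w_fl > w_fly else "flying",
        omega_by_class={
            "background": omegas.get(0), "flightless": w_fl, "flying": w_fly,
            "pooled": pooled,
        },
        converged=null_fit.converged and alt_fit.converged,
    )
    result.relaxed = bool(p <= 0.05 and w_fl > w_fly and 0 < w_fl < 1 and 0 < w_fly < 1)
    return result


def bh_adjust(p_values, alpha: float = 0.05):
    """Benjamini-Hochberg step-up adjusted p-values and significance flags.

    Returns ``(p_adjusted, significant)``; adjusted p-values are
    ``min_{j >= i} m p_(j) / j`` capped at 1, flags are ``adjusted <= alpha``.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return p_adj, p_adj <= alpha


def annotate_family(results: list[GeneTestResult], alpha: float = 0.05) -> list[GeneTestResult]:
    """Apply BH across one family of gene tests, filling p_bh and flags in place."""
    if not results:
        return results
    p_adj, sig = bh_adjust([r.p_raw for r in results], alpha)
    for r, pa, s in zip(results, p_adj, sig):
        r.p_bh = float(pa)
        r.significant = bool(s)
        if r.kind == "branch_site" and r.positive_selection is not None:
            r.positive_selection = bool(
                s and r.omega_by_class.get("omega2", 1.0) > 1.0 and r.omega_by_class.get("p2", 0.0) > 0.0
            )
        if r.kind == "branch_rates":
            w_fl = r.omega_by_class.get("flightless")
            w_fly = r.omega_by_class.get("flying")
            r.relaxed = bool(
                s and w_fl is not None and w_fly is not None
                and w_fl > w_fly and 0 < w_fl < 1 and 0 < w_fly < 1
            )
    return results
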