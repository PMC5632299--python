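"""Independent oracles used by the test suite.

The brute-force likelihood enumerates every assignment of codon states
to internal nodes and sums the joint probabilities explicitly — no
pruning recursion — so it checks the engine by a different algorithm.
"""

from itertools import product

import numpy as np

from flightsel.likelihood import _site_class_table
from flightsel.model import RateMatrix, class_rate_multipliers


def brute_force_log_likelihood(alignment, tree, model):
    """Joint-enumeration log-likelihood (trees of <= 4 leaves, few sites)."""
    pi = np.asarray(model.freqs, float)
    S = len(pi)
    states = alignment.encode()
    row_of = {t: i for i, t in enumerate(alignment.taxa)}
    classes = _site_class_table(model, tree.classes[1:])
    mults = class_rate_multipliers(classes, model.kappa, pi, alignment.code)
    internals = [i for i in range(tree.n_nodes) if tree.children[i]]
    assert internals and internals[0] == 0
    others = internals[1:]
    lnl = 0.0
    for s in range(alignment.sites):
        site_total = 0.0
        for (prob_c, omega_of), mult in zip(classes, mults):
            rms = {}
            P = {}
            for node in range(1, tree.n_nodes):
                w = omega_of[int(tree.classes[node])]
                rm = rms.get(w)
                if rm is None:
                    rm = RateMatrix.build(model.kappa, w, pi, alignment.code)
                    rms[w] = rm
                P[node] = rm.probs(float(tree.lengths[node]) * mult[int(tree.classes[node])])
            total = 0.0
            # enumerate non-root internal assignments; vectorise over root state
            for assign in product(range(S), repeat=len(others)):
                amap = dict(zip(others, assign))
                vec = pi.copy()  # probability vector over root states
                for node in range(1, tree.n_nodes):
                    parent = tree.parent[node]
                    if tree.children[node]:
                        child_state = amap[node]
                    else:
                        obs = states[row_of[tree.names[node]], s]
                        if obs < 0:
                            continue  # missing data: sums to one over codons
                        child_state = obs
                    if parent == 0:
                        vec = vec * P[node][:, child_state]
                    else:
                        vec = vec * P[node][amap[parent], child_state]
                total += vec.sum()
            site_total += prob_c * total
        lnl += np.log(site_total)
    return lnl


def bh_step_up(p_values, alpha=0.05):
    """Hand-rolled Benjamini-Hochberg step-up (independent of statsmodels)."""
    p = np.asarray(p_values, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * p[idx] / rank)
        adj[idx] = running
    return adj, adj <= alpha
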