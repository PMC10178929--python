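"""Independent oracles used by the test suite.

Everything here is deliberately computed by a different route than the
package: sequential conjugate predictive densities instead of the
determinant-ratio score, brute-force enumeration instead of incremental
graph algorithms.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.stats import multivariate_t


def seq_nw_log_marginal(x: np.ndarray, cols, nu, alpha_mu, alpha_w, t_matrix):
    """log p(D_Y) via sequential normal–Wishart posterior predictives.

    The joint marginal of the n×l data block factorises into n
    multivariate-t predictive densities under conjugate updating; this
    never touches the closed-form determinant-ratio expression.
    """
    cols = list(cols)
    l = len(cols)
    if l == 0:
        return 0.0
    n, d = x.shape
    xx = x[:, cols]
    m = np.asarray(nu, float)[cols].copy()
    k = float(alpha_mu)
    nu0 = alpha_w - d + l
    s = np.asarray(t_matrix, float)[np.ix_(cols, cols)].copy()
    total = 0.0
    for i in range(n):
        dfp = nu0 - l + 1
        shape = s * (k + 1.0) / (k * dfp)
        total += multivariate_t.logpdf(xx[i], loc=m, shape=shape, df=dfp)
        xi = xx[i]
        s = s + np.outer(xi - m, xi - m) * k / (k + 1.0)
        m = (k * m + xi) / (k + 1.0)
        k += 1.0
        nu0 += 1.0
    return float(total)


def all_dags(nodes):
    """All DAG edge sets over the given labelled nodes (brute force)."""
    pairs = [(u, v) for u, v in itertools.permutations(nodes, 2)]
    for mask in range(2 ** len(pairs)):
        edges = {pairs[k] for k in range(len(pairs)) if mask >> k & 1}
        if _is_acyclic(nodes, edges):
            yield frozenset(edges)


def _is_acyclic(nodes, edges):
    children = {n: set() for n in nodes}
    indeg = {n: 0 for n in nodes}
    for u, v in edges:
        if (v, u) in edges:
            return False
        children[u].add(v)
        indeg[v] += 1
    queue = [n for n in nodes if indeg[n] == 0]
    seen = 0
    while queue:
        n = queue.pop()
        seen += 1
        for c in children[n]:
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    return seen == len(nodes)


def skeleton_and_vstructures(edges):
    """Equivalence-class invariants: skeleton and v-structure set."""
    skeleton = frozenset(frozenset(e) for e in edges)
    parents = {}
    for u, v in edges:
        parents.setdefault(v, set()).add(u)
    vstructs = set()
    for z, ps in parents.items():
        for x, y in itertools.combinations(sorted(ps), 2):
            if frozenset((x, y)) not in skeleton:
                vstructs.add((x, z, y))
    return skeleton, frozenset(vstructs)


def markov_equivalent(edges_a, edges_b):
    return skeleton_and_vstructures(edges_a) == skeleton_and_vstructures(edges_b)


def enumerate_structure_posterior(nodes, score_of_edges):
    """Exact posterior over all DAGs given a log-score function."""
    dags = list(all_dags(nodes))
    logs = np.asarray([score_of_edges(e) for e in dags])
    logs -= logs.max()
    probs = np.exp(logs)
    probs /= probs.sum()
    return dict(zip(dags, probs))
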