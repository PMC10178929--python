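"""BGe scoring: Gaussian-equivalent marginal likelihood of a node given parents.

The score of a DAG decomposes into per-node local terms.  Each local term
is the ratio of two marginal data likelihoods under a conjugate
normal–Wishart prior: the marginal over the node together with its parents
divided by the marginal over the parents alone.  For a feature subset Y of
size l (out of d features in total, n samples):

    log p(D_Y) = -(n·l/2)·log(π) + (l/2)·log(α_μ/(n+α_μ))
                 + log Γ_l((n+α_w-d+l)/2) - log Γ_l((α_w-d+l)/2)
                 + ((α_w-d+l)/2)·log|T_Y| - ((n+α_w-d+l)/2)·log|R_Y|

with R = T + S + (n·α_μ/(n+α_μ))·(ν-x̄)(ν-x̄)ᵀ, S the centred scatter
matrix, Γ_l the multivariate gamma, and T_Y, R_Y principal submatrices.
This parameterisation is score equivalent: all DAGs in one Markov
equivalence class receive the same total score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from scipy.special import multigammaln

from .datasets import OmicsDataset, Node
from .errors import ContractError, DegenerateDataError, InsufficientDataError
from .network import NetworkStructure

__all__ = [
    "BGeHyperparameters",
    "ScoreCache",
    "default_hyperparameters",
    "bge_local_score",
    "bge_network_score",
]


def dataset_node_order(ds: OmicsDataset) -> list[Node]:
    """Canonical node order: GE genes, then CNV nodes, then METH probes."""
    from .datasets import GE, CNV, METH, cnv_node_id

    nodes = [Node(g, GE) for g in ds.genes]
    if ds.cnv is not None:
        nodes += [Node(cnv_node_id(g), CNV) for g in ds.cnv.columns]
    if ds.meth is not None:
        nodes += [Node(p, METH) for p in ds.meth.columns]
    return nodes


@dataclass
class BGeHyperparameters:
    """Normal–Wishart prior hyperparameters for the BGe score.

    nu        prior mean vector over all features,
    alpha_mu  prior precision multiplier on the mean (>0),
    alpha_w   Wishart degrees of freedom (> d-1; default d+2),
    t_matrix  SPD parametric matrix of the Wishart prior.
    """

    nu: np.ndarray
    alpha_mu: float
    alpha_w: float
    t_matrix: np.ndarray
    feature_ids: tuple[str, ...]

    def __post_init__(self):
        d = len(self.feature_ids)
        self.nu = np.asarray(self.nu, float)
        self.t_matrix = np.asarray(self.t_matrix, float)
        if self.nu.shape != (d,) or self.t_matrix.shape != (d, d):
            raise ContractError("hyperparameter shapes do not match the feature set")
        if self.alpha_mu <= 0:
            raise ContractError("alpha_mu must be positive")
        if not np.allclose(self.t_matrix, self.t_matrix.T):
            raise ContractError("t_matrix must be symmetric")
        try:
            np.linalg.cholesky(self.t_matrix)
        except np.linalg.LinAlgError as exc:
            raise ContractError("t_matrix must be positive definite") from exc
        if self.alpha_w <= d - 1:
            raise ContractError("alpha_w must exceed d - 1 for a proper Wishart")

    @property
    def dim(self) -> int:
        return len(self.feature_ids)


def default_hyperparameters(ds: OmicsDataset) -> BGeHyperparameters:
    """Score-equivalent defaults.

    nu is the per-feature sample mean, alpha_mu = 1, alpha_w = d + 2 and
    T = alpha_mu·(alpha_w − d − 1)/(alpha_mu + 1) · I — the standard choice
    making the prior marginal variance match a unit-scale baseline.
    """
    if ds.n_samples < 2:
        raise InsufficientDataError("BGe scoring needs at least 2 samples")
    nodes = dataset_node_order(ds)
    d = len(nodes)
    x = np.column_stack([ds.node_column(n) for n in nodes])
    nu = x.mean(axis=0)
    alpha_mu = 1.0
    alpha_w = d + 2.0
    t_scale = alpha_mu * (alpha_w - d - 1.0) / (alpha_mu + 1.0)
    t_matrix = t_scale * np.eye(d)
    return BGeHyperparameters(
        nu=nu, alpha_mu=alpha_mu, alpha_w=alpha_w, t_matrix=t_matrix,
        feature_ids=tuple(n.id for n in nodes),
    )


class ScoreCache:
    """Memoised local scores for one dataset / hyperparameter pair.

    Caches both subset log marginals and (node, parent-set) local scores;
    hits return bit-identical values.  A cache is tied to the arrays it was
    built from — rebuild it whenever the data change.
    """

    def __init__(self, ds: OmicsDataset, hp: BGeHyperparameters):
        nodes = dataset_node_order(ds)
        ids = tuple(n.id for n in nodes)
        if ids != hp.feature_ids:
            raise ContractError("hyperparameters were built for a different dataset")
        self.ids = ids
        self.index = {i: k for k, i in enumerate(ids)}
        self.n = ds.n_samples
        self.d = len(ids)
        self.hp = hp
        x = np.column_stack([ds.node_column(n) for n in nodes])
        xbar = x.mean(axis=0)
        centred = x - xbar
        s = centred.T @ centred
        diff = (hp.nu - xbar)[:, None]
        w = self.n * hp.alpha_mu / (self.n + hp.alpha_mu)
        self.r_full = hp.t_matrix + s + w * (diff @ diff.T)
        self._logp: dict[tuple[int, ...], float] = {}
        self._local: dict[tuple[int, tuple[int, ...]], float] = {}

    def _logdet(self, mat: np.ndarray, cols: tuple[int, ...]) -> float:
        try:
            chol = np.linalg.cholesky(mat)
        except np.linalg.LinAlgError:
            # one jitter retry before declaring the subset degenerate
            try:
                chol = np.linalg.cholesky(mat + 1e-8 * np.eye(mat.shape[0]))
            except np.linalg.LinAlgError as exc:
                names = [self.ids[c] for c in cols]
                raise DegenerateDataError(
                    f"singular posterior matrix over columns {names}"
                ) from exc
        return 2.0 * float(np.sum(np.log(np.diag(chol))))

    def subset_log_marginal(self, cols: tuple[int, ...]) -> float:
        """log p(D_Y) for the feature subset Y given by column indices."""
        key = tuple(sorted(cols))
        hit = self._logp.get(key)
        if hit is not None:
            return hit
        l = len(key)
        if l == 0:
            self._logp[key] = 0.0
            return 0.0
        hp, n, d = self.hp, self.n, self.d
        idx = np.asarray(key)
        t_sub = hp.t_matrix[np.ix_(idx, idx)]
        r_sub = self.r_full[np.ix_(idx, idx)]
        a = hp.alpha_w - d + l
        val = (
            -0.5 * n * l * np.log(np.pi)
            + 0.5 * l * np.log(hp.alpha_mu / (n + hp.alpha_mu))
            + multigammaln(0.5 * (n + a), l)
            - multigammaln(0.5 * a, l)
            + 0.5 * a * self._logdet(t_sub, key)
            - 0.5 * (n + a) * self._logdet(r_sub, key)
        )
        val = float(val)
        self._logp[key] = val
        return val

    def local_score(self, node_id: str, parents: Iterable[str]) -> float:
        j = self.index[node_id]
        pa = tuple(sorted(self.index[p] for p in parents))
        if j in pa:
            raise ContractError(f"node {node_id} cannot be its own parent")
        key = (j, pa)
        hit = self._local.get(key)
        if hit is not None:
            return hit
        val = self.subset_log_marginal(pa + (j,)) - self.subset_log_marginal(pa)
        self._local[key] = val
        return val

    def dump_tsv(self, path) -> None:
        import pandas as pd

        rows = [
            (self.ids[j], ",".join(self.ids[p] for p in pa), v)
            for (j, pa), v in sorted(self._local.items())
        ]
        pd.DataFrame(rows, columns=["node", "parents", "log_score"]).to_csv(
            path, sep="\t", index=False
        )


def bge_local_score(node_id: str, parents: Iterable[str], ds: OmicsDataset,
                    hp: BGeHyperparameters,
                    cache: Optional[ScoreCache] = None) -> float:
    """Log marginal likelihood of ``node_id``'s column given its parents."""
    if ds.n_samples < 2:
        raise InsufficientDataError("BGe scoring needs at least 2 samples")
    if cache is None:
        cache = ScoreCache(ds, hp)
    return cache.local_score(node_id, parents)


def bge_network_score(g: NetworkStructure, ds: OmicsDataset,
                      hp: BGeHyperparameters,
                      cache: Optional[ScoreCache] = None) -> float:
    """Total (decomposable) BGe log score of a DAG."""
    if cache is None:
        cache = ScoreCache(ds, hp)
    return float(sum(cache.local_score(n.id, g.parents_of(n.id)) for n in g.nodes))
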