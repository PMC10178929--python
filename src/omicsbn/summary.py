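"""Posterior summaries: edge weights, thresholding, CPDAGs, diagnostics.

An edge's weight w_i is its empirical frequency over the retained
(post-burn-in, thinned) structure snapshots.  Thresholded networks are
reported as CPDAGs: edges compelled in every member of the (layer-
restricted) Markov equivalence class stay directed, the rest are
undirected.  Convergence of the chain is assessed by mean-shift
changepoint detection on the snapshot-level log-posterior series.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .datasets import GE, CandidateEdgeSet, Node
from .errors import ContractError
from .mcmc import PosteriorTrace, TraceRecord
from .network import NetworkStructure
from .priors import PriorKnowledgeTable

logger = logging.getLogger(__name__)

__all__ = [
    "WeightedNetwork",
    "EdgeRecord",
    "ConvergenceReport",
    "edge_weights",
    "threshold_edges",
    "to_cpdag",
    "build_weighted_network",
    "convergence_check",
    "export_network",
    "read_network_tsv",
    "trace_plot",
    "network_plot",
]


# ---------------------------------------------------------------------------
# edge weights and thresholding


def edge_weights(trace: PosteriorTrace, burn_in: Optional[int] = None,
                 thin: Optional[int] = None) -> dict:
    """Direction-specific edge frequencies over retained snapshots.

    ``burn_in``/``thin`` default to the values the trace was recorded
    with; a larger burn-in or coarser thinning re-filters the stored
    snapshots.  Every candidate edge is present in the result (absent
    candidates get weight 0.0).
    """
    if burn_in is None:
        burn_in = trace.burn_in
    if burn_in >= trace.n_iterations:
        raise ValueError(
            f"burn_in {burn_in} must be smaller than the trace span "
            f"({trace.n_iterations} iterations)")
    kept = [r for r in trace.records if r.iteration > burn_in]
    if thin is not None:
        stride = max(1, int(thin) // max(1, trace.thin))
        kept = kept[::stride]
    counts = np.zeros(len(trace.edge_list))
    for rec in kept:
        for k in rec.edge_indices:
            counts[k] += 1
    denom = max(1, len(kept))
    return {e: float(counts[k]) / denom for k, e in enumerate(trace.edge_list)}


def threshold_edges(weights: Mapping, mode: str = "quantile",
                    value: float = 0.75) -> set:
    """Retain edges with weight at or above a threshold.

    ``quantile`` mode computes the value-quantile (linear interpolation)
    of the *nonzero* weights; ``absolute`` mode uses the value directly.
    Ties at the threshold are retained.
    """
    if not len(weights):
        raise ValueError("empty weight mapping")
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"threshold value {value} outside [0, 1]")
    if mode == "quantile":
        nonzero = np.asarray([w for w in weights.values() if w > 0.0])
        if nonzero.size == 0:
            return set()
        thr = float(np.quantile(nonzero, value))
    elif mode == "absolute":
        thr = value
    else:
        raise ValueError(f"unknown threshold mode {mode!r}")
    return {e for e, w in weights.items() if w >= thr and w > 0.0}


# ---------------------------------------------------------------------------
# CPDAG


@dataclass
class EdgeRecord:
    parent: str
    child: str
    weight: float
    directed: bool
    in_pk: bool = False


@dataclass
class WeightedNetwork:
    """Thresholded CPDAG with edge weights.

    ``directed=False`` edges are reversible within the equivalence class;
    they are stored with canonically (lexicographically) ordered endpoints
    so all members of one class map to the identical object.
    """

    nodes: list  # (id, layer, symbol)
    edges: list  # EdgeRecord

    def canonical(self) -> "WeightedNetwork":
        nodes = sorted(self.nodes)
        edges = []
        for e in self.edges:
            if not e.directed and e.parent > e.child:
                e = EdgeRecord(e.child, e.parent, e.weight, False, e.in_pk)
            edges.append(e)
        edges.sort(key=lambda e: (e.parent, e.child, e.directed))
        return WeightedNetwork(nodes=nodes, edges=edges)

    def __eq__(self, other):
        if not isinstance(other, WeightedNetwork):
            return NotImplemented
        a, b = self.canonical(), other.canonical()
        return a.nodes == b.nodes and a.edges == b.edges


def _meek_closure(nodes, skeleton: set, directed: set) -> set:
    """Close a pattern under Meek's orientation rules.

    ``skeleton``: frozenset pairs; ``directed``: oriented subset (v-structure
    members plus layer background knowledge).  Returns the full directed set;
    remaining skeleton edges are reversible.
    """
    adj = {n: set() for n in nodes}
    for pair in skeleton:
        a, b = tuple(pair)
        adj[a].add(b)
        adj[b].add(a)
    directed = set(directed)

    def undirected(a, b):
        return (frozenset((a, b)) in skeleton
                and (a, b) not in directed and (b, a) not in directed)

    changed = True
    while changed:
        changed = False
        for pair in skeleton:
            for a, b in (tuple(pair), tuple(pair)[::-1]):
                if not undirected(a, b):
                    continue
                oriented = False
                # R1: c -> a, a - b, c not adjacent to b  =>  a -> b
                for c in adj[a]:
                    if (c, a) in directed and b not in adj[c] and c != b:
                        oriented = True
                        break
                # R2: a -> c -> b and a - b  =>  a -> b
                if not oriented:
                    for c in adj[a] & adj[b]:
                        if (a, c) in directed and (c, b) in directed:
                            oriented = True
                            break
                # R3: a - c -> b, a - d -> b, c,d nonadjacent  =>  a -> b
                if not oriented:
                    cand = [c for c in adj[a] & adj[b]
                            if undirected(a, c) and (c, b) in directed]
                    for i in range(len(cand)):
                        for j in range(i + 1, len(cand)):
                            if cand[j] not in adj[cand[i]]:
                                oriented = True
                                break
                        if oriented:
                            break
                # R4: d -> c -> b, a - d, b,d nonadjacent  =>  a -> b
                if not oriented:
                    for d in adj[a]:
                        if d == b or not undirected(a, d) or b in adj[d]:
                            continue
                        for c in adj[d] & adj[b]:
                            if (d, c) in directed and (c, b) in directed:
                                oriented = True
                                break
                        if oriented:
                            break
                if oriented:
                    directed.add((a, b))
                    changed = True
    return directed


def cpdag_edges(g: NetworkStructure) -> list[tuple[str, str, bool]]:
    """Compelled/reversible labels for every edge of a DAG.

    Initial orientations are the v-structure members plus all inter-layer
    (CNV/METH → GE) edges, whose reversal lies outside the candidate
    space; Meek's rules propagate them.  Returns (parent, child, compelled)
    with the DAG's own orientation for reversible edges.
    """
    if not g.is_acyclic():
        raise ContractError("CPDAG computation requires a DAG")
    nodes = [n.id for n in g.nodes]
    skeleton = {frozenset(e) for e in g.edges}
    parents = {n: set() for n in nodes}
    for u, v in g.edges:
        parents[v].add(u)
    directed = set()
    for z in nodes:
        ps = sorted(parents[z])
        for i in range(len(ps)):
            for j in range(i + 1, len(ps)):
                x, y = ps[i], ps[j]
                if (frozenset((x, y)) not in skeleton):
                    directed.add((x, z))
                    directed.add((y, z))
    for u, v in g.edges:
        if g.layer_of(u) != GE:
            directed.add((u, v))
    directed = _meek_closure(nodes, skeleton, directed)
    out = []
    for u, v in g.edges:
        out.append((u, v, (u, v) in directed))
    return out


def to_cpdag(g: NetworkStructure, weights: Optional[Mapping] = None,
             symbols: Optional[Mapping] = None) -> WeightedNetwork:
    """CPDAG of a DAG as a :class:`WeightedNetwork` skeleton.

    For reversible (undirected) edges the reported weight is the skeleton
    weight: the combined frequency of either direction.
    """
    labelled = cpdag_edges(g)
    symbols = symbols or {}
    nodes = [(n.id, n.layer, symbols.get(n.id, n.id)) for n in g.nodes]
    edges = []
    for u, v, compelled in labelled:
        if weights is None:
            w = 1.0
        elif compelled:
            w = float(weights.get((u, v), 0.0))
        else:
            w = float(min(1.0, weights.get((u, v), 0.0)
                          + weights.get((v, u), 0.0)))
        edges.append(EdgeRecord(u, v, w, compelled))
    return WeightedNetwork(nodes=nodes, edges=edges).canonical()


def build_weighted_network(weights: Mapping, candidates: CandidateEdgeSet,
                           retained: Optional[Iterable] = None,
                           pk: Optional[PriorKnowledgeTable] = None,
                           symbols: Optional[Mapping] = None,
                           cpdag: bool = True) -> WeightedNetwork:
    """Weighted network over the retained edges, CPDAG-labelled if a DAG.

    ``retained`` defaults to all nonzero-weight edges.  When the retained
    edge set is cyclic (possible after thresholding), CPDAG labelling is
    skipped and all edges stay directed.
    """
    if retained is None:
        retained = {e for e, w in weights.items() if w > 0.0}
    retained = set(retained)
    pk_pairs = set()
    if pk is not None and len(pk):
        present = pk.records[pk.records["edge_type"] == "present"]
        pk_pairs = set(zip(present["src_gene"], present["dst_gene"]))
    used_nodes = {u for u, _ in retained} | {v for _, v in retained}
    nodes = [n for n in candidates.nodes if n.id in used_nodes]
    g = NetworkStructure(nodes=tuple(nodes), edges=set(retained))
    if cpdag and g.is_acyclic():
        net = to_cpdag(g, weights=weights, symbols=symbols)
        for e in net.edges:
            e.in_pk = (e.parent, e.child) in pk_pairs or (
                not e.directed and (e.child, e.parent) in pk_pairs)
        return net
    symbols = symbols or {}
    edges = [EdgeRecord(u, v, float(weights.get((u, v), 0.0)), True,
                        (u, v) in pk_pairs)
             for u, v in sorted(retained)]
    node_rows = [(n.id, n.layer, symbols.get(n.id, n.id)) for n in nodes]
    return WeightedNetwork(nodes=node_rows, edges=edges).canonical()


# ---------------------------------------------------------------------------
# convergence diagnostics


@dataclass
class ConvergenceReport:
    converged: bool
    changepoints: list  # iteration numbers
    minseglen: int
    n_snapshots: int
    stats: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "converged": self.converged,
            "changepoints": self.changepoints,
            "minseglen": self.minseglen,
            "n_snapshots": self.n_snapshots,
            "stats": self.stats,
        }, indent=2))


def _binseg(x: np.ndarray, minseg: int, penalty: float) -> list[int]:
    """Binary segmentation for mean shifts on a 1-d series.

    Splits whenever the within-segment sum-of-squares reduction exceeds
    ``penalty``; segments never get shorter than ``minseg`` points.
    """
    def sse(lo, hi):  # [lo, hi)
        seg = x[lo:hi]
        if len(seg) == 0:
            return 0.0
        return float(np.sum((seg - seg.mean()) ** 2))

    out: list[int] = []

    def recurse(lo, hi):
        n = hi - lo
        if n < 2 * minseg:
            return
        total = sse(lo, hi)
        seg = x[lo:hi]
        csum = np.cumsum(seg)
        csq = np.cumsum(seg ** 2)
        best_gain, best_t = -np.inf, None
        for t in range(minseg, n - minseg + 1):
            left = csq[t - 1] - csum[t - 1] ** 2 / t
            right = (csq[-1] - csq[t - 1]) - (csum[-1] - csum[t - 1]) ** 2 / (n - t)
            gain = total - left - right
            if gain > best_gain:
                best_gain, best_t = gain, t
        if best_t is not None and best_gain > penalty:
            split = lo + best_t
            out.append(split)
            recurse(lo, split)
            recurse(split, hi)

    recurse(0, len(x))
    return sorted(out)


def convergence_check(trace: PosteriorTrace, minseglen: int) -> ConvergenceReport:
    """Mean-shift changepoint scan of the post-burn-in log-posterior.

    Operates on the snapshot-level series; the minimum segment length is
    ``minseglen`` iterations, i.e. ``minseglen / thin`` snapshots.  The
    penalty is 2·log(n)·var̂ with var̂ the half mean squared successive
    difference (robust to mean shifts).  Converged = no changepoint.
    """
    if minseglen <= 0:
        raise ValueError("minseglen must be positive")
    if trace.n_iterations <= 2 * minseglen:
        raise ValueError(
            f"trace span {trace.n_iterations} must exceed 2*minseglen "
            f"({2 * minseglen})")
    series = np.asarray([r.log_score + r.log_prior for r in trace.records])
    n = len(series)
    minseg = max(1, int(minseglen) // max(1, trace.thin))
    if n < 2 * minseg:
        raise ValueError("too few snapshots for the requested minseglen")
    if n > 1:
        var_hat = 0.5 * float(np.mean(np.diff(series) ** 2))
    else:
        var_hat = 0.0
    penalty = 2.0 * math.log(max(2, n)) * var_hat
    splits = _binseg(series, minseg, penalty)
    changepoints = [int(trace.records[t].iteration) for t in splits]
    return ConvergenceReport(
        converged=len(changepoints) == 0,
        changepoints=changepoints,
        minseglen=int(minseglen),
        n_snapshots=n,
        stats={
            "mean_log_posterior": float(series.mean()) if n else float("nan"),
            "sd_log_posterior": float(series.std()) if n else float("nan"),
            "penalty": penalty,
        },
    )


# ---------------------------------------------------------------------------
# export


_TSV_COLUMNS = ["parent", "parent_layer", "child", "child_layer",
                "weight", "directed", "in_pk"]


def export_network(net: WeightedNetwork, fmt: str, path) -> None:
    """Write a weighted network as edge-list TSV, GraphML or SIF."""
    net = net.canonical()
    layer_of = {nid: lay for nid, lay, _ in net.nodes}
    try:
        if fmt == "tsv":
            rows = [(e.parent, layer_of[e.parent], e.child, layer_of[e.child],
                     e.weight, e.directed, e.in_pk) for e in net.edges]
            pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(
                path, sep="\t", index=False)
        elif fmt == "graphml":
            import networkx as nx

            g = nx.DiGraph()
            for nid, lay, sym in net.nodes:
                g.add_node(nid, layer=lay, symbol=sym)
            for e in net.edges:
                g.add_edge(e.parent, e.child, weight=e.weight,
                           directed=e.directed, in_pk=e.in_pk)
            nx.write_graphml(g, path)
        elif fmt == "sif":
            lines = [f"{e.parent}\t{layer_of[e.parent]}-{layer_of[e.child]}\t{e.child}"
                     for e in net.edges]
            Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
        else:
            raise ValueError(f"unknown export format {fmt!r}")
    except OSError as exc:
        raise OSError(f"failed to write network to {path}: {exc}") from exc


def read_network_tsv(path) -> WeightedNetwork:
    """Inverse of the TSV export (node symbols default to their ids)."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != _TSV_COLUMNS:
        raise ContractError(f"unexpected network TSV columns in {path}")
    nodes = {}
    edges = []
    for _, r in df.iterrows():
        nodes[r["parent"]] = (r["parent"], r["parent_layer"], r["parent"])
        nodes[r["child"]] = (r["child"], r["child_layer"], r["child"])
        edges.append(EdgeRecord(r["parent"], r["child"], float(r["weight"]),
                                bool(r["directed"]), bool(r["in_pk"])))
    return WeightedNetwork(nodes=sorted(nodes.values()), edges=edges).canonical()


# ---------------------------------------------------------------------------
# plots (never affect numeric outputs)


def trace_plot(trace: PosteriorTrace, path, burn_in: Optional[int] = None,
               changepoints: Optional[list] = None) -> None:
    """Log-posterior and β traces with burn-in / changepoint markers."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    burn_in = trace.burn_in if burn_in is None else burn_in
    fig, axes = plt.subplots(2, 1, figsize=(8, 6), sharex=True)
    it = np.arange(1, trace.n_iterations + 1)
    axes[0].plot(it, trace.log_posterior, lw=0.5)
    axes[0].axvline(burn_in, color="red", ls="--", label="burn-in")
    for cp in changepoints or []:
        axes[0].axvline(cp, color="orange", ls=":")
    axes[0].set_ylabel("log posterior")
    axes[0].legend(loc="lower right")
    axes[1].plot(it, trace.beta_series, lw=0.5, color="tab:green")
    axes[1].set_ylabel("beta")
    axes[1].set_xlabel("iteration")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


_LAYER_COLORS = {"GE": "tab:blue", "CNV": "tab:orange", "METH": "tab:green"}


def network_layout(net: WeightedNetwork, seed: int = 0) -> dict:
    """Deterministic layered layout (GE centre, CNV above, METH below)."""
    import networkx as nx

    g = nx.Graph()
    order = {"CNV": 0, "GE": 1, "METH": 2}
    for nid, lay, _ in sorted(net.nodes):
        g.add_node(nid, subset=order.get(lay, 1))
    for e in net.edges:
        g.add_edge(e.parent, e.child)
    return nx.multipartite_layout(g, subset_key="subset", align="horizontal")


def network_plot(net: WeightedNetwork, path, seed: int = 0) -> None:
    """Layered rendering; node colour encodes the omics layer."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.lines import Line2D

    pos = network_layout(net, seed=seed)
    fig, ax = plt.subplots(figsize=(8, 6))
    layer_of = {nid: lay for nid, lay, _ in net.nodes}
    for nid, (x, y) in pos.items():
        ax.scatter([x], [y], s=450, c=_LAYER_COLORS.get(layer_of[nid], "gray"),
                   zorder=2, edgecolors="black")
        ax.annotate(nid, (x, y), ha="center", va="center", fontsize=7, zorder=3)
    for e in net.edges:
        x0, y0 = pos[e.parent]
        x1, y1 = pos[e.child]
        style = "-|>" if e.directed else "-"
        ax.annotate("", xy=(x1, y1), xytext=(x0, y0),
                    arrowprops=dict(arrowstyle=style, lw=0.5 + 2.5 * e.weight,
                                    color="black", alpha=0.6,
                                    shrinkA=12, shrinkB=12))
    layers_present = sorted({lay for _, lay, _ in net.nodes},
                            key=["GE", "CNV", "METH"].index)
    handles = [Line2D([], [], marker="o", ls="", color=_LAYER_COLORS[l], label=l)
               for l in layers_present]
    ax.legend(handles=handles, loc="upper right")
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
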