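"""Ground-truth layered networks and matched synthetic omics datasets.

Data are drawn from linear-Gaussian structural equations on a known
layered DAG, the model family under which the BGe score is well posed:
root nodes (CNV, METH and parentless GE) are standard normal, every other
GE node is a linear combination of its parents plus Gaussian noise.
Coefficients are bounded away from zero so effects stay detectable at
test sample sizes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .datasets import (
    GE,
    CNV,
    METH,
    CandidateEdgeSet,
    FeatureAnnotation,
    LayerDefinition,
    Node,
    OmicsDataset,
    cnv_node_id,
    enumerate_candidate_edges,
)
from .errors import ConfigurationError
from .network import NetworkStructure
from .priors import PriorKnowledgeTable

__all__ = ["GroundTruth", "generate_true_network", "simulate_dataset",
           "corrupt_prior"]

MIN_COEF = 0.2  # coefficients are drawn from ±[0.5, 1.5], well above this floor


@dataclass
class GroundTruth:
    """A known layered DAG with edge coefficients and per-node noise."""

    structure: NetworkStructure
    coefficients: dict  # (u, v) -> nonzero float
    noise_sd: dict  # node id -> float
    annotation: FeatureAnnotation
    noise_probes: tuple  # probe ids present in METH but independent of all
    seed: int

    def __post_init__(self):
        for e, c in self.coefficients.items():
            if abs(c) < MIN_COEF:
                raise ConfigurationError(f"coefficient for {e} below {MIN_COEF}")

    @property
    def genes(self) -> list[str]:
        return [n.id for n in self.structure.nodes if n.layer == GE]

    @property
    def ge_edges(self) -> set:
        return {(u, v) for u, v in self.structure.edges
                if self.structure.layer_of(u) == GE}

    def true_edge_set(self) -> set:
        return set(self.structure.edges)

    def layer_definition(self, ge_fan_in: int = 3) -> LayerDefinition:
        layers = [(GE, ge_fan_in)]
        if any(n.layer == CNV for n in self.structure.nodes):
            layers.append((CNV, 1))
        if any(n.layer == METH for n in self.structure.nodes) or self.noise_probes:
            layers.append((METH, 3))
        return LayerDefinition(tuple(layers))

    def save(self, edges_path, meta_path) -> None:
        rows = [(u, self.structure.layer_of(u), v, self.coefficients[(u, v)])
                for u, v in sorted(self.structure.edges)]
        pd.DataFrame(rows, columns=["parent", "parent_layer", "child",
                                    "coefficient"]).to_csv(
            edges_path, sep="\t", index=False)
        Path(meta_path).write_text(json.dumps({
            "seed": self.seed,
            "genes": self.genes,
            "noise_sd": self.noise_sd,
            "noise_probes": list(self.noise_probes),
            "probe_to_gene": self.annotation.probe_to_gene,
        }, indent=2))


def generate_true_network(n_genes: int, edge_prob: float = 0.2,
                          p_cnv: float = 0.0, probes_per_gene: int = 0,
                          fan_in_max: int = 3, seed: int = 0,
                          noise_probes_per_gene: int = 0,
                          max_retries: int = 1000) -> GroundTruth:
    """Sample a random layered ground-truth network.

    A uniform random topological order over the GE genes is drawn, then
    each forward pair receives an edge with probability ``edge_prob``;
    draws violating the GE fan-in limit are rejected and redrawn (up to
    ``max_retries``).  Each gene gets a CNV parent with probability
    ``p_cnv`` and ``probes_per_gene`` methylation parents;
    ``noise_probes_per_gene`` additional probes are annotated to the gene
    but causally unconnected.  Coefficients are uniform on ±[0.5, 1.5],
    noise standard deviations uniform on [0.5, 1].
    """
    if n_genes < 1:
        raise ConfigurationError("n_genes must be positive")
    if not 0.0 <= edge_prob <= 1.0 or not 0.0 <= p_cnv <= 1.0:
        raise ConfigurationError("edge_prob and p_cnv must lie in [0,1]")
    rng = np.random.default_rng(seed)
    width = len(str(max(n_genes, 1)))
    genes = [f"G{k:0{width}d}" for k in range(1, n_genes + 1)]

    ge_edges = None
    for _ in range(max_retries):
        order = list(rng.permutation(n_genes))
        trial = []
        indeg = np.zeros(n_genes, dtype=int)
        ok = True
        for i in range(n_genes):
            for j in range(i + 1, n_genes):
                if rng.random() < edge_prob:
                    trial.append((genes[order[i]], genes[order[j]]))
                    indeg[order[j]] += 1
        if np.all(indeg <= fan_in_max):
            ge_edges = trial
            break
    if ge_edges is None:
        raise ConfigurationError(
            f"could not draw a network obeying fan_in_max={fan_in_max} "
            f"within {max_retries} retries; lower edge_prob")

    nodes = [Node(g, GE) for g in genes]
    edges = set(ge_edges)
    probe_to_gene = {}
    noise_probes = []
    probe_counter = 1
    for g in genes:
        if rng.random() < p_cnv:
            nodes.append(Node(cnv_node_id(g), CNV))
            edges.add((cnv_node_id(g), g))
    for g in genes:
        for _ in range(probes_per_gene):
            p = f"cg{probe_counter:05d}"
            probe_counter += 1
            probe_to_gene[p] = g
            nodes.append(Node(p, METH))
            edges.add((p, g))
        for _ in range(noise_probes_per_gene):
            p = f"cg{probe_counter:05d}"
            probe_counter += 1
            probe_to_gene[p] = g
            noise_probes.append(p)

    coefficients = {}
    for e in sorted(edges):
        coefficients[e] = float(rng.uniform(0.5, 1.5) * rng.choice([-1.0, 1.0]))
    noise_sd = {g: float(rng.uniform(0.5, 1.0)) for g in genes}

    structure = NetworkStructure(nodes=tuple(nodes), edges=edges)
    annotation = FeatureAnnotation(probe_to_gene=probe_to_gene)
    return GroundTruth(structure=structure, coefficients=coefficients,
                       noise_sd=noise_sd, annotation=annotation,
                       noise_probes=tuple(noise_probes), seed=seed)


def simulate_dataset(gt: GroundTruth, n_samples: int, seed: int = 0
                     ) -> OmicsDataset:
    """Draw samples from the ground truth's structural equations."""
    if n_samples < 3:
        raise ConfigurationError("n_samples must be at least 3")
    rng = np.random.default_rng(seed)
    g = gt.structure
    genes = gt.genes
    cnv_nodes = [n.id for n in g.nodes if n.layer == CNV]
    meth_nodes = [n.id for n in g.nodes if n.layer == METH]

    values: dict[str, np.ndarray] = {}
    for nid in cnv_nodes + meth_nodes:
        values[nid] = rng.standard_normal(n_samples)
    # evaluate GE nodes in (deterministic) topological order of the GE subgraph
    parents = {gname: sorted(g.parents_of(gname)) for gname in genes}
    remaining = set(genes)
    topo: list[str] = []
    while remaining:
        ready = [gname for gname in sorted(remaining)
                 if not any(p in remaining for p in parents[gname])]
        if not ready:
            raise ConfigurationError("ground-truth GE subgraph is cyclic")
        topo.extend(ready)
        remaining -= set(ready)
    for gname in topo:
        x = rng.standard_normal(n_samples) * gt.noise_sd[gname]
        for p in parents[gname]:
            x = x + gt.coefficients[(p, gname)] * values[p]
        values[gname] = x

    samples = [f"S{k:04d}" for k in range(1, n_samples + 1)]
    ge = pd.DataFrame({gname: values[gname] for gname in genes}, index=samples)
    cnv = None
    if cnv_nodes:
        cnv = pd.DataFrame(
            {nid[len("cnv_"):]: values[nid] for nid in cnv_nodes}, index=samples)
    meth = None
    all_probes = meth_nodes + list(gt.noise_probes)
    if all_probes:
        cols = {}
        for p in meth_nodes:
            cols[p] = values[p]
        for p in gt.noise_probes:
            cols[p] = rng.standard_normal(n_samples)
        meth = pd.DataFrame({p: cols[p] for p in sorted(cols)}, index=samples)
    ds = OmicsDataset(ge=ge, cnv=cnv, meth=meth, annotation=gt.annotation)
    return ds.validate()


def corrupt_prior(gt: GroundTruth, true_frac: float, false_frac: float,
                  seed: int = 0) -> PriorKnowledgeTable:
    """Prior-knowledge table mixing true edges with misinformation.

    Emits floor(true_frac·|true GE edges|) true GE→GE edges as "present"
    plus floor(false_frac·|true GE edges|) random GE→GE non-edges as
    "present".
    """
    if not 0.0 <= true_frac <= 1.0 or not 0.0 <= false_frac <= 1.0:
        raise ConfigurationError("fractions must lie in [0,1]")
    rng = np.random.default_rng(seed)
    true_edges = sorted(gt.ge_edges)
    genes = gt.genes
    non_edges = sorted(
        {(a, b) for a in genes for b in genes if a != b} - set(true_edges))
    n_true = int(len(true_edges) * true_frac)
    n_false = int(len(true_edges) * false_frac)
    rows = []
    if n_true:
        picks = rng.choice(len(true_edges), size=n_true, replace=False)
        rows += [true_edges[i] for i in sorted(picks)]
    if n_false:
        picks = rng.choice(len(non_edges), size=min(n_false, len(non_edges)),
                           replace=False)
        rows += [non_edges[i] for i in sorted(picks)]
    if not rows:
        return PriorKnowledgeTable.empty()
    return PriorKnowledgeTable.from_edges(rows, "present")
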