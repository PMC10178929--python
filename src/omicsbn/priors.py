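"""Biological prior knowledge: the prior matrix B and the structure prior.

Curated interactions and TF→target tables give per-candidate-edge beliefs
b(i,j) ∈ [0,1].  A structure g is scored against the beliefs through the
energy

    E(g) = Σ_(i,j) |b(i,j) − a(i,j)|,   a(i,j) = 1 if the edge is in g,

and the structure prior p(g | β) ∝ exp(−β·E(g)), with inverse temperature
β controlling how strongly the beliefs bind the sampler.  The normaliser
is approximated edge-factorised (acyclicity ignored):

    Ẑ(β) = Π_(i,j) [exp(−β·b(i,j)) + exp(−β·(1 − b(i,j)))],

which is what makes sampling β by Metropolis–Hastings cheap.  Candidate
edges with no curated information start at b = 0.5 and are later replaced
by empirical frequencies estimated from a first MCMC phase.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .datasets import CandidateEdgeSet
from .errors import ContractError, ParseError
from .network import NetworkStructure

logger = logging.getLogger(__name__)

EPSILON = 0.01  # belief clamp: no structure gets prior probability zero

CURATED = "curated"
TF_TARGET = "tf_target"
EMPIRICAL = "empirical"
DEFAULT = "default"


@dataclass
class PriorKnowledgeTable:
    """Curated interactions: (src gene, dst gene, present/absent)."""

    records: pd.DataFrame  # columns src_gene, dst_gene, edge_type

    def __post_init__(self):
        need = {"src_gene", "dst_gene", "edge_type"}
        if not need.issubset(self.records.columns):
            raise ParseError(f"prior-knowledge table needs columns {sorted(need)}")
        bad = ~self.records["edge_type"].isin(["present", "absent"])
        if bad.any():
            vals = sorted(self.records.loc[bad, "edge_type"].unique())
            raise ParseError(f"malformed edge_type values: {vals}")
        if (self.records["src_gene"] == self.records["dst_gene"]).any():
            raise ParseError("prior-knowledge self-loops are not allowed")
        if self.records.duplicated(["src_gene", "dst_gene"]).any():
            raise ParseError("duplicate (src,dst) pairs in prior knowledge")

    @classmethod
    def empty(cls) -> "PriorKnowledgeTable":
        return cls(pd.DataFrame(columns=["src_gene", "dst_gene", "edge_type"]))

    @classmethod
    def from_tsv(cls, path) -> "PriorKnowledgeTable":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    @classmethod
    def from_edges(cls, edges, edge_type: str = "present") -> "PriorKnowledgeTable":
        df = pd.DataFrame(list(edges), columns=["src_gene", "dst_gene"])
        df["edge_type"] = edge_type
        return cls(df)

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class BiologicalPriorMatrix:
    """Per-candidate-edge prior belief with provenance flags."""

    b: dict
    provenance: dict
    candidates: CandidateEdgeSet

    def __post_init__(self):
        if set(self.b) != set(self.candidates.edges):
            raise ContractError("prior matrix domain must equal the candidate set")
        for e, val in self.b.items():
            if not 0.0 <= val <= 1.0:
                raise ContractError(f"belief outside [0,1] for edge {e}: {val}")

    def copy(self) -> "BiologicalPriorMatrix":
        return BiologicalPriorMatrix(dict(self.b), dict(self.provenance),
                                     self.candidates)

    def __getitem__(self, edge):
        return self.b[edge]

    def values_for(self, edges) -> np.ndarray:
        return np.asarray([self.b[e] for e in edges], float)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (u, self.candidates.layer_of(u), v, self.candidates.layer_of(v),
             self.b[(u, v)], self.provenance[(u, v)])
            for (u, v) in sorted(self.b)
        ]
        return pd.DataFrame(rows, columns=[
            "src", "src_layer", "dst", "dst_layer", "belief", "provenance"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def build_prior_matrix(pk: Optional[PriorKnowledgeTable],
                       candidates: CandidateEdgeSet,
                       tf_targets: Optional[pd.DataFrame] = None
                       ) -> BiologicalPriorMatrix:
    """Assemble B from curated edges and TF→target evidence.

    Curated present → 1−ε, curated absent → ε; TF→target pairs (columns
    ``TF``, ``target``) count as curated-present unless contradicted by an
    explicit curated entry; everything else starts at the uninformative 0.5.
    Rows naming genes outside the candidate node set are ignored (counted
    in a warning).
    """
    b = {e: 0.5 for e in candidates.edges}
    prov = {e: DEFAULT for e in candidates.edges}
    ignored = 0
    if tf_targets is not None and len(tf_targets):
        need = {"TF", "target"}
        if not need.issubset(tf_targets.columns):
            raise ParseError("TF-target table needs columns TF, target")
        for tf, tgt in zip(tf_targets["TF"], tf_targets["target"]):
            e = (tf, tgt)
            if e in b:
                b[e] = 1.0 - EPSILON
                prov[e] = TF_TARGET
            else:
                ignored += 1
    if pk is not None:
        for _, row in pk.records.iterrows():
            e = (row["src_gene"], row["dst_gene"])
            if e not in b:
                ignored += 1
                continue
            b[e] = 1.0 - EPSILON if row["edge_type"] == "present" else EPSILON
            prov[e] = CURATED
    if ignored:
        logger.warning("%d prior-knowledge rows reference non-candidate edges; ignored",
                       ignored)
    return BiologicalPriorMatrix(b=b, provenance=prov, candidates=candidates)


def graph_energy(g: NetworkStructure, b: BiologicalPriorMatrix) -> float:
    """Belief-mismatch energy E(g) = Σ |b(i,j) − a(i,j)| over candidates."""
    outside = set(g.edges) - set(b.candidates.edges)
    if outside:
        raise ContractError(f"structure edges outside the candidate set: {sorted(outside)}")
    total = 0.0
    for e, belief in b.b.items():
        a = 1.0 if e in g.edges else 0.0
        total += abs(belief - a)
    return total


def log_pseudo_z(beta: float, b_values: np.ndarray) -> float:
    """log Ẑ(β): edge-factorised pseudo partition function."""
    return float(np.sum(np.logaddexp(-beta * b_values, -beta * (1.0 - b_values))))


@dataclass
class PriorModel:
    """Prior matrix plus the inverse temperature of the structure prior."""

    b_matrix: BiologicalPriorMatrix
    beta: float = 1.0
    beta_max: float = 10.0
    sample_beta: bool = True

    def __post_init__(self):
        if not 0.0 <= self.beta <= self.beta_max:
            raise ContractError("beta must lie in [0, beta_max]")
        self._edge_order = sorted(self.b_matrix.b)
        self._b_values = self.b_matrix.values_for(self._edge_order)

    def refresh(self) -> None:
        """Recompute cached belief arrays after b_matrix is replaced."""
        self._edge_order = sorted(self.b_matrix.b)
        self._b_values = self.b_matrix.values_for(self._edge_order)

    @property
    def b_values(self) -> np.ndarray:
        return self._b_values

    def log_pseudo_z(self, beta: Optional[float] = None) -> float:
        return log_pseudo_z(self.beta if beta is None else beta, self._b_values)


def log_structure_prior(g: NetworkStructure, pm: PriorModel) -> float:
    """log p(g | β) = −β·E(g) − log Ẑ(β) (pseudo-normalised across β)."""
    return -pm.beta * graph_energy(g, pm.b_matrix) - pm.log_pseudo_z()


def empirical_prior_update(b: BiologicalPriorMatrix,
                           phase1_weights: Mapping) -> BiologicalPriorMatrix:
    """Replace uninformative entries with clamped phase-1 edge frequencies.

    Entries with provenance ``default`` become
    clamp(frequency, ε, 1−ε) with provenance ``empirical``; curated and
    TF-target entries are untouched.  Edges missing from ``phase1_weights``
    are treated as frequency 0.
    """
    out = b.copy()
    for e in out.b:
        if out.provenance[e] != DEFAULT:
            continue
        w = float(phase1_weights.get(e, 0.0))
        if not 0.0 <= w <= 1.0:
            raise ContractError(f"phase-1 weight outside [0,1] for edge {e}: {w}")
        out.b[e] = float(np.clip(w, EPSILON, 1.0 - EPSILON))
        out.provenance[e] = EMPIRICAL
    return out
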