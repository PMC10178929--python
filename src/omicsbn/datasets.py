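"""Loading, validation and preprocessing of multi-omics matrices.

The package works on up to three modalities measured on the same samples:
gene expression (GE), copy-number estimates (CNV) and DNA methylation
(METH).  Matrices are tab-separated text, samples in rows (first column is
the sample identifier), features in columns.  CNV columns are named after
genes; METH columns are probe identifiers that map to genes through an
annotation table.

Candidate regulatory edges are layered: GE genes may regulate each other,
while CNV and METH nodes act only as cis covariates of their own gene's
expression.  Edges from GE into the CNV/METH layers are never candidates.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    AlignmentError,
    ConfigurationError,
    InsufficientDataError,
    ParseError,
)

logger = logging.getLogger(__name__)

GE = "GE"
CNV = "CNV"
METH = "METH"
LAYERS = (GE, CNV, METH)

#: prefix distinguishing CNV node ids from the gene's expression node
CNV_PREFIX = "cnv_"


class Node(NamedTuple):
    """A typed network node: a feature identifier plus its omics layer."""

    id: str
    layer: str


def cnv_node_id(gene: str) -> str:
    return CNV_PREFIX + gene


@dataclass
class FeatureAnnotation:
    """Maps methylation probes to genes and genes to display symbols."""

    probe_to_gene: dict[str, str] = field(default_factory=dict)
    gene_symbol_map: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_tsv(cls, annot_path, gene_annot_path=None) -> "FeatureAnnotation":
        """Read probe→gene (columns probe_id, gene_id) and optional
        gene→symbol (gene_id, gene_symbol) tables."""
        probe_to_gene: dict[str, str] = {}
        if annot_path is not None:
            tab = pd.read_csv(annot_path, sep="\t", dtype=str)
            need = {"probe_id", "gene_id"}
            if not need.issubset(tab.columns):
                raise ParseError(
                    f"annotation {annot_path} must have columns {sorted(need)}"
                )
            dup = tab["probe_id"].duplicated()
            if dup.any():
                bad = sorted(tab.loc[dup, "probe_id"].unique())
                raise ParseError(f"probes mapped to more than one gene: {bad}")
            probe_to_gene = dict(zip(tab["probe_id"], tab["gene_id"]))
        symbols: dict[str, str] = {}
        if gene_annot_path is not None:
            gt = pd.read_csv(gene_annot_path, sep="\t", dtype=str)
            symbols = dict(zip(gt["gene_id"], gt["gene_symbol"]))
        return cls(probe_to_gene=probe_to_gene, gene_symbol_map=symbols)

    def symbol(self, gene: str) -> str:
        return self.gene_symbol_map.get(gene, gene)


@dataclass
class OmicsDataset:
    """Aligned continuous matrices for up to three modalities.

    All present matrices share the same samples in the same row order and
    contain no missing values; these invariants are established by
    :func:`load_omics` / :meth:`validate`.
    """

    ge: pd.DataFrame
    cnv: Optional[pd.DataFrame] = None
    meth: Optional[pd.DataFrame] = None
    annotation: Optional[FeatureAnnotation] = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.ge.index)

    @property
    def n_samples(self) -> int:
        return self.ge.shape[0]

    @property
    def genes(self) -> list[str]:
        return list(self.ge.columns)

    @property
    def probes(self) -> list[str]:
        return [] if self.meth is None else list(self.meth.columns)

    def modalities(self) -> list[str]:
        mods = [GE]
        if self.cnv is not None:
            mods.append(CNV)
        if self.meth is not None:
            mods.append(METH)
        return mods

    def feature_names(self, layer: str) -> list[str]:
        if layer == GE:
            return self.genes
        if layer == CNV:
            return [] if self.cnv is None else list(self.cnv.columns)
        if layer == METH:
            return self.probes
        raise KeyError(layer)

    def node_column(self, node: Node) -> np.ndarray:
        """Data column for a typed node (CNV ids carry the cnv_ prefix)."""
        if node.layer == GE:
            return self.ge[node.id].to_numpy(float)
        if node.layer == CNV:
            gene = node.id[len(CNV_PREFIX):]
            return self.cnv[gene].to_numpy(float)
        if node.layer == METH:
            return self.meth[node.id].to_numpy(float)
        raise KeyError(node.layer)

    def validate(self) -> "OmicsDataset":
        for name, mat in (("ge", self.ge), ("cnv", self.cnv), ("meth", self.meth)):
            if mat is None:
                continue
            if mat.isna().any().any():
                rows = mat.index[mat.isna().any(axis=1)].tolist()
                raise ParseError(
                    f"{name} matrix contains missing values (samples {rows}); "
                    "pre-impute or drop these samples"
                )
            if not all(np.issubdtype(dt, np.number) for dt in mat.dtypes):
                bad = [c for c, dt in mat.dtypes.items() if not np.issubdtype(dt, np.number)]
                raise ParseError(f"{name} matrix has non-numeric columns {bad}")
        for name, mat in (("cnv", self.cnv), ("meth", self.meth)):
            if mat is None:
                continue
            if list(mat.index) != self.sample_ids:
                raise AlignmentError(
                    f"{name} matrix rows are not aligned with the GE matrix"
                )
        if self.cnv is not None:
            extra = set(self.cnv.columns) - set(self.ge.columns)
            if extra:
                raise AlignmentError(
                    f"CNV columns without a matching GE gene: {sorted(extra)}"
                )
        if self.meth is not None:
            if self.annotation is None:
                raise ConfigurationError(
                    "METH matrix present but no probe annotation supplied"
                )
        return self

    def drop_probes(self, probes: Iterable[str]) -> "OmicsDataset":
        """Copy of the dataset with the given METH probes removed."""
        drop = set(probes)
        meth = None
        if self.meth is not None:
            meth = self.meth.drop(columns=[p for p in self.meth.columns if p in drop])
        return OmicsDataset(self.ge.copy(), None if self.cnv is None else self.cnv.copy(),
                            meth, self.annotation)


def _read_matrix(path, what: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            row = bad[0] if len(bad) else "?"
            raise ParseError(
                f"non-numeric cell in {what} matrix {path} at row {row!r}, "
                f"column {col!r}"
            )
    return df


def load_omics(ge_path, cnv_path=None, meth_path=None, annot_path=None,
               gene_annot_path=None) -> OmicsDataset:
    """Load and sample-align TSV matrices into a validated dataset.

    Samples of the CNV/METH matrices are reordered to the GE row order;
    a sample present in one matrix and absent from another is an error.
    """
    ge = _read_matrix(ge_path, "GE")
    samples = list(ge.index)

    def align(df: pd.DataFrame, what: str) -> pd.DataFrame:
        missing = sorted(set(samples) - set(df.index))
        extra = sorted(set(df.index) - set(samples))
        if missing or extra:
            raise AlignmentError(
                f"sample mismatch between GE and {what}: "
                f"missing from {what}: {missing}; not in GE: {extra}"
            )
        return df.loc[samples]

    cnv = align(_read_matrix(cnv_path, "CNV"), "CNV") if cnv_path else None
    meth = align(_read_matrix(meth_path, "METH"), "METH") if meth_path else None

    annotation = None
    if annot_path is not None or gene_annot_path is not None:
        annotation = FeatureAnnotation.from_tsv(annot_path, gene_annot_path)
    if meth is not None and annotation is None:
        raise ConfigurationError("METH matrix requires a probe annotation table")
    if meth is not None:
        known = [p for p in meth.columns if p in annotation.probe_to_gene]
        unknown = [p for p in meth.columns if p not in annotation.probe_to_gene]
        if unknown:
            logger.warning("dropping %d unannotated METH probes: %s",
                           len(unknown), unknown[:10])
            meth = meth[known]
    return OmicsDataset(ge=ge, cnv=cnv, meth=meth, annotation=annotation).validate()


@dataclass(frozen=True)
class LayerDefinition:
    """Ordered omics layers with per-layer fan-in limits.

    ``fan_in`` maps layer name to the maximum number of parents a GE node
    may take *from that layer*.  The GE layer is always present.
    """

    layers: tuple[tuple[str, int], ...]

    def __post_init__(self):
        names = [n for n, _ in self.layers]
        if GE not in names:
            raise ConfigurationError("GE layer must always be present")
        for name, fi in self.layers:
            if name not in LAYERS:
                raise ConfigurationError(f"unknown layer {name!r}")
            if fi < 1:
                raise ConfigurationError(f"fan_in_max for {name} must be >= 1")

    @classmethod
    def for_dataset(cls, ds: OmicsDataset, ge_fan_in: int = 3,
                    cnv_fan_in: int = 1, meth_fan_in: int = 3) -> "LayerDefinition":
        layers = [(GE, ge_fan_in)]
        if ds.cnv is not None:
            layers.append((CNV, cnv_fan_in))
        if ds.meth is not None:
            layers.append((METH, meth_fan_in))
        return cls(tuple(layers))

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.layers]

    def fan_in(self, layer: str) -> int:
        for name, fi in self.layers:
            if name == layer:
                return fi
        raise KeyError(layer)


@dataclass
class CandidateEdgeSet:
    """The universe of directed edges the sampler may propose.

    GE→GE ordered pairs (no self loops), cnv_g→GE_g for genes with copy
    number data, and probe→GE_gene(probe) for retained methylation probes.
    CNV and METH nodes never have parents.
    """

    nodes: tuple[Node, ...]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self):
        self._layer = {n.id: n.layer for n in self.nodes}

    @property
    def node_ids(self) -> list[str]:
        return [n.id for n in self.nodes]

    def layer_of(self, node_id: str) -> str:
        return self._layer[node_id]

    def __contains__(self, edge: tuple[str, str]) -> bool:
        return edge in self.edges

    def __len__(self) -> int:
        return len(self.edges)

    def candidate_parents(self, node_id: str) -> dict[str, list[str]]:
        """Candidate parents of a node, grouped by the parent's layer."""
        if node_id not in self._layer:
            raise KeyError(f"unknown node {node_id!r}")
        out: dict[str, list[str]] = {}
        for u, v in self.edges:
            if v == node_id:
                out.setdefault(self._layer[u], []).append(u)
        for lay in out:
            out[lay].sort()
        return out


def enumerate_candidate_edges(ds: OmicsDataset, layers: LayerDefinition,
                              annot: Optional[FeatureAnnotation] = None
                              ) -> CandidateEdgeSet:
    """Build the layered candidate-edge universe for a dataset."""
    annot = annot if annot is not None else ds.annotation
    nodes = [Node(g, GE) for g in ds.genes]
    edges: set[tuple[str, str]] = set()
    for a, b in itertools.permutations(ds.genes, 2):
        edges.add((a, b))
    if ds.cnv is not None and CNV in layers.names:
        for g in ds.cnv.columns:
            nodes.append(Node(cnv_node_id(g), CNV))
            edges.add((cnv_node_id(g), g))
    if ds.meth is not None and METH in layers.names:
        if annot is None:
            raise ConfigurationError("METH candidate edges require annotation")
        for p in ds.meth.columns:
            gene = annot.probe_to_gene.get(p)
            if gene is None or gene not in ds.ge.columns:
                logger.warning("METH probe %s has no mapped gene in GE; skipped", p)
                continue
            nodes.append(Node(p, METH))
            edges.add((p, gene))
    return CandidateEdgeSet(nodes=tuple(nodes), edges=frozenset(edges))


def enumerate_parent_sets(node_id: str, candidates: CandidateEdgeSet,
                          layers: LayerDefinition) -> list[frozenset[str]]:
    """All legal parent sets of a node under the per-layer fan-in limits.

    Parents from each layer are limited by that layer's fan_in_max
    independently; CNV/METH nodes are roots and have only the empty set.
    """
    layer = candidates.layer_of(node_id)  # raises KeyError for unknown nodes
    if layer != GE:
        return [frozenset()]
    grouped = candidates.candidate_parents(node_id)
    per_layer_choices: list[list[tuple[str, ...]]] = []
    for lay in layers.names:
        pool = grouped.get(lay, [])
        limit = min(layers.fan_in(lay), len(pool))
        choices = [()]
        for k in range(1, limit + 1):
            choices.extend(itertools.combinations(pool, k))
        per_layer_choices.append(choices)
    out = []
    for combo in itertools.product(*per_layer_choices):
        out.append(frozenset(itertools.chain.from_iterable(combo)))
    return out


@dataclass
class MethFilterResult:
    """Outcome of the methylation-probe relevance filter."""

    records: pd.DataFrame  # probe_id, gene_id, r_squared, p_value, retained
    retained_probes: list[str]
    filtered_dataset: OmicsDataset
    r_squared_thres: float
    p_val_thres: float

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def filter_meth_probes(ds: OmicsDataset, annot: Optional[FeatureAnnotation] = None,
                       r_squared_thres: float = 0.3,
                       p_val_thres: float = 0.05) -> MethFilterResult:
    """Filter methylation probes by simple linear regression on expression.

    For each probe, the mapped gene's expression is regressed on the probe's
    methylation level; the probe is retained iff R² >= ``r_squared_thres``
    and the slope's two-sided p-value (t-test, n−2 df) <= ``p_val_thres``.
    Zero-variance probes and probes mapping to genes absent from GE are
    dropped with a warning.
    """
    annot = annot if annot is not None else ds.annotation
    if ds.meth is None:
        raise ConfigurationError("dataset has no METH matrix to filter")
    if annot is None:
        raise ConfigurationError("METH filtering requires a probe annotation")
    if ds.n_samples < 3:
        raise InsufficientDataError("METH filtering needs at least 3 samples")
    rows = []
    for probe in ds.meth.columns:
        gene = annot.probe_to_gene.get(probe)
        if gene is None or gene not in ds.ge.columns:
            logger.warning("probe %s maps to no gene present in GE; dropped", probe)
            continue
        x = ds.meth[probe].to_numpy(float)
        y = ds.ge[gene].to_numpy(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            logger.warning("probe %s (or its gene) has zero variance; dropped", probe)
            rows.append((probe, gene, 0.0, 1.0, False))
            continue
        fit = stats.linregress(x, y)
        r2 = fit.rvalue ** 2
        p = fit.pvalue
        retained = bool(r2 >= r_squared_thres and p <= p_val_thres)
        rows.append((probe, gene, r2, p, retained))
    records = pd.DataFrame(
        rows, columns=["probe_id", "gene_id", "r_squared", "p_value", "retained"]
    )
    retained_probes = records.loc[records["retained"], "probe_id"].tolist()
    dropped = [p for p in ds.meth.columns if p not in set(retained_probes)]
    filtered = ds.drop_probes(dropped)
    return MethFilterResult(
        records=records,
        retained_probes=retained_probes,
        filtered_dataset=filtered,
        r_squared_thres=r_squared_thres,
        p_val_thres=p_val_thres,
    )
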