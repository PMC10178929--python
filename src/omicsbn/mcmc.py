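"""Metropolis–Hastings (MC3-style) sampling over layered DAG structures.

The sampler walks the space of DAGs restricted to the layered candidate
edge set with single-edge moves (add / delete / reverse), proposing
uniformly from the legal neighborhood and correcting the acceptance ratio
by the neighborhood-size (Hastings) factor:

    A(g → g') = min(1, exp(Δ log BGe + Δ log prior) · |N(g)| / |N(g')|)

The prior's inverse temperature β is itself sampled by a reflected
uniform-step MH update once per structure sweep (every |nodes| proposals).

Sampling runs in two phases: phase 1 uses the curated/default prior matrix
and its edge frequencies provide *empirical* beliefs for candidate edges
without curated knowledge; phase 2 restarts from the phase-1 final
structure under the completed prior and produces the reported trace.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .bge import BGeHyperparameters, ScoreCache, default_hyperparameters
from .datasets import (
    GE,
    CNV,
    METH,
    CandidateEdgeSet,
    LayerDefinition,
    Node,
    OmicsDataset,
)
from .errors import ConfigurationError, SamplerStuckError
from .network import NetworkStructure
from .priors import (
    BiologicalPriorMatrix,
    PriorModel,
    empirical_prior_update,
    graph_energy,
    log_pseudo_z,
)

logger = logging.getLogger(__name__)

_LAYER_CODE = {GE: 0, CNV: 1, METH: 2}


@dataclass
class McmcSettings:
    """Iteration budget and chain options for :func:`run_mcmc`."""

    total_iterations: int
    burn_in: int = 0
    thin: int = 1
    seed: int = 0
    phase1_fraction: float = 0.5
    sample_beta: Optional[bool] = None  # None: defer to the PriorModel
    beta_init: Optional[float] = None

    def __post_init__(self):
        if self.total_iterations <= 0:
            raise ConfigurationError("total_iterations must be positive")
        if not 0 <= self.burn_in < self.total_iterations:
            raise ConfigurationError("burn_in must satisfy 0 <= burn_in < total_iterations")
        if self.thin < 1:
            raise ConfigurationError("thin must be >= 1")
        if not 0.0 <= self.phase1_fraction <= 1.0:
            raise ConfigurationError("phase1_fraction must lie in [0,1]")


@dataclass
class TraceRecord:
    """One retained structure snapshot."""

    iteration: int
    edge_indices: tuple[int, ...]
    log_score: float
    log_prior: float
    beta: float
    accepted: bool


@dataclass
class PosteriorTrace:
    """Snapshots plus per-iteration diagnostics from one sampling phase."""

    nodes: tuple[Node, ...]
    edge_list: tuple[tuple[str, str], ...]
    records: list[TraceRecord]
    log_posterior: np.ndarray  # per iteration
    beta_series: np.ndarray
    counters: dict
    seed: int
    burn_in: int
    thin: int
    phase: int

    @property
    def n_iterations(self) -> int:
        return len(self.log_posterior)

    def edges_of(self, record: TraceRecord) -> frozenset[tuple[str, str]]:
        return frozenset(self.edge_list[k] for k in record.edge_indices)

    def structure_of(self, record: TraceRecord) -> NetworkStructure:
        return NetworkStructure(nodes=self.nodes, edges=set(self.edges_of(record)))

    def structures(self):
        for rec in self.records:
            yield self.structure_of(rec)

    def to_json(self, path) -> None:
        payload = {
            "nodes": [[n.id, n.layer] for n in self.nodes],
            "edge_list": [list(e) for e in self.edge_list],
            "records": [
                [r.iteration, list(r.edge_indices), r.log_score, r.log_prior,
                 r.beta, r.accepted]
                for r in self.records
            ],
            "log_posterior": self.log_posterior.tolist(),
            "beta_series": self.beta_series.tolist(),
            "counters": self.counters,
            "seed": self.seed,
            "burn_in": self.burn_in,
            "thin": self.thin,
            "phase": self.phase,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "PosteriorTrace":
        payload = json.loads(Path(path).read_text())
        return cls(
            nodes=tuple(Node(i, l) for i, l in payload["nodes"]),
            edge_list=tuple((u, v) for u, v in payload["edge_list"]),
            records=[TraceRecord(it, tuple(idx), ls, lp, b, bool(acc))
                     for it, idx, ls, lp, b, acc in payload["records"]],
            log_posterior=np.asarray(payload["log_posterior"], float),
            beta_series=np.asarray(payload["beta_series"], float),
            counters=payload["counters"],
            seed=payload["seed"],
            burn_in=payload["burn_in"],
            thin=payload["thin"],
            phase=payload["phase"],
        )


class _Problem:
    """Index-based view of the candidate universe for the fast sampler."""

    def __init__(self, candidates: CandidateEdgeSet, layers: LayerDefinition):
        self.candidates = candidates
        self.layers = layers
        self.nodes = candidates.nodes
        self.node_ids = [n.id for n in self.nodes]
        self.node_index = {nid: k for k, nid in enumerate(self.node_ids)}
        self.layer_code = np.asarray(
            [_LAYER_CODE[n.layer] for n in self.nodes], dtype=np.int64)
        self.n = len(self.nodes)
        self.edge_list = tuple(sorted(candidates.edges))
        self.m = len(self.edge_list)
        self.pu = np.asarray([self.node_index[u] for u, _ in self.edge_list],
                             dtype=np.int64)
        self.pv = np.asarray([self.node_index[v] for _, v in self.edge_list],
                             dtype=np.int64)
        self.parent_layer = self.layer_code[self.pu]
        index = {(u, v): k for k, (u, v) in enumerate(self.edge_list)}
        self.edge_index = index
        self.rev_index = np.asarray(
            [index.get((v, u), -1) for u, v in self.edge_list], dtype=np.int64)
        self.fan_in = np.full(3, np.iinfo(np.int64).max // 2, dtype=np.int64)
        for name, fi in layers.layers:
            self.fan_in[_LAYER_CODE[name]] = fi

    def beliefs(self, b: BiologicalPriorMatrix) -> np.ndarray:
        return np.asarray([b[e] for e in self.edge_list], float)


def _closure(adj: np.ndarray) -> np.ndarray:
    """Boolean transitive closure (reachability by >=1 step) of a DAG."""
    reach = adj.astype(np.float64)
    base = reach.copy()
    while True:
        nxt = np.minimum(reach + reach @ base, 1.0)
        if np.array_equal(nxt, reach):
            return reach > 0.0
        reach = nxt


def _legal_masks(p: _Problem, present, adj, counts, reach):
    """Boolean masks over candidate edges for legal add/delete/reverse moves."""
    add_mask = (~present
                & (counts[p.pv, p.parent_layer] < p.fan_in[p.parent_layer])
                & ~reach[p.pv, p.pu])
    del_mask = present
    rev_mask = np.zeros(p.m, dtype=bool)
    for e in np.flatnonzero(present & (p.rev_index >= 0)):
        u, v = p.pu[e], p.pv[e]
        if counts[u, p.layer_code[v]] >= p.fan_in[p.layer_code[v]]:
            continue
        if np.any(adj[u] & reach[:, v]):  # alternate path u -> v survives reversal
            continue
        rev_mask[e] = True
    return add_mask, del_mask, rev_mask


class _Sampler:
    """Mutable MCMC state over the indexed problem."""

    def __init__(self, problem: _Problem, cache: ScoreCache,
                 b_values: np.ndarray, beta: float, beta_max: float,
                 sample_beta: bool, rng: np.random.Generator,
                 start_edges: tuple[int, ...] = ()):
        self.p = problem
        self.cache = cache
        self.b = np.asarray(b_values, float)
        self.beta = float(beta)
        self.beta_max = float(beta_max)
        self.sample_beta = sample_beta
        self.rng = rng
        p = problem
        self.present = np.zeros(p.m, dtype=bool)
        self.adj = np.zeros((p.n, p.n), dtype=bool)
        self.counts = np.zeros((p.n, 3), dtype=np.int64)
        for e in start_edges:
            self.present[e] = True
            self.adj[p.pu[e], p.pv[e]] = True
            self.counts[p.pv[e], p.parent_layer[e]] += 1
        self.cur_local = np.zeros(p.n)
        for v in range(p.n):
            self.cur_local[v] = self._local(v)
        self.log_score = float(self.cur_local.sum())
        self.energy = float(np.where(self.present, 1.0 - self.b, self.b).sum())
        self.log_z = log_pseudo_z(self.beta, self.b)
        self.counters = {k: {"proposed": 0, "accepted": 0}
                         for k in ("add", "delete", "reverse", "beta")}

    # -- scoring helpers -------------------------------------------------
    def _local(self, v: int, adj: Optional[np.ndarray] = None) -> float:
        a = self.adj if adj is None else adj
        parents = [self.p.node_ids[u] for u in np.flatnonzero(a[:, v])]
        return self.cache.local_score(self.p.node_ids[v], parents)

    @property
    def log_prior(self) -> float:
        return -self.beta * self.energy - self.log_z

    @property
    def log_posterior_value(self) -> float:
        return self.log_score + self.log_prior

    def edge_indices(self) -> tuple[int, ...]:
        return tuple(int(k) for k in np.flatnonzero(self.present))

    # -- neighborhood ----------------------------------------------------
    def neighborhood_size(self, present, adj, counts) -> int:
        reach = _closure(adj)
        a, d, r = _legal_masks(self.p, present, adj, counts, reach)
        return int(a.sum() + d.sum() + r.sum())

    def legal_moves(self):
        reach = _closure(self.adj)
        return _legal_masks(self.p, self.present, self.adj, self.counts, reach)

    # -- structure move --------------------------------------------------
    def step(self) -> bool:
        p = self.p
        add_mask, del_mask, rev_mask = self.legal_moves()
        adds = np.flatnonzero(add_mask)
        dels = np.flatnonzero(del_mask)
        revs = np.flatnonzero(rev_mask)
        n_g = len(adds) + len(dels) + len(revs)
        if n_g == 0:
            raise SamplerStuckError("no legal single-edge move from this structure")
        k = int(self.rng.integers(n_g))
        if k < len(adds):
            kind, e = "add", int(adds[k])
        elif k < len(adds) + len(dels):
            kind, e = "delete", int(dels[k - len(adds)])
        else:
            kind, e = "reverse", int(revs[k - len(adds) - len(dels)])
        self.counters[kind]["proposed"] += 1
        u, v = int(p.pu[e]), int(p.pv[e])

        present = self.present.copy()
        adj = self.adj.copy()
        counts = self.counts.copy()
        delta_local = {}
        if kind == "add":
            present[e] = True
            adj[u, v] = True
            counts[v, p.parent_layer[e]] += 1
            delta_energy = 1.0 - 2.0 * self.b[e]
            delta_local[v] = self._local(v, adj) - self.cur_local[v]
        elif kind == "delete":
            present[e] = False
            adj[u, v] = False
            counts[v, p.parent_layer[e]] -= 1
            delta_energy = 2.0 * self.b[e] - 1.0
            delta_local[v] = self._local(v, adj) - self.cur_local[v]
        else:
            r = int(p.rev_index[e])
            present[e] = False
            present[r] = True
            adj[u, v] = False
            adj[v, u] = True
            counts[v, p.parent_layer[e]] -= 1
            counts[u, p.layer_code[v]] += 1
            delta_energy = (2.0 * self.b[e] - 1.0) + (1.0 - 2.0 * self.b[r])
            delta_local[v] = self._local(v, adj) - self.cur_local[v]
            delta_local[u] = self._local(u, adj) - self.cur_local[u]

        delta_score = float(sum(delta_local.values()))
        n_gp = self.neighborhood_size(present, adj, counts)
        log_ratio = (delta_score - self.beta * delta_energy
                     + math.log(n_g) - math.log(n_gp))
        accepted = bool(math.log(self.rng.random()) < log_ratio)
        if accepted:
            self.present = present
            self.adj = adj
            self.counts = counts
            for node, dl in delta_local.items():
                self.cur_local[node] += dl
            self.log_score += delta_score
            self.energy += delta_energy
            self.counters[kind]["accepted"] += 1
        return accepted

    # -- beta move -------------------------------------------------------
    def beta_update(self) -> bool:
        self.counters["beta"]["proposed"] += 1
        prop = self.beta + self.rng.uniform(-0.5, 0.5)
        # reflect into [0, beta_max]
        while prop < 0.0 or prop > self.beta_max:
            if prop < 0.0:
                prop = -prop
            if prop > self.beta_max:
                prop = 2.0 * self.beta_max - prop
        log_z_prop = log_pseudo_z(prop, self.b)
        log_ratio = -(prop - self.beta) * self.energy + self.log_z - log_z_prop
        accepted = bool(math.log(self.rng.random()) < log_ratio)
        if accepted:
            self.beta = prop
            self.log_z = log_z_prop
            self.counters["beta"]["accepted"] += 1
        return accepted


# ---------------------------------------------------------------------------
# public single-step API


def initial_structure(candidates: CandidateEdgeSet, mode: str = "empty",
                      b: Optional[BiologicalPriorMatrix] = None,
                      seed: int = 0,
                      layers: Optional[LayerDefinition] = None) -> NetworkStructure:
    """Edgeless start, or greedy seeding with curated-present edges.

    ``pk_seeded`` adds curated/TF-target edges with belief > 0.5 in random
    order, skipping any that would create a cycle or break a fan-in limit.
    """
    g = NetworkStructure.empty(candidates)
    if mode == "empty":
        return g
    if mode != "pk_seeded":
        raise ConfigurationError(f"unknown initial-structure mode {mode!r}")
    if b is None:
        raise ConfigurationError("pk_seeded initialisation needs a prior matrix")
    rng = np.random.default_rng(seed)
    seeds = [e for e, val in b.b.items()
             if b.provenance[e] in ("curated", "tf_target") and val > 0.5]
    seeds.sort()
    rng.shuffle(seeds)
    for u, v in seeds:
        trial = g.copy()
        trial.add_edge(u, v)
        if trial.is_acyclic() and (layers is None or trial.fan_in_ok(layers)):
            g = trial
    return g


def _sampler_for(g: NetworkStructure, pm: PriorModel, ds, hp, cache,
                 rng, layers: Optional[LayerDefinition]) -> _Sampler:
    candidates = pm.b_matrix.candidates
    if layers is None:
        layers = LayerDefinition.for_dataset(ds)
    problem = _Problem(candidates, layers)
    start = tuple(problem.edge_index[e] for e in sorted(g.edges))
    if hp is None:
        hp = default_hyperparameters(ds)
    if cache is None:
        cache = ScoreCache(ds, hp)
    return _Sampler(problem, cache, problem.beliefs(pm.b_matrix), pm.beta,
                    pm.beta_max, pm.sample_beta, rng, start)


def neighborhood(g: NetworkStructure, candidates: CandidateEdgeSet,
                 layers: Optional[LayerDefinition] = None) -> list[tuple[str, tuple[str, str]]]:
    """All legal single-edge moves from ``g``: (kind, (u, v)) pairs."""
    if layers is None:
        layers = LayerDefinition(((GE, max(1, len([n for n in g.nodes if n.layer == GE]))),
                                  (CNV, 1), (METH, 10 ** 6)))
    problem = _Problem(candidates, layers)
    present = np.zeros(problem.m, dtype=bool)
    adj = np.zeros((problem.n, problem.n), dtype=bool)
    counts = np.zeros((problem.n, 3), dtype=np.int64)
    for u, v in g.edges:
        e = problem.edge_index[(u, v)]
        present[e] = True
        adj[problem.pu[e], problem.pv[e]] = True
        counts[problem.pv[e], problem.parent_layer[e]] += 1
    reach = _closure(adj)
    add_mask, del_mask, rev_mask = _legal_masks(problem, present, adj, counts, reach)
    moves = []
    for e in np.flatnonzero(add_mask):
        moves.append(("add", problem.edge_list[e]))
    for e in np.flatnonzero(del_mask):
        moves.append(("delete", problem.edge_list[e]))
    for e in np.flatnonzero(rev_mask):
        moves.append(("reverse", problem.edge_list[e]))
    return moves


def mh_step(g: NetworkStructure, pm: PriorModel, ds: OmicsDataset,
            hp: Optional[BGeHyperparameters] = None,
            cache: Optional[ScoreCache] = None,
            rng: Optional[np.random.Generator] = None,
            layers: Optional[LayerDefinition] = None
            ) -> tuple[NetworkStructure, bool]:
    """One Metropolis–Hastings structure move starting from ``g``."""
    rng = rng if rng is not None else np.random.default_rng()
    sampler = _sampler_for(g, pm, ds, hp, cache, rng, layers)
    accepted = sampler.step()
    edges = set(sampler.p.edge_list[k] for k in sampler.edge_indices())
    return NetworkStructure(nodes=g.nodes, edges=edges), accepted


def beta_step(pm: PriorModel, g: NetworkStructure,
              rng: Optional[np.random.Generator] = None) -> tuple[float, bool]:
    """One reflected-uniform MH update of the inverse temperature β."""
    if not pm.sample_beta:
        return pm.beta, False
    rng = rng if rng is not None else np.random.default_rng()
    energy = graph_energy(g, pm.b_matrix)
    prop = pm.beta + rng.uniform(-0.5, 0.5)
    while prop < 0.0 or prop > pm.beta_max:
        if prop < 0.0:
            prop = -prop
        if prop > pm.beta_max:
            prop = 2.0 * pm.beta_max - prop
    log_ratio = (-(prop - pm.beta) * energy
                 + pm.log_pseudo_z(pm.beta) - pm.log_pseudo_z(prop))
    accepted = bool(math.log(rng.random()) < log_ratio)
    return (prop if accepted else pm.beta), accepted


# ---------------------------------------------------------------------------
# full runs


def _run_phase(sampler: _Sampler, n_iter: int, burn_in: int, thin: int,
               phase: int, seed: int, checkpoint=None,
               start_iter: int = 0, carried=None) -> PosteriorTrace:
    records = [] if carried is None else carried["records"]
    log_post = [] if carried is None else carried["log_posterior"]
    betas = [] if carried is None else carried["beta_series"]
    n_nodes = sampler.p.n
    for i in range(start_iter + 1, n_iter + 1):
        accepted = sampler.step()
        if sampler.sample_beta and i % n_nodes == 0:
            sampler.beta_update()
        log_post.append(sampler.log_posterior_value)
        betas.append(sampler.beta)
        if i > burn_in and (i - burn_in) % thin == 0:
            records.append(TraceRecord(
                iteration=i,
                edge_indices=sampler.edge_indices(),
                log_score=sampler.log_score,
                log_prior=sampler.log_prior,
                beta=sampler.beta,
                accepted=accepted,
            ))
        if checkpoint is not None and checkpoint.due(i, n_iter):
            checkpoint.write(phase, i, sampler, records, log_post, betas)
    return PosteriorTrace(
        nodes=sampler.p.nodes,
        edge_list=sampler.p.edge_list,
        records=records,
        log_posterior=np.asarray(log_post),
        beta_series=np.asarray(betas),
        counters=sampler.counters,
        seed=seed,
        burn_in=burn_in,
        thin=thin,
        phase=phase,
    )


def phase_edge_frequencies(trace: PosteriorTrace) -> dict:
    """Direction-specific edge frequency over a trace's snapshots."""
    counts = np.zeros(len(trace.edge_list))
    for rec in trace.records:
        for k in rec.edge_indices:
            counts[k] += 1
    denom = max(1, len(trace.records))
    return {e: counts[k] / denom for k, e in enumerate(trace.edge_list)}


class _Checkpoint:
    """JSON checkpoint of the sampler mid-run, for resumable inference."""

    def __init__(self, path, every: Optional[int]):
        self.path = Path(path)
        self.every = every

    def due(self, i: int, n_iter: int) -> bool:
        return self.every is not None and (i % self.every == 0 or i == n_iter)

    def write(self, phase, i, sampler: _Sampler, records, log_post, betas,
              completed_b=None) -> None:
        payload = {
            "phase": phase,
            "iteration": i,
            "edge_indices": list(sampler.edge_indices()),
            "beta": sampler.beta,
            "rng_state": sampler.rng.bit_generator.state,
            "records": [[r.iteration, list(r.edge_indices), r.log_score,
                         r.log_prior, r.beta, r.accepted] for r in records],
            "log_posterior": list(log_post),
            "beta_series": list(betas),
            "counters": sampler.counters,
            "completed_b": completed_b,
        }
        tmp = self.path.with_suffix(".tmp")
        tmp.write_text(json.dumps(payload))
        tmp.replace(self.path)

    def load(self) -> Optional[dict]:
        if not self.path.exists():
            return None
        return json.loads(self.path.read_text())


def run_mcmc(ds: OmicsDataset, layers: LayerDefinition, pm: PriorModel,
             settings: McmcSettings,
             candidates: Optional[CandidateEdgeSet] = None,
             hp: Optional[BGeHyperparameters] = None,
             cache: Optional[ScoreCache] = None,
             init_mode: str = "empty",
             checkpoint_path=None, checkpoint_every: Optional[int] = None,
             resume: bool = False
             ) -> tuple[PosteriorTrace, BiologicalPriorMatrix]:
    """Two-phase structure MCMC; returns the phase-2 trace and completed B.

    Phase 1 runs ``floor(phase1_fraction · total_iterations)`` iterations
    under the curated/default prior matrix; its post-burn-in edge
    frequencies (burn-in: half of phase 1, same thinning) replace the
    uninformative prior entries.  Phase 2 restarts from the phase-1 final
    structure under the completed matrix and runs ``total_iterations``;
    its trace is returned.  Fully reproducible given ``settings.seed``.
    """
    if candidates is None:
        candidates = pm.b_matrix.candidates
    if hp is None:
        hp = default_hyperparameters(ds)
    if cache is None:
        cache = ScoreCache(ds, hp)
    sample_beta = (pm.sample_beta if settings.sample_beta is None
                   else settings.sample_beta)
    beta0 = pm.beta if settings.beta_init is None else settings.beta_init
    rng = np.random.default_rng(settings.seed)
    problem = _Problem(candidates, layers)
    ckpt = _Checkpoint(checkpoint_path, checkpoint_every) if checkpoint_path else None
    state = ckpt.load() if (ckpt is not None and resume) else None

    n1 = int(math.floor(settings.phase1_fraction * settings.total_iterations))

    def new_sampler(b_matrix, beta, start_edges):
        s = _Sampler(problem, cache, problem.beliefs(b_matrix), beta,
                     pm.beta_max, sample_beta, rng, start_edges)
        return s

    completed = None
    carried = None
    start_iter_2 = 0

    if state is not None and state["phase"] == 2:
        if state["completed_b"] is None:
            raise ConfigurationError("phase-2 checkpoint lacks the completed prior")
        completed = _b_from_payload(state["completed_b"], pm.b_matrix)
        sampler2 = new_sampler(completed, state["beta"],
                               tuple(state["edge_indices"]))
        sampler2.rng.bit_generator.state = state["rng_state"]
        sampler2.counters = state["counters"]
        carried = {
            "records": [TraceRecord(it, tuple(idx), ls, lp, b, bool(a))
                        for it, idx, ls, lp, b, a in state["records"]],
            "log_posterior": list(state["log_posterior"]),
            "beta_series": list(state["beta_series"]),
        }
        start_iter_2 = state["iteration"]
    else:
        g0 = initial_structure(candidates, init_mode, pm.b_matrix,
                               settings.seed, layers)
        start0 = tuple(problem.edge_index[e] for e in sorted(g0.edges))
        if n1 > 0:
            if state is not None and state["phase"] == 1:
                sampler1 = new_sampler(pm.b_matrix, state["beta"],
                                       tuple(state["edge_indices"]))
                sampler1.rng.bit_generator.state = state["rng_state"]
                sampler1.counters = state["counters"]
                carried1 = {
                    "records": [TraceRecord(it, tuple(idx), ls, lp, b, bool(a))
                                for it, idx, ls, lp, b, a in state["records"]],
                    "log_posterior": list(state["log_posterior"]),
                    "beta_series": list(state["beta_series"]),
                }
                start1 = state["iteration"]
            else:
                sampler1 = new_sampler(pm.b_matrix, beta0, start0)
                carried1 = None
                start1 = 0
            trace1 = _run_phase(sampler1, n1, burn_in=n1 // 2,
                                thin=settings.thin, phase=1,
                                seed=settings.seed, checkpoint=ckpt,
                                start_iter=start1, carried=carried1)
            freqs = phase_edge_frequencies(trace1)
            completed = empirical_prior_update(pm.b_matrix, freqs)
            start2 = sampler1.edge_indices()
            beta2 = sampler1.beta
        else:
            completed = pm.b_matrix.copy()
            start2 = start0
            beta2 = beta0
        sampler2 = new_sampler(completed, beta2, start2)

    if ckpt is not None:
        # phase-2 checkpoints must carry the completed prior
        b_payload = _b_to_payload(completed)
        original_write = ckpt.write

        def write_with_b(phase, i, sampler, records, log_post, betas,
                         completed_b=None):
            original_write(phase, i, sampler, records, log_post, betas,
                           completed_b=b_payload)

        ckpt.write = write_with_b

    trace2 = _run_phase(sampler2, settings.total_iterations,
                        burn_in=settings.burn_in, thin=settings.thin,
                        phase=2, seed=settings.seed, checkpoint=ckpt,
                        start_iter=start_iter_2, carried=carried)
    return trace2, completed


def _b_to_payload(b: BiologicalPriorMatrix) -> dict:
    return {f"{u}\t{v}": [b.b[(u, v)], b.provenance[(u, v)]]
            for (u, v) in b.b}


def _b_from_payload(payload: dict, template: BiologicalPriorMatrix
                    ) -> BiologicalPriorMatrix:
    bvals = {}
    prov = {}
    for key, (val, pr) in payload.items():
        u, v = key.split("\t")
        bvals[(u, v)] = val
        prov[(u, v)] = pr
    return BiologicalPriorMatrix(b=bvals, provenance=prov,
                                 candidates=template.candidates)
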