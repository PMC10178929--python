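import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import omicsbn as o
import omicsbn.mcmc as mcmc_mod
from omicsbn.bge import ScoreCache
from omicsbn.datasets import GE, CNV, Node, cnv_node_id
from omicsbn.errors import SamplerStuckError

from oracles import enumerate_structure_posterior


def _flat_prior(cand, beta=0.0, sample_beta=False, beta_max=10.0):
    b = o.build_prior_matrix(None, cand)
    return o.PriorModel(b_matrix=b, beta=beta, beta_max=beta_max,
                        sample_beta=sample_beta)


class TestInitialStructure:
    def test_empty_mode(self, three_gene_setup):
        _, _, cand, _, _ = three_gene_setup
        assert o.initial_structure(cand, "empty").edges == set()

    def test_pk_seeded_acyclic_set_fully_included(self, three_gene_setup):
        _, layers, cand, _, _ = three_gene_setup
        pk = o.PriorKnowledgeTable.from_edges([("A", "B"), ("B", "C")], "present")
        b = o.build_prior_matrix(pk, cand)
        g = o.initial_structure(cand, "pk_seeded", b, seed=0, layers=layers)
        assert g.edges == {("A", "B"), ("B", "C")}

    def test_pk_seeded_two_cycle_keeps_exactly_one(self, three_gene_setup):
        _, layers, cand, _, _ = three_gene_setup
        pk = o.PriorKnowledgeTable.from_edges([("A", "B"), ("B", "A")], "present")
        b = o.build_prior_matrix(pk, cand)
        outcomes = set()
        for seed in range(20):
            g = o.initial_structure(cand, "pk_seeded", b, seed=seed, layers=layers)
            assert len(g.edges) == 1
            outcomes.add(next(iter(g.edges)))
        assert outcomes == {("A", "B"), ("B", "A")}


class TestNeighborhood:
    def test_two_node_exhaustive(self):
        ge = pd.DataFrame(np.random.default_rng(0).standard_normal((5, 2)),
                          index=[f"S{i}" for i in range(5)], columns=["A", "B"])
        ds = o.OmicsDataset(ge=ge).validate()
        layers = o.LayerDefinition(((GE, 3),))
        cand = o.enumerate_candidate_edges(ds, layers)
        g = o.NetworkStructure(nodes=cand.nodes, edges={("A", "B")})
        moves = set(o.neighborhood(g, cand, layers))
        assert moves == {("delete", ("A", "B")), ("reverse", ("A", "B"))}

    def test_cis_edge_not_reversible(self):
        gt = o.generate_true_network(2, 0.0, 1.0, 0, 3, seed=1)
        ds = o.simulate_dataset(gt, 10, seed=2)
        layers = o.LayerDefinition(((GE, 3), (CNV, 1)))
        cand = o.enumerate_candidate_edges(ds, layers)
        gene = ds.genes[0]
        g = o.NetworkStructure(nodes=cand.nodes,
                               edges={(cnv_node_id(gene), gene)})
        kinds = {kind for kind, e in o.neighborhood(g, cand, layers)
                 if e == (cnv_node_id(gene), gene)}
        assert kinds == {"delete"}

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_legality_oracle(self, seed):
        """Random 6-node layered structures: the move list equals the
        brute-force filter of all add/delete/reverse candidates."""
        gt = o.generate_true_network(4, 0.5, 1.0, 1, 2, seed=seed)
        ds = o.simulate_dataset(gt, 10, seed=seed + 100)
        layers = o.LayerDefinition(((GE, 2), (CNV, 1), ("METH", 3)))
        cand = o.enumerate_candidate_edges(ds, layers)
        rng = np.random.default_rng(seed)
        # grow a random legal structure
        g = o.NetworkStructure.empty(cand)
        for u, v in sorted(cand.edges):
            if rng.random() < 0.35:
                trial = g.copy()
                trial.add_edge(u, v)
                if trial.is_acyclic() and trial.fan_in_ok(layers):
                    g = trial

        moves = set(o.neighborhood(g, cand, layers))

        def legal(edges):
            t = o.NetworkStructure(nodes=cand.nodes, edges=edges)
            return t.is_acyclic() and t.fan_in_ok(layers)

        oracle = set()
        for e in sorted(cand.edges):
            if e in g.edges:
                oracle.add(("delete", e))
                rev = (e[1], e[0])
                if rev in cand.edges and legal(g.edges - {e} | {rev}):
                    oracle.add(("reverse", e))
            elif legal(g.edges | {e}):
                oracle.add(("add", e))
        assert moves == oracle


class TestMhStep:
    def test_improving_move_with_equal_neighborhoods_accepted(self,
                                                              three_gene_setup):
        ds, layers, cand, hp, cache = three_gene_setup
        pm = _flat_prior(cand)
        rng = np.random.default_rng(0)
        g = o.NetworkStructure.empty(cand)
        accepted_any = False
        for _ in range(30):
            g, acc = o.mh_step(g, pm, ds, hp, cache, rng, layers)
            accepted_any = accepted_any or acc
            g.validate(cand, layers)
        assert accepted_any

    def test_beta_zero_ignores_beliefs(self, three_gene_setup):
        """With beta = 0 the trajectory is identical whatever b is."""
        ds, layers, cand, hp, cache = three_gene_setup
        pm_flat = _flat_prior(cand, beta=0.0)
        b2 = o.build_prior_matrix(None, cand)
        rng_vals = np.random.default_rng(77)
        for e in b2.b:
            b2.b[e] = float(rng_vals.uniform(0.01, 0.99))
        pm_biased = o.PriorModel(b_matrix=b2, beta=0.0, sample_beta=False)
        settings = o.McmcSettings(total_iterations=2000, burn_in=0, thin=10,
                                  seed=5, phase1_fraction=0.0,
                                  sample_beta=False)
        t1, _ = o.run_mcmc(ds, layers, pm_flat, settings, candidates=cand,
                           hp=hp, cache=cache)
        t2, _ = o.run_mcmc(ds, layers, pm_biased, settings, candidates=cand,
                           hp=hp, cache=cache)
        assert [r.edge_indices for r in t1.records] == \
               [r.edge_indices for r in t2.records]

    def test_two_node_posterior_matches_enumeration(self):
        """Long-run structure frequencies on a 2-gene problem match the
        exhaustively enumerated posterior over the 3 DAGs within 0.02."""
        rng = np.random.default_rng(8)
        n = 60
        x = rng.standard_normal(n)
        y = 0.9 * x + rng.standard_normal(n)
        ge = pd.DataFrame({"X": x, "Y": y}, index=[f"S{i}" for i in range(n)])
        ds = o.OmicsDataset(ge=ge).validate()
        layers = o.LayerDefinition(((GE, 3),))
        cand = o.enumerate_candidate_edges(ds, layers)
        hp = o.default_hyperparameters(ds)
        cache = ScoreCache(ds, hp)
        pm = _flat_prior(cand)
        settings = o.McmcSettings(total_iterations=100000, burn_in=5000,
                                  thin=1, seed=3, phase1_fraction=0.0,
                                  sample_beta=False)
        trace, _ = o.run_mcmc(ds, layers, pm, settings, candidates=cand,
                              hp=hp, cache=cache)
        counts = {}
        for rec in trace.records:
            counts[rec.edge_indices] = counts.get(rec.edge_indices, 0) + 1
        total = len(trace.records)
        emp = {trace.edges_of_key(k) if hasattr(trace, 'edges_of_key') else
               frozenset(trace.edge_list[i] for i in k): c / total
               for k, c in counts.items()}
        post = enumerate_structure_posterior(
            ["X", "Y"],
            lambda edges: o.bge_network_score(
                o.NetworkStructure(nodes=cand.nodes, edges=set(edges)),
                ds, hp, cache))
        for dag, p in post.items():
            assert emp.get(dag, 0.0) == pytest.approx(p, abs=0.02)


class TestBetaStep:
    def test_disabled_sampling_keeps_beta_constant(self, three_gene_setup):
        ds, layers, cand, hp, cache = three_gene_setup
        pm = _flat_prior(cand, beta=1.3, sample_beta=False)
        settings = o.McmcSettings(total_iterations=500, burn_in=0, thin=10,
                                  seed=1, phase1_fraction=0.0)
        trace, _ = o.run_mcmc(ds, layers, pm, settings, candidates=cand,
                              hp=hp, cache=cache)
        assert np.all(trace.beta_series == 1.3)

    def test_uniform_beliefs_make_beta_a_free_random_walk(self,
                                                          three_gene_setup):
        """With b = 0.5 everywhere the energy term cancels against the
        pseudo partition function: every beta proposal is accepted and the
        stationary distribution is uniform on [0, beta_max]."""
        _, _, cand, _, _ = three_gene_setup
        pm = _flat_prior(cand, beta=1.0, sample_beta=True, beta_max=2.0)
        g = o.NetworkStructure.empty(cand)
        rng = np.random.default_rng(12)
        betas = []
        beta = pm.beta
        for _ in range(3000):
            pm.beta = beta
            beta, accepted = o.beta_step(pm, g, rng)
            assert accepted
            betas.append(beta)
        assert abs(np.mean(betas) - 1.0) < 0.3

    def test_beta_drifts_to_zero_when_structure_contradicts_prior(self,
                                                                  three_gene_setup):
        _, _, cand, _, _ = three_gene_setup
        b = o.build_prior_matrix(None, cand)
        for e in b.b:
            b.b[e] = 0.99  # prior demands every edge; structure has none
        pm = o.PriorModel(b_matrix=b, beta=5.0, beta_max=10.0, sample_beta=True)
        g = o.NetworkStructure.empty(cand)
        rng = np.random.default_rng(2)
        beta = pm.beta
        for _ in range(400):
            pm.beta = beta
            beta, _ = o.beta_step(pm, g, rng)
        assert beta < 1.0


class TestRunMcmc:
    def test_snapshot_counting_contract(self, three_gene_setup):
        ds, layers, cand, hp, cache = three_gene_setup
        pm = _flat_prior(cand)
        settings = o.McmcSettings(total_iterations=150, burn_in=100, thin=50,
                                  seed=0, sample_beta=False)
        trace, _ = o.run_mcmc(ds, layers, pm, settings, candidates=cand,
                              hp=hp, cache=cache)
        assert len(trace.records) == 1
        assert trace.records[0].iteration == 150

    def test_identical_seeds_give_identical_traces(self, three_gene_setup):
        ds, layers, cand, hp, cache = three_gene_setup
        pm = _flat_prior(cand, beta=1.0, sample_beta=True)
        settings = o.McmcSettings(total_iterations=1500, burn_in=100, thin=10,
                                  seed=99)
        t1, b1 = o.run_mcmc(ds, layers, pm, settings, candidates=cand,
                            hp=hp, cache=cache)
        t2, b2 = o.run_mcmc(ds, layers, pm, settings, candidates=cand,
                            hp=hp, cache=cache)
        assert t1.records == t2.records
        np.testing.assert_array_equal(t1.log_posterior, t2.log_posterior)
        np.testing.assert_array_equal(t1.beta_series, t2.beta_series)
        assert b1.b == b2.b

    def test_snapshots_satisfy_structure_invariants(self):
        gt = o.generate_true_network(6, 0.3, 1.0, 1, 3, seed=4)
        ds = o.simulate_dataset(gt, 40, seed=5)
        layers = gt.layer_definition()
        cand = o.enumerate_candidate_edges(ds, layers)
        pm = _flat_prior(cand, beta=1.0, sample_beta=True)
        settings = o.McmcSettings(total_iterations=2000, burn_in=200, thin=20,
                                  seed=6)
        trace, _ = o.run_mcmc(ds, layers, pm, settings, candidates=cand)
        assert len(trace.records) > 10
        for g in trace.structures():
            g.validate(cand, layers)

    def test_recorded_scores_equal_full_rescoring(self, three_gene_setup):
        """The incrementally maintained log BGe score of every snapshot
        equals a from-scratch recomputation."""
        ds, layers, cand, hp, cache = three_gene_setup
        pm = _flat_prior(cand, beta=0.7, sample_beta=True)
        settings = o.McmcSettings(total_iterations=1200, burn_in=100, thin=25,
                                  seed=11)
        trace, _ = o.run_mcmc(ds, layers, pm, settings, candidates=cand,
                              hp=hp, cache=cache)
        for rec in trace.records:
            g = trace.structure_of(rec)
            assert rec.log_score == pytest.approx(
                o.bge_network_score(g, ds, hp, cache), abs=1e-9)

    def test_single_gene_problem_has_no_moves(self):
        ge = pd.DataFrame({"A": np.arange(5.0)},
                          index=[f"S{i}" for i in range(5)])
        ds = o.OmicsDataset(ge=ge).validate()
        layers = o.LayerDefinition(((GE, 1),))
        cand = o.enumerate_candidate_edges(ds, layers)
        pm = _flat_prior(cand)
        settings = o.McmcSettings(total_iterations=10, sample_beta=False)
        with pytest.raises(SamplerStuckError):
            o.run_mcmc(ds, layers, pm, settings, candidates=cand)

    def test_recovery_of_simulated_network(self):
        """5-gene ground truth, n = 200, flat prior: phase-2 edge
        frequencies rank true edges above non-edges."""
        from omicsbn.cli import auroc

        gt = o.generate_true_network(5, 0.4, 0.0, 0, 3, seed=21)
        ds = o.simulate_dataset(gt, 200, seed=22)
        layers = o.LayerDefinition(((GE, 3),))
        cand = o.enumerate_candidate_edges(ds, layers)
        pm = _flat_prior(cand, beta=1.0, sample_beta=True)
        settings = o.McmcSettings(total_iterations=8000, burn_in=1000,
                                  thin=20, seed=23)
        trace, _ = o.run_mcmc(ds, layers, pm, settings, candidates=cand)
        w = o.edge_weights(trace)
        edges = sorted(cand.edges)
        scores = np.array([w[e] for e in edges])
        labels = np.array([e in gt.true_edge_set() for e in edges])
        assert auroc(scores, labels) > 0.8


class TestCheckpointResume:
    def test_resume_after_interrupt_reproduces_uninterrupted_run(
            self, three_gene_setup, tmp_path, monkeypatch):
        ds, layers, cand, hp, cache = three_gene_setup
        pm = _flat_prior(cand, beta=1.0, sample_beta=True)
        settings = o.McmcSettings(total_iterations=800, burn_in=100, thin=10,
                                  seed=31, phase1_fraction=0.5)
        ref_trace, ref_b = o.run_mcmc(ds, layers, pm, settings,
                                      candidates=cand, hp=hp, cache=cache)

        ckpt = tmp_path / "ck.json"
        calls = {"n": 0}
        orig = mcmc_mod._Checkpoint.write

        def interrupting(self, *args, **kwargs):
            orig(self, *args, **kwargs)
            calls["n"] += 1
            if calls["n"] == 2:
                raise KeyboardInterrupt

        monkeypatch.setattr(mcmc_mod._Checkpoint, "write", interrupting)
        with pytest.raises(KeyboardInterrupt):
            o.run_mcmc(ds, layers, pm, settings, candidates=cand, hp=hp,
                       cache=cache, checkpoint_path=ckpt, checkpoint_every=100)
        monkeypatch.setattr(mcmc_mod._Checkpoint, "write", orig)

        trace, b = o.run_mcmc(ds, layers, pm, settings, candidates=cand,
                              hp=hp, cache=cache, checkpoint_path=ckpt,
                              checkpoint_every=100, resume=True)
        assert trace.records == ref_trace.records
        np.testing.assert_array_equal(trace.log_posterior,
                                      ref_trace.log_posterior)
        assert b.b == ref_b.b
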