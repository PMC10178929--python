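# Methods

## Model

`omicsbn` treats regulatory-network inference as Bayesian-network
structure learning over typed continuous nodes. Nodes are gene
expression levels (GE), copy-number estimates (CNV, one node per gene
with copy-number data) and methylation levels (METH, one node per
retained probe). The candidate edge universe is layered:

- GE → GE, any ordered pair without self-loops, with a per-node GE
  in-degree bound (`fan_in_max`, default 3);
- `cnv_g → GE_g`: a gene's copy number may affect only its own
  expression (cis effect);
- `probe → GE_gene(probe)`: a methylation probe may affect only the
  expression of its annotated gene.

Edges out of GE into CNV/METH are excluded, CNV/METH nodes are roots,
and cis parents do not count against the GE in-degree limit. The
cis-only restriction for CNV/METH is a modelling choice: trans effects
of copy number or methylation are deliberately outside the candidate
space, which mirrors the dominant biological mechanism and keeps
parent-set enumeration tractable. Either or both of the CNV/METH layers
may be absent; inference then proceeds on the remaining layers.

### Methylation probe filter

Probes are screened before network inference by simple least squares:
the mapped gene's expression is regressed on the probe's methylation,
and the probe is retained iff R² ≥ `r_squared_thres` and the slope's
two-sided p-value (t statistic, n−2 df) ≤ `p_val_thres`. Defaults are
0.3 and 0.05; the worked examples use 0.5. R² is symmetric in the two
variables, so the direction of the regression affects only the reported
slope, not the retained set. Zero-variance probes are recorded with
R² = 0, p = 1 and dropped.

### Structure score

DAGs are scored by the BGe metric under a conjugate normal–Wishart
prior. For a feature subset Y of size l out of d features and n samples,

    log p(D_Y) = −(n·l/2)·log π + (l/2)·log(α_μ/(n+α_μ))
                 + log Γ_l((n+α_w−d+l)/2) − log Γ_l((α_w−d+l)/2)
                 + ((α_w−d+l)/2)·log|T_Y| − ((n+α_w−d+l)/2)·log|R_Y|

with R = T + S + (n·α_μ/(n+α_μ))·(ν−x̄)(ν−x̄)ᵀ, S the centred scatter
matrix and Γ_l the multivariate gamma. A node's local score is
log p(D_{Pa∪{node}}) − log p(D_Pa); the network score is the sum of
local scores (decomposable). Defaults: ν = sample means, α_μ = 1,
α_w = d + 2, T = α_μ(α_w−d−1)/(α_μ+1)·I — the standard score-equivalent
choice, under which all members of a Markov equivalence class score
identically (verified exhaustively on 4 nodes to 1e−8, and against an
independent sequential conjugate-predictive oracle to machine
precision). All linear algebra is done in log space via Cholesky
factorisations; a single +1e−8 diagonal jitter retry precedes a
degeneracy error. Subset marginals and local scores are memoised per
dataset; caches must be rebuilt if the data change.

### Prior knowledge and the structure prior

Curated interactions give per-edge beliefs: present → 0.99, absent →
0.01 (never exactly 0/1, so no structure has zero prior probability and
the sampler stays ergodic). TF→target pairs count as curated-present
unless contradicted by an explicit curated entry. All other candidate
edges start at the uninformative 0.5. A structure g is scored against
the belief matrix B by the additive mismatch energy

    E(g) = Σ_(i,j) |b(i,j) − a(i,j)|,  a(i,j) = 1[(i,j) ∈ g],

and the prior p(g | β) ∝ exp(−β·E(g)). The normaliser is approximated
edge-factorised, Ẑ(β) = Π_(i,j) [e^(−β·b) + e^(−β·(1−b))], ignoring
acyclicity; this makes the β update O(#edges) and is exact for the
relative comparison of structures at fixed β (Ẑ cancels). β is sampled
by Metropolis–Hastings with a symmetric uniform step of half-width 0.5,
reflected at 0 and `beta_max` (default 10), once per structure sweep
(every |nodes| structure proposals). With uniform beliefs the energy is
constant, the Ẑ ratio cancels the energy term exactly, and β performs a
free reflected random walk — the prior is then provably inert.

### Sampling and empirical prior completion

The structure sampler is single-edge-move Metropolis–Hastings: from the
current DAG, all legal moves (add an absent candidate edge preserving
acyclicity and fan-in; delete any edge; reverse an edge whose reversal
is itself a candidate and stays legal) are enumerated, one is proposed
uniformly, and accepted with probability

    min(1, exp(Δ log BGe + Δ log prior) · |N(g)| / |N(g′)|).

Only the affected local scores are recomputed (one child for
add/delete, two for reverse); the incrementally maintained total equals
full rescoring to 1e−9 (property-tested).

Sampling is two-phase. Phase 1 runs floor(`phase1_fraction` · total)
iterations (default 0.5) under the curated/default B; its post-burn-in
edge frequencies (burn-in: half of phase 1, same thinning) replace the
`default`-provenance entries of B, clamped to [0.01, 0.99], with
provenance `empirical`; curated and TF-target entries are never
touched. Phase 2 restarts from the phase-1 final structure and β under
the completed matrix and runs the full `total_iterations`; the returned
trace and all reported weights come from phase 2. Running the whole
budget again in phase 2 (rather than the remainder) keeps the
burn-in/thinning semantics of the returned trace independent of the
phase-1 schedule. A single seeded generator drives move choice,
acceptance and β proposals, so runs are bit-reproducible; a JSON
checkpoint (iteration, edges, β, RNG state, snapshots) makes
interrupted runs resumable with outputs identical to an uninterrupted
run.

### Posterior summaries

Edge weights are direction-specific empirical frequencies over the
post-burn-in, thinned snapshots. Thresholding retains edges at or above
either an absolute weight or a quantile of the *nonzero* weights
(linear-interpolation quantile; restricting to nonzero weights prevents
the threshold collapsing to 0 on sparse candidate spaces). The retained
network is reported as a CPDAG: v-structure members and all cis
(CNV/METH→GE) edges are oriented — the latter as background knowledge,
since their reversal lies outside the candidate space — and Meek's
orientation rules (R1–R4) propagate to the remaining edges; what stays
un-oriented is reversible within the (layer-restricted) equivalence
class and is reported undirected with the combined weight of both
directions. The implementation is validated exhaustively against a
skeleton+v-structure oracle on all 543 four-node DAGs and against
brute-force enumeration of the restricted class on layered graphs.

Convergence is assessed by binary-segmentation mean-shift changepoint
detection on the snapshot-level log-posterior series: a split is
accepted when it reduces the within-segment sum of squares by more than
2·log(n)·σ̂², with σ̂² the half mean squared successive difference
(robust to mean shifts) and segments no shorter than `minseglen`
iterations (i.e. `minseglen`/thin snapshots). The chain is declared
converged when no changepoint is found. At typical summary resolutions
(≈200 snapshots, minseglen/thin ≈ 50–100) the false-alarm rate under a
stationary chain is below 1%; at much finer resolutions the BIC-style
penalty is less conservative.

## Synthetic data

The generator draws a ground-truth layered DAG (uniform random
topological order over genes, independent edge coin-flips with
probability `edge_prob`, rejection on GE fan-in violations; a CNV
parent per gene with probability `p_cnv`; `probes_per_gene` methylation
parents, plus optional annotated but causally unconnected noise probes)
and samples it as a linear-Gaussian structural-equation model: roots
are standard normal, each GE node is the coefficient-weighted sum of
its parents plus Gaussian noise. Coefficients are uniform on ±[0.5,
1.5] and noise standard deviations uniform on [0.5, 1] — effects
bounded away from zero so that recovery at a few hundred samples is
well-posed, matched to the Gaussian model family the BGe score assumes.
The sample covariance converges to the closed-form
(I−Cᵀ)⁻¹D(I−Cᵀ)⁻ᵀ (tested at n = 20000).

What this emulates — and what it does not: the synthetic data are
exactly linear-Gaussian with independent roots. Real methylation beta
values are bounded and skewed, copy-number estimates are segmented and
discrete-ish, expression is heteroscedastic, and real regulatory
effects are nonlinear and confounded. Passing recovery tests therefore
demonstrates correctness of the machinery under its own model
assumptions, not performance on real arrays.

One consequence worth stating plainly: under these generator settings a
linked methylation probe explains R² = c²/(c² + V_rest) of its gene's
expression variance, where V_rest contains the gene's noise and its
other (CNV, GE) parents. With coefficients in ±[0.5, 1.5] this is
typically 0.2–0.5, so a strict R² ≥ 0.5 screen keeps only ~20–30% of
truly linked probes while removing essentially all noise probes: at
that threshold the filter is high-precision, low-recall on this data
model. The threshold is exposed (`r_squared_thres`) and the filter
report records every probe's R² and p-value.

## Problem sizes and defaults used in validation

The validation suite exercises: exact-enumeration sampler checks on 2–3
genes (25 DAGs, 100k–200k iterations, thin 1); exhaustive CPDAG and
score-equivalence checks on 4 nodes (543 DAGs); and recovery studies at
10 genes, CNV on every gene, one linked and one noise probe per gene,
n = 200, 100k-iteration two-phase runs (burn-in 10k, thin 100) over 5
seeds — sizes at which exhaustive oracles are feasible and a full run
takes well under a minute. Single-edge-move MCMC on strongly
concentrated posteriors can lock into near-tied modes (e.g. one of two
Markov-equivalent orientations, or competing parent sets separated by a
low-probability intermediate); direction-specific frequencies from
independent finite chains therefore agree only up to this mode-locking,
which is why chain-agreement checks are run either at identical seeds
(law equality) or on small problems where the Monte-Carlo error is
below tolerance. For real analyses, running replicate chains with
different seeds and comparing edge weights is the recommended
diagnostic, alongside the changepoint report.

## Known limitations

- Linear-Gaussian modelling only (BGe); no discrete or nonparametric
  scores.
- Cis-only CNV/METH candidate edges; no trans effects.
- The pseudo partition function ignores the DAG constraint; β is
  therefore sampled under an approximate normaliser.
- Single-edge-move MCMC mixes slowly between near-tied modes on
  concentrated posteriors; no order- or partition-MCMC.
- The empirical prior is estimated once (two-phase), not continuously
  adapted.
- Missing values are rejected rather than imputed: imputation choices
  materially affect the score and belong upstream.
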