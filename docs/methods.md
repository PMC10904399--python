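# Methods

## Overview

`funcsig` represents genes as learned functional embedding vectors, gene
signatures (the gene sets produced by perturbation experiments) as weighted
averages of those vectors, and compound–target relationships as a learned
similarity between a compound's transcriptional signature and the signature
of a genetic perturbation of the candidate target.  The motivating problem
is the sparseness of experimental signatures: two experiments perturbing the
same pathway typically report mostly non-overlapping gene identities (two
independent 10-gene draws from a 100-gene pathway share three or more genes
only ~6% of the time), so identity-overlap statistics such as Fisher's exact
test discard most of the shared functional signal.  Embeddings let two
signatures agree through functionally similar — not identical — genes.

## Gene embeddings from weighted hypergraphs

Each annotation modality becomes a hypergraph: genes are nodes; each
ontology term or each expression-derived differential gene set is a
hyperedge connecting its member genes.  Hyperedge weights are information
content in bits.  In ontology mode

    w(e) = -log2( Σ_{c ∈ C(e)} |c| / Σ_{e'} |e'| ),

where C(e) is the set of in-collection descendants of e plus e itself, so a
term's frequency absorbs its sub-terms' membership and root-like terms get
weight 0.  In expression mode the same formula without descendants,
w(e) = -log2(|e| / Σ|e'|).

A two-step random walk (pick an incident hyperedge proportional to its
weight, then a member of that edge uniformly) gives the transition matrix

    B(u,v) = Σ_e w(e) · H(u,e)/d(u) · H(v,e)/|e|,

with H the incidence matrix and d(u) = Σ_{e∋u} w(e).  Functional proximity
of v to a source u is the stationary distribution of a walk with restart,
iterated as s ← (1−q)·Bᵀs + q·a_u until the change (Frobenius norm over the
full source matrix, 2-norm per single source) drops below 1e-6.  We apply
Bᵀ, not B, to the distribution vector: that is the orientation under which
probability mass is conserved (row-stochastic B propagates distributions by
its transpose); the spelled-out update in matrix notation is otherwise
conventional.  The restart probability q defaults to 0.5 and is exposed;
small q mixes farther into the graph, q = 1 degenerates to the restart
state.

Embeddings minimize a negative-sampling contrastive objective.  Per anchor
gene u we draw N(u) (positives, proportional to s_u) and R(u) (negatives,
proportional to 1/(s_u + 1e-12)), at the fixed ratio |R| = 5·|N|, excluding
the anchor itself, with replacement, resampled every epoch; the loss is

    -Σ_{v∈N(u)} log σ(x_v·x_u) - Σ_{z∈R(u)} log σ(-x_z·x_u).

The negative term uses σ(−x_z·x_u); a literal reading of the objective with
+log σ(x_z·x_u) inside an outer minus would be unbounded below, and the
standard word2vec-family form is clearly intended.  Dot products are clamped
to ±30 before the sigmoid.  Optimization is sparse Adam (learning rate
1e-3, β = 0.9/0.999): one update per anchor per epoch touching only the
anchor's sampled rows, each row with its own bias-correction step counter.
This choice was made after observing that one dense step per epoch is far
too few updates to converge at desk scale.  Embeddings start from a seeded
normal at scale 1/√dim.  The per-modality width defaults to 256; the joint
gene representation is the ordered concatenation [x_ontology,
x_expression] (512 when both modalities are at default width).  Genes in no
hyperedge are carried as flagged zero vectors and never sampled.

## Signature vectors

For a gene u in signature G, its average within-set cosine similarity
r_u = (1/|G|) Σ_{v∈G} cos(x_u, x_v) is computed per modality — the sum
includes v = u as the formula states; the resulting constant offset does not
change the ordering of z-scores within a set.  r_u is z-scored against the
exact genome-wide background (mean and sd of cos(x_u, x_v) over all v ≠ u;
computed once per modality and cached; zero-variance backgrounds give
z = 0).  The weight is w_u = min(max(z_ont, z_expr, 0), 1): a gene whose
similarity to its set does not exceed its genome background contributes
nothing; strong genes saturate at 1.  A gene with a zero embedding block in
one modality gets z = −∞ there so the other modality decides.  The
signature vector is x_G = (1/|G|) Σ w_u x_u over the concatenated vectors.
If every weight clamps to zero the unweighted mean is used with a warning.
Genes absent from the embedding universe are dropped with a logged count;
up- and down-regulated genes are pooled into one set per signature.

## Co-target pair classifier

A Siamese network scores whether a compound signature and a genetic
(shRNA/cDNA) signature share a target.  One shared dense layer D (default
2048 units, ReLU) maps both inputs; the merge is the element-wise product
D(x_cpd) ⊙ D(x_gene) — symmetric, so the score is invariant to swapping
inputs — followed by a 512-unit ReLU layer and a sigmoid unit.  Hidden
activations are not dictated by the architecture description; ReLU is the
conventional choice.  Training minimizes binary cross-entropy with Adam
(batch 128, learning rate 1e-3, 60 epochs), implemented in numpy with
hand-derived gradients.  Negatives are balanced per target gene: each
positive (c, g) pair spawns one negative pairing g with a compound not
annotated to g, so every gene is seen with a 1:1 label ratio and popular
targets gain no prior.  Compounds with more than five annotated targets are
excluded from training (polypharmacology filter).  Predictions average a
3-model ensemble trained on the same data from different initializations.
Cross-validation folds split by compound; within each training fold the
negative compounds are drawn only from that fold's compounds, otherwise
held-out compounds leak into training as "negative" exemplars and held-out
scores invert.  Separate models are trained per perturbagen type.  Signature
vectors are L2-normalized before pairing; the raw aggregated vectors have
small, training-dependent scale and the product merge otherwise operates in
a near-linear regime where the network memorizes instead of generalizing.

## Consensus ranking and logistic fusion

Per (cell line, perturbagen type) context, candidate targets are sorted by
decreasing probability (ties by gene id) and assigned normalized ranks
O_g/n.  Pooling across contexts keeps each gene's first occurrence — its
minimum normalized rank — giving one consensus list per compound.  Recall@N%
is the fraction of compounds with an annotated target at consensus rank
≤ N/100 (strict boundary), N = 5 by default.

Rank evidence enters the fusion model through the odds ratio x = (1−r)/r;
activity evidence through the maximum Pearson correlation between the query
compound's activity profile and any reference compound of the target
(≥ 3 shared assays required, otherwise flagged missing).  When fusing
trained models, features are logits of their probabilities, clipped to
[1e-6, 1−1e-6].  The fusion classifier is logistic regression with
non-negative weights — predictions are then monotone in every evidence
channel, the guilt-by-association constraint — minimizing the
class-weighted negative log-likelihood (positives weighted 1/n_p, negatives
1/n_n) plus λ‖w‖² via L-BFGS-B with box constraints.  The printed form of
this cost adds the penalty to a log-likelihood being maximized; we minimize
the standard weighted NLL + penalty, which is the unambiguous intent.  λ is
selected by seeded stratified inner CV over a decade grid 1e-3…1e3.
Performance metrics reweight confusion counts by 1/n_p and 1/n_n (an
effective 1:1 balance); ROC/PR areas use the same per-sample weights.

## Statistical utilities

Fisher similarity between gene sets is −log10 of the one-sided
hypergeometric tail (enrichment).  The benchmark's separation statistic is
−log10(p) of a one-sided Wilcoxon signed-rank test that paired
foreground–foreground similarities exceed foreground–background ones; the
exact null is used for n ≤ 25 without ties, otherwise the normal
approximation with continuity correction; zero differences are dropped and
an all-zero difference vector returns p = 1.  Small helpers compute the
hypergeometric overlap tail P(X ≥ k) for two independent n-subsets of a
K-gene pathway, the 1-NN label z-score (µ−µ0)/δ, the binomial standard
error of a confirmation rate, and fold enrichment between two confirmation
arms with a one-sided chi-square p-value.

## Synthetic data and what it does (not) show

All tests run on generated data; nothing is downloaded.

* **Ontology fixture** — a three-level DAG (leaf terms partitioning the
  genes, branch terms, one root) with nested membership; exercises IC
  weighting and the hierarchy I/O.
* **Pathway collection** — random (possibly overlapping) gene subsets with
  sizes uniform in 50–200, the desk-scale stand-in for a curated pathway
  database.
* **Benchmark triplets** — per pathway W: two independent foreground
  100-gene sets with λ genes from W and the rest uniform outside W, plus a
  background set disjoint from W; λ ∈ {5, 10, 15, 20}, 200 repetitions at
  full scale, 50 in the shipped tests.  Foreground fillers may coincide by
  chance (independent draws).  Benchmark embeddings are trained on the
  pathway collection itself as expression-mode hyperedges.
* **Co-target fixture** — 60 target genes each owning a pathway (30–60
  genes) in an 800-gene universe; 80 compounds with 1–3 annotated targets
  (cap 5); signatures of 50 genes plant 15 pathway genes, filler uniform.
  Setting the planted-gene count to 0 yields an exact null (uniform draws).
  Defaults were sized so a training fold retains enough compounds (~64) for
  the pair classifier to fit stably — roughly 20× below the real problem.
* **Cluster embeddings** — genes placed at unit cluster centers plus
  isotropic noise; used where tests need embeddings with known structure
  without training.

Synthetic pathways are random sets: they lack the hierarchical, correlated,
size-skewed structure of real annotation databases, and the signature
generator plants a single clean effect size rather than dose/time/cell-line
gradients.  Passing tests therefore demonstrate that each algorithmic
component behaves as specified and that the end-to-end pipeline recovers
planted co-targeting structure under honest held-out evaluation — not that
real-data recall figures are reproduced.

## Numerical choices and degenerate inputs

Cosine with a zero vector is 0 (logged).  Probabilities are clipped to
[1e-7, 1−1e-7] before cross-entropy logs, and to [1e-6, 1−1e-6] before
logits.  RWR convergence threshold 1e-6; non-convergence raises with the
last residual.  Candidate-list and top/bottom-ranking ties break by gene id
(stable, reproducible).  Network export keeps edges with probability > 0.8
and normalized rank ≤ 0.05.  Expression preprocessing is log2(x+1) (the
pseudocount guards zero counts), quantile normalization against the pooled
sorted-mean reference with tie averaging, then per-gene z-scores (constant
rows become 0, logged); stages only move forward.  Differential sets take
the top/bottom 100 ranked genes that also pass |Z| ≥ 2.  Exemplar selection
keeps the highest-TAS signature per (perturbagen, cell line), ties by
signature id.

## Problem sizes used by tests and the acceptance script

Cluster recovery: 20 genes, dim 16, 40 epochs, 5 seeds.  Benchmark: 2000
genes, 20 pathways, dim 256, 30 epochs, 50 reps.  Co-target pipeline:
defaults above with embedding dim 32, Siamese hidden sizes 64/16, 5 folds,
3-model ensembles, 60 epochs.  These sizes are the package's desk-scale
defaults; the estimator classes accept the full-scale settings (256-dim
modalities, 2048/512 hidden units) unchanged.

## Known limitations

Dense RWR limits the universe to a few thousand genes; no
approximate/landmark solvers are provided.  Direction-aware (up vs down)
sub-signatures are not modeled.  The activity-evidence path expects a
compounds × assays matrix with per-target reference compounds and does not
implement assay-quality filters of any specific real dataset.  Structure
(fingerprint) similarity evidence is out of scope.
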