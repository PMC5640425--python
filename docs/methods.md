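# Methods

## Data model

A hetnet couples a metagraph (node types and edge types) with a typed
instance graph. Directionality is a metaedge-level property and is only
meaningful for self-relationships (here, Gene→regulates→Gene); every other
metaedge is undirected. Traversal is orientation-aware: an undirected edge
can be walked from either endpoint and both orientations expose identical
neighbor sets, while a directed edge walked against its arrow is the same
edge in a distinct traversal orientation, not a second edge. Self-edges
(both endpoints one node) and parallel edges of one metaedge between one
node pair are forbidden; the degree-preserving permutation algorithm assumes
both absences.

Abbreviations compose a source metanode abbreviation, a lowercase kind
letter, and a target abbreviation (CbG; Gr>G with `>` marking direction).
Metapath abbreviations concatenate these along the walk; a backward directed
traversal renders as a mirrored marker (`G<rG`). Parsing relies on metanode
abbreviations being uppercase and kind abbreviations lowercase.

## Metapath enumeration

A metapath is an endpoint-compatible sequence of metaedge traversals.
Identity is orientation-sensitive: each undirected metaedge contributes one
orientation-free traversal step (so an undirected self-metaedge like GiG is
a single step type), while a directed self-metaedge contributes two distinct
steps, one per orientation. Metaedges may repeat, and immediate
back-and-forth over one undirected metaedge (CbGbC…) is legitimate — such
metapaths express "compounds that bind the same gene". Enumeration is
depth-first over the step graph with results sorted by length then
abbreviation; connectivity counts per metanode pair are computed by powers
of the step-count matrix, which agrees with exhaustive enumeration because
the count factorizes over per-step choices. On the bundled 11-metanode /
24-metaedge biomedical schema this convention yields 1206 Compound→Disease
metapaths of length 2–4, which the tests pin along with three length-4
pair counts.

## DWPC

For a conforming node-distinct path, the path-degree product multiplies, for
each traversed edge, the degrees of its two endpoints — specific to that
edge's metaedge and traversal orientation — each raised to −w. A path of
length L therefore contributes 2·L degree factors. The DWPC is the sum of
PDPs over all paths; w = 0.4 by default (the value established by prior
optimization of this metric family), and w = 0 recovers the raw path count.
Path extraction is explicit depth-first search with a visited set (paths,
not walks); a node pair's direct supervised edge can be excluded from
traversal (`exclude_query_edge`, default on) so a supervised pair's features
do not trivially encode the label through paths that reuse the very edge
being predicted. Degrees in the PDP are always taken on the full network,
including any excluded edge.

## Permutation null

XSwap repeatedly samples two edges (a–b, c–d) and exchanges endpoints to
(a–d, c–b), rejecting swaps that would create a self-edge or duplicate.
Applied per metaedge, it preserves every node's metaedge-specific degree
exactly. For metaedges joining two distinct metanodes, and for the directed
self-metaedge, source/target roles are fixed, so source- and target-side
degrees (out/in for directed) are each conserved. For undirected
self-metaedges, candidate edges are randomly re-oriented before the
exchange and duplicates are detected up to endpoint order, making the
proposal symmetric over the undirected configuration space. Attempts — not
successful swaps — are counted against the budget (multiplier × edge count,
default 10); the fraction of edges unchanged relative to the original is
reported per metaedge as the mixing diagnostic. Permuted hetnets form a
Markov chain (each permutes its predecessor), matching how the baselines
are used: a handful (default 5) of permuted networks whose AUROCs have low
variance.

The treatment prior for a compound–disease pair is the fraction of
degree-preserving permutations of the bipartite treatment edge list in
which that pair is connected — a connection probability given only the two
endpoint degrees. It is the raw empirical fraction (no smoothing), computed
along a single XSwap chain sampled once per multiplier×m attempts; pairs
with a zero-degree endpoint get exactly 0. The desk-scale default is 500 to
10,000 permutations depending on context, far below production scale, which
only widens Monte Carlo error on individual priors; the sum of priors over
all pairs equals the edge count by construction.

## Feature assessment and the model

Raw DWPCs and endpoint degree counts are mean-scaled then transformed by
the inverse hyperbolic sine, x′ = asinh(x/mean(x)); an all-zero column is
left unchanged. Degree features get the same transform as DWPCs, both being
nonnegative right-skewed counts.

The workflow is bifurcated. The *all-features* stage scores every candidate
metapath on the positives plus a uniform subsample of negatives (4 per
positive by default; AUROC precision is dominated by the positive count).
Δ AUROC is the real-network AUROC minus the mean across permuted networks.
The p-value is a predictive t-test of the observed AUROC against the k
permuted AUROCs: t = Δ / (sd·√(1+1/k)) with k−1 degrees of freedom — the
exact test for one new observation against a normal sample. The published
description does not pin this test down; this is the package's choice.
Zero permuted variance makes p indeterminate and flags the feature.
Benjamini–Hochberg q-values are computed across all assessed metapaths;
selection keeps q ≤ 0.05 with Δ > 0. Excluding metapaths whose first step
is the supervised metaedge is supported but off by default, since such
metapaths legitimately carry signal once the query edge itself is excluded
from traversal.

The *all-observations* stage restricts to the nonzero-prior block (pairs
whose endpoints both have supervised degree — the only pairs with finite
prior logit), computes prior, degree, and selected-DWPC features there, and
fits a binomial GLM in which the logit prior is an unpenalized term and all
other features are standardized and elastic-net penalized (mixing 0.2
toward ridge by default; not a published value). Penalty strength is chosen
on a log grid anchored at the smallest all-zeroing penalty, by stratified
cross-validation (10-fold default; 3–5 folds in desk-scale runs) at minimum
mean held-out deviance, then refit on all rows. Zero-variance columns get a
unit standard deviation so standardization is defined. Predictions replace
the prior term with the logit of a constant prior — conventionally the
overall positive prevalence — giving degree-agnostic probabilities;
fold-over-null is probability divided by that constant, taken literally.

## Decomposition

A prediction's positive support is attributed hierarchically. Each metapath
feature's regression term is its coefficient times its standardized value;
positive terms are normalized to percentages. Prior and degree terms are
excluded from the denominator, and negative or unsupported terms are
reported as diagnostics rather than percentages. Because standardization
centers features, a pair with zero DWPC can have a positive term under a
negative coefficient; such metapaths have no paths and are excluded from
positive support (credited support always corresponds to actual paths).
Within a metapath, each path receives the metapath percentage times its PDP
share of the DWPC; path percentages are then aggregated by first edge and
by last edge. Mass is conserved to numerical precision at all three levels,
and requesting path contributions for a supported percentage with no
extractable paths raises an inconsistency error.

## Synthetic data

The generator emulates the structural premises of the method — typed nodes,
heavy-tailed metaedge-specific degrees, and a supervised edge type whose
occurrence correlates with specified metapaths — on a three-metanode schema
(Compound, Gene, Disease) with CbG, CrC, DaG, GiG and the supervised CtD.
Endpoint sampling is weighted by per-node lognormal propensities (σ = 1 by
default); only heavy-tailedness matters, not a particular degree law.
Treatment labels are sampled from P = sigmoid(logit(prevalence) +
Σ effect·asinh(path count)) per compound–disease pair, and positive pairs
become CtD edges, so the network is self-consistent with its labels.

Defaults are desk-scale: 50 compounds, 25 diseases, 140 genes, ~1020
non-treatment edges, one planted CbGaD mechanism with effect 2.5, baseline
prevalence 1.5% (realized prevalence ~6–8% after the mechanism lift). These
sizes give ~100 positives — enough for stable AUROCs — while keeping
brute-force oracles and 20-replicate pipeline tests fast. The generator does
not reproduce a production-scale knowledge graph: degree distributions are
a single-parameter skew rather than fitted, all edges are equally reliable
(no source heterogeneity or curation noise), the schema is small, and the
planted mechanism is exactly the kind of signal the features measure. Tests
passing on this generator therefore demonstrate correctness and internal
consistency of the machinery, not real-world predictive performance.

## Numerical and design notes

- AUROC uses the Mann–Whitney formulation (ties count one half), via
  scikit-learn; tests cross-check a brute-force pairwise count.
- The permuted baselines inherit serial correlation from the Markov chain,
  which makes the predictive t-test mildly anti-conservative; the
  shuffled-label calibration check budgets for this (observed null rate
  ≈5–10% at nominal 5% with 5-element chains).
- Prior logits clip probabilities to [1e−12, 1−1e−12]; model fitting
  refuses non-finite prior logits rather than silently dropping rows.
- The elastic-net path is fit with statsmodels' coordinate descent using
  per-parameter penalty weights (zero on intercept and prior term).
  Occasional non-convergence warnings at the weakest grid penalties do not
  affect the selected fit.
- Determinism: every stochastic step (generation, sampling, XSwap, CV
  folds) takes an explicit seed; pipeline replicates derive sub-seeds from
  the replicate seed.

## Limitations

Path extraction is explicit traversal — fine for desk-scale networks,
orders of magnitude too slow for a production knowledge graph, where
matrix-based DWPC computation or a graph database would be required. The
prior is purely empirical per degree pair; no analytic approximation or
smoothing is provided. The model does not calibrate predicted probabilities
beyond the constant-prior scaling, and external validation against
held-out edge sets is out of scope.
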