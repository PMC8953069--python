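# Methods

This note records the models, the numerical choices, and what the synthetic
benchmarks do and do not demonstrate.

## Count model and the exact conditional test

Reads per gene are negative binomial in the mean–dispersion form,
Var(Y) = μ + φμ² with φ = BCV². With a single library per condition there is
no residual variation to estimate φ from, so it is fixed: either the
conventional value 0.045 (the package default throughout the pipeline) or a
housekeeping-gene estimate (below).

The test conditions on the equalized pair total. Both counts are scaled to
the geometric mean of the two library sizes and rounded half-to-even (a
deterministic, oracle-checkable choice; quantile-based equalization used by
replicate-oriented tools is deliberately not reproduced). Given total *s*,
P(y | s) ∝ NB(y; s/2, φ)·NB(s − y; s/2, φ) is evaluated by direct summation
over 0..s in log space; the two-sided p-value is the summed probability of
all splits with probability ≤ the observed one ("small-p" rule, ties
included, relative tie tolerance 1e−9 in log space). At φ ≤ 1e−12 the
conditional law is exactly Binomial(s, ½), and the implementation matches
the conditional binomial exact test to 1e−8 for s ≤ 200. The test is
symmetric in its arguments at equal library sizes and monotone in |y₁ − y₂|
at fixed total.

Discreteness makes the test conservative: on a 10,000-gene null simulation
at the generating dispersion, the fraction of p ≤ 0.05 is ≈ 0.04–0.045
(computed by `scripts/acceptance.py`), never anticonservative.

**logFC** is log₂((cpm₁ + c)/(cpm₂ + c)) with prior c = 0.5 cpm (configurable);
the prior keeps zero-count genes finite. **Abundance filter**: a gene is
kept when cpm > 5 in at least one of the two samples — the least destructive
reading of a "cpm ≤ 5 filtered out" rule; whether the original filter was
per-sample or per-pair is not decidable from its one-line description.

## BCV from housekeeping genes

Housekeeping genes are assumed unchanged between conditions, so their
across-sample scatter is biological noise plus Poisson counting noise. The
estimator: (1) cpm-normalize and drop low-abundance housekeeping genes;
(2) apply a median-ratio normalization *within the housekeeping panel* —
a block of strongly regulated genes changes the effective sequencing depth
and would otherwise masquerade as biological variation common to every
housekeeping gene; (3) compute each gene's squared CV across the m samples;
(4) divide the median CV² by median(χ²_{m−1})/(m−1) — with m = 2 the
per-gene CV² is approximately (total CV²)·χ²₁, whose median is only 0.455 of
the mean, so the raw median underestimates by ≈ 35%; (5) subtract the
Poisson term (median 1/mean-count) in quadrature and floor the result at
BCV = 0.01. On the default simulation (200 housekeeping genes, 10⁷ reads)
the estimate lands within ±0.01 of the generating 0.045 across seeds.

## PCSF: objective, solvers, tuner

Effective prize p′(v) = max(β·p(v) − μ·deg(v), 0), with deg taken in the
full interactome; the clamp keeps exclusion penalties nonnegative.
Objective of forest F with κ trees:
Σ_{v∉F} p′(v) + Σ_{e∈F} cost(e) + ω·κ, cost(e) = −log₁₀(confidence).
A valid forest is acyclic and every tree contains ≥ 1 prized gene; both
solvers assert this and re-derive the reported objective after solving.

**Exact solver** (guarded to 20 nodes): enumerate node subsets; on a fixed
subset the optimal edge set is an ω-aware minimum spanning forest — Kruskal
that only adds an edge while its cost is below ω, because merging two trees
trades one ω charge for the edge. (A plain MSF is wrong: it force-merges
terminals whose connecting edge costs more than ω.) Subsets whose forest
strands a terminal-free tree are dominated by the subset without those
nodes and are skipped. Ties break toward fewer nodes, then the
lexicographically smallest node set, making tests deterministic.

**Heuristic**: a virtual root is wired to every positive-p′ node at cost ω.
Two candidate node sets are built — (a) cheapest terminal-to-tree
shortest-path growth from the root, (b) the union of shortest paths along
the terminal metric-closure MST — and each is finished identically: MST of
the induced augmented subgraph, bottom-up strong prune (a subtree survives
only while its collected p′ exceeds its connection cost; ties prune), then
exact re-optimization of every surviving tree of ≤ 14 nodes over its own
node set. The re-optimization step repairs rootings where the MST entered a
tree through a weak terminal, the dominant failure mode of prune-only
pipelines. The better-scoring candidate (or the empty forest) is returned.
Against the exact solver on 4,000 random ≤ 12-node instances the heuristic
matches the optimum on ≈ 99% and is never below it (it is an upper bound by
construction); residual gaps come from growth picking a different Steiner
routing than the optimum.

**Tuner**: grid over ω × β × μ (defaults ω ∈ {1,5,10}, β ∈ {1,5,10,15},
μ ∈ {0.01,0.03,0.05}, inside the conventional ranges ω 1–15, β 1–15,
μ 0.01–0.05); admissible points have a nonempty forest capturing ≥ 10% of
prized genes (the admissibility floor is this package's addition — the
min-mean-degree rule alone would accept degenerate near-empty forests);
selection is minimum mean degree, ties → more terminals, then smaller ω,
β, μ.

## Randomization and prioritization

Each of n = 100 replicates samples |terminals| nodes uniformly without
replacement, assigns them the original prize multiset in random order, and
re-solves with identical parameters. Per node we report: frequency
(fraction of replicates whose forest contains it), the mean degree
centrality over the forests containing it, and the *expectation* of its
random degree centrality (sum over replicates / n, absences = 0).
Degree-matched terminal sampling is available behind
`sampling="degree"`.

The selection rule (defaults: frequency ≤ 0.01; degree, eigenvector and
betweenness centralities in the optimal network all > 0.001, conjunctively;
random degree statistic < 0.001; rank by eigenvector, ties by betweenness
then gene id; top 6). Two deliberate choices:

* The random-degree filter uses the **expectation** statistic by default.
  In small randomized forests (tens of nodes) any member's within-forest
  degree centrality is ~0.03–0.1, so a containing-mean filter at 0.001
  degenerates to "never appeared once", strictly subsuming — and thereby
  voiding — the explicit frequency ≤ 0.01 rule. The expectation scales with
  both how often and how centrally a node recurs, which is what
  "predominant in the random networks" is meant to exclude;
  `random_degree_stat="containing"` restores the literal reading.
* The conjunctive "> 0.001 on all three centralities" rule
  (`rule="methods"`) is the default; the alternative reading that *drops*
  nodes with betweenness above the floor (favoring branch-end genes) is
  available as `rule="results"`. The two appear side by side in the
  procedure this package operationalizes, and they select disjoint node
  classes; the conjunctive form matches the character of the reported
  candidates (mid-branch, non-hub, non-leaf).

Zero-prize Steiner nodes pass through prioritization on equal footing —
the headline use of the method is surfacing exactly such genes.

Eigenvector centrality is computed per connected component by dense
symmetric eigendecomposition (forests are small and bipartite, where power
iteration oscillates), entries made nonnegative, L2 norm 1 per component;
singletons get 1. Betweenness uses exact all-pairs shortest paths with the
standard 2/((N−1)(N−2)) normalization; degree centrality is deg/(N−1).

## Clustering and enrichment

Girvan–Newman removal of the highest edge-betweenness edge (lexicographic
tie-break on the edge), scoring every partition along the removal sequence
by modularity on the original graph and keeping the best (earliest on
ties). Annotations are first restricted to experimental evidence codes
(EXP, IDA, IEP, IGI, IMP, IPI); unknown codes are dropped with a warning.
Per cluster, each term with k ≥ 1 annotated members is tested with the
hypergeometric upper tail P(X ≥ k) against the background universe (all
interactome genes by default); BH adjustment is applied within the cluster
and q ≤ 0.005 is flagged (0.005 is the stringent procedural threshold; the
looser 0.05 sometimes quoted alongside it is available via `q_max`). Term
ancestry is not propagated — annotations are used flat, as given.

## ZIP synergy

Inhibition at the 72 h timepoint is 1 − CI_treated/CI_control (clipped to
[0,1]). Monotherapy curves are smoothed with 4-parameter logistic fits
(bounds: floor ∈ [0, 0.3], plateau ∈ [0.3, 1], slope ∈ [0.05, 10], EC50
within 100× the dose range; fit failures fall back to the observed values,
logged). The independence surface is ŷ₁ + ŷ₂ − ŷ₁ŷ₂; the score is the mean
of observed − expected over all combination cells, classified by sign.
This is the independence-surface form of ZIP: the full published model
refits potency along each row and column, which changes per-cell deltas
but not the sign/classification contract this package relies on. The
plateau bound starts at 0.3 rather than 0.7 so sub-maximal inhibitors
(including the synthetic default, plateau 0.6) are fitted without bias.

## What the synthetic data emulates — and what it does not

`SynthConfig` defaults define the study conditions: 2,000 genes, 100 DE at
|log₂FC| = 3, 200 housekeeping, BCV 0.045, 10⁷ reads/library; a 500-gene
preferential-attachment interactome (confidences 0.7–0.99) carrying a
15-gene planted module wired as a spanning tree plus ~20% extra internal
edges in the top confidence decile, its 8 prized members attached through
the 7 unprized ones (so recovering the module *requires* Steiner nodes), and
module members placed on low-degree backbone positions — a
treatment-specific sub-pathway lives in network branches, and placing it on
hubs would turn its cheap internal edges into a shortcut corridor for
unrelated shortest paths; 50 annotation terms at background rate 0.08 with
one term enriched 10× on the module and 30% electronic (IEA) records; 8-dose
two-fold dilution surfaces from 4PL curves with plateau 0.6, chosen so a
planted delta of +0.15 never clips against 1.

Deliberately not simulated: read-level data, batch effects, more than two
conditions per comparison, annotation-term hierarchy, and measurement noise
on dose–response surfaces (the generator emits expected inhibitions; ZIP
recovery results therefore demonstrate estimator correctness, not
robustness to assay noise). Passing tests show the algorithms recover
planted structure under their own model assumptions; they do not certify
performance on real interactomes, whose confidence scores, degree
distributions and annotation biases differ.

One scale effect deserves emphasis: with 8 terminals over 500 nodes, a
uniformly sampled random-terminal replicate hits any given node with
probability 8/500 ≈ 1.6%, so over 100 replicates a typical forest node
appears 1–3 times and module neighbourhoods more often. Specificity
filtering at frequency ≤ 0.01 is therefore intentionally harsh at this
scale — often everything is filtered — whereas on interactome-scale graphs
(10⁴ nodes, hundreds of terminals) the same thresholds are informative.
The randomization machinery itself is deterministic under a fixed seed and
is tested as such.

## Problem sizes and determinism

Default test and acceptance workloads: 200 exact-vs-heuristic instances at
≤ 12 nodes; 500 exact-test oracle triples at s ≤ 200; 10,000-gene null
calibration; one 500-node tune + solve + 100-replicate randomization;
100-seed enrichment sweep; 800-gene two-treatment pipeline run twice for
byte-identity. All randomness flows through explicit integer seeds
(numpy `default_rng`; per-treatment seeds derived via CRC32 below 2³¹);
all outputs are plain text with fixed float formatting, so identical
configurations produce byte-identical files.
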