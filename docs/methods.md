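# Methods

This note documents the models, the numerical choices, and what the
synthetic data does and does not emulate.

## Discrete traits: the Mk model and the re-rooting method

Binary traits evolve under a 2-state continuous-time Markov chain. Two
parameterisations are supported: **ER** (default), one rate *q* in both
directions with closed-form transition probability
P(stay | t) = ½(1 + e^(−2qt)); and **ARD**, rates q01/q10 with
stationary distribution (q10, q01)/(q01+q10). Branch lengths are in
whatever time-like units the input tree carries; rates are per unit
branch length.

The tip-state likelihood is computed by the pruning algorithm
(post-order conditional likelihood vectors) with per-node rescaling, so
trees of 55+ taxa do not underflow. The root prior defaults to flat
(½, ½) and can be set to the stationary distribution or an explicit
vector.

**Rate fitting** maximises the log-likelihood over log q ∈
[ln 10⁻⁶, ln 10³]: a 33-point log-spaced scan locates the basin for
every trait (these likelihood surfaces can be bimodal — see the
branch-length artefact below — and plateau at both extremes), followed
by golden-section refinement, converging far below 1e−8 in
log-likelihood. The search is fully deterministic. Data with all tips
identical drive the rate to the lower bound; this is reported via an
`at_bound` flag, not an exception. The ER path is vectorised across
trait columns (`fit_er_rates`), which makes 500-trait simulation
studies run in seconds. ARD uses L-BFGS-B from three fixed starts.

**Marginal ancestral states** use the re-rooting method: each internal
node in turn is made the root (the original degree-2 root being
suppressed, its two incident edges merged — valid by
Chapman–Kolmogorov), the pruning pass is rerun, and the node's marginal
posterior is the normalised prior-weighted root conditional vector. For
a time-reversible model with its matching prior (ER + flat, ARD +
stationary) this equals the exact marginal obtained by summing over all
other nodes' states; the test suite verifies this against exhaustive
enumeration on trees of ≤ 6 leaves and against
`phytools::rerootingMethod`. The fitted root marginal log-likelihood is
the per-trait tree goodness-of-fit score used in the arbitration table.

**Missing data** ("prune" policy, default): per trait, taxa without an
observed state are removed from the tree, with unifurcations collapsed
by summing branch lengths, so all retained path lengths are exact.
"strict" raises instead. When two trees are compared on one trait, both
are pruned to the *same* taxon set first — log-likelihoods on different
data are not commensurable.

**Polytomies** are accepted by the tree layer but rejected by both ASR
modules, with one deliberate exception: a trifurcating *root*, which is
exactly the shape a re-rooted binary tree takes.

## Continuous traits: Brownian motion

Tip values are jointly normal with covariance σ²C, where C_ij is the
shared root-to-MRCA path length. The root estimate is the GLS mean
â = (1ᵀC⁻¹1)⁻¹1ᵀC⁻¹x; σ² is estimated by ML — residual quadratic form
divided by *n*. The estimate at any internal node is the GLS root
estimate of the tree re-rooted at that node (equal to the conditional
expectation of the node's value given the tips under a flat root
prior), with variance σ̂²(1ᵀC_r⁻¹1)⁻¹ and 95 % CI multiplier 1.959964.

Note on the rate estimator: `phytools::fastAnc` scales its node
variances by the REML (independent-contrasts) estimator, RSS/(n−1);
this package uses the ML estimator, RSS/n, as the simpler and clearly
documented choice. The two differ by the constant factor (n−1)/n, which
cancels exactly in the between-tree variance *ratios* that the
arbitration reports — the cross-validation test against fastAnc
rescales by this factor and then demands exact agreement. Traits are
analysed on the scale given; a per-trait log10 transform is available
as a flag and off by default.

The continuous-trait tree-fit score is the arithmetic mean of the
ancestral variances over all interior nodes; between trees it is
reported as the ratio A/B (smaller = A's reconstruction tighter).

## The arbitration summary

Per binary trait: (logL_A, logL_B, favoured), favoured being the higher
log-likelihood; |ΔlogL| < 1e−6 counts as a tie, excluded from the
mean-advantage denominators. Per continuous trait: mean variances and
their ratio. The summary reports favoured counts per tree, the mean
log-likelihood advantage within each favoured class, and the grand mean
of the variance ratios. Running the shipped published Dictyostelia
table through this summariser yields 7/6/0 favoured counts, a mean
multi-protein advantage of 3.44, and a mean variance ratio of 0.2533;
the published text also quotes "1.06" for the SSU-favoured mean, which
does not match recomputation from the published per-trait column
(≈ 1.43) — this package always reports the recomputed value.

## Topology comparison

Splits are non-trivial bipartitions of the unrooted tree; comparison is
outgroup-agnostic on the leaf-set intersection (≥ 4 shared leaves
required). The non-consensual count is |splits(test) −
splits(reference)|, equal to RF/2 for binary trees (property-tested
against dendropy's RF on hundreds of random pairs). Polytomous test
trees are not penalised for nodes they do not resolve; reference splits
absent from the test tree are reported separately as `unresolved`.

## Sequence statistics

Concatenation pads taxa missing a fragment with gaps across that
fragment's span and records 0-based half-open fragment intervals.
Column filtering is an explicit, reproducible proxy for manual
alignment editing: a column survives when its gap fraction is ≤ 0.2
(default) and its modal non-gap residue reaches the consensus threshold
(default 0, i.e. gap-only filtering). It is a proxy only — it is not
claimed to reproduce any manually edited column count. G/C content
pools (G+C)/(A+C+G+T) per taxon across fragments; gaps and N/X are
excluded from both numerator and denominator.

## The synthetic study generator

`make_study_fixture` emulates the *shape* of the real inputs, not their
content: 55 taxa (3 outgroup + groups of 3, 6, 12, 31, matching the
real sampling emphasis on group 4), two rival trees over the same leaf
set with identical topology, 13 binary + 12 continuous traits, and six
coding fragments of 0.4–1.3 kb.

* **Trees.** Each group is a Yule subtree rescaled to depth 0.4,
  attached to a fixed backbone (stems 0.15–0.3); the uniform tree's
  root-to-tip depth is ≈ 0.9. The rate-heterogeneous ("SSU-like") rival
  rescales the uniform tree clade-by-clade: everything in group 4 —
  stem included — × 0.02 (the 50-fold compression of that region in
  SSU-style trees), groups 1–3 interiors × 5, and the group-1 stem × 8
  (the long deep branch isolating that group).
* **Traits.** The first binary trait is clade-diagnostic: present
  throughout group 4 *except three scattered taxa*. The scattered
  absences matter: real presence/absence traits are not perfectly clean
  on any tree (in the real data the trait-lacking violaceum-complex
  species sit inside the SSU tree's compressed region), and it is
  precisely the within-clade changes forced onto near-zero branches
  that produce the reconstruction artefact below. A second trait marks
  a group-4 subclade; the rest are Mk-simulated at q = 0.5. Continuous
  traits are BM at σ² = 1, the first three with a +2 shift in group 4
  (the size-increase pattern). 5 % of trait cells are masked as missing
  (the diagnostic trait is kept complete so deep-node queries always
  resolve). Every third discrete trait is written as raw
  "present"/"absent" strings with a YAML binarization rule, so the
  binarization path is exercised end-to-end.
* **Fragments.** Per-taxon G/C targets follow a clade gradient
  (group 4 ≈ 0.30, group 3 ≈ 0.35, outgroup ≈ 0.45, group 1 ≈ 0.50,
  group 2 ≈ 0.57, ± 0.02 jitter), with one designated group-4 taxon at
  exactly 0.27 and one group-2 taxon at 0.61 — the span reported for
  the real amplicons. Bases are i.i.d. with P(G)=P(C)=gc/2; at ~4 kb
  per taxon the realised G/C lands within ±2 pp of target. A few taxa
  lose a fragment at random (failed amplifications); the two
  G/C-extreme taxa are protected.
* **Determinism.** One seeded numpy Generator threads through all
  simulators; a fixed seed gives byte-identical files. Seeds and the
  group membership are recorded in `rules.yaml` / `manifest.json`.

What the fixture does **not** emulate: real sequence content or
alignment structure (bases are i.i.d.), topological conflict between
the rival trees (they differ only in branch lengths, per the fixture's
design), realistic trait correlations, and rate variation beyond the
block-wise clade scalers. Passing tests on the fixture therefore
demonstrate correctness of the inference machinery under the stated
models, not robustness to real-data model violations.

## The branch-length artefact

On the uniform tree the diagnostic trait's fitted rate is moderate and
deep ancestors outside group 4 are confidently trait-free (posterior
< 0.01). On the rate-heterogeneous tree the same data force the trait's
within-clade changes onto ×0.02 branches; the ML rate escapes into a
saturation basin (q̂ ~ 50 vs ~0.5), transition probabilities on the
long deep branches approach ½, and the deep ancestors of groups 1–3 are
assigned the trait with ≈ 50 % probability. Notably this is
*impossible* for a perfectly clean clade trait on an
identical-topology rival: there the single-change explanation on the
clade stem is always cheaper than saturation and deep posteriors stay
near 0 on both trees. The few within-clade absences are what arm the
artefact — a caveat worth knowing when using deep-node posteriors to
judge tree quality.

## Problem sizes and tolerances

Oracle-equivalence tests enumerate all internal-state assignments on
100 random trees of ≤ 6 leaves (tolerance 1e−8); parameter recovery
uses 500 Mk traits on a 300-leaf Yule tree and 200 BM replicates on 200
leaves (mean estimate within 10 % of truth); the marker statistic is
checked against dendropy's RF on 500 random pairs of 5–25 leaves.
Branch lengths of exactly 0 are clamped to 1e−8 before any likelihood
or covariance computation. Ties in the arbitration use |ΔlogL| < 1e−6.
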