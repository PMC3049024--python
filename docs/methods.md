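# Methods

`dogphylo` implements a complete pipeline for asking where a monophyletic
clade (for example the eukaryotes, or the bacteria) attaches to a fixed
reference ("host") phylogeny, starting from nothing but per-taxon protein
sets.  The stages are: (1) discovery of discrete orthologous groups
(DOGs) by iterative profile search; (2) construction of a binary
detection/non-detection matrix and a concatenated amino-acid supermatrix;
(3) Bayesian and maximum-likelihood tree inference; (4) a constrained
"intersection" scan that evaluates, for every branch of the host tree,
the marginal likelihood of the outgroup attaching there, summarized as
log10 Bayes factors; (5) SH and AU topology tests over the same
hypothesis set; and (6) quartet-support and compositional diagnostics.
A synthetic-data module generates every input with known ground truth,
so the whole pipeline can be exercised and validated without any genome
downloads.

## Orthologue discovery

Each sequence in the proteome set seeds an iterative search.  The
current hit set is aligned (progressive aligner: 3-mer distances, UPGMA
guide tree, profile–profile alignment under BLOSUM62 sum-of-pairs
scores with affine gaps; the aligner is a pluggable callable), columns
with strictly more than 50 % gaps are removed, sequences with strictly
more than 95 % identity to an already-kept sequence are dropped (greedy,
input order; identity is computed over mutually ungapped columns), and a
new profile is built.  Iteration stops when the hit set is identical to
the previous iteration's, or at a hard cap (default 30) with a
`converged=False` flag — the fixpoint definition guarantees termination
even for oscillating hit sets.

The profile is a log-odds position-specific scoring matrix with
per-column affine gap penalties (penalties shrink with the column's gap
fraction), scored against targets by banded local dynamic programming
(Gotoh three-state recursion; band half-width 12 around the scaled
diagonal).  E-values use a Gumbel null fitted by maximum likelihood to
the scores of 500 shuffled decoys drawn from the database residue pool,
refitted at every iteration; `E = D * P(score >= s)` with `D` the number
of database sequences.  The default acceptance threshold is `E <= 1e-5`.
This PSSM machinery deliberately replaces a full profile-HMM engine: it
preserves every behaviour the protocol depends on (iteration, E-value
thresholding, category calls) at a fraction of the complexity, and the
search interface is pluggable so an external engine can be substituted.

Search outcomes fall into three categories: (1) only the seed; (2) more
than one sequence but at most one per taxon; (3) paralogues in at least
one taxon.  Category-2 hit sets are accepted as DOGs only if **every**
member's own search returns exactly the same sequence set (set
equality); disagreement discards the group.  This reciprocal-consistency
rule is the pipeline's main precision guard: a single spurious hit in
one member's search (for example a borderline E-value fluctuation)
disqualifies the group rather than contaminating downstream matrices.
Outgroup proteomes are scanned per genome with each DOG's final profile;
only the highest-scoring hit at the threshold is kept per genome, ties
broken by sequence id.

## Character matrices

Detection/non-detection of each DOG across taxa gives a binary matrix
(no all-zero columns can occur, since an undetected family is never
observed).  Family alignments are trimmed by a conserved-block filter:
a column is conserved when its modal residue occurs in more than half
the sequences and gaps are under half; retained blocks start and end on
conserved columns, tolerate at most 8 contiguous non-conserved columns,
and must span at least 5 columns.  These defaults stand in for a
Gblocks-style cleanup and are configurable; the filter is deliberately
pluggable so an external trimmer's output can be substituted.  Trimmed
alignments are concatenated over the full taxon set (absent taxa
contribute all-gap rows) and columns observed in fewer than a minimum
number of taxa (default 10) are removed; a stricter variant keeps only
columns observed in at least a chosen fraction of taxa.  Coordinates in
all reports are 1-based inclusive.

## Likelihood models

Amino-acid likelihoods use the empirical WAG, Dayhoff and BLOSUM62
exchangeability matrices (shipped as plain-text data, frequencies
included), rate matrices normalized to one expected substitution per
unit branch length.  Binary detection characters use a two-state
reversible "restriction" model with free stationary frequencies, with
every site likelihood conditioned on observability (divided by
`1 - P(all absent)`), because families absent everywhere cannot enter
the matrix.  Rate variation across sites is discrete-gamma with
equal-probability categories (8 for binary data, 4 for amino acids by
convention here) whose rates are the conditional bin means and average
exactly 1.  The covarion extension doubles the state space with hidden
ON/OFF classes; OFF states are frozen and switching occurs at rates
`(s_on, s_off)`.  No covarion renormalization is applied, so with an
all-ON root the model reduces exactly to the base model as the switch
rates vanish — the property the limit tests assert.  Branch lengths are
therefore in expected substitutions per site *for an ON site*.

The pruning engine compresses alignments to site patterns, uses
eigendecomposition of the symmetrized rate matrix for transition
probabilities, and rescales partial likelihoods per pattern to avoid
underflow.  Branch-length proposals and optimization use an exact
Euler-tour sweep: the partial likelihoods flanking one edge are
maintained incrementally so a single-edge evaluation costs O(1) matrix
products; a dirty-flag scheme skips recomputation of untouched
subtrees.  Ascertainment conditioning rides along as an extra
zero-weight all-absent pattern, so every edge-local evaluation is
conditioned exactly.  Branch lengths are bounded to [1e-8, 20];
per-branch scalar optimization uses bounded Brent with tolerance 1e-7,
and coordinate-ascent sweeps stop when the log-likelihood improves by
less than 1e-6 (gamma shape, when optimized, alternates with the sweep).

## MCMC and ML search

The sampler is Metropolis–Hastings over branch lengths (multiplier
proposals in a systematic Euler-tour scan; exponential prior with rate
10), gamma shape (reflected sliding window, uniform prior on
[0.01, 100]), and NNI topology moves when the topology is free.  One
generation is one elementary proposal.  Two tuning knobs trade mixing
granularity for throughput on large pattern tables: `proposals_per_edge`
makes several consecutive proposals per edge visit (amortizing the
edge-flanking partials), and `shape_every` spaces shape moves out to
every k-th sweep (each shape evaluation costs a full recompute).
Optional Metropolis coupling
runs `n_chains` incrementally heated chains (heat `1/(1 + T·i)`,
default temperature 0.2) with adjacent-pair swap proposals; large
fixed-topology scans default to a single cold chain, since topology —
the hard mixing problem — is held fixed there.  Burn-in is explicit
configuration, not auto-detected; `plot_trace` renders lnL/parameter
traces for manual inspection.  For the large fixed-topology scans the
engine stores partial likelihoods in single precision; the resulting
log-likelihood error (relative ~1e-5) is negligible against the
hundreds of log-units separating attachment hypotheses, and all oracle
tests run in double precision.

ML search starts from a deterministic neighbour-joining tree on LogDet
distances (ties broken by index; the implementation is deliberately
order-stable so the pipeline is a pure function of config and seed) and
hill-climbs over NNI neighbours, re-optimizing branch lengths per
candidate, until no neighbour improves.  Bootstrap supports come from
full re-searches on multinomially resampled columns.

## Intersection scan and Bayes factors

Attachment hypotheses are one per internal host edge, plus any
explicitly listed terminal edges (the analogue of adding unusually long
tip branches by hand).  The outgroup subtree is grafted at the midpoint
of the host edge via a stem (all lengths then free in the MCMC).  Per
hypothesis and model, a fixed-topology MCMC yields sampled
log-likelihoods; the log marginal likelihood is the harmonic-mean
estimate computed in log space (`log n - logsumexp(-lnL)`), with a
moving-block bootstrap standard error (block length ~ sqrt(n), 1,000
pseudo-replicates).  The harmonic mean is upward-biased and noisy in
absolute terms, but every downstream quantity depends only on
*differences and ranks* across hypotheses evaluated on the same data,
where the shared bias largely cancels; stepping-stone sampling over a
Beta(0.3, 1)-spaced ladder of 8 power posteriors is provided as an
independent cross-check and is validated against a quadrature oracle in
the tests.  Log10 Bayes factors are `(logML_best - logML_h) / ln 10`
per model (best = 0); the across-model average ranks the edges, values
above 1000 are flagged, and the host tree is emitted with per-edge
annotations.  Cross-model agreement is summarized by OLS r² between
per-model Bayes-factor vectors — the model-independence diagnostic.
A lateral-transfer control removes families whose host-side presence is
confined to a focal clade while also being detected in the outgroup.

## Topology tests

Per-site log-likelihoods are computed at each hypothesis's optimized
branch lengths, stored at the pattern level with weights (resampling
patterns with multinomial weights is equivalent to resampling sites and
much faster; the equivalence is asserted in tests).  The SH test uses
the classic simultaneous construction: centred RELL replicates, null
deviate `max_g S_gb - S_hb`, one-sided against the observed deficit;
the ML hypothesis has p = 1 by construction and the test protects each
true hypothesis at the nominal level.  The AU test fits
`z(BP) = d*sqrt(r) + c/sqrt(r)` by weighted least squares over bootstrap
proportions at scales 0.5–1.4 (step 0.1, 1,000 replicates per scale
by default) and reports `1 - Phi(d - c)`; hypotheses winning or losing
every replicate at every scale are clamped to 1 or 0 with a degenerate
flag.  Reported p-values are floored at 1e-5.  Only the standard joint
test over the full hypothesis set is implemented; pairwise AU variants
are out of scope.

## Quartet support and composition

Every gene tree is decomposed into all four-taxon subsets; the induced
quartet topology comes from the four-point condition on topological
(edge-count) distances, with ties treated as unresolved and
uninformative.  A quartet votes on every reference edge that splits its
four taxa two-against-two (the standard quartet-mapping attribution),
and per-edge support is the percentage of informative quartets that
agree.  Compositional profiles are pooled amino-acid frequencies (gaps
excluded); the heterogeneity diagnostic regresses the Euclidean (or
chi-square) distance between each hypothesis's profile and a target
composition against the average Bayes factors, to check that
attachment preference is not a compositional artefact.

## Synthetic data

The generator produces: birth–death species trees (optionally rescaled
to a target height in expected substitutions per site); gene content by
a reversible two-state gain/loss Markov chain along the tree (gain 0.5,
loss 1.0 per unit branch length, root presence probability 0.6 by
default — loss-biased dynamics with a majority-present root, a regime
in which detection patterns are informative but far from saturated).
Families absent in every taxon are discarded and replaced until the
requested count is met, mirroring the fact that undetected families are
unobservable — closed-form checks of tip presence must therefore use
the observability-conditioned expectation.  Gene gain is modelled as a
reversible chain rather than innovation-only so the generating process
matches the restriction model used for inference.  Sequences evolve
site-i.i.d. under the empirical models with per-site gamma categories
(covarion on the doubled state space when enabled); proteomes are built
per family from presence patterns, with optional diverged paralogous
copies; intersection datasets graft a labelled outgroup subtree onto a
known host edge and record the truth.  Indels are off by default — when
enabled, gaps are a per-site Bernoulli deletion on a random subtree,
which exercises gap handling but is not a model of indel evolution.
All generators are driven by seeded NumPy generators with fixed child
streams, so identical seeds give byte-identical outputs.

What the generator does **not** emulate: lineage-specific compositional
bias, rate variation across branches beyond the covarion, alignment
error (sequences are simulated already homologous per column), domain
shuffling, and realistic paralogue birth–death.  Passing tests
therefore demonstrate correctness of the machinery and recoverability
under model-matched data, not robustness to every real-data pathology.

## Problem sizes used by the test suite

The validation suite runs on one CPU; sizes were chosen as the smallest
that leave the assertions far from their noise floor.  Likelihood
oracles use all topologies of up to 5 taxa with up to 6 site patterns.
Parameter recovery uses 8 taxa x 10,000 sites (WAG+Γ4).  Orthologue
recovery uses 200 families (plus two injected paralogous families) over
12 taxa at 50 residues per protein.  Attachment recovery uses ten
seeded datasets of a 12-taxon host with a 4-taxon outgroup at 1,200
amino-acid sites, MCMC of 1,200 generations per hypothesis, with the
first dataset scanned under both WAG and Dayhoff for the cross-model
correlation; the SH corroboration uses 1,000 RELL replicates.  The
pipeline smoke test runs 8 host taxa, 3 outgroup taxa, 100 families and
2,000 intersection sites.  The acceptance script uses 10,000 sites and
5,000-generation chains per hypothesis and model.

## Known limitations

The harmonic-mean marginal likelihood is a high-variance estimator; it
is used for ranking on shared data, and the stepping-stone alternative
exists for absolute comparisons.  The SH test's least-favourable null
makes it conservative, so "not significantly worse" statements are
weak.  NNI-only topology search (both ML and Bayesian) can in principle
be trapped by local optima that SPR would escape; at the taxon counts
used here the tests show exact recovery.  The aligner and block filter
are serviceable stand-ins with pluggable interfaces, not competitors to
dedicated alignment/trimming tools.  Split networks and pairwise AU
comparisons are explicitly out of scope.
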