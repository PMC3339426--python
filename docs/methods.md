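# Methods

This note documents the models, algorithms and default parameters behind
`xhyb`, the choices made where the design was genuinely open, and what
the synthetic generators do and do not emulate.

## Hybridization graph

Similarity hits (BLAST-tabular rows) between transcript queries and probe
subjects are retained when `percent_identity >= 80` **and**
`alignment_length >= 100` bp; both thresholds are inclusive. Duplicate
(probe, transcript) pairs collapse to the single best-scoring hit
(bitscore, then identity): the graph models *whether* hybridization is
plausible, not how many local alignments support it. Probes with no
qualifying hit remain in the graph as isolated nodes labeled "no
predicted target" rather than being dropped, so the probe universe is
preserved for downstream accounting.

Per-probe **ambiguity** is the number of adjacent transcripts and
**redundancy partners** the number of other probes sharing at least one
transcript; a probe with ambiguity 1 and no partners is "specific".
These are one explicit operationalization of informal notions of probe
specificity/redundancy; other readings (e.g. weighting by identity) are
possible and the raw graph is exported (XGMML/GraphML) for them.

`estimate_gene_count(graph, P)` counts connected components of the
subgraph induced by the probes P, their adjacent transcripts and all
edges among them. It satisfies `count <= |P|` with equality iff no two
probes in P share a transcript, and is non-decreasing in either
threshold for a fixed probe set (fewer edges can only split components).

## EST translation

The translator takes, per EST, the longest ATG-to-stop ORF of at least
`min_orf_aa` (default 30) amino acids across all six frames (standard
genetic code); if no ATG ORF qualifies it falls back to the longest
stop-free stretch. Ties break to the canonical frame order
+1, +2, +3, −1, −2, −3, then to the leftmost start, making the output
deterministic. This is a deliberate simplification of ensemble EST
translators (BLASTX/HMM/heuristic pipelines): the downstream workflow
only needs one protein per EST, and externally produced translations can
be supplied instead.

## Ortholog clustering

All-vs-all protein hits are converted to a similarity graph with
s(i,j) = −log10(evalue), capped at 200 (e-value 0 maps to the cap) and
symmetrized by max; hits with e-value above `evalue_cutoff` (default
1e-5) are discarded. Markov clustering runs on the column-normalized
matrix with expansion power 2 and configurable inflation (default 1.5,
the conventional mid-granularity value), pruning entries below 1e-8,
until the matrix changes by less than 1e-6 or 100 iterations; clusters
are the connected components of the converged support. Reciprocal-
best-hit between-species normalization (as in full ortholog pipelines)
is intentionally omitted — the reusable contribution here is the
projection logic, and precomputed cluster files are accepted as input.
Node ordering is canonicalized (sorted ids) before clustering, so the
partition is invariant to input row order.

**Annotation projection** gives every cluster member the *union* of the
terms of all annotated members (accumulation, not voting — consistent
with transferring curated annotation across orthologs), with provenance
recording the source species/gene per term. Projection is monotone:
adding an annotated member never removes a term. Probe annotation is the
union over the probe's adjacent transcripts; isolated probes keep an
explicit empty set.

## Two-color differential expression

The chain operates on GPR-style per-spot tables (median foreground and
background per channel — the median columns are used throughout; 635 nm
is channel 1).

* **Flags**: spots with negative scanner flags get weight 0; they are
  retained in the data structure and still normalized, but excluded from
  curve fitting and model fitting.
* **normexp background correction**: the net intensity x = fg − bg is
  modeled as B + S with B ~ N(μ, σ²) and S ~ Exp(α). Parameters are
  estimated per array per channel by direct maximum likelihood of the
  closed-form convolution density (Nelder–Mead from two starting points
  on (μ, log σ, log α)); the corrected value is the posterior mean
  E[S | x] = μ_sf + σ·φ(μ_sf/σ)/Φ(μ_sf/σ) with μ_sf = x − μ − σ²/α,
  computed via the scaled complementary error function for numerical
  stability at very negative arguments. An offset (default 50 intensity
  units) is added so downstream log-ratios are damped at low
  intensities; output is strictly positive for any input. Degenerate
  (constant) input falls back to floored subtraction with a warning.
  The MLE was validated against an independently coded optimizer and
  against reference values from an established implementation on a
  frozen fixture (agreement ~1e-7 relative).
* **M/A transform**: M = log2(treatment/reference) with the channel
  roles resolved per slide from its dye orientation, so dye-swapped
  slides share one sign convention and the design matrix needs no swap
  column; A = ½·log2(ch1·ch2). Relabeling the channels and flipping the
  orientation leaves all downstream coefficients unchanged to 1e-10.
* **Print-tip loess**: within each print-tip group (block), M is
  recentred by subtracting a loess fit of M on A — locally weighted
  linear regression with tricube weights, span 0.3, 4 robustness
  iterations (conventional values; the data are not informative about
  them). Groups with fewer than 10 usable spots fall back to the
  whole-array fit with a warning. Weight-0 spots are excluded from
  fitting but still normalized. No between-array scale normalization is
  applied afterwards; the chain deliberately stops at the steps listed.
* **Duplicate correlation**: per duplicated probe, the M-values of its
  two spots are paired across arrays and correlated; per-probe
  correlations are clipped to ±0.9999, Fisher-z transformed, corrected
  for the known small-sample bias of z (subtracting r/(2(n−1)) for n
  arrays), robustly averaged with a 15 %-per-tail trimmed mean, and
  back-transformed, clamping the consensus to ±0.99. This is a
  deterministic consensus estimator, not the REML mixed-model estimator
  used by some packages; the difference is recorded in the fit metadata
  and the estimator is validated by parameter recovery (±0.05 at 2000
  probes × 6 arrays). At least 5 probes with complete duplicate data are
  required.
* **Linear model**: per probe, generalized least squares of M on the
  array-level design (one 0/1 column per line; the dye-swapped pair
  shares the line-37 column because orientation is already folded into
  M). Within-array duplicate spots are treated as observations with
  correlation ρ (block-structured covariance, whitened by Cholesky).
  Coefficients whose design column vanishes over a probe's usable
  observations are marked unestimable (NaN) rather than extrapolated.
* **Empirical Bayes**: the residual variances s²_g with d_g degrees of
  freedom are modeled as s₀²·F(d_g, d₀); (d₀, s₀²) are estimated by
  matching the mean and variance of log s²_g using digamma/trigamma
  corrections (trigamma inverted by Newton iteration). Posterior
  variances s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g) yield moderated
  t-statistics on d₀ + d_g degrees of freedom (normal reference in the
  d₀ = ∞ branch, which is taken when the log-variances show no excess
  dispersion). Probes with zero residual df inherit the prior variance.
  At least 50 probes with residual variance are required to fit the
  prior. On a 5000-gene null with d₀ = 4, s₀ = 1 the fit recovers d₀
  within [3, 5.5] and the moderated p-values are KS-uniform.
* **FDR and classification**: Benjamini–Hochberg step-up per contrast
  (NaN p-values are excluded from the test count and propagate to NaN
  q). A probe is *jointly significant* iff q ≤ α (default 0.05) in both
  per-line contrasts — the intersection reading, chosen because the two
  transgenic lines have independent insertion backgrounds and are not
  biological replicates; the per-probe category is the sign pair of the
  two log2 fold changes (Down/Down, Down/Up, Up/Down, Up/Up). The
  intersection is conservative: under a global null the joint rate is
  ≤ α². An exactly zero fold change at significance (impossible for
  continuous data) tie-breaks to "up" with a warning.

## GO enrichment

Direct annotations are propagated to all ancestors along is_a/part_of
edges with set semantics (an entity reachable by several paths counts
once). Each term with k ≥ 1 selected entities is tested with the
one-sided hypergeometric upper tail p = P(X ≥ k | N, K, n). The default
universe is all probes carrying ≥ 1 propagated term (the full array is
available behind a flag); the default adjustment is Benjamini–Yekutieli,
appropriate for the strong positive dependence of tests along a DAG,
with BH and Bonferroni as options, applied within each namespace
(BP/MF/CC tested separately). No monotonicity of p along the DAG is
assumed or enforced — only set containment of the propagated entities.

## Co-expression

Ortholog clusters map to reference-array probesets through gene→probeset
hits filtered at the same 80 %/100 bp thresholds; a cluster's probeset
set is the union over its members, and clusters with none are reported
unmappable. Probeset expression vectors across the compendium's arrays
are Pearson-correlated; items are clustered by average-linkage
agglomeration (single/complete available) on d = 1 − r and the tree is
cut at height 0.05, 0.1 or 0.2 — *dissimilarity* cut heights, so smaller
is stricter and members of a reported group correlate at r ≥ 1 − h at
the linkage level. The alternative reading of such thresholds as
p-values on r is not taken (the stated intent is to keep only the most
strongly co-expressed groups, which is a statement about r, not about
its significance); groups of size ≥ 2 are reported, singletons
separately. Cutting one tree at increasing heights makes group
membership monotone in the threshold, and canonical id ordering makes
the result independent of input order.

## Synthetic data

All generators are pure functions of (parameters, seed) using
`numpy.random.default_rng`, and each returns its planted truth
(serializable to JSON).

* **Hybridization fixtures** plant probe-transcript edges with identity
  85–99 % over 120–500 bp (mean `edge_density` per probe) plus decoy
  hits failing exactly one threshold; filtering at the defaults recovers
  the planted edge set exactly. A companion fixture wires a chosen
  number of probes (e.g. 318) into an exact number of gene components
  (e.g. 250) by attaching surplus probes to existing transcripts
  round-robin.
* **Two-color experiments** default to the three-slide layout (a
  dye-swapped pair for line 37, one slide for line 45), 2000 duplicated
  probes, per-channel log2 noise sd 0.2 with within-array duplicate
  correlation 0.7 shared between the duplicate spots, additive N(100,
  10) background, a smooth quadratic-in-A dye bias added to the Cy5
  channel, 8 print-tip blocks, 2 % flagged spots, and planted shared
  effects of |log2 FC| 1.5 with 75 % down-regulated. These values were
  chosen once as realistic for spotted cDNA arrays of this vintage; the
  sd, correlation, bias, and effect size are all exposed as parameters.
  The generator does **not** emulate spatial artifacts, saturation,
  carry-over between channels, or sequence-driven intensity differences
  — so passing recovery tests demonstrate the statistics chain, not
  robustness to every real-array pathology.
* **GO fixtures** build a layered random DAG (single root, occasional
  second `part_of` parent), annotate entities with 1–3 random terms, and
  construct the selected set so the planted term's carrier rate among
  selected equals `fold × prevalence` (fold 1 reproduces the background
  rate exactly).
* **Compendia** give module members a shared latent factor with loading
  √r, so expected pairwise correlation equals the requested within-r;
  non-members are independent noise.

## Problem sizes

The test suite and the acceptance script run at desk scale: 2000-probe
× 3-slide experiments, 5000-gene variance ensembles, 2000-probe × 6-array
duplicate panels, 50-term DAGs over 500 entities, and 100-probeset ×
200-array compendia. These sizes were chosen as the smallest at which
the estimators' sampling noise is comfortably inside the asserted
tolerances.

## Known limitations

* The duplicate-correlation consensus is not REML; for designs with few
  arrays it carries the (bias-corrected) small-sample behaviour of
  per-probe correlations rather than a likelihood-based pooling.
* The Markov-clustering pipeline omits between-species score
  normalization, so clusters from very unevenly sampled proteomes may be
  coarser than a full ortholog pipeline's.
* The six-frame translator does not model frameshifts or sequencing
  error, which dedicated EST translators handle.
* Enrichment treats InterPro ids as opaque terms; only GO terms
  participate in DAG propagation.
* The workflow consumes precomputed hit tables; it never runs an aligner
  itself.
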