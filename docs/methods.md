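# Methods

This note documents the models, defaults and numerical choices behind
`kmersig`, and what the synthetic tests do and do not establish.

## Canonical k-mer counting

Counting is exact and strand-agnostic.  With k odd, no k-mer equals its
own reverse complement, so mapping every window to the lexicographically
smaller of (window, reverse complement) is a well-defined canonical form;
ascending order of the 2-bit packed code (A=0, C=1, G=2, T=3) coincides
with lexicographic order, which the implementation exploits to count and
sort k-mers as unsigned 64-bit integers (hence k ≤ 31).  Windows
containing any non-ACGT byte are skipped, as standard counters do; base
qualities are ignored.

Defaults: `k = 31` (the usual human-transcriptome choice; values ≥ 11 are
sensible on real data, while the toy examples in the tests use k = 3–9);
`min_recurrence = max(2, 10% of samples)`; `min_recurrence_abundance = 5`.
The recurrence filter is the only noise control — sequencing errors
produce k-mers seen well in very few samples, which it removes.

## Contig assembly

The assembly reduces the k-mer matrix to contigs in two phases.

**Overlap k−1** is classic unitig-style compaction on the bidirected
k-mer graph.  Junction ambiguity is judged on the *original* k-mer set:
an edge (a → b) is followed only when b is a's sole successor and a is
b's sole predecessor, candidates from a k-mer's own reverse complement
being excluded (a contig never merges with itself).  Each maximal
non-branching path is walked once, in the direction that spells the
lexicographically smaller sequence; walking accumulates a contig whose
running mean count vector is compared with the next k-mer's vector by the
mean absolute contrast

    MAC(c1, c2) = mean_s |c1_s − c2_s| / (c1_s + c2_s),

cutting the contig wherever MAC > `mac_threshold` (default 0.25).  A
sample where both counts are zero contributes 0 to the mean — the formula
is undefined there, and zero is the compatibility-preserving reading
(both vectors agree the sequence is absent).  With the gate disabled
(threshold 1) the output provably equals brute-force unambiguous-path
compaction, which the test suite checks against an independent oracle.

**Overlaps k−2 down to k−max_shift** (default `max_shift = 15`) then
merge the ends of the resulting contigs, bridging k-mers lost to the
recurrence filter.  These passes are dynamic — ambiguity is evaluated on
current contig ends — processed longest overlap first, sweeping contigs
in lexicographic order of sequence, so the result is deterministic and
independent of input order.  A bridge at overlap < k−1 introduces
junction windows that were never features of the matrix; consequently the
asserted invariant is that every *member* k-mer occurs as a window of its
contig (the converse cannot hold for bridged contigs), and members
partition the input k-mer set exactly.

A contig's count vector is the element-wise mean of its member k-mers'
count vectors, updated as members accumulate; the MAC gate therefore
compares current contigs, not just raw k-mer pairs.

## Normalization and labelling

Feature f in sample s becomes `raw_{f,s} / Σ_f raw_{f,s} · C_b`, with
C_b = 10⁹ for contig matrices (counts per billion; contig counts are
small fractions of a library, so CPM would produce awkwardly tiny values)
and 10⁶ for gene matrices.  Downstream models use `log(x + 1)`; the +1
offset avoids log 0.  An all-zero sample normalizes to zeros with a
warning rather than NaN.

Risk labels implement the PSA-free d'Amico adaptation: high risk iff
Gleason ∈ {8, 9} or stage ∈ {pT3b, pT4}; low risk iff Gleason ∈
{6, 7(3+4)} and stage ∈ {pT1, pT2}; everything else — pT3a, pT2 with
Gleason 7(4+3), Gleason 7 without a pattern split, unparseable fields —
is excluded as intermediate.  The source rule lists pT1 both as low-risk
and as intermediate; `pt1_policy` ∈ {"low", "intermediate"} (default
"low") makes the choice explicit rather than guessing.  Relapse labels:
positive iff the event occurred before `t_relapse` years (default 2),
negative iff no event after `t_nonrelapse` years (default 5; (5, 10)
suits low-follow-up cohorts).  Labels are never imputed; unlabeled
samples are excluded from training and evaluation.

## Univariate ranking

Each feature is scored by the positive-class F1 of a one-dimensional
Gaussian naive Bayes classifier under stratified 5-fold CV.  One shared
fold split serves all features, making scores comparable and the whole
matrix scoreable in a few vectorized passes.  Per fold and class the
class-conditional normal uses the training fold's mean and variance (a
10⁻⁹ variance floor prevents degenerate zero-variance fits) and the
training-fold priors; posterior ties resolve to the negative class.
F1 is computed as 2TP / (2TP + FP + FN); a fold where that is undefined
contributes 0, and a feature constant across the cohort scores 0
outright — the worst score, since such a feature carries no signal.
Final ranking ties break by feature id, making the ranking bit-for-bit
reproducible under a fixed seed.

## Stability selection and the final model

2000 resamples (tests and the examples use 200 for runtime) of a
class-stratified half of the cohort, drawn without replacement
(the Meinshausen–Bühlmann subsample size).  Per resample, features are
standardized within the subsample — the L1 penalty must be scale-fair,
as in glmnet — and an L1-penalized logistic regression (liblinear) is
fit with its penalty chosen by internal 3-fold CV over a 5-point grid
anchored at the smallest C that produces any nonzero coefficient.

The penalty rule defaults to the CV loss minimizer (the `lambda.min`
analogue).  The one-standard-error rule was tried first and is still
available (`penalty_rule="1se"`), but it produced 2–5-feature per-resample
models; with several correlated informative features (fragments of one
event, or a variant contig and its host transcript) the lasso then
alternates among them and each falls below the 0.5 frequency threshold.
Signature sizes of 10–30 features above frequency 0.5, as seen in
practice, require the denser per-resample fits the min rule gives; on
pure-noise matrices the selected set remains empty either way (verified
by the null acceptance test).

"Frequency above 0.5" is implemented strictly (> 0.5).  The final model
is an unpenalized logistic regression on all labeled discovery samples,
falling back to a tiny ridge (C = 10⁶) if perfect separation prevents
convergence; zero selected features raise an explicit error instead of
yielding a constant model.  Evaluation uses repeated stratified 10-fold
CV (20 repeats), refitting the logistic model per training fold, with
optional over-/down-sampling applied to training folds only (never before
the split, so nothing leaks).

## Transfer to an independent cohort

Signature contigs are decomposed into their distinct canonical k-mers;
the contig's expression in a validation sample is the **median** of the
matched k-mers' counts — robust to a minority of diverged, filtered or
missing k-mers.  K-mers absent from the validation matrix are excluded
from the median by default (`absent_policy="zero"` instead counts them as
zeros; excluding is the default because absence usually reflects the
validation cohort's recurrence filter, not zero expression).  A contig
with no matching k-mer at all is "missing": it is reported, and its
coefficient is zeroed at prediction time — algebraically identical to
removing the feature without renormalizing, and the model is never
refit.  Medians are taken over raw counts and then scaled by
C_b / (validation sample total over the full matrix), mirroring the
discovery normalization; normalizing the tiny contig sub-matrix itself
would put the two cohorts on incommensurable scales.  The validation
matrix is built with the validation cohort's own recurrence settings.

## The synthetic world

`simulate_cohort` generates what the pipeline is designed to find: two
labelled groups sharing a background transcriptome (default 200 random
transcripts of 500–1500 nt, GC 0.5, lognormal baseline abundances),
plus planted events — by default one novel transcript, one SNV variant
and one retained intron, each expressed `fold_change = 8` times higher in
the positive group at `base_expression = 1` (an average transcript's
level).  Per-sample abundances are gamma-perturbed (negative-binomial
dispersion 0.2, a typical bulk RNA-seq value); reads (default 100,000 of
100 nt per sample — the heavy end-to-end tests use 12,500 for the
single-CPU budget) are drawn multinomially, uniformly positioned, with
random strand.  `cohort_seed` draws an independent cohort from the same
world, which is how validation cohorts are made; `downsample_cohort`
thins reads Bernoulli-wise to emulate low-coverage validation data.
Planted-event truth k-mers are verified absent from the background at
generation time, and the truth table can report which planted events a
signature's sequences capture.

What the generator does *not* emulate: sequencing errors and quality
profiles (`error_rate` exists, default 0 — errors only add low-count
k-mers the recurrence filter removes), repeats and homopolymers, GC
bias, isoform structure, batch effects, or label noise.  A green
end-to-end test therefore establishes that the machinery recovers strong
planted signals from NB-noisy counts at realistic depth — not that real
cohorts of this size would yield replicable signatures.

## Numerical and degenerate-input choices

- Canonical-orientation output: every contig is reported in its
  lexicographically smaller orientation; contigs sort by sequence and are
  numbered `ctg_1 …` in that order.
- MAC 0/0 samples contribute 0; vectors must be equal-length and
  non-empty.
- Ranking reduces the fold count (with a warning) when the smaller class
  has fewer members than folds; single-class input is an error.
- Stability resamples that cannot retain both classes after bounded
  redraws, or whose lasso fails to converge, record an empty selection
  with a warning rather than aborting.
- All randomness flows from explicit integer seeds; reruns with the same
  inputs and manifest produce byte-identical signature JSON (sorted keys,
  no timestamps).

## Known limitations

- In-memory exact counting targets desk-scale data (tens of millions of
  read windows per sample), not 100M-read cohorts; there is no
  disk-based or probabilistic counting.
- Stranded libraries are not exploited; counting is always canonical.
- Only logistic regression is delivered as the classifier; the selection
  and evaluation interfaces accept any fitted scorer in principle, but no
  alternative is shipped.
- Survival (time-to-event) modelling is out of scope; labels are binary
  with an excluded middle.
- The shorter-overlap assembly passes re-test ambiguity on current contig
  ends; other reasonable tie-breaking policies exist, and ours is
  documented (deterministic) rather than claimed canonical.
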