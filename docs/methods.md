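# Methods

This note documents the models implemented in `sclineage`, the conventions
chosen where the procedure was genuinely open, and what the synthetic-data
generator does and does not emulate.

## Synthetic experiment generator (`synthdata`)

**Barcoding.** `make_whitelist` draws distinct random 14-nt and 30-nt words
over ACGT. Hamming-1 near-collisions between words are *not* excluded — real
vendor whitelists contain them, and the retrieval stage must reject the
resulting correction ambiguity rather than assume it away. Words containing
the TGGT anchor motif (or ending in its 3-nt prefix, which would recreate the
motif at the barcode–anchor junction) are excluded, mirroring a vocabulary
designed so the anchor occurs exactly once per cassette; without this
constraint a fraction of lineages would be systematically unparseable, which
is not a property of a working recorder construct.

**Infection.** Each of `n_cells` plated cells receives Poisson(`moi`)
integrations; each integration draws a barcode uniformly (with replacement)
from a `library_size`-entry pool whose entries themselves sample bc14:bc30
pairs uniformly, so pair collisions within the pool are allowed. Defaults
mirror the emulated experiment: 50,000 cells, MOI 0.05, 10⁷-barcode library —
infecting ≈ 1 − e^(−0.05) ≈ 4.9% of cells and yielding ≈ 2,500 distinct
barcodes. Libraries above 10⁶ entries are never materialized; a drawn slot is
mapped to its pair by a counter-based generator keyed on (seed, slot), keeping
memory flat and output deterministic. A cell's reported lineage is its first
integration; multi-integration cells (~2.4% of infected at MOI 0.05) are
flagged so analyses can exclude them.

**Selection.** A fraction `frac_tolerant` (default 0.0822 ≈ 192/2,336) of
founder lineages is drawn without replacement as tolerant; `n_dominant`
(default 2) of these gain a multiplicative per-interval `advantage`. The
default advantage 4.3 puts the two dominant clones at ~45% of the population
by the last sampled day (2·4.3³ / (190 + 2·4.3³)). Sensitive lineages decay
linearly to zero across the timepoints — the simplest model consistent with
their disappearance by the end of selection. Per timepoint (days 0, 3, 6, 9),
`cells_per_timepoint` cells are drawn multinomially from the true lineage
frequencies; frequencies sum to 1 per timepoint by construction.

**Expression.** Counts are negative binomial with log-normal baseline gene
means (σ = 1.2), a shared dispersion θ (default 2), and log-normal per-cell
size factors (σ = 0.25) around a mean depth of 10,000 UMIs. `n_marker_up`
genes (default 50) are shifted up by `effect_log2fc` (default 1 ⇒ 2×) in
tolerant cells and `n_marker_down` (default 30) in sensitive cells; the truth
table records every marker with its sign. Ten mitochondrial genes (`MT-*`)
carry 5% of UMIs; 2% of cells are mito outliers at a 40% share. No generative
model for expression was available to copy, so all of these are artifact
conventions, one knob each, chosen to look like a deeply sequenced cell-line
run.

**Doublets.** 5% of cells are doublets. The two cells' count vectors are
summed and the droplet's library is then re-captured multinomially with gene
shares sharpened by a `doublet_concentration` exponent (default 2.0). The
sharpening models capture saturation in overloaded droplets — UMIs concentrate
in the most abundant transcripts — which is the "high total UMI in few genes"
signature the downstream ratio filter targets. A plain sum cannot carry this
signature: the union of two NB cells always *detects more* genes than a
depth-matched singlet (p₀,doublet = (θ/(θ+μ))^2θ < (θ/(θ+2μ))^θ = p₀,deep
singlet for all μ, θ > 0), so pure-sum doublets are invisible to a
genes-per-UMI lower-tail rule by construction. The default exponent is set so
the planted artifact is unambiguous relative to NB sampling noise; the filter
tests exercise detection of a planted artifact, not the power of the rule on
any particular chemistry.

**Reads.** Read 1 is the 16-nt cell barcode + a random 12-nt UMI. Read 2 is a
10-nt random flank, the 48-nt cassette, and a poly-A tail padding to 90 nt;
only the cassette and its rough distance to the poly-A are constrained by the
construct, and neither flank length affects retrieval. Substitution errors are
injected i.i.d. per base of read 2 at `error_rate`; read 1 is left clean
because no droplet-barcode correction is modelled (see limitations).
Identical config + seed ⇒ byte-identical FASTQ.

## Barcode retrieval (`barcode_trace`)

Per read 2 the TGGT anchor is located allowing one mismatch, at positions
leaving ≥14 nt upstream and ≥30 nt downstream. Exact occurrences beat
single-mismatch ones; among equals the leftmost valid position wins — a
deterministic convention that maximizes valid extractions (the source
procedure does not say how multiple hits were resolved). The 14 nt before and
30 nt after the anchor are validated against the whitelists with unique
Hamming-1 correction: a putative barcode not in the vocabulary is replaced by
the single vocabulary word at distance 1, and rejected if zero or ≥2 such
words exist. When both halves are absent, bc14 is corrected first and bc30 is
attempted only if that succeeds — the sequential rule that keeps the search
cheap without losing sensitivity. Only reads whose halves both end up in the
whitelists survive.

Cells are keyed by the raw 16-mer of read 1 (no 10x-style cell-barcode
whitelist matching — synthetic reads have exact cell barcodes; a documented
limitation for real data). Per cell, each surviving lineage's abundance is its
number of *distinct UMIs* (deduplicating PCR copies); the most abundant pair
is assigned, ties broken by read count, then by lexicographically smallest
lineage id with an `ambiguous` flag. Assignment is independent of record
order.

## Quality control (`qc`)

Cells with fewer than 5,000 UMIs are discarded (a cell at exactly 5,000 is
kept). Two loess-deviation filters follow, each a loess (local linear,
span 0.75, natural-log x) fit of a per-cell ratio on log total UMI:
mito-UMI share (upper tail) and detected-genes/UMI (lower tail). "Deviates
significantly" is made concrete as: robust z-scores of the residuals
(median/1.4826·MAD), a one-tailed normal p-value, Benjamini–Hochberg
adjustment, flag at FDR < 0.1. Zero residual MAD (constant ratios) flags
nothing. Genes are excluded only when rare in absolute count (<50 cells), rare
as a fraction (<5%), *and* weak on average (<1.12 UMIs over all cells —
denominator all cells, reading the rule as a global average). Filter order:
UMI → mito → doublet → gene. Batch correction across captures is a
pass-through hook, not implemented.

## Clone analyses (`clonedyn`)

Cells are labelled tolerant iff their assigned lineage is in the
terminal-survivor set; ambiguous assignments are excluded. Expression is
log-normalized (ln(1 + 10⁴·count/total)) and each gene tested with a two-sided
Wilcoxon rank-sum (tie-corrected normal approximation; exact enumeration when
both groups ≤10 and tie-free). log2FC = log2((μ_t+ε)/(μ_s+ε)) on
de-transformed means, ε = 10⁻⁹. The marker panel is FDR < 0.05 split by sign.
A caveat the tests document: planted fold-changes shift every *other* gene
through per-cell normalization, so at small gene counts the null genes are not
exactly null; at realistic gene counts (≥2,000) the compositional shift is
negligible and the empirical FDR stays at its nominal level.

Clone frequency = cells of the lineage / cells sequenced, per timepoint.
Dominance is called by a pooled two-proportion z-test of first- vs
last-timepoint frequency, BH-adjusted, gated on fold change ≥5 in the
increasing direction — the source reports the phenomenon without a test, so
the gate is set where dynamics of the emulated magnitude (sub-1% → ~20% per
clone) are called and neutral clones are not. Lineages unobserved at both
endpoints are neutral by definition.

## Time-course analysis (`timecourse`)

Pseudotime is an L1-penalized cumulative-logit (proportional-odds) regression
of the ordered day labels on standardized log-normalized expression, fit by
proximal gradient (soft-thresholding on the gene weights, monotonicity
projection on the thresholds). The penalty is selected on a stratified 20%
held-out split by ordinal classification accuracy, then the model is refit on
all cells; the sign convention makes mean pseudotime non-decreasing in day.
This re-specifies the published core of label-supervised pseudotime; the exact
solver schedule and λ grid (0.3–0.003, 5 points) are conventions.

Each gene's pseudotime-ordered expression is smoothed with a centered rolling
median (window 51, symmetric truncation at the edges) and averaged into 50
*equal-count* bins (robust to pseudotime density; an open choice, documented
as such), remainder cells spread over the leading bins. Dominant and neutral
50-bin profiles are compared by OLS on a cubic B-spline basis of bin index
(3 df, the tool-default df) plus group and group×basis terms, with a joint
F-test against the shared-curve null; empirical-Bayes moderation of the
original tool is replaced by the plain F-test. Up-regulated driver genes have
FDR < 5% and positive mean dominant−neutral difference; their z-scored
profiles are clustered with k-means (k = 4 per the observed pattern count,
25 restarts, fixed seed). Note the F-test treats bins as independent
observations; on binned real cells the smoothing induces autocorrelation, so
p-values there are anticonservative — the type-I calibration asserted in the
tests holds for independent bin noise.

## Response classifier (`scastral`)

Inputs are CPM counts cut to the marker panel (374 genes in the emulated
study; a parameter here) and rescaled by tf-idf: tf = the gene's share of the
cell's panel counts, idf = ln(N_cells/(1 + cells expressing)); idf is frozen
at training and reused at prediction so single cells and pseudobulk are scored
on the same scale. The encoder is panel→64→32 with ReLU, decoder mirrored.
Training builds, per cell, one random same-class and one random
different-class partner (2n pairs per batch) and minimizes
w_cos·L_cos + w_rec·MSE + w_lat·mean‖z‖² with L_cos = 1 − cos(z₁,z₂) for
positive pairs and max(0, cos − margin) for negative ones. The three weights,
margin and the regularizer's exact form are unstated in the source; defaults
w_cos = w_rec = 1, w_lat = 0.01, margin = 0 (latent regularizer read as the
mean squared L2 norm, the simplest interpretation). Optimization is Adam
(lr 10⁻⁴) on minibatches of pairs, early stopping with patience 20 over max
250 epochs on a stratified 10% validation split, improvement = lower
validation loss *or* higher validation SVM accuracy. The autoencoder is
implemented directly in numpy with hand-written gradients (verified against
finite differences in the tests).

Cells are split class-stratified into 5 equal batches; per batch the
autoencoder is trained on that batch's pairs, a cosine-kernel SVM (C = 100,
Platt-style sigmoid calibration) is fit on the batch's embeddings, and the
model is scored by raw argmax accuracy on the 4 left-out batches; the
best-scoring of the 5 is kept. Predictions use the calibrated probability:
class assigned iff > 0.75, else undetermined; per-sample fractions keep
undetermined cells in the denominator. Pseudobulk sums counts across cells
and scores the sum as one cell.

Permutation feature importance is the mean drop in AUROC (tolerant
probability vs labels) when one panel gene's tf-idf column is shuffled,
averaged over repetitions with per-gene seeds derived from the master seed.
The random-panel benchmark trains a fresh model per random size-matched panel
and scores each by the Spearman correlation between predicted tolerant
fractions and the planted tolerance across evaluation samples; a panel whose
predictions are constant has no rank correlation and scores 0.

## Problem sizes

The default test-suite and analysis runs use: 50,000-cell infections;
2,000-gene matrices with 500–1,000 cells per timepoint; 10,000 read pairs for
retrieval at a 0.5% error rate; 2,000-gene null panels for test calibration;
500+500-cell classifier fixtures with 40-gene panels; and 100 random panels
(150+150 training cells, 10 evaluation samples) in the benchmark. These sizes
give every statistic enough resolution to assert the stated bounds while a
full suite run completes in about a minute of CPU.

## What passing tests do and do not show

The generator produces clean droplet data: exact cell barcodes, no ambient
RNA, no indels, uniform base errors, a single shared NB dispersion, and
class-conditional means that differ only on the marker program. Passing the
recovery suites therefore demonstrates that each algorithm implements its
specification and can recover planted structure at realistic effect sizes —
not that the pipeline's operating characteristics (recall at a given error
rate, filter FDR, marker power, classifier accuracy) transfer to any
particular chemistry or cell line. Quantities that depend on the deposited
data of the emulated study (specific marker lists, panel size 374, the 549
driver genes, correlations with external drug-sensitivity databases) are out
of reach by design and are represented here by their synthetic analogues.
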