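# Methods

## The individual-sample calling model

The core object is the within-sample ordering relation between two
genes' expression values. Orderings are invariant under any strictly
monotone within-sample transform, so calls do not depend on
normalization choices or on the measurement platform, which is what
makes pooling normal samples "from different sources" into one
background defensible.

**Stable-pair background.** For every gene pair in a normal cohort we
count the samples with a strict ordering each way. The pair is stable
when the majority direction holds in at least a threshold fraction
(default 0.90) of the strictly ordered samples. Samples where the two
values are exactly equal support neither ordering and are excluded from
both numerator and denominator; a pair tied in more than half of the
samples can never be stable. A support of exactly 0.5 has no majority —
the direction is recorded with the lexicographically smaller gene first
and the pair is never stable. The threshold comparison is inclusive
(≥); sources that state the rule as "more than 90%" can set the
threshold accordingly.

**Per-sample test.** For gene *i* with stable partners, the 2×2
contingency table has rows = context (normal background vs the disease
sample) and columns = ordering (*i* above vs below its partner),
counted over the identical partner set. Pairs tied inside the disease
sample are dropped from both rows, so the row margins are always equal
(`a + b = c + d`); this symmetric tie rule is our choice where the
method description is silent. The two-sided Fisher exact p-value comes
from the hypergeometric distribution with fixed margins (degenerate
margins give p = 1). Because the margins agree, the direction rule —
up when the disease-sample fraction of partners below *i* exceeds the
background fraction — reduces to comparing `c` with `a`. Genes with no
stable partner are stable with p = 1 by convention.

**Multiple testing.** Benjamini–Hochberg across the tested genes within
each sample, the only scope that yields per-sample calls. The FDR
threshold comparison is inclusive (q ≤ 0.05) by default and
configurable, as is whether BH runs per sample or the threshold itself.

**Refinement (partner exclusion).** A gene falling from the top to the
bottom of a sample reverses its orderings against every gene it passes,
fabricating "up" evidence for all of them. The guard: a gene keeps its
call only if it remains significant after excluding, from the reversed
pairs supporting its up-regulation (down-regulation), those whose
partner is called down (up). We iterate this to a fixed point, starting
each pass from the full tables with exclusions derived from the current
status map, and make refinement *revocation-only*: a pass can revoke a
call (no longer significant, or direction no longer matching) but never
create one. Revocation-only is the reading of "remained significant",
and it matters: if statuses are instead recomputed freely each pass,
fabricated up-calls and the true down-calls that explain them exclude
each other's evidence in alternation and the iteration oscillates with
period 2. With monotone revocation the called set shrinks every
non-terminal pass, so convergence is guaranteed within one pass per
called gene; in practice two to three passes suffice. `max_iter`
(default 100) is a safety valve; hitting it flags the call as
non-converged.

**Paired calls.** Tumor vs adjacent value per patient per gene; exact
equality is stable. Deterministic rule, no test: called genes carry
p = q = 0, stable genes 1.

**UDEG selection.** Dysregulation frequency = fraction of cohort
samples calling the gene up (down). A gene is a UDEG when it meets the
frequency threshold (default 0.85, inclusive, configurable to strict)
with the same direction in both the paired and the unpaired cohort.
Genes absent from either cohort's universe are not candidates and are
reported separately.

## Association screens

Drugs observed in fewer than `ceil(min_coverage × n_lines)` cell lines
(default half, inclusive) are dropped; each remaining gene–drug pair is
Spearman-correlated over pairwise-complete observations (pairs with
fewer than 3 observations are skipped). Ties get average ranks. The
two-sided p-value uses the exact permutation null of the rank statistic
for n ≤ 9 without ties and the large-sample t approximation otherwise;
every result row records which regime was used. By design the screen
retains raw p < 0.05 without multiplicity correction, matching common
practice in drug-repurposing screens; a BH-adjusted mode is available
but off by default. The immune screen is the same engine against
per-sample cell-type proportions, which must sum to 1 per sample
(tolerance 1e-6). The pathway consistence of two enriched-pathway sets
of sizes n and t sharing con pathways is `(con/n + con/t)/2`, a
fraction in [0, 1], symmetric in (n, t), equal to 1 iff the sets
coincide; it is conventionally reported as a percentage with two
decimals.

## The synthetic-data generator

Gene *i* carries a fixed log-scale location μ_i on an evenly spaced
grid of step `baseline_spread` (default 0.1); a sample's value is
`exp(μ_i + patient_effect + planted_shift + N(0, noise_sd))` with
`noise_sd` 0.2 by default. The grid makes ordering stability tunable:
with these defaults, pairs separated by a few grid steps are stable at
90% while adjacent pairs are not, giving a background that is dense but
not saturated — the regime the method assumes. Defaults (300 genes, 100
normal, 100 tumor, 50 pairs) keep all-pairs computation comfortable on
a laptop while leaving enough samples for frequency thresholds at 85%
to be meaningful. Planted genes shift by their effect size in a random
subset of samples of the stated frequency (nearest-integer count, ties
up; sampled without replacement per gene, independently across genes);
the truth object records exactly which samples were shifted. Paired
cohorts add a shared per-patient, per-gene effect (sd 0.3) to both
members, so tumor and adjacent values correlate within a patient as
real paired tissue does. IC50 matrices set a linked drug's log-IC50 to
a sign-directed multiple of the z-scored log expression of the linked
gene plus unit noise. Immune proportions are Dirichlet (concentration
2) per sample. One global seed feeds a named child stream per generator
call, so outputs are bitwise reproducible and independent of call
order.

What the generator does **not** emulate: multi-platform batch
structure, probe-level artifacts, count noise of single-cell data,
correlated gene modules, or survival outcomes. Passing tests therefore
demonstrate correctness of the algorithmic machinery under a clean
log-normal ordering model, not robustness to every artifact of real
archival expression data.

## Numerical and design choices

- Fisher p-values delegate to `scipy.stats.fisher_exact` with an LRU
  cache over tables (many genes in a concordant sample share the same
  table); tests verify them to 1e-9 against an explicit hypergeometric
  enumeration.
- All-pairs background construction is vectorized row-by-row and
  quadratic in genes; it targets matrices up to a few thousand genes in
  memory. Larger gene universes should be processed in chunks against a
  fixed partner set.
- Tables are written with shortest round-trip float representation and
  read back with `float_precision="round_trip"`, so write/read cycles
  and re-runs are byte-identical.
- Threshold comparisons (stability, FDR, UDEG frequency, drug coverage)
  are inclusive by default with explicit strict variants, since the
  method's descriptions alternate between "at least" and "more than".

## Known limitations

- **Extreme baseline ranks are blind spots.** A gene near the top of
  the normal ordering has few stable partners above it, so even a
  saturating up-shift yields only a handful of reversed pairs and the
  Fisher test cannot reach significance after FDR control (mirrored for
  down-shifts at the bottom). Synthetic studies should plant
  dysregulated genes at interior ranks; for real data this means the
  method under-calls dysregulation of genes already at the extremes of
  normal expression.
- The Fisher test treats a sample's reversed pairs as independent,
  which they are not (pairs share genes); the null calibration tests
  show the net effect is conservative under this generator's model.
- Refinement guards against oppositely-called partners only; a
  coordinated shift of many genes in the *same* direction compresses
  the evidence for all of them and is not corrected.
- The unpaired caller needs a normal cohort large enough to define a
  stable background; with very few normal samples the background
  saturates (every pair trivially "stable") and calls lose meaning.
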