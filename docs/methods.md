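# Methods

## Model

Base-call counts at a site are modeled per replicate as
Dirichlet-Multinomial: **p** ~ Dirichlet(**α**), **x** | **p** ~
Multinomial(n, **p**).  The compound density (with all factorials
generalized through the Gamma function so real-valued inputs are accepted)
is evaluated entirely in log space via `gammaln`, which keeps it finite at
coverages of thousands.  The hierarchical reading also drives the sampler
used in tests and the benchmark generator: a Dirichlet draw per replicate,
then a multinomial draw.

The model's key assumption is exchangeability of replicates within a
sample: replicate stacks are i.i.d. given **α**.  Overdispersion is captured
by α₀ = Σα_k (small α₀ = high inter-replicate variability); systematic
between-replicate effects (batch, library chemistry) are not modeled.

## Pseudocounts

Raw counts are augmented before any likelihood evaluation:
x̃ = x + x_P, where each retained call with error probability
e = 10^(−q/10) contributes ε + e/3 to each of its three *uncalled* channels
and nothing to its own.  ε (default 0.01) models sequencing-independent
noise.  Consequences used by the tests: Σx̃ − n = 3nε + Σ_l e_l exactly, and
every channel is strictly positive whenever n ≥ 1, so no Gamma evaluation
ever sees zero.  The called channel keeps its integer count by default; a
`downweight_called` flag instead credits it 1 − e per call for users who
want the called-base probability reflected there.

## Maximum-likelihood fitting

`fit_alpha` maximizes Σ_i log DirMult(x̃_i; α) with a Minka-style fixed
point

    α_k ← α_k · [Σ_i ψ(x̃_ik + α_k) − N ψ(α_k)] / [Σ_i ψ(n_i + α₀) − N ψ(α₀)]

from a method-of-moments start (mean proportions; α₀ from channelwise
variance matching, defaulting to the mean total count when one replicate or
zero variance makes moments uninformative).  Convergence: relative
log-likelihood change < 1e-6, cap 100 iterations.  Each accepted step must
not decrease the likelihood; a decrease, or hitting the cap with a
non-negligible gradient, triggers an L-BFGS-B fallback on log α with the
analytic gradient.  Details that matter numerically:

- Rows are sorted into a canonical order before fitting, which makes the
  fit exactly invariant under replicate permutation and sample swap.
- Channels with no mass are floored at α_k = 1e-6 to keep the domain open.
- log α is capped at 16 in the fallback: beyond e^16 the density is
  numerically indistinguishable from its multinomial limit, which is the
  supremum direction for under-dispersed (e.g. single-replicate) input.
  Such fits terminate on the flat plateau and are reported converged when
  the log-space gradient has vanished.

## The two-sample score

z is the log likelihood ratio of separate fits (α̂ᴵ, α̂ᴵᴵ) against one
pooled fit α̂ᴵ·ᴵᴵ on the union of the adjusted stacks.  Two safeguards keep
the statistic exact rather than exact-up-to-optimizer-noise, exploiting the
fact that an MLE dominates every other parameter value:

1. the separate optima are also tried as candidates for the pooled optimum;
2. each per-sample likelihood is taken at the better of its own fit and the
   pooled α.

With identical samples the three optima coincide and z = 0 exactly; in
general z ≥ 0 holds exactly, not merely up to tolerance.  No p-value is
attached — the score is thresholded directly (defaults: 1.15 RDD, 1.56 RRD,
always overridable).

Coverage balancing: when exactly one side is mono-allelic on raw counts and
its total coverage exceeds the other side's by more than `trigger_ratio`
(default 2.0), it is replaced by a copy of the other side's replicate
vectors with all non-reference calls renamed to the reference base
(qualities and read contexts retained), so the balanced side inherits the
other side's replicate count.  The rule is flagged in output
(`balanced=1`) and can be disabled.

## Filters

Distance filters (D = read edge, I = INDEL, Y = splice site,
B = homopolymer) flag a site when a fraction r (default 0.5) of the
retained RNA calls lies within d nt (default 5) of the feature; calls whose
read lacks the feature count as infinitely distant.  Letters follow the
conventional flags of difference callers; features are individually
configurable and the letters are aliases.  Distance conventions: deleted or
intronic reference bases are counted directly (an aligned base adjacent to
a splice junction has distance 1); an insertion sits between two reference
bases and both flanking aligned bases get distance 1.  A homopolymer is a
run of ≥ 7 identical reference bases (configurable), scanned within ±100 nt
of the region of interest; distance is 0 inside a run, else the distance to
the nearest run boundary.

H (RDD mode only) rejects sites whose pooled gDNA evidence is not a
confident homozygote: coverage < 10 or minor-allele fraction > 0.05.  The
fraction rule (rather than a genotype-likelihood call) was chosen for
transparency; 0.05 tolerates sequencing error at q ≥ 13 without passing
real heterozygotes.  M rejects sites whose pooled RNA counts show ≥ 3
distinct bases.  `apply_panel` is a pure function returning the union of
flags, so evaluation order can never matter.  An optional raw
variant-fraction screen (coverage ≥ 10, non-reference fraction ≥ 10%) is
provided off-by-default for reproducing simple threshold-based baselines.

Count-table input carries no read-level context, so distance filters are
disabled on it with a warning; H and M still operate.

## Pileup construction

BAM input is walked read by read (CIGAR-aware), excluding unmapped,
secondary, supplementary, QC-fail and duplicate-flagged (0x400) reads,
reads under `min_mapq` (default 20), and calls under `min_bq` (default 20)
or calling N.  Deletions and reference skips contribute no call at a site;
insertions contribute context only.  Only sites with ≥ 1 retained call in
every replicate of both samples are emitted.  For stranded libraries
(`fr-firststrand` / `fr-secondstrand`) counts are reported on the
transcribed strand, complementing base identities for reverse-strand
assignment, and sites on opposite strands are kept separate.  Overlapping
mate pairs are counted twice (both calls retained); PCR-duplicate *marking*
is expected upstream — only the flag is honored here.

## Benchmark generator

The generator emulates the in-silico study design at the count-stack level
(no read-level FASTQ simulation): per site and replicate, a realized variant
frequency is drawn from a Beta distribution with mean equal to the site's
target frequency and concentration β (10/50/100 = high/medium/low
variability), then counts are multinomial over a channel distribution with
a uniform per-base error (default 0.001, matching the default simulated
quality q=30).  Coverage is uniform per replicate in [5, 1000] by default.

Scenario RDD: one gDNA sample (target frequency 0) vs N cDNA replicates
with variants implanted at target frequencies drawn uniformly from
[0.05, 0.95].  Scenario RRD: two cDNA replicate sets; variant sites are
separated by exactly Δ in target frequency (default 0.1 — the floor of the
design and its hardest case, which also makes power sweeps over Δ
well-posed), SNP sites carry pairwise-equal frequencies and act as
negatives.  Half the sites carry signal by default; a quarter are SNPs in
RRD.  The desk-scale default is 2,000 sites, overridable to full scale.

What the generator does *not* emulate — mapping artifacts, position-in-read
error structure, strand bias, real coverage distributions — is exactly what
the distance filters target, so green benchmark metrics certify the
statistical engine, not the filters; the filters are instead validated
against a brute-force oracle on randomized SAM fixtures.

Evaluation: variant sites are positives; clean and SNP sites are negatives.
TPR, precision, accuracy and F-score follow their standard definitions;
precision with zero predicted positives is reported as NaN with a warning.
A threshold sweep over all distinct z values supports operating-point
selection, including TPR at a fixed false-positive budget.

## Output format

A BED-like TSV (0-based half-open; one row per tested site) rather than
VCF, because the method scores sample differences, not genotypes.  z is
printed with six decimals under round-half-even on the printed decimal
value.  All configuration is echoed in a `##config=` line.  Output bytes
are independent of the thread count: work is partitioned into chunks and
merged in input order.

## Scale choices

Tests and the acceptance script run the benchmark at 2,000 sites with
replicate counts 1–5 and β = 100; behavioral checks (power monotone in Δ,
median z non-decreasing in replicate count, RRD harder than RDD) use fixed
coverage 200 to isolate the effect under test.  These sizes give stable
qualitative behavior across seeds while keeping a full run in minutes on a
single core.

## Known limitations

- No p-value/FDR calibration for z; thresholds are empirical.
- The H filter's fraction rule can mis-handle sites with copy-number
  variation, where genomic allele fractions are not near 0, 0.5 or 1.
- CRAM input, mate-overlap deduplication and local INDEL realignment are
  out of scope (realignment belongs upstream).
- Single-replicate samples are supported but the dispersion estimate is
  then driven by the pseudocounts alone; the fit sits in the multinomial
  limit.
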