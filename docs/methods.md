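# Methods

## Scope

`mtmosaic` implements an analysis pipeline for mtDNA mosaicism in cohorts
of single-cell–derived clones: read-level QC of candidate calls, a
locus-specific background-noise model with false-positive removal and
false-negative rescue, origin classification of variants, drift summary
statistics, forward simulation of intracellular mtDNA turnover, inference
of turnover and mutation rates by MSE rejection, and a dN/dS test against
a simulated neutral null. Alignment and primary variant calling are
upstream of the package; it consumes caller output (VCF with AD fields or
TSV tables) or synthetic equivalents.

## Coordinates, strands and consequences

Positions are 1-based inclusive on a circular reference; intervals may wrap
the coordinate origin (the replication-origin region m.16,197–191 on the
real genome does). The deposited reference sequence is treated as the
light strand; base substitutions are classed by the strand carrying the
mutated pyrimidine, which is how replication-strand asymmetry is usually
tabulated for mtDNA. Consequences use the vertebrate mitochondrial code
(Biopython table 2); incomplete terminal codons (`T`, `TA`), completed to
stops by polyadenylation, count as stops. Truncating = stop-gain SNV or
frameshift InDel in a CDS; in-frame InDels are grouped with missense.
Overlapping features resolve CDS > tRNA > rRNA > noncoding. Annotation is
checked in the tests against an independent oracle that mutates the
sequence and re-translates the whole protein.

## Read-level QC

Per-(clone, variant) summaries of the supporting reads are filtered with
strict inequalities: mean mapping quality < 25, mean base quality < 15,
mean relative position of the variant base < 0.15 or > 0.85, forward-read
fraction < 0.10 or > 0.90, five or more mismatches in a supporting read,
or improper mate pairing (both mates must map to mtDNA, non-chimeric,
correctly oriented — the NUMT guard). Boundary values pass. Fixed
blacklists cover the homopolymer/repeat regions 302–315, 513–525,
3,105–3,109 and 16,182–16,187; InDels additionally fail above 50% extra
InDels in supporting reads and at the noisy homopolymer loci 567, 955 and
5,894. Whether quality cutoffs apply to means or minima of supporting
reads is not standardized upstream; the summaries carry means, and the
choice is confined to the summary producer.

## Background-noise model

For every (position, alternate allele) the panel holds the VAFs of all
clones, zeros included (the clone under evaluation is not left out). Two
cutoffs are derived per site:

* **CI bound** — mean + 1.645·sd (one-sided 95% on a normal
  approximation; sample sd).
* **Relative-gap threshold** — panel VAFs inside [0.05%, 15%] are sorted;
  among adjacent pairs with relative gap `(VAF′−VAF)/VAF ≥ 0.33`, the pair
  with the largest *absolute* gap marks the noise/signal boundary and the
  cutoff is `min(mean(VAF, VAF′), VAF × 1.33)`. A relative-gap maximum
  would be dominated by near-zero VAFs, so the 0.33 floor qualifies pairs
  and the absolute gap selects among them. With fewer than two values in
  the window, or no qualifying pair, the threshold is absent.

Reconciliation uses the gap threshold when present, else the CI bound
(precedence configurable), and additionally never calls a mutant below the
assay's practical detection floor of 0.3% VAF — at typical depths a lower
cutoff would promote Poisson-level background to mutant status. Called
VAFs at or below the effective cutoff are removed; uncalled VAFs above it
are rescued. Reconciliation is idempotent.

Binning convention: clone-VAF bins for summary statistics are
right-inclusive — [0.5%, 5%], (5%, 10%], …, (95%, 100%] — so a VAF of
exactly 0.5 falls in the 45–50% bin.

Two caveats, deliberate consequences of the literal thresholding rules:
when several true carriers sit spread inside the 0.05–15% window, the
largest qualifying gap can fall between carriers rather than between noise
and signal, removing the lowest carriers; and at sites whose noise sits
entirely below 0.05% while carriers are common, the CI bound is inflated
by the carriers themselves. Both effects are visible on synthetic cohorts
with dense mid-VAF carriers and bound the achievable sensitivity; on
drift-shaped (U-shaped) carrier distributions they are rare.

## Origin classification

Each (donor, position, alt) with at least one mutant clone gets exactly
one class, in precedence order:

1. **PZ_recurrent** — seen in ≥ 2 donors each with ≥ 2 mutant clones, or
   in ≥ 10 donors of a configured full panel of 86 individuals (the count
   scales proportionally when the configured panel size differs).
2. **Late-branch PZ_simple** — the donor's mutant clones are confined to a
   subtree whose ancestor accumulated ≥ 100 nuclear somatic mutations
   before diverging; sharing that deep in development cannot be a
   fertilized-egg signal.
3. **Het_FE** — shared by ≥ 2 clones of exactly one donor, absent
   elsewhere.
4. **Binomial framework** — shared here, sporadic elsewhere: the
   spontaneous rate is estimated by maximum likelihood from the other
   donors' clones (p̂ = x_exp/n) and the one-sided binomial tail
   P(X ≥ x_obs) computed at the focal donor's clone count; tail < 0.01
   gives Het_FE, else PZ_simple.
5. **Matched bulk** — a singleton shared by the donor's bulk tissue at
   VAF ≥ 0.005 (configurable) is Het_FE.
6. Otherwise PZ_simple.

A variant that satisfies both the Het_FE sharing pattern and the
recurrence rule is resolved as recurrent (rule 1 first) and the fired rule
is recorded per variant for audit. Tissue-specific hotspots are flagged
when a site recurs in ≥ 2 donors of a tissue and carrier ages exceed
non-carrier ages by a one-sided Wilcoxon rank-sum test (default α = 0.05,
normal approximation with tie correction).

## Drift metrics

caVAF is the arithmetic mean clone-VAF over *all* retained clones of the
donor, zeros included; on simulated cohorts it is an unbiased estimator of
the initial (egg) frequency. F_ST uses the population variance of
clone-VAFs over P̄(1−P̄) — the Bernoulli variance at the mean, which is
what equates σ²_T with full fixation — and is computed only for P̄ > 0.01.
S_VAF sums the clone-VAFs of PZ_simple mutations only; homoplasmy in
summaries means clone-VAF > 0.9, while fixation in the drift simulations
means frequency exactly 1.0. Strand spectra count the six pyrimidine-based
substitution types per strand, inside and outside the replication-origin
region (where the asymmetry reverses), with an optional 0.5 pseudocount
for log2 ratios and a chi-squared comparison of tissue spectra.

## Turnover models and sampling shortcuts

One **mitotic turnover** doubles the pool by n sequential replications —
each copying a molecule chosen uniformly from the current, growing pool —
and halves it by drawing n of the 2n molecules without replacement. The
one-by-one doubling is a Pólya urn, so the added copies follow a
Dirichlet-multinomial law with concentration equal to the current counts,
and the halving is multivariate hypergeometric; the engines sample these
laws directly. One **homeostatic turnover** is n replacement events
(degrade one uniform molecule, replicate one of the n−1 survivors); for
two types each event is ±1 with probability k(n−k)/(n(n−1)).

A molecule-by-molecule oracle implements both models literally and is part
of the test suite; the shortcut engines match it in one-step distribution
(chi-squared at n ≤ 20) and in mean fixation time. Copy number is
conserved after every completed turnover; the frequency is a martingale;
fixation probability converges to the initial frequency.

Mutations arise per replication event as Poisson(r·L), attached to the new
molecule. Within a mitotic doubling, a mutation created at the j-th
replication is itself copied by later replications of the same phase; its
copy number at the end of the doubling is 1 + BetaBinomial(n−j; 1, n+j−1),
which the engines sample exactly (j uniform on 1..n). Two engines exist:

* the **genotype engine** tracks genotypes (mutation sets) per cell with
  full linkage — used for dynamics modeling, contour tables and synthetic
  truth generation;
* the **independent-lineage engine** evolves each mutation's copy number
  as its own two-type chain — each mutation's marginal law is exact, only
  the within-cell joint distribution is approximate. It is orders of
  magnitude faster at high mutation rates and backs the mutation-rate
  inference; the two engines are cross-checked on shared summary
  statistics in the tests.

Randomness comes from a single NumPy Generator consumed in a fixed
vectorized order, so fixed seeds give bit-identical outputs.

## Rate inference

**Turnover rate.** For a fertilized-egg variant with caVAF > 0.005, cells
are simulated at the donor's copy number from p₀ = caVAF over a grid of
candidate total turnover counts g (default 0–5,000). Because the process
is Markovian, one population trajectory snapshotted at each grid value is
distributed as independent runs per candidate; each snapshot is resampled
(without replacement) 100 times at the observed clone count to mimic
sequencing, summarized into the 25 statistics (20 bin counts, mean, sd,
wild-type < 5%, heteroplasmic 5–90%, homoplasmic > 90% proportions) and
scored by MSE against the observed statistics. The estimate is the mean g
(and g/age) over the 50 lowest-MSE draws, with the min–max range; tissue
aggregates are means with normal-approximation 95% CIs across variants.
With ~100 clones and a few variants per tissue the aggregate recovers a
known rate within ±25%; single 40-clone variants carry sampling noise of
similar magnitude to that tolerance.

**Mutation rate.** With g fixed at tissue rate × age, log₁₀(r) is drawn
uniformly on (−9, −3); each draw runs a mutation-accumulation simulation,
is resampled 10 times at the clone count, summarized into the 22
statistics (20 bins of the per-cell maximum clone-VAF above the 0.5%
floor, counts of cells with exactly two and exactly three homoplasmic
mutations), and MSE-ranked; the estimate is 10^mean(log₁₀ r) over the 50
lowest-MSE draws. Draws with extreme expected mutation loads (large r) are
simulated with proportionally fewer cells under an explicit event budget
(default 3×10⁵ expected mutation births per draw, floor two cells,
resampling then with replacement): such draws sit far from any low-rate
observation, so coarse statistics suffice to rank them. Recovery of
log₁₀ r is well within ±0.5 on synthetic donors.

MSE is computed on standardized statistics by default: counts are
converted to proportions and every statistic is divided by its standard
deviation across all candidate draws (zero-variance statistics drop out);
a raw mode is available. MSE is zero iff simulated and observed statistics
coincide, and estimates are deterministic given the seed and candidate
set.

## Selection (dN/dS)

Opportunity counts enumerate all CDS positions × 3 alternate bases,
optionally after substituting individual germline variants. The neutral
null places the observed number of mutations at random — uniformly or
weighted by the strand-resolved substitution spectrum (weighted by
default) — and computes the opportunity-normalized ratios. Because a
change's class depends only on (position, alternate base), the per-
iteration class counts are exactly multinomial over the class probability
masses, and the null is drawn that way. Iterations with zero synonymous
draws are excluded and counted. The observed/null comparison is pooled per
tissue; the expansion-constraint test compares the proportion of VAF > 0.9
mutations between truncating and synonymous classes (VAF ≥ 0.1 only) with
a two-sided Fisher exact test. Note the null ratio's mean carries a small
Jensen bias of order 1/E[synonymous count]; the tests account for it.

## Synthetic cohorts

The generator emulates: fertilized-egg variants drifting per clone for
(rate × age) turnovers; postzygotic mutations from the genotype engine at
a per-bp-per-replication rate; hotspot loci recurring across donors;
per-clone sequencing depth lognormal around 6,000× (σ = 0.5, matching the
wide empirical spread); per-(locus, alt) background error rates from a
two-component mixture — most loci at the bottom of the 0.05–15%
thresholding window (2×10⁻⁴–1.2×10⁻³), a minority strongly elevated
(1.2×10⁻³–5×10⁻³) — chosen so the gap-threshold algorithm is genuinely
exercised; binomial alt counts; a caller that reports VAFs above a 0.3%
detection floor with a small miss rate (so reconciliation has both false
positives and false negatives to fix); donor phylogenies with shallow
early splits, long terminal branches and optional late-branching clades
(stem ≥ 100 nuclear mutations); and matched bulk VAFs near the egg
frequency. Default per-donor conditions are the emulated study's: 750
copies per cell, ~15 mitotic turnovers per year, r = 5×10⁻⁸.

What it does not emulate: read-level artifacts (the QC module is tested on
planned summaries instead), NUMT misalignment structure, culture-induced
VAF shifts, copy-number variation across clones of a donor, UV-driven
turnover acceleration, selection on variants, and linkage between hotspot
recurrences. Passing tests therefore demonstrate correctness of the
algorithms under the stated generative model, not robustness to every
artifact of real sequencing data.

Everything is written as plain text (TSV/VCF/newick/FASTA) and re-read by
the IO layer; outputs are byte-identical under a fixed seed, and the VAF
matrix round-trips bitwise (`%.17g` on write, round-trip float parsing on
read).

## Problem sizes and numerical choices

Simulation sizes used in the test suite and acceptance script: 10,000
cells for two-type drift runs, 1,000–1,500 cells for lineage-tracking and
mutation runs at n = 750, 100 draws for mutation-rate recovery — sizes at
which the Monte-Carlo error is comfortably below the stated tolerances.
Degenerate inputs return structured absences rather than errors where the
quantity is genuinely undefined (gap threshold with no qualifying pair,
F_ST at P̄ ≤ 0.01 or zero total variance, dN/dS with no synonymous
mutations); ties in the Wilcoxon test use the tie-corrected normal
approximation; z = 1.645 for the one-sided 95% bound.

## Known limitations

* Under the stated mitotic mechanism, a variant at 10% initial
  heteroplasmy with n = 750 fixes (frequency exactly 1.0) in ~6% of cells
  by 1,440 turnovers, not the full 10% fixation probability — absorption
  is only ~60% complete at that point (several thousand turnovers are
  needed for the asymptote; the homoplasmic-cell fraction at VAF > 0.9 is
  ~6.6% there too). The *relative* homeostatic/mitotic comparison (~50% of
  rounds) and the 1,000-turnover purification fractions (~30% purified,
  ~5% homoplasmic mutations) are insensitive to this and are the
  quantities the acceptance script reports.
* The late-branch rule needs the donor phylogeny; without one it is
  skipped with a warning.
* The homeostatic model has no fast multi-category shortcut (replacement
  events are inherently sequential); lineage tracking and mutation
  accumulation under it are practical at small n, and mutation-rate
  inference is implemented for the mitotic model.
* The ≥ 10-of-86 recurrence rule and the binomial framework assume the
  configured panel approximates an unrelated-donor background; small
  cohorts should keep the default panel size of 86 rather than scaling it
  down, or recurrence will over-trigger.
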