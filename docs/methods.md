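# Methods

## Scope and data model

`plateletmir` analyses two kinds of measurements of stored platelet
concentrate (PC):

1. **Small-RNA sequencing counts** — one library per storage day
   (days 1, 2, 3, 4, 5, 7), held as an integer matrix of miRNA × sample.
   The bundled reference dataset provides the per-day abundances of the
   ten dominant platelet miRNAs and the per-day totals of detected
   species (675 / 526 / 579 on days 1 / 5 / 7).
2. **RQ-PCR Ct tables** — triplicate cycle-threshold measurements per
   (bag, day, target), validated on a 100-bag cohort for the two
   storage-damage biomarkers mir-127 and mir-320a plus the mir-191
   endogenous control.

All containers are plain pandas DataFrames; every operation is a pure
function over them.

## Normalization and detection

RPM(i, j) = 10⁶ · count(i, j) / colsum(j).  The denominator is the
column total of the matrix at hand (the package never sees unmapped
reads, so no external miRNA universe enters the denominator); each
un-logged column sums to 10⁶ and normalization is invariant to
per-column rescaling.  The log transform is log₂(RPM + pseudocount)
with pseudocount 1.0 by default — the standard choice that maps zero to
zero and preserves rankings.

A miRNA is *detected* in a sample when its raw count is ≥ 10 reads
(inclusive).  The percent-loss helper, 100·(n₁ − n₅)/n₁, turns per-day
detection totals into the headline decay figure (675 → 526 detected
species ≈ 22 % loss).

## Differential expression

With one pooled library per day there are no replicates, so the test is
the exact conditional binomial: under the null of equal relative
abundance, the count in library *a* given the pooled total n = count_a
+ count_b is Binomial(n, total_a/(total_a + total_b)).  The two-sided
p-value follows the minimum-likelihood convention — sum the
probabilities of every outcome no more likely than the observed one,
ties included — making results bit-reproducible; the implementation
delegates to `scipy.stats.binomtest` and the test suite checks it
against brute-force enumeration for pooled totals up to 50.  Because
the exact p includes the observed outcome it is strictly positive; we
floor the floating-point result at the smallest denormal so that a
degenerate screen with α = 0 passes nothing.  A miRNA is called
differentially expressed when |fold change| ≥ 2 on the RPM scale *and*
p ≤ 0.05.  No multiplicity correction is applied — the decision rule is
deliberately the raw two-fold/p ≤ 0.05 filter — and no replicate-aware
model is attempted.

## Rank trajectories and crossover

Per-day top-k lists (k = 10 by default) are ranked on expression with
lexicographic tie-breaks for determinism.  The trajectory table derives
the union of lists (14 miRNAs over the six reference days), the
entry/exit turnover between consecutive days, and per-miRNA rank paths.
Crossover detection between a designated pair returns the earliest day
on which the first miRNA's expression falls *strictly* below the
second's — a tie is not a crossover, mirroring the inclusive boundary
of the validity rule.  When only ranked lists are available, ranks
stand in for expression; days on which either miRNA is outside the list
are flagged incomparable and skipped.

## RQ-PCR reduction

Triplicates are reduced to the arithmetic mean and sample SD; a
replicate SD above 0.5 cycles (a common lab QC convention, configurable)
flags the summary.  Relative quantity uses the ΔCt method against
mir-191 — chosen as control because it is the most abundant miRNA on
every storage day:

    ΔCt = Ct(target) − Ct(reference),   RQ = 2^(−ΔCt)

Amplification efficiency is fixed at 2.0 (100 %) and no inter-day
calibrator sample is used, so log₂(RQ) = −ΔCt exactly; the sub-unit
day-1 RQ values of the calibration are consistent with this convention.
Cohort summaries report the cross-bag mean, sample SD and n per
(day, target).  The paired t-test pairs by bag — the only entity
repeated across days; which day pairs to compare is left to the caller.

## Validity classification

A bag (or cohort-day summary) is VALID iff RQ(mir-127) ≥ RQ(mir-320a),
equivalently ratio ≥ 1, with the boundary inclusive.  The rule is
invariant to common rescaling of both RQs, isotone in mir-127 and
antitone in mir-320a.  Applied to the reference per-day cohort means it
labels days 1–3 VALID and days 4, 5 and 7 DAMAGED.  No tolerance band
around ratio = 1 is applied by default; measurement noise near the
boundary is the caller's concern.  The same comparison applies to
sequencing RPM values; outputs should be labelled with their input
mode.  The label is an in-vitro proxy for platelet aging, not a claim
of clinical transfusion suitability.

## Clustering

Per-bag RQ profiles (bags × days, one matrix per target) are clustered
on plain Euclidean distance; the default linkage is average (UPGMA) —
only the metric is dictated by the analysis, so the linkage is a
package choice made for determinism and monotone merge heights.  SciPy
resolves equal-height merge candidates by lowest cluster index, making
leaf order reproducible.  Rows are not scaled by default; a per-row
z-score flag exists for heatmap display parity.  No cluster-significance
p-values are computed.

## Synthetic cohort generator

The generator exists so that every downstream stage is testable with no
external download.  It emulates:

* **Monotone decay** — expected abundance of species *i* on day *d* is
  `initial_rpm · exp(−decay_rate · (d − 1))` for d ≤ 5: anucleate cells
  cannot make new miRNA, so expectation is non-increasing through
  day 5.  (`initial_rpm` is defined as the day-1 expectation.)
* **Day-7 rebound** — after day 5 a configurable fraction of the
  initial abundance is re-added (`+ rebound_fraction · initial_rpm`),
  standing in for late cleavage of miRNA precursors without modelling
  the enzymology.
* **Count noise** — Poisson around the expected abundance scaled to the
  library size (10⁶ reads by default); a gamma-mixture negative-binomial
  option (`nb_dispersion`) is available but off by default, since the
  per-bag count dispersion is not calibratable from pooled reference
  data.  `count_noise="none"` gives deterministic rounded expectations
  for noise-free tests.
* **Calibrated abundances** — the ten dominant miRNAs take their day-1
  values from the reference table, with decay rates fitted from the
  day-1 → day-5 drop (clamped at zero where the table value rises) and
  rebound fractions from the day-7 excess.  A synthetic background tail
  of 665 species (log-spaced 800 → 12 RPM; decay rate rising linearly
  to 0.36/day for the rarest; rebound fraction 0.5 on the 0.70–0.90
  rarity band) reproduces the cohort-level detection behaviour: ~675
  species detected on day 1, a loss of roughly a fifth by day 5, and a
  partial recovery at day 7.  Tail species are named `syn-mir-bg*` to
  mark them as synthetic.
* **Ct generation** — per bag, day and target, the bag-level ΔCt
  against the control is Gaussian on the cycle scale (the physically
  meaningful domain), with moments chosen by log-normal moment matching
  so that the *triplicate-reduced* RQ has exactly the calibrated
  cross-bag mean and SD: the technical-replicate variance contribution
  (2·ct_tech_sd²/m for m replicates) is subtracted from the bag-level
  spread, and the log-normal mean correction uses the effective total
  spread.  The control's bag-level Ct is fixed at 16 cycles, so the
  control quantified against itself gives RQ 1 in the noise-free limit.
* **Reproducibility** — one global seed; per-bag and per-column
  substreams derived via `numpy` seed sequences, so identical
  (config, params, seed) yields bit-identical output.

Default noise levels: `ct_tech_sd = 0.15` cycles (a typical
within-triplicate spread for a well-behaved TaqMan assay) and three
replicates, matching the triplicate design of the validation
experiment.

What the generator does **not** emulate: raw reads, adapters or
alignment artefacts; bag-to-bag library-size variation; donor covariates
(age, nutrition) behind the bag heterogeneity; any correlation between
a bag's sequencing counts and its Ct values; storage-bag chemistry.
Passing tests therefore demonstrate the *pipeline's* correctness under
the stated statistical structure, not the biological claims themselves.

## Problem sizes and statistical checks

Seeded tests run the generator at the cohort sizes of the reference
design — 16 bags for the sequencing side, 100 for the validation side —
which keeps the full suite under ten seconds.  Two checks warrant
detail:

* *Parameter recovery*: at 100 bags, each per-day/target cohort-mean RQ
  must land within two standard errors (SE = calibrated SD/√100) of its
  calibrated value.
* *Monotone dispersion*: cross-bag RQ spread must grow with storage
  time.  Adjacent calibrated SDs differ by less than the sampling error
  of an SD estimate at n = 100, so strict sample monotonicity is the
  wrong oracle; the test instead allows a two-sigma inversion where
  sigma is the kurtosis-correct sampling SE of the sample SD under the
  calibrated log-normal, and requires strict day-1 → day-7 growth.

## Known limitations

* The per-day detection totals themselves (675/579/526) come from a
  full sequencing-and-alignment stack and are not recomputable here;
  the package reproduces the derived loss percentage and the
  qualitative decline/rebound only.
* The differential-expression stage is a defined stand-in statistic for
  the unreplicated two-library comparison; published DE counts from
  other tools are not comparison targets.
* Day-4 placements of the three list entrants (miR-92a-1, let-7d,
  miR-28) within ranks 6–10 are not fully determined by the reference
  narrative; the bundled lists fix them at ranks 7/9/10, which does not
  affect union or turnover quantities.
* Cluster significance, amplification-efficiency estimation, absolute
  quantification and FDR control are out of scope by design.
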