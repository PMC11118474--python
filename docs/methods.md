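# Methods

`nascentmech` analyzes how a DNA-binding transcription factor changes RNA
polymerase II behaviour in the minutes after its rapid (degron-mediated)
depletion, using nascent-transcription (PRO-seq) coverage, the factor's
binding sites, and ChIP-style peak intensities.  This note records the
models, the defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical conventions.

## Compartment model of the transcription cycle

Polymerase enters the promoter-proximal pause compartment at initiation
rate α (events/time), leaves it into productive elongation at pause-release
rate β, may be lost to premature termination at rate γ, and elongates at
velocity v (bases/time).  At steady state:

    dP/dt = α − (β + γ)·P = 0      ⇒  P* = α / (β + γ)
    body occupancy per base        ∝  β·P* / v = α·β / ((β+γ)·v)

With γ = 0 and v assumed unaffected by treatment, fold changes of the
observed densities identify fold changes of the rates:

    Δlog₂α = log₂(B₁/B₀)
    Δlog₂β = log₂((B₁/P₁) / (B₀/P₀))   (= −Δlog₂ pausing index)

where P is the summed, size-factor-normalized 3′-end count in the pause
window and B the mean per-base normalized 3′ count in the gene body.

**Identifiability caveat.** A decrease in apparent initiation is
algebraically indistinguishable from an increase in premature termination
(both drain the pause compartment), so every estimate carries a mandatory
caveat flag; the package reports point estimates under γ = 0 and does not
attempt to resolve the confound.  Follow-up evidence (e.g. prominent-TSS
redistribution) is the intended way to distinguish the two.

**Windows.** Pause window = TSS..TSS+100; body window from TSS+500 to the
gene end, capped at 30 kb.  These are standard PRO-seq quantification
choices, configurable per call; the pause window deliberately covers the
entire +20..+60 pause zone with margin for TSS-call imprecision.
Replicates are size-factor-normalized and then summed (not averaged as
ratios) before densities are formed, which weights replicates by depth and
avoids ratios of small counts.

## Motif machinery

**Scoring and p-values.** Standard log₂-odds PWM scoring against genomic
background frequencies; N scores 0.  Hit p-values are exact tail
probabilities of the background score distribution, computed by
dynamic-programming convolution of per-column score distributions on a
discretized grid (1/1000 bit, configurable).  Scanning uses the same
integer grid, so scan p-values are exact for the discretized score;
column probabilities are floored at 1e-4 when forming log odds so that
consensus-like matrices remain finite.  For widths ≤ 6 the DP agrees with
exhaustive enumeration of all 4^W words to the grid resolution.

**Discovery.** Zero-or-one-occurrence-per-sequence (ZOOPS) EM with fixed
width per run, seeded from the most frequent W-mers (both strands) and run
to convergence of the penalized (MAP) log-likelihood (Dirichlet
pseudo-counts 0.25 per cell; the reported likelihood path is the MAP
objective, which EM increases monotonically).  The EM is strand-aware: a
sequence's single occurrence may sit at any position on either strand.
This matters because real binding sites occur on both strands, and a
single-strand model halves the effective occurrence fraction and corrupts
downstream alignment.  Motif significance is empirical: the statistic
(relative entropy to background × expected occurrence count) must exceed
the same statistic on every one of 20 per-sequence base-shuffled copies of
the input, which preserve composition while destroying motifs.  Because
the original noise input and its shuffles are exchangeable, this is an
exact 1/21 ≈ 5% level test; tests budget for the residual rate binomially
rather than demanding zero.

**Iterative discovery.** Repeat {discover on unexplained peaks; scan *all*
peaks at p ≤ 0.0005; peaks with any hit leave the discovery set} until the
significance test fails or 6 rounds.  The 0.0005 hit threshold is the
package-wide definition of a motif match.

**Composite motif.** Discovered variants are canonicalized to the
orientation whose core pentamer (default TGGGA) placement scores best;
each hit contributes its ±50-base window aligned on the core start
(reverse-complemented for minus-strand hits).  The composite width is the
maximal contiguous run of columns containing the core whose
total-variation distance from the background exceeds 0.05, bridging at
most 2 consecutive sub-threshold columns.  The 0.05 tolerance is ~3
standard errors of a column frequency at ~1000 aligned sites; width
estimates from fewer than 50 hits are flagged low-confidence because
column noise then approaches the tolerance.

**Site assignment.** Each peak's binding site is the lowest-p-value hit
among all discovered motifs plus the composite; ties go to the hit nearer
the peak summit, then upstream-most.  The winning hit's core position
anchors a composite-width interval, which becomes the binding site; peaks
with no hit at p ≤ 0.0005 are retained but flagged motif-less.

## TSS calling and shifts

The prominent TSS is the argmax of raw 5′-end counts in a ±500-base window
around the annotated start (ties break upstream in gene orientation; calls
require ≥ 5 reads).  No smoothing is applied by default — initiation
positions are base-precise in 5′ pileups — but ±2-base aggregation is
available behind a flag.  A shift between conditions requires the
prominent position to move ≥ 10 bases (`min_shift`); the threshold is a
declared convention balancing base-level jitter of the argmax against real
redistribution, and is configurable.  Shift rates of a case cohort are
compared against controls matched on log₁₀ TSS intensity (greedy nearest
neighbour without replacement, caliper 0.5 log₁₀ units, case order
randomized under a seed).  Coupled redistribution is the normalized
treated-minus-control 5′ signal in ±5-base windows at the control and
treated prominent positions; initiation moving between start sites gives
the (−, +) sign pattern.

**Divergent regions.** A deliberately simple threshold caller replaces
SVM-based detectors: 500-base sliding windows with ≥ 5 reads per strand
whose strand maxima are divergently oriented (minus-strand peak upstream
of plus-strand peak) within 300 bases; overlapping windows merge and the
center is the midpoint of the opposing maxima.  Output is plain BED so
externally called regions can be substituted.

## Mechanism classification

Genes that *increase* transcription upon depletion of an activator are
candidates for cis repression.  The classifier gates on an up-regulated
gene with an assigned binding site within ±500 bases of the control
prominent TSS (otherwise `no_local_site`), then evaluates rules in
precedence order, accumulating every satisfied label; the primary label is
the first satisfied:

1. **tss_occlusion** — the site interval covers the control prominent TSS.
2. **roadblock** — site center within (0, +500] downstream;
   `roadblock_bidirectional` is added when divergent transcription at the
   site decreases significantly after depletion.
3. Upstream site (center in [−500, 0)):
   a. **dse_occlusion** — the treated prominent TSS moved upstream of the
      site and the site covers the DPE window (+27..+32 of the treated
      TSS, the union of the canonical +28..+32 element definition and an
      observed +27..+31 case) or a YY1 motif hit (p ≤ 1e-4) within the
      site and the +1..+300 zone;
   b. **competition** — a partner-family motif (SP/KLF, ETS, NRF1, bZIP,
      YY1) overlaps the site by ≥ 1 base with conformity quantile ≥ 0.99;
      `competition_sp1` when the family is SP/KLF and SP1 ChIP signal
      increased, else `competition_other`;
   c. otherwise **unexplained**.

**Conformity quantiles.** The best overlapping hit's score is ranked
against the best-window scores (both strands) of n i.i.d. background
sequences of the same length as the scanned region (default 10⁶; tests
and the bundled pipeline use 10⁴).  Matching the null statistic to the
max-over-windows scan statistic keeps the quantile honest: a random site
reaches quantile q with probability 1−q per family.

## The synthetic-data generator

The generator emulates the statistical structure of a degron time-course:

* a background i.i.d. genome with binding sites drawn column-wise from a
  degenerate 29-column composite-style PWM (near-deterministic TGGGA core,
  flank information tapering to background);
* 3′ tracks: pause reads Poisson with mean d·α/β spread uniformly over
  +20..+60, body reads Poisson(d·α/v) per base; defaults give 400 expected
  pause reads and 2 reads/base per replicate, two replicates;
* 5′ tracks: Poisson totals distributed over 21-point TSS weight vectors;
  promoter-divergent antisense reads ~110 bases upstream;
* per-gene treatment effects by class: down genes lose initiation
  (Δlog₂α ~ U(−2, −0.5) by default), up genes gain it, with mechanism-
  specific geometry — sites spanning the TSS, sites 80–450 bases
  downstream (roadblock; control-only suppression of body signal past the
  site, and for the bidirectional subclass, site ≥ 200 bases into the gene
  with planted divergent reads that drop to 30% after treatment), upstream
  sites whose removal exposes a planted YY1/DPE element 28 bases upstream
  of the site (the treated TSS weight vector is recentered there), and
  upstream sites containing a planted partner consensus (competition);
* ChIP intensities: control counts Poisson around lognormal site
  affinities; treated counts keep 3% of the mean, enforcing the >95%
  depletion contract; SP1 partner peaks at SP-competition sites gain
  0.7–1.5 log₂ units after treatment;
* TSS redistribution: half of the bound (down) genes move their prominent
  TSS by 15–60 bases after treatment versus 15% of unchanged genes, so the
  case/control shift-rate ratio is ~3.3 in expectation (the qualitative
  "twice the rate" pattern with margin for argmax noise; at the 150-case
  cohort used in tests the sampling standard deviation of the ratio is
  ~0.7).

An event-driven ("Gillespie") mode draws initiation events from a Poisson
process and exponential pause dwells per polymerase and converts occupancy
into reads.  It shares no algebra with the steady-state estimator and
serves as the independent oracle in rate-recovery tests (300 genes at
these depths give median |error| ≈ 0.03 for Δlog₂α and ≈ 0.09 for Δlog₂β).

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: mappability and library-prep biases,
fragment-level autocorrelation, multi-modal and dispersed TSS architecture
beyond a single 21-point mode, overdispersion beyond Poisson, chromatin
context, and any trans/indirect regulatory effects.  Real analyses should
treat the pipeline's thresholds (hit p-value, proximity, min_shift,
conformity quantile) as starting points.

## Numerical conventions and edge cases

* Coordinates are 0-based half-open everywhere; BED and bedGraph writers
  emit canonical sorted, run-merged, zero-free records; the negative-value
  minus-strand bedGraph dialect is accepted on input and preserved on
  round-trip.
* Genes with an empty body window (shorter than the body offset) or zero
  density in any required window are excluded with an explicit reason, not
  silently dropped.
* The differential test is a conditional two-sided Poisson rate test
  (binomial on summed normalized counts) with BH adjustment — a documented
  simplification of negative-binomial dispersion modelling, calibrated on
  Poisson nulls (empirical type-I error ≈ 0.057 at α = 0.05) but expected
  to be anti-conservative under real overdispersion.
* Size factors follow median-of-ratios; only factor ratios are meaningful
  under per-sample rescaling.
* Ambiguity codes other than N are rejected; N scores 0 in PWMs and is
  excluded from composite frequency averaging.
* All stochastic components take explicit seeds; identical configs and
  seeds reproduce byte-identical outputs and manifests.

## Problem sizes used in the bundled checks

Rate recovery uses 300 genes (plus a 500-gene null); discovery recovery
uses 1,000 200-base peaks with the motif planted in 60%; composite-width
recovery uses 2,000 sites per planted width (11/21/29); the TSS cohort
uses 150 down genes against a 300-gene matching pool with 20
element-occlusion genes; the labeled mechanism cohort has 60 up genes.
These sizes keep every Monte-Carlo band (documented above) a few standard
errors wide while the whole suite runs on a laptop.
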