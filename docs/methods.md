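# Methods

## Barcode extraction

Amplicon read pairs (150 bp each) carry a 48-bp variable barcode region
in constant flanking sequence. Coordinates are 0-based half-open
throughout: the forward mate's region is `[20, 68)`, the reverse mate's
`[79, 127)`, and the reverse window is reverse-complemented into library
orientation before matching so a single whitelist serves both mates.

Quality control is operationalized per read: a mate passes when its
length is at least 147 bp and its mean Phred score is at least 20. This
is a deterministic, per-read restatement of the usual
report-then-discard QC workflow; it applies the same thresholds but
needs no external tool.

Whitelist matching is exact by default. With `max_mismatch=1`, every
single-base substitution of the observed 48-mer is probed and a hit is
accepted only when all hits agree on one barcode (unique minimizer;
exact matches always win). One mismatch is a close stand-in for k-mer
indexing with k = 47 over 48-mers, since a single substitution disrupts
every 48-mer but leaves one intact 47-mer.

Pair reconciliation: each read pair contributes exactly one count.
Mates agreeing on a barcode, or one matching mate with the other
unmatched, count once; mates matching *different* barcodes are discarded
as ambiguous (double-counting would break the multinomial semantics of
read sampling); fully unmatched pairs are tallied separately. Matched +
ambiguous + unmatched always equals the input pair count.

The low-count filter removes barcodes whose count is below 2 in every
drug-selected replicate *and* the DMSO control. The initial and medium
samples deliberately do not rescue a barcode; the filter is idempotent
and frequencies are computed after filtering.

## Phenotype classification

The growth rate of barcode *b* in replicate *R* is

    r = (1/T) · log(f_R / f_0)

with `T` the weeks between first treatment and harvest (default 26, the
six-month schedule), `f_R` the barcode's endpoint frequency in the
replicate, and `f_0` its baseline. Natural log is the default; the
choice of base cannot flip a label because the classification uses only
the sign.

Two baseline modes are provided because the two natural readings of
"the DMSO frequency" differ:

- `per_barcode_dmso` (default): each barcode is compared to its own
  frequency in the DMSO control. Barcodes invisible in DMSO receive a
  pseudo-frequency of half a read (`0.5 / total DMSO reads`), without
  which a de novo clone absent from the control could never be scored.
- `max_dmso`: the maximum barcode frequency of the DMSO control is used
  as one common baseline for all barcodes. This is more conservative
  (fewer positive rates) and is retained for comparability.

A barcode is *detected* in a replicate when its endpoint count reaches
the filter threshold (2). Among detected replicates, those with r > 0
form the positive set P: |P| ≥ 2 labels each member pre-existing,
|P| = 1 labels it de novo, and detected replicates with r ≤ 0 are
sensitive. An exactly-zero rate is classed sensitive — the conservative
tie-break, and a measure-zero event on real counts. No multiple-testing
machinery is involved; the classifier is a deterministic sign rule, not
a hypothesis test.

Phenotype population shares are endpoint-frequency sums per label,
renormalized over the replicate's called barcodes so the three
percentages always total 100.

## Temporal tracking

Medium samples are normalized within-timepoint over the barcodes
retained by the endpoint filter: the absolute amount of shed DNA varies
between medium changes, so only composition is informative and absolute
shed mass is not modeled. A barcode absent from a timepoint has
frequency 0; trajectory barcodes are fixed to the endpoint-filtered set
so the ID space matches the endpoint classification.

Temporal classification reuses the endpoint rule with the last medium
timepoint as `f_R` and the same DMSO baseline (the baseline is an
endpoint-arm property, and reusing it keeps the two classifications
directly comparable); a barcode counts as detected in a series when its
last-medium frequency is nonzero. Medium-versus-harvest concordance is
summarized by Spearman rank correlation, which is robust to the
(possibly large) depth difference between medium and harvested samples;
disjoint supports or constant vectors are flagged as undefined rather
than reported as a number.

## Simulator

A discrete-generation Wright–Fisher-with-selection model — the simplest
stochastic model that exhibits the experiment's qualitative dynamics;
the monthly sampling cadence does not warrant continuous time. Within
each generation every clone independently undergoes:

1. **Death**: survivors ~ Binomial(n, 1 − d). Deaths accumulate into
   the current medium-sampling interval (dead-cell shedding).
2. **Reproduction**: next size ~ Poisson(survivors × g·φ), with base
   growth factor g = 2 (one doubling per generation at fitness 1) and
   relative fitness φ per compartment.
3. **De novo conversion** (drug arms only): sensitive cells flip to
   resistant with a small per-cell probability, keeping their library
   barcode — resistance arising on an existing lineage is exactly what
   "replicate-private expansion" means operationally, since barcodes are
   fixed at infection.

At each week's end the dish is passaged: if the population exceeds the
bottleneck size it is subsampled by a multivariate hypergeometric draw.
Passage discards are removed from the system; they are not shed.

Compartments and rates (defaults): sensitive cells under drug die at
d = 0.5 per generation and grow at relative fitness 0.35 (0.2 after the
dose escalation at week 17, mirroring the 1×IC50-for-four-months →
2×IC50 schedule); resistant cells have fitness 1. With d = 0.5 and
g = 2, the *net* per-generation multiplier of a sensitive clone equals
its fitness value, which makes the parameters directly interpretable.
All compartments additionally turn over at a baseline death fraction of
0.05 per generation: without some turnover of resistant cells the
medium would contain no resistant barcodes at all and longitudinal
tracking of the expanding clones — the phenomenon the medium assay
exists to observe — would be impossible. A small class of *partially
resistant* barcodes (0.2% of the library) tolerates the starting dose
(fitness 1, baseline death) but reverts to sensitive-like rates after
escalation; these produce the characteristic rise-then-fall
trajectories across the dose switch.

The shared founding pool is log-normal in clone size (σ = 1) over 7,000
barcodes, scaled to the bottleneck (10⁵ cells, a desk-scaled stand-in
for the experimental 2×10⁶ per dish; the `scaled_down` regime). 1% of
barcodes are pre-existing resistant — identical across arms because all
arms are cloned from the one pool. The de novo conversion rate, 10⁻⁶
per cell per generation, is defined at the full dish scale; the
simulator multiplies it by the desk factor (full-scale population /
bottleneck) so the *expected number* of de novo events per arm is
preserved under scaling. Conversions occur only under drug; the DMSO
arm can never acquire a resistant truth label.

Sequencing is a multinomial draw of `read_depth` reads (default 10⁶)
from clone frequencies, per sample; medium samples draw from each
interval's accumulated shed counts. FASTQ emission places each barcode
at the configured offsets inside fixed constant flanks, pads to 150 bp
at Q37, and applies i.i.d. substitution errors at the configured rate
(default 0). All randomness flows from one integer seed through
independent named streams, so runs are bit-reproducible.

What the generator does *not* emulate: PCR amplification bias and
duplicate structure, depth variation between samples, barcode-library
synthesis errors, cross-contamination between arms, spatial structure,
cell-cycle state, pharmacokinetics and microenvironment. Passing
recovery tests on this generator therefore demonstrates correctness of
the analysis logic under idealized sampling, not robustness to every
artifact of real amplicon data.

## Dose–response and synergy

Viability (fraction of untreated control) is fitted by the
four-parameter logistic `v(d) = floor + (ceiling − floor)/(1 + (d/IC50)^h)`
with the Hill slope constrained positive (monotone-decreasing
viability), via bounded least squares. Flat data (range < 10⁻³) and
non-convergence yield a flagged fit with NaN IC50 instead of an
exception; an IC50 outside `[min dose/10, max dose×10]` is flagged
extrapolated. IC50 fold changes are reported with an explicit
direction: resistance (test/reference) or sensitization
(reference/test).

Inhibition is 1 − viability. The Loewe expectation for dose pair
(a, b) solves `a/A(y) + b/B(y) = 1`, where A and B invert the
single-agent fits; the left side is strictly decreasing in y, so the
root is found by bracketing bisection (Brent) on the inhibition range
both agents can reach, to a tolerance of 10⁻⁸, with combinations beyond
that shared range clamped to its boundary. The synergy score is the
mean of `100 × (observed − expected inhibition)` over all nonzero-dose
combination cells — averaging over the whole grid is the one
well-defined choice when no dose window is singled out — and
background-drug designs (one agent fixed while the other is titrated)
are simply one-row grids. Scores in [−10, +10] are additive with the
boundaries inclusive (the stated band is "between −10 and +10"); above
+10 synergistic; below −10 antagonistic. The Loewe equation is
symmetric in the two agents, and the solver is verified against a dense
grid search in the test suite.

## Problem sizes

Validation runs use 10⁵ read pairs over 1,000 barcodes for the
round-trip check, 10⁴ random growth-rate rows for classifier
equivalence, ten seeded default-condition experiments (7,000 barcodes,
26 weeks, depth 10⁶) for phenotype recovery, and the default experiment
for temporal concordance — sizes at which every check completes in
seconds on one core while leaving the default study conditions intact.

## Known limitations

- The classifier is a sign rule on endpoint ratios; it does not
  estimate fitness, abundance posteriors or lineage structure.
- Whitelist matching tolerates at most one substitution and no indels.
- Real printed IC50s and fold changes from wet-lab viability assays
  cannot be reproduced computationally without the raw absorbance data;
  the pharmacology module is validated by self-consistency (exact
  recovery on generated curves, sham combinations) instead.
- With the default selection strength, sensitive clones are extinct by
  the endpoint, so simulated endpoints contain almost no
  sensitive-labelled survivors; sensitive-label logic is exercised on
  constructed count matrices instead.
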