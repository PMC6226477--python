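# Methods

This note documents the models, conventions and numerical choices behind
`g4rp`, in the spirit of a package methods appendix: what is computed, what
the synthetic generator does and does not emulate, and where genuinely open
design choices were settled.

## pG4 motif model

A putative G-quadruplex (pG4) motif is four tracts of at least `g`
consecutive guanines separated by three loops of `loop_min..loop_max`
nucleotides. The shipped stringencies are `G3L1-7` (g=3, loops 1–7; the
canonical/mid setting used for the headline densities), `G3L1-5` (high) and
`G2L1-10` (low, admitting two-quartet quadruplexes and long loops); custom
presets are one constructor call.

Because published motif counters differ silently in tie-breaking, the policy
here is explicit and frozen: **leftmost, shortest (lazy) match,
non-overlapping, scan resumes after each hit's end**. Tracts may sit inside
longer G-runs; loops may contain guanines (including runs) whenever the lazy
decomposition is valid; `N` never counts as G but is legal in loops; `T`/`U`
are equivalent and case is ignored. The scanner is a minimal-end dynamic
program over (position, tracts-remaining) states; the test suite proves it
equivalent to a brute-force enumeration of *all* tract/loop decompositions on
thousands of random and adversarial (poly-G) sequences, so the counts are
reproducible by construction rather than by convention-matching.

Coordinates are 0-based half-open everywhere, including BED6 output
(score column = number of tracts). RNA analyses scan the sense strand only;
`scan_pg4_both_strands` exists for genomic DNA.

## Enrichment model

Counts are normalized with **median-of-ratios size factors**: per gene, the
geometric mean across samples defines a pseudo-reference; per sample, the
factor is the median ratio to it over genes positive in all samples, then
factors are rescaled to geometric mean 1. A `pseudo_reference` flag handles
sparse matrices with no all-positive gene (geometric means over positive
entries only). Differential-expression machinery (NB GLMs, Wald tests,
shrinkage) is deliberately out of scope: the downstream quantities are ratio
thresholds and ranks, so the package computes ratio statistics on normalized
means.

Per condition with pulldown replicates and a matched input,
`ES = (mean pulldown + ε)/(mean input + ε)` with ε = 0.5 on the normalized
scale. The pseudocount keeps ES finite and positive; at the abundance
filters used here (means ≥ 500) its bias is below 0.1%. Each condition's own
input is the denominator (one input per condition is the emulated design);
pooling inputs is a flag.

`ΔES = ES(treated)/ES(untreated)` by default. The input-unadjusted variant
`(mean treated pulldown + ε)/(mean untreated pulldown + ε)` is available as
`des_mode="pulldown_ratio"`; it does not re-correct for treatment-induced
expression changes but has roughly half the log-scale variance, because the
default ratio-of-ES carries the noise of two unreplicated input libraries.
The acceptance script reports responder-recovery operating characteristics
under both definitions so that this trade-off is visible; the input-adjusted
form remains the default because it is the statistically defensible choice
when treatment can shift expression.

Filters: *expressed* iff mean normalized count strictly > 50; *abundant* iff
mean ≥ 500 (the boundary is stated inconsistently in common usage, so a
`strict_abundant` flag switches to strictly >); *induced* iff expressed and
ΔES strictly > 1.75 (log2 ≈ 0.8). Ranks are descending by ES / ΔES over
expressed genes with ties broken by gene id; filtered-out genes carry NaN
ranks and never enter top/bottom lists.

## Landscape statistics

Simple OLS (`scipy.stats.linregress`) with two-sided slope p-values for
ES/ΔES against G/C fraction, length, abundance or pG4 density; constant
inputs raise an explicit undefined-correlation error. Top-k vs bottom-k
contrasts use Student's t (equal variances) by default with a Welch flag —
the choice is recorded in the output. Regression p-values are reported
unadjusted (a Bonferroni helper exists); the default regression subset is
the abundant tier, matching how such landscapes are usually summarized.
One-/two-way ANOVA wrappers are provided as plumbing for plate-format data.

## Assay computations

- **Melt curves**: emission is min-max normalized per curve (plate-wide
  extrema can be supplied); T1/2 is the first *upward* crossing of 0.5,
  linearly interpolated between bracketing samples; multiple crossings warn
  and use the first. ΔT1/2 subtracts paired curves first and averages the
  differences (average-after-subtraction; the alternative order is not
  exposed). On the 25→90 °C ramp sampled at 1 °C, a logistic midpoint is
  recovered to well within 0.25 °C.
- **Capture efficiency**: mean probe-well signal over mean no-probe control
  signal; homogeneous of degree zero under common rescaling.
- **qPCR**: technical replicates are averaged on the Ct scale before
  differencing (the common convention); ΔCt = Ct(pulldown) − Ct(input),
  fold = E^(ΔCt_untreated − ΔCt_treated) with amplification efficiency
  E = 2 (perfect doubling) by default.
- **Dose–response**: confluency is normalized with the stated max/min
  achievable values; LDx is read off at normalized response 1 − x/100 by
  linear interpolation in log10(dose) (doses come from serial dilutions);
  extrapolation is refused.

## Synthetic data generator

The generator emulates a ligand-perturbed pulldown/input study with three
conditions (untreated + two G4 ligands), one input and two pulldown
replicates each, on a ribodepleted transcriptome.

**Sequences.** Loops and background come from a guanine-depleted alphabet in
which no two guanines are ever adjacent (non-adjacent G positions are placed
combinatorially; composition is exact, so G/C lands within ±0.05 of target by
construction). Planted `GGG-loop-GGG-loop-GGG-loop-GGG` cassettes are the
only possible G3 tracts, and cassettes are separated by spacers longer than
the longest loop, so the scanned `G3L1-7` count equals the planted count
exactly — every sequence is re-scanned to enforce this. Infeasible requests
(motifs that cannot fit, unreachable G/C targets) fail loudly with the
transcript index.

**Counts.** Input counts are NB(mean s_j·λ_i, dispersion α) with variance
μ + αμ²; pulldown means are multiplied by the capture rate

    r_i = b + c · f_i,    f_i = expit(intercept + slope · density_i[/kb])

Under a ligand, a fraction of transcripts ("responders") have f_i multiplied
by `responder_effect`, capped at 1. Size factors s_j equalize expected
library totals, mimicking fixed sequencing depth. Optional spiked "residual
rRNA" transcripts get very high expression and a capture rate below b.
A single RNG stream (`numpy` Generator) drives each run; the seed is
recorded in the truth object and output metadata.

**Frozen defaults.** 2,000 transcripts of 500–3,000 nt; Poisson(3) planted
motifs (capped at 10); G/C target uniform on 0.35–0.55 plus 0.03 per
motif/kb (coupling G/C to pG4 density, as in real transcriptomes);
log-normal expression with median 300 expected input reads; α = 0.05;
b = 0.002, c = 0.45; logistic folding intercept −3.0 and slope 0.6 per
motif/kb (baseline folding propensities ≈ 0.05–0.7); 10% responders with a
3-fold effect. The folding/capture parameters were fixed by a single
calibration run of the generator — chosen so that capture rates span a
realistic dynamic range (ES ≈ 0.05–3 before normalization) and the latent
signal is neither saturated nor vanishing — and were not revisited per
analysis.

**What the generator does not emulate**, and hence what passing tests do not
show about real data: no isoforms, positional coverage, mappability or GC
sequencing bias; expression does not shift under treatment (so the two ΔES
definitions differ only in variance here, not in bias); planted motif counts
are drawn independently of length, so synthetic pG4 *density* anti-correlates
with length and ES inherits a negative length trend that real landscapes
need not show; folding propensity is a deterministic logistic in density,
whereas real G4 folding depends on sequence context, topology and
protein competition. Recovery numbers on this generator characterize the
pipeline's statistical behaviour, not biological truth.

**Recovery characteristics at the frozen conditions** (computed by
`scripts/acceptance.py`, not asserted here): ES ranks track the latent
capture rate (Spearman ≈ 0.89); a no-enrichment run centers ES at 1. The
ΔES > 1.75 responder rule is variance-limited under the default ΔES: with
dispersion 0.05, two pulldown replicates and unreplicated inputs, the null
log-ΔES standard deviation is ≈ √(3α) ≈ 0.39, so ~7–8% of null genes exceed
the threshold and the false-discovery proportion among calls sits near
0.3–0.4 with 10% responders, while per-gene power tops out near 0.9
(sensitivity ≈ 0.7–0.85). The input-unadjusted ΔES variant reaches
sensitivity ≈ 0.8–0.9 at FDP ≈ 0.02–0.08 on the same data. Raising input or
pulldown replication is the principled remedy within the default
definition.

## Determinism and numerics

Identical config + seed give byte-identical FASTA, counts and truth tables;
pipeline manifests record version, thresholds, seed and SHA-256 checksums of
inputs and outputs, and are stable under reruns. Floating-point table output
uses 6 significant digits; identifiers and integer counts round-trip
exactly. Degenerate inputs (empty sequences, flat curves, constant
covariates, missing inputs, non-positive library sizes) raise typed,
message-bearing errors rather than propagating NaNs.
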