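# Methods

This note records the models implemented in `mirtargetome`, the defaults
and why they were chosen, what the simulators do and do not emulate, and
the numerical decisions a maintainer would want to know about.

## Differential small-RNA expression (`smallrna`)

Counts from a two-group design (default: 4 tumour cell lines vs 3 sorted
germinal-center B-cell samples) are normalized per sample to 10^6 reads
(RPM). The abundance filter keeps miRNAs with ≥ 50 raw reads in **every**
sample; it is applied to raw counts, not RPM, and normalization and
filtering are independent functions so either order can be composed.
log2 RPM uses a pseudocount of 1 RPM to avoid −∞ at zero counts; at the
≥50-read abundance floor the pseudocount is negligible.

Testing uses an equal-variance pooled t moderated by an empirical-Bayes
variance prior: s² | σ² ~ σ²·χ²_d/d with 1/σ² ~ χ²_{d₀}/(d₀·s₀²), i.e.
s²/s₀² ~ F(d, d₀). The prior is estimated by a method of moments on
z = log s²: after removing the digamma/trigamma offsets implied by the
model, the excess variance of z identifies d₀ (via a Newton inversion of
the trigamma function) and its mean identifies s₀². When the observed
spread of log variances does not exceed the theoretical sampling minimum,
d₀ = +∞ and every posterior variance equals s₀²; literally identical
input variances short-circuit to that common value. The moderated
statistic is referred to t with d₀ + d degrees of freedom (normal when
d₀ = ∞); setting d₀ = 0 recovers the classical pooled t exactly, which
the tests assert to 1e-10. Benjamini–Hochberg adjustment is implemented
from the step-up definition and cross-checked in tests against both a
brute-force double loop and `statsmodels.stats.multitest.multipletests`.
Two-sided p-values; BH runs over the post-filter test set only.

The exact moderated-t variant of the commercial array software that
motivated this module is not published, so numeric parity with it is not
claimed; the implementation follows the standard scaled-F empirical-Bayes
formulation.

## RIP-Chip differential targetome (`ripchip`)

Samples are single signal columns tagged (condition, fraction ∈ {T, IP},
replicate); two-color chemistry is treated as upstream of the supplied
table. Quantile normalization replaces each value by the cross-sample
mean of its rank, ties receiving the mean of the reference values across
the tied span; the definitional invariant (identical sorted columns) and
a brute-force oracle are asserted in tests.

Probe filtering implements three rules with a per-probe audit: (1)
present flags true in all samples of the comparison; (2) signal at or
above the within-sample 25th percentile (computed over all probes on that
sample) in at least half of the T-fraction samples, ties counting as
passing; (3) every replicate pair within a (condition, fraction) group
strictly below 2-fold apart — strict, so a duplicate pair at exactly 2.0
fails. The percentile rule intentionally uses only T fractions: IP
signals reflect RISC loading, not expression.

Enrichment is the ratio of replicate-mean IP to replicate-mean T signal
per (probe, condition). The comparison's denominator condition is floored
at 1.0 (ratios < 1 are raised to 1), so depletion from RISC in the
reference condition can never inflate a fold change; an optional
symmetric-floor flag exists for sensitivity analysis. The differential
call emits probes with FC = ratio_num / floored_ratio_den ≥ 2 (threshold
compared on unrounded values; one-decimal rounding is display only,
half-away-from-zero) and collapses them to genes by the maximum-FC probe,
reporting the number of passing probes per gene; sorting is FC
descending, ties by gene label. A consequence of the flooring, asserted
as an invariant, is that every emitted record's numerator ratio is at
least the threshold. Threshold-count tables tally probes per condition
and genes per comparison at ratio/FC ≥ 2, 4, 8.

Annotation scans each record's transcript with the seed scanner and lists
the site types found per region in the conventional short notation
(7mA1/7m8/8m); a user-supplied gene → growth-GO table provides the
growth-related flag. Records without an available transcript are left
unannotated and logged.

### Bundled reference screens

`mirtargetome.data` ships the printed IP/T ratio tables of the two
published miR-378a-3p Ago2-RIP-Chip screens in ST486 cells
(overexpression vs empty vector, 20 genes; scrambled control vs
inhibition, 63 genes) together with their seed-site and growth-GO
annotation columns and the originally printed fold changes. Feeding the
ratio columns back through `differential_targetome` reproduces the
published membership and threshold structure exactly. The printed fold
changes themselves were computed from unrounded ratios before rounding,
so recomputing them from the 1-decimal printed ratios matches the
overexpression table exactly at one decimal but deviates by up to ~0.25
in a few inhibition rows (e.g. a printed 3.3/1.0 beside a printed FC of
3.1); the tests bound the deviation accordingly. Membership and counts
are unaffected.

## Seed-site scanning (`seedscan`)

Patterns are built from the mature miRNA (an input, never a baked-in
constant; the bundled miR-378a-3p sequence is miRBase v21): 7mer-m8 =
reverse complement of positions 2–8; 8mer = 7mer-m8 followed by A;
7mer-A1 = reverse complement of positions 2–7 followed by A, the target A
being required opposite position 1 regardless of its identity.
Classification is hierarchical — an 8mer occurrence is reported once and
suppresses the 7mer-m8 at its own offset and the 7mer-A1 one position
downstream; the published tables list one site type per region, which is
consistent with this per-locus deduplication. Overlapping occurrences at
distinct loci are all reported. Coordinates are 0-based half-open
throughout; regions are assigned by the match's 5′-most nucleotide
(boundary-spanning sites are rare and no finer rule is defined); sites on
noncoding transcripts are reported under 3′UTR, the reporting convention
of the reference tables. Scanning is case-insensitive and U/T-agnostic.
Equivalence with a brute-force all-substrings oracle under the same
suppression rule is asserted on hundreds of random sequences.

## Assay statistics (`assays`)

**GFP competition.** Trajectories are normalized so the baseline day
(default day 4) equals 100 exactly; normalization is idempotent. The
mixed model is fit by REML (statsmodels `MixedLM`) with a random
intercept per replicate-within-construct, on the linear normalized scale
by default (a log-scale option exists). Two defaults deviate from the
minimal textbook layout, both for calibration at realistic replicate
counts (three per construct), and both established by null simulation
during design:

* the normalized baseline rows are dropped — they are identically 100,
  carry no information, and bias the residual variance toward zero;
* a construct main effect is included alongside time and time×construct.
  Because normalization divides by the *observed* baseline value, its
  measurement error shifts an entire series up or down; without a main
  effect those construct-level shifts leak into the slope contrast and
  inflate its type-I error (≈0.08–0.15 at α = 0.05 in null simulations,
  and a Satterthwaite correction does not repair it). With both choices
  the null rejection rate is 0.025–0.04 at α = 0.05 over 200–400
  simulated assays. `construct_main_effect=False` / `drop_baseline=False`
  recover the minimal structure.

Interaction p-values are two-sided on a t reference with
n_obs − n_fixed − n_groups degrees of freedom. The fixed-effect estimates
agree with R's lme4/lmerTest REML fit to ~1e-7 on a frozen simulated
dataset (asserted in tests). The random-effects structure is a random
intercept only; a random-slope option is exposed but off by default. A
perfectly linear noiseless input yields the constructed slope difference
exactly (the SE degenerates; p is reported as 0 for a nonzero estimate).

**Luciferase.** Duplicate wells are averaged *before* forming the
Renilla/firefly ratio, giving one value per biological replicate and arm;
arms are compared by a two-sided paired t-test on replicate-matched
ratios. Identical arms return t = 0, p = 1 rather than the 0/0 of the
naive formula; a single pair is an error.

**qPCR.** Relative expression is 2^−(Cp_miRNA − Cp_housekeeping).

**Protein.** Band intensity over total-lane intensity, relative to a
control lane fixed at 1; the accompanying one-tailed paired t-test
returns t = 0, p = 0.5 on identical inputs.

## Synthetic data (`synthetic`)

All randomness flows from the config's single integer seed through one
`numpy` Generator; identical configs give identical outputs. Each
generator returns a `PlantedTruth` whose identifiers are guaranteed to
resolve in the generated dataset.

**Counts.** Negative-binomial (gamma-Poisson) counts around
library-size-scaled expected proportions; baseline abundances are
log-normal across miRNAs (log-sd 1.8, giving a top-10 share of ~30–37% —
real miRNA libraries are even more concentrated, up to ~70%), library
sizes log-normal with CV 0.3 around 2×10^6 reads. Defaults plant 50
four-fold changes among 500 miRNAs in a (4, 3) design with dispersion
0.2. The planted effect is split symmetrically (×2^(fc/2) in one group,
×2^(−fc/2) in the other) so the expected group-mean ratio is exactly
2^fc, and the unplanted complement is rescaled so each group's expected
proportions sum to one: sequencing is compositional and per-million
normalization enforces exactly this compensation, so the planted ratio
also holds in expectation on the RPM scale. Effects are planted on
quantifiable miRNAs (expected count ≥ 200·2^(|fc|/2), individual share ≤
5%); planting more effect mass than the complement can absorb is a
configuration error.

**Arrays.** Log-normal probe baselines (log2 sd 1.5 around 10), iid
log2 replicate noise (sd 0.15), two conditions × {T, IP} × duplicates.
Planted targets add the effect to the IP signal of the miRNA-high
condition only. Absent flags go to the lowest-baseline probes (real
detection calls fail on dim probes), each flagged in at least one sample;
duplicate-inconsistent probes have one replicate raised 1.1 log2 units
above its group's maximum, so the ≥2-fold violation holds by
construction. Targets are planted on probes that are present, consistent
and above the filter percentile — i.e. on probes a real screen could call
at all; this is what makes the end-to-end precision/recall ≥ 0.9 check a
test of the pipeline rather than of the corruption process.

**Transcripts.** Random sequences at configurable GC content; coding
transcripts get CDS boundaries at ~15% and ~70% of their length. Each
requested (site type, region) is planted on its own transcript at a
uniform position inside the region, with two guards so a hierarchical
scan recovers the planted type exactly: a planted 7mer-m8 is never
followed by A (which would promote it to an 8mer) and a planted 7mer-A1
is never preceded by the base completing the 8mer. Sites requested on
noncoding transcripts are recorded under 3′UTR, matching the scanner's
reporting convention.

**GFP.** Trajectories baseline·exp(slope·(day − day₄)) with a log-scale
replicate intercept (sd 0.05) and log-scale observation noise (sd 0.04),
triplicates, read days 4–18 three times a week, baseline 40% GFP⁺, a mild
control decline of −0.01/day. The default knockdown construct loses an
additional 0.12/day.

**Luciferase.** Duplicate wells, three biological replicates, a shared
log-normal batch effect per replicate-pair (the paired design's target),
5% technical CV; planted suppression multiplies Renilla only in the
experimental arm.

What the simulators do **not** emulate: sequencing reads and mapping,
isomiRs, dye-channel chemistry and background, probe cross-hybridization,
transcript secondary structure or site-context effects, flow-cytometry
gating noise. Passing tests therefore demonstrate the correctness of the
statistical machinery under its assumed generative structure, not
robustness to every artefact of real data.

## Problem sizes

The test suite runs desk-scale problems throughout: 300–500 miRNAs × 7
samples (200 null datasets for type-I calibration), 1000–2000 probes × 8
arrays, 500 random sequences for scanner/oracle equivalence, 5000
variances for empirical-Bayes recovery (20 seeds), and 200 null plus 200
power mixed-model fits. The genome-scale results of the motivating study
(26 differentially expressed miRNAs, 73%/71% top-10 abundance shares,
absolute probe counts of the full arrays) depend on the deposited
experimental data and are deliberately out of scope; the bundled printed
ratio tables are reconstructed instead.
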