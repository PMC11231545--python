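# Methods

This note documents the statistical model, the fixed constants and the
design decisions behind `tgrisk`, in the spirit of a model-description
appendix. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Phenotyping

Each participant needs at least one TG measurement (mg/dl, strictly
positive). Measurements taken while exposed to a lipid-lowering drug class
are corrected multiplicatively: the measurement is multiplied by the class's
adjustment factor, and when several exposures overlap a measurement date the
largest factor wins. The participant summary is the median of adjusted
values (even-length lists: mean of the central pair). The default factors
invert assumed fractional TG reductions — statin 15%, fibrate 30%, omega-3
25%, niacin 20%, i.e. factor = 1/(1−reduction) — and are configuration, not
constants of the method: published analyses of this design keep their exact
factors in supplementary material, and the pipeline's contract is the
mechanism. Whether adjustment should act on individual measurements or on
the final median, and additively or multiplicatively, is genuinely open;
per-measurement multiplicative adjustment was chosen because it composes
naturally with exposure intervals and with log-normal TG marginals, and it
is isolated behind the `AdjustmentTable` contract so an alternative can be
swapped in.

Category boundaries: severe is TG > 885 mg/dl and mild-to-moderate is
300 ≤ TG ≤ 885. Inclusivity at the boundaries is not standardized; both
ends of the middle band are inclusive here (the upper end is unreachable
because severe claims > 885 first). The normal group is the 25th–75th
percentile band of the non-excluded cohort, excluding anyone whose exposure
interval overlaps a measurement date (potentially well-treated HTG).
Percentiles use linear interpolation between order statistics (the default
of mainstream numeric stacks). Sensitivity labels: AHA severe (> 500 mg/dl)
and top 1% (TG ≥ the cohort 99th percentile, ties included — no tie rule is
standard for "top 1%"). Exclusions (metastatic cancer, hospice, feeding
tube, severe malnutrition) are boolean flags; a helper matches user-supplied
code lists against per-participant code tables by exact string, because the
source concept sets are environment-specific.

## Variant classification

MAF is computed in the analysis cohort (not an external reference): minor
allele count over 2 × non-missing genotypes, oriented so MAF ≤ 0.5. Rare
means MAF ≤ 1%; rare and common variants are analyzed separately.

The in-silico functional filter requires CADD PHRED > 10 **and** at least
one secondary predictor calling the variant damaging (PolyPhen-2
"damaging", SIFT "deleterious", or MutationTaster score > 0.5). When no
secondary classification is available the second clause is vacuously
satisfied ("when classification was available" semantics); a strict mode
requiring an available secondary call is a config switch. The filter is
monotone in CADD by construction.

Carriage per gene is biallelic if the participant is homozygous for the
minor allele of any functional variant or heterozygous at ≥ 2 distinct
functional variants in that gene; this compound-heterozygous proxy is
phase-unaware because short-read WGS phasing is generally unavailable.
Heterozygous variants in different genes never combine to biallelic.
Missing genotypes never count as carriage. Common functional variants are
additionally screened data-driven: only those positively associated with
adjusted TG (additive-model p ≤ 0.05 by default) enter the common-carriage
factor, formalizing as a rule the published practice of restricting to the
one common variant associated in the expected direction.

## Scores and flags

The PRS is the plain weighted sum of effect-allele dosages; effect alleles
are resolved against VCF ref/alt and a mismatch is an error rather than a
silent skip. Missing dosages contribute 0 (and are logged); this is
reproducible and conservative, and the alternative of mean imputation was
rejected as the default because it manufactures signal at sparse loci. The
causal-allele count sums TG-increasing alleles over the panel, bounded by
2 × panel size.

Two top-decile rules coexist because the two scores are referenced to
different populations: the PRS threshold is the minimum score of the top
⌈0.10·N⌉ members of the normal-TG group (flag = score ≥ threshold, so the
threshold-setting member is flagged), while the causal-count threshold is
the 90th percentile of the whole cohort with a strict > comparison — with
heavily tied integer counts the flagged fraction of a subgroup can exceed
the nominal 10%, and with all values tied nobody is flagged. The collective
flag is the logical OR of the four factor flags.

## Enrichment statistics

Tables are oriented as (a, b) = exposed/unexposed cases, (c, d) =
exposed/unexposed controls. The OR is ad/bc with the Woolf (log-normal)
95% CI; Woolf was chosen because it reproduces published CIs of this design
to the printed 2 decimals (verified in the test suite on five reconstructed
tables). Tables with a zero cell receive the Haldane–Anscombe +0.5
correction to all cells and are flagged as corrected. The test is
chi-square (1 df, without Yates correction) when every observed cell is
≥ 5, otherwise the two-sided Fisher exact test under the point-probability
summation convention; the Fisher branch is verified against an exhaustive
exact-arithmetic hypergeometric enumeration on all tables with total ≤ 30.
Published p-values of this design cannot always be matched exactly — a
reconstructed table's chi-square p lands between the corrected and
uncorrected variants — so the OR/CI, not p, is the reproduction surface.
No multiple-testing correction is applied (comparisons are reported
marginally); a Bonferroni helper exists but is off by default. Spearman
correlation uses mid-ranks with the large-sample p approximation, and
single-variant association is OLS of natural-log TG on allele dosage
(slope, SE, Wald p), the additive model.

## Synthetic cohort generator

The generator's job is to realize the statistical structure the analysis
assumes. All genetic effects act additively on natural-log TG — the scale
on which a reported per-allele effect of 0.12 from a transformed-TG
regression is coherent with multiplicative medication effects and
log-normal TG marginals (the source transformation is not recoverable; this
is the package's documented choice, and the recovery analysis regresses on
the same scale):

latent_i = μ + β·x_i + PRS-liability_i + γ·(causal count_i − E) + s·1[secondary HTG] + ε_i

with μ = ln 108.4, β = 0.12 for the common variant (MAF 0.063, matching the
observed ~6.3%), PRS liability the centered weighted dosage sum with
per-locus weights ~ N(0, 0.015²) over 285 loci (≈ 0.15 SD on log TG),
γ = 0.001 per allele over 140 panel loci, person-level noise
ε ~ N(0, 0.40²), and each measurement exp(latent + N(0, 0.15²)).
Participants on a drug class (probability 0.20) have all observed values
multiplied by (1 − reduction); their exposure interval spans their
measurements, so the phenotyping adjuster can invert the effect exactly.
The secondary-HTG term (probability 0.004, shift +2.0 on log TG) models
non-genetic severe hypertriglyceridemia: a pure log-normal at the target
IQR (79–149 mg/dl around a 108 mg/dl median) essentially never exceeds
885 mg/dl, whereas real cohorts report a ~0.1% severe tail, and without it
the severe arm of the comparison grid would always be empty.

Genotypes are independent Hardy–Weinberg draws (no LD — deliberately, since
nothing downstream uses LD). Rare-variant allele frequencies follow
10^U(−5, −2.8), a singleton-heavy spectrum chosen so aggregate functional
carriage in the normal group lands near the ~11% such studies report; 48
rare variants per gene give 240 in total, with a configurable fraction
(default 0.9) passing the functional filter. Annotations are drawn
consistently with the intended filter outcome and exercise both passing
branches (secondary-predictor support and the all-absent vacuous branch).
CADD is uniform on the passing/failing side of the gate; secondary
predictors are independently present/absent. Missing genotypes (rate 0.002)
are masked only after the latent phenotype is fixed. Measurement counts are
uniform on 1–5 per person with synthetic dates used only for interval
logic.

What the generator does **not** emulate — LD between loci, ancestry
structure, genotype uncertainty, EHR billing-code realism, secular trends
in lab values, and correlated comorbidity effects on TG. Passing recovery
tests therefore demonstrates the correctness of the pipeline's estimators
under the stated generative assumptions, not robustness to those real-data
complications.

## Masking

Counts below the threshold (20) render as "≤20"; their percentages render
as bands of width 5 containing the true value ("35–40%"), and a parent
group at or below the threshold is banded as well. An alternative mode
renders the percentage of a hidden subgroup of a disclosed parent as the
upper bound the threshold represents ("≤50%" for a parent of 40); its
trigger is group_n > threshold while n < threshold, and it is off by
default because the banded form matches the frequency-figure convention.
Masking applies to the report, the frequency table and the 2×2 cell
columns of the enrichment CSV; statistical results (OR, CI, p) are never
masked.

## Problem sizes and numerical choices

Distribution-level tests and the acceptance script use cohorts of n = 5,000
(50 replicates for effect-recovery coverage; 200 replicates for the OR = 2
recovery with the published group sizes 342/3,532 and a 13.2% control
exposure rate), sizes at which the checks are well-powered while the whole
suite stays around a minute. The normal 95% quantile 1.959964 is used
rather than 1.96 (indistinguishable at printed precision). Determinism:
one `numpy` Generator seeded from the config drives every draw, outputs are
written in fixed orders with fixed float formats, and an identical
seed + config yields byte-identical cohorts and report bundles. Degenerate
inputs are errors with messages, not silent results: empty measurement
lists, all-missing genotype columns, constant vectors in correlation or
regression, degenerate 2×2 margins, empty reference groups, multi-allelic
VCF records (pre-split required), and effect-allele mismatches.

## Known limitations

* Compound-heterozygous calls are phase-unaware and overcall true biallelic
  carriage when two heterozygous variants share a haplotype.
* The medication adjustment assumes class-level multiplicative effects that
  are constant across patients and doses.
* The common-variant screening step conditions on the same data used in the
  enrichment comparison; it mirrors the published procedure rather than
  correcting its selection effect.
* Config validation covers ranges and signs, not cross-field coherence
  (e.g. a normal band wider than the severe threshold).
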