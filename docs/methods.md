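# Methods

## Scope and model

The package models a 12-week, parallel-arm, genotype-guided weight-loss
trial. Subjects are classified *a priori* from a 10-SNP panel as
fat-responders or carbohydrate-responders, randomized 1:1 to a high-fat
(45/40/15 %energy carbohydrate/fat/protein) or high-carbohydrate (65/20/15)
hypocaloric diet within (responder class, sex) strata, prescribed an energy
tier, and analysed for the adjusted difference in weight change between
genotype-concordant and genotype-discordant diets.

## Responder scoring

Each panel locus maps its three diploid genotypes to points on a fat axis
and a carbohydrate axis; axis totals are compared to inclusive thresholds.
`FAT_RESPONDER` requires the fat threshold met and the carb threshold not
met (symmetrically for `CARB_RESPONDER`); meeting both gives `BOTH`,
neither gives `NEITHER`, and both of those are ineligible. Inclusive
comparisons mean boundary subjects who reach both thresholds are `BOTH`,
hence excluded.

The scoring engine is entirely table-driven. The shipped
`score_table_10snp_synthetic.yaml` is a **synthetic stand-in**: the actual
point values used in practice are not publicly deposited, so the table was
constructed to have the structural property the observed screening split
demands. With independent fat/carb axes, eligible fractions
(P(fat-only), P(carb-only)) = (0.41, 0.20) are mathematically unattainable:
writing a = P(fat axis met), b = P(carb axis met), the system
a(1−b) = 0.41, b(1−a) = 0.20 has negative discriminant. The synthetic table
therefore mixes four fat-axis loci, three carb-axis loci and three
antagonistic loci whose alleles push the two axes in opposite directions,
inducing the necessary negative correlation.

`class_probabilities` computes the exact four-class distribution for any
table and allele-frequency vector by convolving the per-SNP joint point
distributions under Hardy-Weinberg proportions (the panel is simulated
without linkage disequilibrium). `calibrate_allele_frequencies` runs
bounded least-squares on that exact map; the shipped frequencies were
calibrated so the class probabilities equal the target split
112/275 fat, 57/275 carb (both to < 0.5% absolute). Because mirrored tables
make the objective symmetric, the default start point is asymmetric to
avoid the saddle at equal frequencies.

Missing-call policy defaults to `REJECT_IF_ANY_MISSING` for screening
(a complete export is required for eligibility); `ZERO_CONTRIBUTION` is
available for sensitivity analyses. The default generator injects no
missing calls at panel loci, matching a screening flow in which every
genotyped subject is classifiable.

## Genotype file handling

Both DTC dialects are parsed line-wise with `#` comments and Ancestry-style
`rsid …` header lines skipped; fields may be tab- or comma-separated.
Missing sentinels `--`, `00`, `0`, `D`, `DD`, `I`, `II` and blanks all map
to a missing call. A single-allele (hemizygous) genotype is duplicated to a
homozygous pair; all ten panel loci are autosomal, so this path only
affects non-panel records. Positions are opaque labels — the panel keys on
rsID only and no genome-build validation or liftover is attempted.
Duplicate rsIDs with identical calls collapse silently; discordant
duplicates raise a conflict error when the locus is extracted for scoring.
Strand normalisation returns the Watson-Crick complement when the observed
pair fits the locus definition only on the opposite strand (including
homozygous calls such as CC at an A/G locus, which flip to GG); A/T and C/G
loci are accepted as-is and flagged ambiguous, since a flip there is
undetectable from the data.

## Randomization and energy prescription

Within each (responder class, sex) stratum, allocation uses permuted blocks
— females 6 then 4, males 4 then 2, the size dropping after a configurable
enrolment fraction (default 0.5, since the real switch point was an
in-study decision that is not public). Inside a block with slots open in
both arms, the subject is steered toward the arm that reduces the running
between-arm mean-BMI difference with probability 0.8 (deterministically if
the difference already exceeds the tolerance, default 1.5 kg/m²);
otherwise the only open arm is taken. Completed blocks are therefore
exactly balanced and the stratum imbalance never exceeds half the current
block size, while BMI stays balanced: over 1000 seeded runs of a
trial-scale cohort the mean between-arm BMI difference averages ≈ 0 and
lies within the tolerance in ≥95% of runs. The exact balancing equation
used in practice is unknown; the biased-coin mechanism is a standard
stand-in and every knob (block sizes, switch fraction, tolerance, coin
probability) is configurable.

Energy tiers: Mifflin-St Jeor resting energy expenditure
(male 10W + 6.25H − 5A + 5; female 10W + 6.25H − 5A − 161, W kg, H cm,
A years) × activity factor (default 1.4, sedentary-to-light; not a
published trial parameter) − 750 kcal/day deficit, snapped to the nearest
tier in {1400, 1600, …, 2800} kcal/day with ties rounding up (favouring
meal-plan adequacy) and clamping at the grid ends.

## Synthetic cohort and outcomes

Demographics: age ~ N(54.4, 13.2²) truncated to 18–75 y; BMI ~
N(34.9, 5.1²) truncated to the 27.0–47.5 kg/m² eligibility window; 84%
female; race white/black/other with probabilities 0.68/0.295/0.025; height
drawn per sex and weight derived from BMI so the three are consistent to
0.1. Fasting glucose and insulin are log-normal (medians 95 mg/dL and
12 µU/mL).

Outcomes: weight change (kg) = μ + β·1[concordant] + ε with defaults
μ = −4.8 kg, β = −0.6 kg and ε ~ N(0, 2.8²). The 2.8 kg is taken as the
individual-level SD of the change score — the interpretation under which
the published 80%/95% power figures are recovered; the group-level
dispersion figures printed alongside arm means are treated as standard
errors (an alternative `sd_interpretation="group_se"` switch rescales
instead). Secondary changes (percent weight, body fat, SBP, DBP, a craving
scale) follow analogous linear models with configurable effects and SDs.
Attrition is Bernoulli(0.11), non-informative by default; an
`informative_attrition_beta` slope couples dropout to the (latent) weight
change for sensitivity analyses. Non-completers' outcomes are missing, and
the analysis is complete-case. A pre-randomization dropout of 24/169
thins eligible subjects to the randomized set.

Adherence: for each arm × week, carbohydrate and fat percentages are drawn
from Normals at the arm-specific reported means/SDs (e.g. high-carb week 4:
63.4 (2.3) carb, 20.9 (2.4) fat) and protein is the residual
100 − carb − fat, so records sum to 100 exactly and the carb/fat means are
preserved. (Multiplicative renormalisation of three independent draws
would bias the carb mean, because the configured means sum slightly above
100; the residual-protein construction trades a ~0.3-point shift in the
protein mean for exactness on the two macros that define the diets.)

What the generators do **not** emulate: linkage disequilibrium between
panel loci, seasonal/temporal enrolment structure, site effects,
measurement error in anthropometrics, within-subject weekly weight
trajectories, and any genotype-phenotype correlation beyond the injected
concordance effect. Passing tests therefore validate the pipeline's
statistical machinery, not the biological hypothesis.

## Analysis

The treatment effect is fitted as ANCOVA on the change score — change ~
group + sex + race + baseline — which for a single pre/post pair is the
standard equivalent of a two-timepoint mixed model with subject-level
correlation; a random-intercept longitudinal fit is available via
`fit(method="mixed")` and agrees with the ANCOVA contrast. CIs are t-based
with residual degrees of freedom. Covariates that are constant in the
analysis set are dropped with a warning rather than producing a singular
design; two groups with identical constant outcomes return a zero estimate
flagged degenerate with p = 1. With no covariates the model reduces
exactly to the pooled-variance two-sample t-test (tested against scipy).

Holm-Bonferroni step-down is authored in-package (sort ascending, multiply
the i-th smallest by m − i + 1, running maximum, cap at 1, map back) and
cross-checked against statsmodels' implementation. The six-member family
(five craving subscales + total) makes a smallest raw p of 0.001 adjust to
0.006. HOMA-IR uses the mass-unit denominator 405 (glucose in mg/dL); the
molar 22.5 variant is a parameter. Insulin/HOMA-IR association models
regress weight change on the predictor, diet group, sex and race; the
interaction p comes from an F-test of the added diet × predictor term.

## Power

Closed form: two-sided two-sample test, noncentrality
δ/(σ√(2/n)), df = 2n − 2, power = 1 − F_nct(t_crit) + F_nct(−t_crit).
At (δ, σ, α) = (2.0, 2.8, 0.05): 0.803 at n = 32/group, 0.980 at
n = 64/group. The `normal_approx` method replaces the noncentral t by a
shifted unit Gaussian while keeping the exact t critical value, which stays
within 0.01 of the exact answer for n ≥ 30. `simulated_power` pushes
Normal draws through the package's own `adjusted_difference` and agrees
with the closed form to Monte-Carlo error; under δ = 0 it recovers the
nominal size.

## Problem sizes and numerical choices

The acceptance script and test suite use: 500 Monte-Carlo replicates for
size/power calibration (binomial SE ≈ 1%), 5,000 subjects per arm for
parameter recovery (SE ≈ 0.04 kg), 275 subjects for the screening split
(3-SD binomial bands), 1,000 seeded randomizations for BMI balance, and
5,000 subjects for adherence/cohort marginals — sizes chosen so each check
has comfortable resolution for the property it verifies while the whole
suite runs in well under a minute per module. All randomness flows through
`numpy.random.default_rng` seeded explicitly; pipeline stages draw
sub-seeds from one generator so a single run seed determines every output,
and the run report records the seed and a configuration hash.

## Known limitations

The shipped score table is synthetic: real scoring criteria must be
supplied as a config to classify real exports. The randomization balancing
equation and the block-size switch point are plausible stand-ins, not
reconstructions. Classification of real DTC files would additionally face
genome-build and indel-encoding quirks that the opaque-position design
deliberately sidesteps. The mixed-model variant uses a large-sample normal
approximation for its CI rather than Satterthwaite degrees of freedom.
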