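# Methods

## Scope and data model

`ptacal` evaluates a quantitative lateral-flow calprotectin rapid test (QBT)
against ELISA and builds the adjusted PTA score on top of it. One row of the
cohort table is one subject: a diagnosis group (healthy control, tonsil
hyperplasia, recurrent tonsillitis, acute tonsillitis, mononucleosis,
peritonsillitis, or peritonsillar abscess), four binary symptoms, and paired
serum/saliva calprotectin in ng/ml from both measurement channels. The
original patient-level data is not public, so all cohort-level numbers in
this repository are computed on synthetic cohorts; the analytic constants
(dilution ranges, cutoff rules, score arithmetic) are exact.

## Assay quantitation model

The cassette is modelled as reporting the concentration of the *diluted*
specimen, with a native quantitation window of 50–1000 ng/ml; effective
specimen concentrations are cassette reading × dilution fold. This convention
reproduces every published effective range (500–10,000 ng/ml at 1:10;
2000–40,000 at 1:40; 100,000 ceiling at 1:100) from two cassette constants,
and keeps all dilution scaling in one module. Values exactly at a limit count
as within range — the re-test rule fires only strictly *above* the upper
limit. Censored results carry the violated effective limit plus a status flag
(`below_lloq` / `above_uloq`), never a bare number, so downstream statistics
can exclude or bound them deliberately. The saliva workflow
(measure at 1:40 → re-test at 1:100 → censor) is deterministic; measurement
noise belongs to the cohort generator.

## Synthetic cohort generator

Group sizes default to the published cohort: 15 controls, 16 hyperplasia,
71 recurrent tonsillitis, 15 acute tonsillitis, 10 mononucleosis,
16 peritonsillitis, 36 abscess — 179 subjects. (The source population is
described both as "179 patients" plus 15 controls and by per-group counts
that, with controls, themselves sum to 179; the generator follows the
printed per-group counts, the only fully specified numbers.)

**Concentrations.** The latent true concentration per (group, fluid) is
log-normal — the simplest positive, right-skewed family consistent with the
reported mean ± SEM summaries. Both channels derive from the same latent
value:

    qbt   = latent × b × exp(ε_q),   ε_q ~ N(0, σ_q²)
    elisa = latent × exp(ε_e),       ε_e ~ N(0, σ_e²)

with independent noises (no within-pair error structure is published) and a
multiplicative rapid-test bias b = 1.15, σ_q = 0.35, σ_e = 0.25. This yields
the two published qualitative findings the evaluation rests on: a slight
positive QBT − ELISA bias and an excellent (> 0.8) Spearman correlation
between channels. The published regression slope β = 0.290 (ELISA on QBT)
is *not* reproduced: a slope that far below one would require ELISA to read
several-fold lower than the rapid test, contradicting the "slightly positive
bias" finding; the generator resolves the tension in favour of the bias.

Latent means are back-solved so that the *measured* rapid-test channel hits
the target group mean, `E[qbt] = E[latent] · b · exp(σ_q²/2)`. Targets for
control and abscess are the published means (serum 780 / 5745 ng/ml, saliva
3386 / 25,825 ng/ml); the five intermediate groups are unpublished and use
plausible severity-ordered values (serum 900–3200, saliva 3800–9000 ng/ml).
Coefficients of variation are back-solved from published SEMs where available
(control serum 0.51, abscess serum 0.86, control saliva 1.30, abscess saliva
1.38) and default to 1.0 elsewhere.

**Symptoms** are independent Bernoulli draws per (group, symptom). The
prevalences are not published; the defaults were chosen once so that
simulated mean adjusted scores approximate the published group means
(abscess ≈ 4.1, peritonsillitis ≈ 2.6, acute tonsillitis ≈ 1.5) given the
biomarker-criterion hit rates implied by the concentration model, and they
are config fields, not constants.

**Mechanics.** One `numpy.random.default_rng(seed)` stream drives the whole
cohort, groups in a fixed order, no reseeding inside loops: identical configs
give bit-identical cohorts. All concentrations are strictly positive by
construction. An optional `missing_rate` blanks symptom/concentration fields
independently to exercise the missing-data policies; the default emits
complete records. Age and sex are descriptive draws (uniform over the
published ranges, male fraction 0.47) and never enter any statistic.

**What the generator does not emulate:** age/sex effects on calprotectin,
within-pair correlated measurement error, assay censoring in the recorded
values (concentrations are stored uncensored; the assay module models the
workflow separately), and whatever real-data features produced the published
saliva AUC of 0.677 from group means that, under any unimodal skewed family
with the published moments, separate more cleanly. Passing calibration tests
therefore shows the pipeline recovers the structure the generator encodes —
not that the generator matches the unavailable data in distribution.

## Agreement statistics

Spearman's coefficient is the Pearson correlation of mid-ranks (average ranks
on ties), computed after pairwise deletion of missing values, and requires at
least three complete pairs and non-degenerate ranks. Strength labels follow
the bands used in the source analysis: negligible ≤ 0.2 < low ≤ 0.5 < good
≤ 0.8 < excellent.

The regression is ordinary least squares with a two-sided t-interval. The
direction is ELISA on QBT: with the rapid test biased high, a slope below one
expresses ELISA reading lower on the QBT scale. (The published figure does
not state the direction; this choice is recorded at the interface.)

Bland–Altman differences are QBT − ELISA; limits of agreement are
bias ± 2 × SD — the factor 2, not 1.96, following the source convention —
with the sample SD (n − 1). The restriction to the clinically relevant range
(≤ 12,000 ng/ml by default) is applied to the per-pair mean, i.e. the plot's
abscissa; which quantity the source restricted is unstated. Normality of the
differences is described by the histogram and an advisory Shapiro–Wilk
p-value; neither gates any result.

## ROC and cutoffs

Positive calls are *strictly above* the threshold, matching the score rule.
Candidate thresholds are midpoints between consecutive sorted unique values
plus sentinels beyond either extreme, so each achievable operating point
appears once; AUC is trapezoidal and equals the tie-adjusted U/(n₁n₂)
(a property test enforces this on random instances). Cutoffs maximise
Youden's J = sensitivity + specificity − 1 over interior thresholds — the
source names no selection rule; J is the standard reading — with ties broken
toward higher specificity, then the larger threshold, and the criterion name
recorded in the result for provenance. AUC bands: excellent > 0.9,
good > 0.8, acceptable ≥ 0.7 (exactly 0.7 is "acceptable" by
closed-lower-bound convention; the published bands leave it unassigned),
else poor. The ROC negative class for abscess detection is configurable:
healthy controls only (default, the group-comparison context) or all
non-abscess subjects.

Mann–Whitney U comes from mid-rank sums; the two-sided p-value uses exact
enumeration when n₁ · n₂ ≤ 400 with no ties, otherwise the normal
approximation with tie correction (scipy's implementations of both, behind
this module's selection rule). Group summaries report mean and
SEM = sample SD / √n; SEM is undefined at n = 1 and reported as missing.

## The adjusted score

Score = number of present symptoms + 1(serum > serum_cutoff) +
1(saliva > saliva_cutoff), an integer in [0, 6]. All "above cutoff"
comparisons are strict; the source never addresses boundary equality, and
strictness is applied uniformly (a concentration exactly at its cutoff scores
nothing). Since individual scores are integers, a non-integer ROC cutoff c
maps to the clinical rule "≥ smallest integer > c" (2.5 → 3; an integer
statistical cutoff maps strictly up, 3.0 → 4). Classification is therefore
equivalent to score > c for any non-integer c. Missing inputs follow an
explicit policy: `error` (default) rejects incomplete work-ups;
`score_available_flagged` scores the available criteria and flags the result.
Both biomarker criteria are always evaluated independently, one point each.

## Pipeline and determinism

`run_full` sequences the stages on one cohort (read from CSV with schema
validation that names offending columns, or simulated in-memory) and emits a
single JSON bundle carrying provenance: seed, a hash of the full
configuration, the negative-class choice and the cutoff criterion behind
every ROC number. Serialisation is key-sorted; identical configuration gives
byte-identical reports, and the CLI subcommands reproduce the corresponding
bundle sections exactly when run on the same CSV.

## Problem sizes

Unit and acceptance property tests run on small enumerable instances
(exhaustive oracles up to a few hundred pairs). Calibration-recovery checks
use 1000 subjects per group — large enough that the sign and ordering
properties they assert (positive saliva bias, Spearman > 0.8, serum AUC >
saliva AUC, abscess scores > peritonsillitis scores) are stable across seeds
— and a single 5000-subject group verifies mean recovery within 5 %,
consistent with its ~1.4 % theoretical sampling error. The analysis drivers
and the acceptance script use the published cohort size (179).

## Known limitations

* Cohort-level statistics (r_sp, cutoffs, AUCs, score sensitivity and
  specificity) are properties of the synthetic calibration, not re-derivations
  of the published values; only their direction and rough magnitude are
  comparable.
* The generator's independence assumptions (symptoms independent of
  concentrations within group, channels independent given the latent value)
  are simplifications; real symptom-biomarker correlation within groups would
  change score variance, not its mean calibration.
* No confidence intervals on AUC and no formal method-comparison regression
  (Passing–Bablok/Deming); the evaluation design uses OLS only.
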