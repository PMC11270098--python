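# Methods

This note records the modelling assumptions, parameter choices and known
limitations of the package.  Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Synthetic cohort generator

The generator emulates a claims-style arrest cohort at the level of detail
the attribution method actually consumes: per-visit diagnosis-code sets,
visit ordering and spacing, an arrest record identified by procedure codes
99.60/99.63, and a 30-day mortality outcome.

* **Visit counts** are negative-binomial (mean `visits_mean`, dispersion
  `visits_dispersion`), truncated below at 1; inter-visit gaps are Poisson
  (mean `inter_visit_days_mean`, floor 1 day), with day offsets 0-based
  from the first visit.  No calendar structure is modelled.
* **Diagnosis draws** are Bernoulli per visit in fixed catalogue order.  A
  code's prevalence is its `base_prevalence` times the product of
  `cooccur` multipliers of codes already drawn in the same visit, clamped
  to [0, 1].  Multipliers below 1 model crowding-out (a severe admission
  recording fewer incidental codes); sources must precede their targets in
  the catalogue.  This is the simplest reproducible mechanism that plants
  controlled within-visit comorbidity structure.
* **Mortality** is per-visit logistic:
  `P(death within 30 d | visit) = σ(baseline_logodds + Σ code effects)`,
  evaluated on the visit's own codes only.  The first triggering visit
  fixes the death day uniformly in the following 30 days and truncates the
  sequence, so no record postdates death.  The 30-day label boundary is
  **inclusive** (death at exactly +30 days counts); the convention is a
  package decision and is pinned by tests.
* **Arrest records.** The terminal visit of each selected patient (rate
  `ihca_rate`, default 1: every generated patient is in the arrest cohort)
  carries a resuscitation procedure code; with probability
  `extra_ihca_rate` (default 0.026, matching a ~97.4% single-arrest share)
  an earlier visit carries one too.  A consequence of tying the arrest to
  the sequence-terminating visit is that arrest records are naturally
  enriched for lethal codes and every cohort death is labelled positive at
  its arrest record.  It also means nearly all deaths occur within the
  first arrest hospitalization (~97% in the calibrated cohort), somewhat
  above the ~94% of real arrest cohorts, where some patients die during a
  later arrest.
* **Reproducibility.** One seed governs a cohort; per-patient substreams
  derive from `(seed, patient_index)`, so identical `(spec, seed)` produce
  byte-identical serialized cohorts, and stage-specific sub-seeds derive
  from the master seed by stable hashing of the stage name.
* **Demographics** (sex ratio 0.62 F, age N(68.66, 18.96) clipped to
  [0, 118], inpatient/outpatient flags) are cosmetic metadata; nothing
  downstream reads them.  The exclusion of dental/traditional-medicine
  records in real claims data is represented only by the count utility
  `records_after_exclusion`, not simulated.

### The `paper_like` calibration

`paper_like` targets the descriptive statistics of a published arrest
cohort: per-visit prevalences are diagnosis-mix shares × ~3 expected
mentions per visit (diabetes mellitus 4.93% of mentions, acute respiratory
failure 4.81%, pneumonia 4.54%, urinary tract infection 4.19%, …), with
pneumonia's base prevalence lowered so its marginal share survives the
UTI→pneumonia boost that fixes P(pneumonia | UTI) = 23.36%.  Baseline
log-odds −4.8 and planned-visit mean 14 were calibrated once so that the
*observed* (post-truncation) cohort shows ~52% patient mortality, ~9.3
analyzed records per patient and ~11% arrest-record share.  Mortality
effects for the named diagnoses are plausible relative magnitudes
(respiratory failure, shock and cardiac arrest strongest; hypertension and
diabetes near zero), not estimates from any dataset.

### What the generator does *not* emulate

Chronic-condition persistence across visits (draws are independent given
the within-visit co-occurrence), coding drift, care-seeking intensity that
depends on latent severity, and any history-dependent mortality: the true
risk of a visit depends on that visit's codes only.  Passing tests
therefore show that the attribution and validation machinery behaves
correctly under controlled confounding — not that the method is validated
on real claims data.  In particular the *historical* impact tables on
synthetic cohorts are a null exercise by construction (history carries no
causal signal), and the historical model-side ranking is dominated by
estimation noise; the machinery is still exercised and its mechanics are
tested on models with planted history weights.

## Risk model

A dense rectifier MLP over the (H+1)-block multi-hot layout, H = 4 by
default (the validation protocol judges a record together with its four
predecessors; H is configurable).  The first `visit_encoder_dims` layers
are initialized block-diagonal with per-visit encoder weights shared
across slots — a hierarchical visit-then-patient encoding as an
initialization prior — and trained unconstrained.  Absent history slots
encode as the all-zeros reference, which forces their attributions to be
exactly zero.  Training is plain minibatch SGD with momentum on the
cross-entropy (fixed seeds, no early stopping: determinism first), with a
patient-level held-out split and a rank-statistic AUROC as the
discrimination summary.  Restricting hidden units to rectifiers keeps the
whole network inside the family for which the rescale attribution rule is
exact per layer.

## Attribution engine

DeepLIFT/DeepSHAP *rescale* semantics with a single reference:

* multipliers through a linear layer: `m ← m Wᵀ`; through a nonlinearity:
  the secant slope between the reference and input pre-activations, with
  the derivative on the reference's side substituted when the two
  pre-activations differ by less than ε = 10⁻⁹ (at a rectifier kink
  exactly at 0 the multiplier is 0).  Any fixed kink convention suffices;
  this one is documented and tested.
* the default reference is the all-zeros multi-hot ("no diagnoses
  recorded"), the natural absence encoding: absent codes and empty history
  slots receive exactly zero attribution.  A multi-reference mean mode
  (`deep_shap_mean`, CLI `--reference mean`) is available but off by
  default to keep worked examples deterministic.
* attributions can be taken on the probability scale (default; the
  logistic output unit is handled by the same rescale rule) or on the
  logit scale.
* completeness |Σφ − (f(x) − f(ref))| ≤ 10⁻⁶ is enforced on every batch;
  in practice the residual is at floating-point rounding level because
  each layer's multiplier identity is exact.

The rescale chain equals the exact Shapley value on affine models (tested
to 10⁻⁹) but is an *approximation* for general rectifier networks; the
suite measures the deviation against the enumeration oracle on ~100 tiny
networks and asserts the axioms that must hold (completeness, dummy,
symmetry of the oracle) rather than pretending equality.  The enumeration
oracle refuses more than 12 players (2¹² evaluations).

## Impact aggregation and segmentation

A code's current (historical) impact is the unweighted sum of φ over its
current-block (history-block) positions — with one position per
(block, code) the unweighted sum is the minimal faithful linear
aggregation; weighted variants are out of scope.  The record segmentation
basis defaults to the maximum per-code impact of the analyzed kind
(`max_code_impact`), with the model's predicted probability
(`predicted_probability`) available as the alternative reading; thresholds
are ≥ 0.25 (high) and ≤ 0.10 (low), inclusive on both sides, and
configurable.  Which basis the original study design intended is not
decidable from its description; both are implemented and the choice is
recorded in output metadata.

## Validation protocol

Patients qualify when their arrest record has a positive 30-day label and
at least four prior records (patients with fewer are excluded and logged;
padding would distort the historical counts).  Each qualifying patient
contributes **5 current** decision points (the arrest record and its four
predecessors, each judged on its own visit's codes) and **4 historical**
points (the last four of those records, each judged on its preceding
window of up to four visits; code counting for historical points covers
the window's prior visits — the scope of the historical impact).

Simulated annotators threshold a logistic-noise-perturbed version of the
record's true generative risk at cut-points 0.5 / 0.2 / 0.05 for scales
1/2/3 (scale 4 below).  The default noise scale is 0.1 on the log-odds —
high-agreement experts; the noise level is configurable, and
inter-annotator exact agreement decreases monotonically in it (tested).
Two annotators judge each point; when they differ by at most one the more
severe (numerically lower) scale is taken — the severity preference is a
package decision, with a rounded-mean mode available — and larger gaps go
to a simulated senior adjudicator, which defaults to zero-noise
thresholding of the true risk.  Scales 2–3 are collected but enter no
statistic, mirroring the exclusive mapping of the thresholds to scales 1
and 4.

The benchmark stratifies the decision points by adjudicated scale
(1 → high, 4 → low); the model-side tables stratify the *same* points by
impact basis.  Importance tables de-duplicate codes per record, rank by
importance descending with ties broken by code string, and include
zero rows for catalogue codes absent from the labelled records so every
code receives a rank.  Segmentation is restricted to the decision-point
record set (consistent with stratum totals far smaller than the cohort
when those totals are recovered from published ratios); this scope is an
inference and is flagged in the output metadata.  Rank comparisons use
top-k overlap and Kendall τ-b over the code union with absent codes ranked
last.  No hypothesis tests are performed on the rankings, and none are
added.

The stratum-total recovery utility inverts published two-decimal
percentage tables: the smallest integer total under which every printed
ratio is an integer count rounded to two decimals (unique once printed
counts are available).  Printed ratios are independently rounded, so
importance identities recomputed from them are asserted to within one unit
in the last printed digit.

## The confounding fixture

`uti_confounder` plants the phenomenon the validation protocol exists to
detect.  Urinary tract infection has zero direct mortality effect,
prevalence 0.20, a boost fixing P(pneumonia | UTI) = 23.36%, and
crowding-out multipliers (0.15) on the four other lethal diagnoses;
lethal effects are +2.9 on baseline −3.5, so a record with a single lethal
code has true risk ≈ 0.35 — *above* the 0.25 impact threshold but *below*
the 0.5 scale-1 cut.  The displacement is therefore structural rather than
an artifact of under-trained weights: records whose only severe diagnosis
is a UTI-accompanying pneumonia are high-impact for the model but scale 2
for the annotators, while UTI-only records (risk ≈ baseline 0.03) fill the
annotators' scale-4 stratum and drive the benchmark importance of UTI
negative.  The margins (impact ≈ 0.33 vs 0.25; single-lethal risk 0.354 vs
0.5; baseline 0.029 vs 0.05) were chosen wide enough that training noise
and annotator noise do not flip the strata.

## Problem sizes

The shipped studies run on one CPU in seconds to low minutes: the
confounding study uses 4,000 patients (~23k records, ~9.4k decision
points), the planted-recovery study 5,000 patients, the calibration checks
3,000 patients (~80k diagnosis mentions), and the attribution property
sweep 1,000 seeded networks.  These sizes give Monte-Carlo errors well
inside every asserted margin.

## Known limitations

* The mortality model is additive in codes on the log-odds scale; no
  interactions, no latent severity, no history dependence.
* Annotator simulation shares the generator's risk model; real experts
  integrate information the model does not see, so real benchmark/model
  divergences can be larger and differently structured.
* The rescale rule's deviation from exact Shapley values on deep rectifier
  networks is measured but not bounded analytically here.
* The discrimination of the original pre-trained clinical model (AUROC
  0.711 per record / 0.808 after arrest) and the literal published table
  counts are **not** reproducible from this package: they derive from a
  restricted national claims database.  The synthetic property checks are
  stand-ins, not replications.
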