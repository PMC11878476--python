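# Methods

`memotrace` re-implements a clinical-NLP-plus-epidemiology workflow: it
extracts prodromal dementia information (memory-loss symptoms, family
caregiver relations, cognition-enhancing medications, dementia diagnosis
mentions) from free-text outpatient notes, combines it with coded EHR
data to phenotype a dementia cohort, and analyzes the trajectory from
first memory complaint to dementia diagnosis.  Because real outpatient
EHR data of this kind is protected health information, the package ships
a synthetic-EHR generator whose defaults encode the published cohort's
marginals and effects; every downstream module is validated against the
generator's planted ground truth.

## Ontology and annotation model

The annotation scheme has 9 entity types — memory-loss symptom (SX),
dementia diagnosis (DX), temporal anchor, duration, status change
(worsening), other symptom, cognitive test result, caregiver relation,
and cognition-enhancing medication (RX) — and 9 relation types that
attach satellite information to its trigger (`HAS_DURATION_INFO`,
`HAS_CAREGIVER_INFO`, `HAS_TREATMENT_INFO`, ...).  Annotations are stored
in the BRAT standoff dialect with 0-based half-open character offsets
over Unicode code points; parsing validates that every surface string
equals its text slice, and `parse ∘ write` is the identity (a property
tested over generated corpora).

The relation direction conventions: SX/DX are heads of everything except
`HAS_EFFECTS`, whose head is the medication.  The head/tail compatibility
map is configurable (YAML) since reasonable ontologies differ here.
Overlapping gold spans are resolved for tagging by keeping the longer
span — linear-chain taggers need disjoint spans and the longer mention
carries more content.  Entity spans that cut through a token are expanded
outward to token boundaries.

## Query expansion

A seed lexicon of memory-loss terms (`memory loss`, `confusion`,
`cognition impairment`, `trouble remembering`, `not recalling`,
`forgetting`, `blackout`) is expanded in two steps: collocation merging
with the count-based phrase score `(count(ab) − δ)·|V| /
(count(a)·count(b))` (defaults min_count 5, δ 5, threshold 10), then a
skip-gram word2vec model with negative sampling (d = 50, window 5, 5
negatives, 5 epochs, plain SGD with linear learning-rate decay,
deterministic under its seed) whose nearest neighbours of each seed
become expansion candidates.  Both components are implemented directly
in numpy.  Expansion is deliberately human-in-the-loop: candidates are
written to a CSV for curation and only accepted terms join the retrieval
query, mirroring how expert-curated query term lists are built in
practice.  Retrieval is case-insensitive, word-boundary-anchored
matching, with multi-word terms matching across single whitespace runs.

## Sequence tagger

Entity extraction uses a BiLSTM-CRF over BIO tags (19 tags: `O` plus
B/I per entity type).  Token representations concatenate a 64-d word
embedding (lowercased; learned UNK; a capitalization bit, since clinical
notes mix case heavily) and the final states of a 16-d character BiLSTM
(16 hidden units/direction).  A word-level BiLSTM (100 units/direction)
feeds a linear projection to per-tag emission scores; a linear-chain CRF
with learned transitions decodes jointly.  Transitions that would
violate BIO well-formedness are pinned at −10⁴, so decoded sequences can
never contain an illegal `I-` transition.  Viterbi ties break toward the
lowest tag index for determinism.

The network and its gradients are hand-written numpy (no deep-learning
framework is required at this scale); correctness is pinned by
finite-difference tests of every layer and of the full loss, and the
decoder and partition function are tested against brute-force
enumeration.  Training minimizes the CRF negative log-likelihood with
Adam (lr 1e-3, batch 16, dropout 0.5 on the encoder input and output,
gradient-norm clipping at 5), records exact-span validation micro-F1
each epoch, keeps the best parameters, and early-stops after 5 epochs
without improvement (≤ 30 epochs).  `train_until` reproduces the
iterative annotation loop: batches of annotated notes are added and the
model retrained until validation micro-F1 exceeds 0.8.

Small-corpus caveat: with fewer than ~100 documents the default
learning rate and patience can stop training before the loss starts
moving; the test fixtures use lr 5e-3 with patience disabled at that
scale.

## Relation linking

The relation extractor is rule-based: each satellite entity links to the
nearest compatible head in the same sentence within 20 tokens (nearest
by token distance; ties prefer SX heads, then the leftmost).  Sentence
splitting is rule-based on `. ! ?` followed by whitespace and a capital,
with a clinical-abbreviation exception list.  A learned linker is out of
scope: the generator's templates follow exactly this nearest-in-sentence
geometry, so with gold entities as input the rule reproduces every gold
relation (tested), and relation evaluation scores (label, head span+label,
tail span+label) triples for exact match.

Because SX and DX act only as heads, `HAS_EFFECTS` is emitted only with
a worsening mention as its tail (medication → status-change); effects on
the symptom itself are representable in the schema but not produced by
the linker.

## Normalization

Surface forms map to closed canonical vocabularies via editable CSV
lexicons (case-insensitive; hyphens fold to spaces): symptom concepts
(memory_loss, forgetfulness, short_term_memory_deficit, confusion,
cognitive_impairment), 13 family caregiver relations (with abbreviations
such as `dtr` → daughter), and the four cognition-enhancing generics with
their US brand names (Aricept → donepezil, Namenda → memantine, Exelon →
rivastigmine, Razadyne → galantamine).  Unknown surfaces return
`UNMAPPED` and are logged for lexicon growth, never raised.  For the
association analyses, caregiver relations group into five categories:
husband; wife; daughter; other adult children (son, son-/daughter-in-law,
grandchildren); other family support (nephew, niece, cousin, siblings).
Cognitive-test names are normalized for entity support but excluded from
the trajectory analysis — their prevalence in notes is too low to be
analytically useful.

## Phenotyping

Cohort membership requires, in order: (1) a dementia diagnosis — a
phenotyping ICD code (prefix-matched against a configurable ICD-9/10
set: F00–F03, F05.1, G30, G31.0, G31.83, 290, 294.1, 331.0) on at least
3 *distinct dates* (guarding against duplicate-coding artifacts) plus a
DX mention in at least one note; (2) at least one outpatient visit in
every calendar year from first visit through the diagnosis year; (3) at
least one visit strictly before the diagnosis date; (4) a memory-loss
symptom note on or before the diagnosis date.  The diagnosis index date
is the earlier of the first qualifying code date and the first DX-note
date; the complaint index date is the earliest note whose SX mention
normalizes to a memory-loss concept.  Patients whose complaint and
diagnosis fall on the same day stay in the included set but are flagged
out of the analysis set.  Attrition is attributed to the first failing
criterion; the final included set is order-independent.

## Trajectory analysis

Each analysis patient yields one record: interval in whole days,
complaint count (distinct pre-diagnosis note dates, not mention counts —
repeated mentions within one visit are one complaint event), a
prior-medication flag (any normalized cognition-enhancing order strictly
before the diagnosis date), the departments of the first complaint and
of the diagnosis event, age group at diagnosis (<65, 65–74, 75–84, 85+),
insurance, and caregiver group (missing for roughly half of patients, an
expected state).

Descriptives use the median and Tukey inclusive-hinge quartiles.  The
interval model is OLS on untransformed days (the additive day scale is
what the estimates mean clinically; a log-outcome option exists behind a
flag) with treatment coding and reference levels 85+, commercial
insurance, primary care (both locations), and husband; per-coefficient
Wald chi-square tests give the p-values.  Standard errors are HC1-robust
because the interval spread grows with the cell mean.  The medication
model is a logistic regression of the prior-medication flag on age
group, both locations, caregiver group and the complaint count, reported
as odds ratios with 95% CIs.  Both models drop records without caregiver
information (complete-case in that factor) and report the n used; single
near-empty factor cells can be single-class, so the logistic fit uses
L-BFGS and falls back to a lightly ridge-penalized Newton fit (α = 1,
intercept unpenalized, Wald CIs from the penalized Hessian) if estimates
blow up; a single-class outcome is an error.

## Synthetic EHR generator

The generator is first-class, tested code, not a fixture.  Each patient
draws demographics, insurance, complaint/diagnosis departments and
caregiver group from configurable categorical marginals whose defaults
are the published cohort proportions (e.g. geriatrics 53% of first
complaints and 60.2% of diagnoses; caregiver missing 49.9%; 85+ 54.2%).
Planted outcome models:

* **Interval**: cell mean = baseline + additive department/caregiver
  shifts (defaults: geriatrics complaint −141 d, neurology complaint
  −158 d, geriatrics diagnosis −152.9 d, wife −249.6 d, daughter
  −176.8 d, ...), multiplied by mean-one log-normal noise (σ = 0.8,
  matching a 200–675 IQR around a 342-day median) and floored at 1 day.
  Mean-one multiplicative noise keeps the cell mean equal to
  baseline + shift, so OLS recovers the planted shifts without
  attenuation and the 1-day floor is hit with negligible probability;
  the baseline is calibrated by bisection so the marginal median equals
  the configured 342 days.
* **Complaint count**: negative binomial (r = 2, mean 3.6) truncated to
  1–18, giving a median of 3; the count is capped by the interval since
  complaint dates are distinct pre-diagnosis days.
* **Medication**: logit P(prior med) = intercept + ln(1.148)·count, the
  intercept calibrated against the count distribution so the marginal
  rate is 25.1%.
* **Same-day fraction**: 20.4% of regular patients get interval 0.

Both calibrations are deterministic (bisection on closed-form mixture
CDFs) and run before any sampling.  Four excluded-by-design patients
(one per cohort criterion) are always present for attrition testing;
same-day patients carry earlier routine visits so they fail no visit
criterion.

Notes are rendered from ~25 sentence templates across complaint,
caregiver, medication, diagnosis and distractor families, with surface
forms drawn from the normalization lexicons — abbreviation and
brand-name knobs control how often `dtr` or `Aricept` appear — and gold
offsets exact by construction.  Relations follow the nearest-in-sentence
geometry the linker assumes.  What the generator does **not** emulate:
misspellings, negation ("denies memory loss"), hedging, family-history
mentions, section structure, co-reference, or any joint dependence of
interval on location/caregiver beyond additive effects.  Passing tests
therefore demonstrate pipeline correctness and statistical recovery
under the planted model, not clinical-grade NER robustness on real
notes, where template-trained models would not transfer.

## Evaluation

Span-level precision TP/(TP+FP), recall TP/(TP+FN) and F1 (harmonic
mean), per label and micro-averaged, with zero denominators scored 0 so
sparse labels aggregate stably.  Matching is greedy 1:1 left-to-right;
exact span+label match is the default criterion, with an overlap mode
for diagnostics.  Greedy matching is provably optimal under exact
matching and is tested against exhaustive assignment on small documents.

## Problem sizes and numerical choices

Test-suite and reproduction runs are desk-scale by design: the tagger
trains on 100–400 template notes (validation micro-F1 > 0.8 is reached
within two 100-note rounds), parameter-recovery uses 20,000-patient
cohorts (20 seeded replicates for CI-coverage, asserted as aggregate
coverage ≥ 90% across replicate × coefficient pairs), and the end-to-end
median check uses 5,000 patients.  All randomness flows through explicit
`numpy` Generators seeded from configs; pipeline stages derive their
seeds from the run seed by hashing the stage name.  CRF computations are
log-domain with log-sum-exp; −10⁴ stands in for −∞ so arithmetic never
produces NaN.

## Known limitations

* The expanded query term list and per-type evaluation breakdowns of the
  original study are not public; defaults ship seeds only, and only the
  overall metric triple is checked.
* The dementia ICD code set is a documented stand-in for the study's
  non-public appendix; sites should review it.
* The rule-based linker cannot represent cross-sentence or
  medication→symptom effect relations.
* Template-generated text gives near-ceiling NER scores; they say
  nothing about performance on real clinical prose.
* The interval model assumes additive effects on days; real intervals
  are skewed and bounded, and the robust-SE linear model is a pragmatic
  mirror of the published analysis, not a survival model.
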