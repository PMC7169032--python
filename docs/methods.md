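# Methods

## Model

A person's coded clinical history is treated as four bags of opaque
codes, one per entity (diagnosis, procedure, prescription, laboratory
test). The recruitment-prediction model is nearest-profile matching: a
*target profile* summarises the training participants of one study
project, and every candidate is scored by similarity to it. The model
assumes that recruited participants share characteristic codes at high
within-cohort frequency, that code occurrence counts (not dates, lab
values or dispensed quantities) carry the signal, and that a linear
combination of the four per-entity similarities is a sufficient ranking
statistic. No code semantics are used: ICD-10/OPCS-4/BNF/read codes are
uninterpreted strings, with no hierarchy rollups and no free text.

### Featured-code selection

Per entity, the support of a code is the fraction of training
participants carrying it at least once (multiplicity ignored at this
stage). Codes with support ≥ `support_threshold` (default 0.8) are
featured. Three branches, recorded in `selection_meta`:

- `threshold_met`: at least `min_codes` (default 10) codes pass — all
  passing codes are kept;
- `topped_up`: some pass but fewer than `min_codes` — the list is
  extended to `min_codes` with the highest-support codes overall. This is
  the reading of the "minimum of 10 codes" rule consistent with both the
  more-than-10 and the none-at-80% branches; `top_up=False` instead
  returns only the passing codes, for sensitivity analysis;
- `all_retained`: no code passes — every observed code is kept (sparse
  data fallback).

Ties in support break lexicographically by code string, making selection
deterministic across runs and platforms.

### Profile weights and similarity

The weight of a featured code is the central tendency of its occurrence
count across training participants — `mean` by default, `median`
available since either is a defensible central tendency; `binary=True`
replaces counts by presence indicators (relevant mainly for repeat
prescriptions, where multiplicity may be an artefact of repeat
dispensing rather than clinical emphasis). With one training participant
the profile is that person's count vector.

Per-entity similarity is the cosine between a person's count vector over
the featured codes and the weight vector; both are nonnegative, so it
lies in [0, 1]. A zero vector on either side yields 0 by convention —
persons carrying no featured codes are maximally dissimilar and sink in
the ranking.

### Combining entities

The four similarities are combined by OLS of the 0/1 recruitment label
on (s_diag, s_proc, s_presc, s_lab) with intercept. Linear regression is
used deliberately (not logistic); coefficients are unconstrained; a
rank-deficient design (e.g. a constant entity score) takes the
minimum-norm solution. Four weights cannot be identified from positives
alone, so the training design is the training-fold participants (label
1) plus `n_negatives` (default 500) registrants sampled, seeded, from
outside that fold's test set — preventing any train/test leakage, which
is additionally asserted on every fold. The fitted score is min–max
scaled to [0, 1] within each test set; the map is rank-preserving, so
AUC and all ranking metrics are unaffected by this choice, and constant
raw scores scale to 0.5.

## Cross-validation and test-set assembly

Each project runs two-fold: participants are halved by a seeded random
split (sizes differ by at most one). A fold's test set is the union of
the held-out participants, `n_random` (default 30,000) registrants drawn
without replacement from the eligible pool, and every database-identified
person not recruited, de-duplicated. The random draw uses an
independently derived seed per fold; whether the original workflow
shared one draw across folds is unknowable, and per-fold draws make fold
evaluations closer to independent. Sub-seeds for every stochastic stage
(split, pool draw, negatives, tie-breaks, bootstrap, Lower reference)
derive deterministically from the master seed via CRC32 of stage labels,
so a run is reproducible end to end and reports are byte-identical
across reruns.

## Evaluation

- **ROC AUC** in Mann–Whitney form (ties count ½), identical to the
  trapezoidal area; quality bands at 0.9/0.8/0.7/0.6/0.5
  (excellent/good/fair/poor/fail, below 0.5 worse than random).
- **Bootstrap CI**: percentile interval from 2000 stratified replicates
  (positives and negatives resampled separately); non-stratified is a
  config option. With fewer than 2 members in either stratum the
  interval is reported as NA (NaN) rather than raised — the degenerate
  two-participant geometry reaches exactly this state.
- **Cut-off sweep**: thresholds 0 to 1 in `grid_step` = 0.01;
  the metric is (sensitivity + specificity)/2, a positive affine scaling
  of their sum chosen so the curve lives in [0, 1]; the smallest
  maximizing threshold is reported for reproducibility.
- **Ranking metrics**: P@5, P@10, average precision, reciprocal rank on
  the list sorted by descending scaled score; equal scores are ordered
  by a seeded random shuffle before the stable sort (deterministic yet
  unbiased). **Upper** references are the closed forms of the ideal list
  (P@k = min(r, k)/k, MAP = MRR = 1); **Lower** is one seeded uniformly
  random list by default (`n_random_refs` averages several).
- **Top-50 overlap**: fraction of the top 50 flagged as
  database-identified, comparing the ranking against the query strategy.

## Synthetic cohorts

The generator emulates what the analysis assumes about registry EHR
extracts: sparse heavy-tailed code usage (Zipf draw over each entity's
vocabulary, exponent 1.2, vocabulary 500 codes per entity), 8 background
events per person per entity on average with at least one guaranteed by
construction (so every person passes the strict inclusion filter — the
filter itself is tested on hand-built records), cohort structure via 10
per-entity signature codes carried with probability 0.9 by participants
and 0.02 by others, and a database-identified set drawn independently of
any similarity (sensitivity 0.7 among participants plus 100
non-participant false positives) so the top-50 overlap is non-trivial.
Signature codes sit outside the background vocabulary, so carriage
probabilities are governed exactly by the two parameters. The null
generator sets penetrance equal to background carriage, making labels
independent of all codes. Not emulated: calendar structure, visit
patterns, code co-occurrence/comorbidity correlation, realistic code
strings, lab values and prescription quantities. Passing tests therefore
demonstrate correct mechanics and statistical behavior of the pipeline,
not performance on real clinical data, where code correlations and
incompleteness can only degrade the separation seen here.

## Problem sizes and numerical choices

The test suite and the acceptance script scale the study geometry down
so the whole analysis is desk-sized: nine projects of 28…2 participants
(119 total) against 2,600-registrant pools with 2,000 drawn per test
fold, 300 regression negatives, and 100–500 bootstrap replicates where
the interval itself is not under study. Monte-Carlo properties use 20
seeds (10 in the acceptance script). Under the null, the fold-averaged
AUC has standard deviation ≈ √((n₁+n₂+1)/(12·n₁·n₂))/√2 ≈ 0.065 at 10
positives per fold, so individual seeds can land outside [0.4, 0.6]
even for a perfectly calibrated pipeline; the calibration checks are
therefore statements about rates over seeds, and their achievable
coverage is bounded by this dispersion.

## Known limitations

- OLS on a 0/1 label is a deliberate design choice but not a calibrated
  probability model; only the ranking is meaningful.
- The profile ignores event timing; eligibility windows must be applied
  upstream.
- Support-based selection treats codes independently; correlated code
  families are over-weighted relative to their information content.
- With two participants the single-person profile makes results highly
  seed-dependent, and the bootstrap CI is undefined — reported as NA by
  design.
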