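# Methods

`textpheno` implements a digital-phenotyping workflow for free-text therapy
messages exchanged on an asynchronous tele-mental-health platform. The goal
is to characterise how a population-level event (a pandemic onset) shows up
in what patients write to their therapists and in their structured intake
assessments, and to surface symptom themes that standard anxiety/depression
instruments miss. Because real platform corpora are proprietary, the package
ships a synthetic-corpus generator with planted ground truth; every analysis
stage is validated by recovering that ground truth.

## Pipeline stages

### 1. Seed-keyword screening

A message *mentions* the pandemic iff one of a small set of literal seed
patterns — `corona`, `virus`, `covid`, `pandemic` by default — occurs as a
case-insensitive substring of its text. Plain substring matching (not
word-boundary-anchored) is a deliberate choice: it makes "coronavirus" hit
both `corona` and `virus`, which is the behaviour that makes pre-onset
incidence of `virus` nonzero in real corpora. A `word_boundary` flag is
available for stricter matching.

From the flags the package derives:

* a **monthly incidence table** — per (year, month), the percentage of that
  month's messages containing each pattern, reported to 4 decimals; months
  with no messages are absent, not zero;
* the **transcript mention rate** — a transcript (all messages between one
  patient and one provider; exactly one per patient) counts as mentioning if
  any of its messages is flagged; the headline rate is rounded
  half-away-from-zero to 1 decimal;
* the **daily mention signal** — per calendar day, the proportion of that
  day's messages flagged. Days with zero messages are *missing*, never zero:
  imputing zeros would manufacture correlation in the trajectory screen.

### 2. Intake score trends

GAD-7 (7 items) and PHQ-9 (9 items) are scored as the sum of 0–3 item
responses (totals 0–21 and 0–27). Incomplete or out-of-range questionnaires
are excluded, not imputed.

The **rolling series** is a trailing 14-day pooled mean: for each day `d`,
the mean over all intake totals in `(d − 14, d]`, every intake weighted
equally. Pooling (rather than averaging daily means) stabilises low-volume
days. Trailing rather than centered is a convention; both windows see the
same data.

The **shift estimate** compares intakes in a comparison window against a
baseline window (both explicit, inclusive date ranges; they must be
disjoint):

* point estimate Δ = mean(comparison totals) − mean(baseline totals);
* 95% CI by percentile bootstrap over patients, default 10,000 resamples,
  seeded (each intake is one patient, so resampling intakes = resampling
  patients);
* p-value from Welch's unequal-variance two-sample t test.

A mean difference with CI does not identify a unique inferential procedure;
the bootstrap/Welch pair is this package's documented default.

### 3. Term-trajectory screening

All messages of a calendar day are pooled into one "text day" document.
Documents are tokenised to lowercase alphanumeric runs; unigrams and bigrams
(`n_max = 2`, configurable) form the vocabulary; terms occurring on fewer
than `min_df = 3` distinct days are dropped (Pearson correlation on fewer
support points is meaningless).

Counts are TF-IDF weighted with the smoothed logarithmic idf

    w(d, t) = count(d, t) × (1 + ln((1 + N) / (1 + df(t))))

where `N` is the number of text days and `df(t)` the number of days on
which `t` occurs. No per-day (row) normalisation is applied: trajectories
stay on a count-proportional scale, a day's weights scale linearly with its
counts, and the sparsity pattern is exactly preserved. The transform is
computed by scikit-learn's `TfidfTransformer(norm=None, smooth_idf=True)`,
which implements this exact formula; tests pin it against the closed form.

Each term's trajectory is Pearson-correlated with the daily mention signal
over the intersection of their day axes (≥ 3 paired days required); the
two-sided p-value comes from the exact t transform of r with n − 2 degrees
of freedom. Zero-variance trajectories (or a zero-variance signal) are
skipped with a warning — r is undefined there.

Selection is Benjamini–Hochberg step-up at FDR level `q = 0.01` over all
tested terms (statsmodels' `fdr_bh`, pinned in tests against an exhaustive
step-up enumeration), with survivors partitioned by the sign of r.
"False discovery rate threshold" names a criterion, not a procedure; BH is
the canonical choice and can be swapped for Benjamini–Yekutieli by editing
one call.

### 4. Topic categorization

Selected terms are assigned to at most one of eleven topical categories
(confusion/negative emotions, health/medical emergencies, work/business/
economic, technology/internet, cleaning/hygiene, government/leadership,
traveling/shopping, party/celebration, positive emotion/love,
friends/children, optimism) by a transparent cue-word lexicon shipped as
editable JSON. A category's score for a term is the number of its cues that
prefix-match any token of the term (cue `lone` matches `lonely`,
`loneliness`); the max-scoring category wins, ties break to the
lexicographically first name, score zero means *unassigned*. An
embedding-derived categorizer with the same single-category contract can be
swapped in behind the `CategoryAssigner` interface. Breakdown percentages
are over the full input (assigned + unassigned), rounded half-away-from-zero
to integers.

### 5. ICD-10 symptom mapping

Selected terms are compared against a packaged dictionary of ICD-10 symptom
descriptors (F43.0 acute stress, F43.1 PTSD, F22 paranoia, Z63.4 grief,
G47.00 insomnia, F41.0 panic, F40.00 agoraphobia, Z91.5 nonsuicidal
self-injury, F42.9 obsession-compulsion, F45.21 hypochondriasis, F41.9
anxiety, plus a pandemic-specific bucket). A term supports a code iff one of
its tokens stem-matches a content token of any descriptor phrase (exact
equality, or a shared prefix of ≥ 4 characters; descriptor function words
are excluded to prevent vacuous matches). Multi-code support is allowed —
acute stress and PTSD share phenomenology by design. Terms supporting no
code are returned for human inspection; the package does not diagnose.

## The synthetic generator

`GeneratorConfig` defaults define the study conditions used throughout the
tests and the acceptance script:

| parameter | default | meaning |
|---|---|---|
| `n_patients` | 200 | cohort size; one transcript each |
| `start/changepoint/end` | 2019-12-01 / 2020-03-15 / 2020-06-09 | study span and onset |
| `episode_days` | 90 | active messaging span per patient after enrollment |
| `messages_per_patient_day` | 0.6 | Poisson rate while active |
| `words_per_message` | 25 | Poisson mean (min 1 token) |
| `vocab_sizes` | (10, 30, 110) | covid-associated / anti-associated / neutral strata |
| `mention_prob_pre/post` | 0.0 / 0.6 | message-level mention probability, linear ramp |
| `ramp_days` | 14 | calendar days to reach the post level |
| `assoc_boost`, `anti_suppress` | 8.0, 0.125 | stratum reweighting in mention-mode messages |
| `gad7_baseline_mean`, `gad7_shift` | 1.43, 0.2 | item-level mean and post-onset shift |
| `phq9_baseline_mean`, `phq9_shift` | 1.2, 0.0 | depression intakes do not shift |

Design choices that matter:

* **Enrollment and episodes.** Patients enroll uniformly over the study span
  and message for a fixed episode. With a span comfortably longer than the
  episode, the number of active patients — hence daily token volume — is
  stationary inside the analysis window. This is essential: TF-IDF rows are
  not normalised, so a secular volume trend would correlate *every* term's
  raw trajectory with the (also trending) mention signal and neutral terms
  would stop being neutral.
* **Neutrality is exact.** In mention-mode messages the boost/suppress
  factors reallocate probability mass *between* the associated and
  anti-associated strata only; the neutral stratum's expected share is
  identical in both modes. Renormalising all three strata would make neutral
  usage shrink whenever associated usage is boosted, i.e. plant a negative
  correlation in the stratum that is supposed to carry none. A consequence:
  the effective per-term usage multiplier of the associated stratum is capped
  at `(n_assoc + n_anti)/n_assoc`, which is why the default strata are
  asymmetric (10 vs 30): that yields a ~3.8× mention-mode multiplier and
  per-term correlations around 0.7 on ~100 analysis days — recoverable with a
  wide margin at FDR 0.01 among ~20,000 tested n-grams.
* **Seed injection.** Every mention-mode message carries exactly one
  uniformly chosen literal seed keyword, so the keyword screen's ground truth
  is exact by construction.
* **Assessments.** Item responses are Binomial(3, mean/3), so the expected
  total is `n_items × item_mean` and the planted total-score shift is
  `7 × gad7_shift = 1.4` by default. Intakes are dated at the patient's first
  message (the enrollment date); enrollment, corpus and assessment draws use
  separate RNG streams spawned from the master seed, so enlarging the corpus
  never perturbs assessment draws.

What the generator does **not** emulate: real language (messages are
bags of synthetic tokens — the analysis consumes counts only), therapist
messages, assessment dropout, weekday/holiday seasonality, or heavy-tailed
message-length distributions. Passing recovery tests therefore demonstrates
the statistical machinery is correct under the planted model, not that the
lexicons or the screen are clinically validated on real text.

## Problem sizes and numerics

* Recovery checks run the full pipeline on the default corpus (~9,000
  messages, ~100 analysis days) over 20 seeds; shift-recovery uses 100
  replicates of 4,000 patients with 2,000 bootstrap resamples per replicate.
  The acceptance script uses 5 corpus seeds and one 4,000-patient assessment
  replicate with 10,000 resamples.
* Percentile-bootstrap CIs use `numpy.random.Generator` with seeds derived
  from the master seed via `SeedSequence`; identical config + seed gives
  byte-identical pipeline reports.
* Correlation p-values clip |r| to 1 before the t transform; |r| = 1 maps to
  p = 0. BH handles p ties by the standard step-up rule (everything at or
  below the largest passing rank is selected).
* Degenerate inputs: empty cohorts yield empty corpora (not errors); an
  all-skipped correlation table yields an empty selection and empty
  breakdowns; a zero-transcript corpus makes the mention rate an error
  rather than a number.

## Known limitations

* Substring matching over-counts (e.g. `antivirus software` is flagged); the
  word-boundary flag trades recall for precision.
* The category and symptom lexicons are small, transparent seed lexicons
  meant to be edited; their coverage of real vocabularies is narrow.
* The shift estimator is a two-window mean comparison; it does not model
  within-patient trajectories, seasonality, or case-mix changes between
  windows.
* Global pooling of all patients into one text day per calendar day is a
  convention; per-patient day vectors would weight prolific patients
  differently.
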