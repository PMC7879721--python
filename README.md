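# textpheno

Digital phenotyping of therapy-transcript text messages. The package is
aimed at computational researchers working with tele-mental-health message
corpora who want to (i) quantify how a population-level event — a pandemic
onset — surfaces in what patients write to their therapists, and (ii)
discover symptom themes associated with that event which the standard
anxiety/depression instruments (GAD-7, PHQ-9) do not ask about.

Because platform corpora are proprietary, the package includes a
synthetic-corpus generator that plants the structure the analysis assumes
(a mention-probability changepoint, vocabulary strata that track or
anti-track mentions, an intake-score shift), so every stage can be validated
by ground-truth recovery.

## What it computes

1. **Keyword screen.** A message mentions the event iff a literal seed
   pattern (`corona`, `virus`, `covid`, `pandemic`) occurs as a
   case-insensitive substring. Outputs: monthly incidence percentages, the
   per-transcript mention rate, and the daily mention-proportion signal
   `y_d` = (flagged messages on day *d*) / (messages on day *d*).
2. **Intake score trends.** GAD-7/PHQ-9 totals (sum of 0–3 items), a
   trailing 14-day pooled rolling mean, and the shift estimate
   Δ = x̄_comparison − x̄_baseline with a percentile-bootstrap 95% CI over
   patients and a Welch two-sample p-value.
3. **Term-trajectory screen.** Each calendar day's pooled text is one
   document; unigram/bigram counts `c(d,t)` are weighted by smoothed log idf,
   `w(d,t) = c(d,t) · (1 + ln((1+N)/(1+df_t)))`, each term's trajectory
   `w(·,t)` is Pearson-correlated with `y`, and terms passing
   Benjamini–Hochberg at FDR `q = 0.01` are selected, split by sign(r).
4. **Topic categorization.** Each selected term goes to at most one of
   eleven topical categories via a transparent cue-word lexicon
   (prefix-stem matching; editable JSON), with integer percentage
   breakdowns.
5. **ICD-10 symptom mapping.** Selected terms are matched against packaged
   ICD-10 symptom descriptors (acute stress F43.0, PTSD F43.1, paranoia F22,
   grief Z63.4, insomnia G47.00, panic F41.0, agoraphobia F40.00,
   self-injury Z91.5, obsession-compulsion F42.9, hypochondriasis F45.21,
   anxiety F41.9); unmatched terms are listed for human review.

See `docs/methods.md` for the model, parameter defaults, and limitations.

## Worked example

```python
import datetime as dt
import textpheno as tp

cfg = tp.GeneratorConfig(seed=7)           # defaults: 200 patients, onset 2020-03-15
messages, truth = tp.simulate_corpus(cfg)
assessments = tp.simulate_assessments(cfg)

flags = tp.flag_messages(messages)
n_m, n_t, pct = tp.transcript_mention_rate(messages, flags)
print(f"transcripts mentioning the pandemic: {n_m}/{n_t} ({pct}%)")

window = (dt.date(2020, 3, 1), dt.date(2020, 6, 9))
signal = tp.daily_mention_proportion(messages, flags, window=window)
screen = tp.TrajectoryScreen(window=window, q=0.01).fit(messages, signal)
sel = screen.selection_
print(f"terms tested: {sel.n_tested}, positive: {len(sel.positive_terms)}, "
      f"negative: {len(sel.negative_terms)} at q={sel.q_threshold}")
pos = set(sel.positive_terms["term"])
print(f"planted covid-associated terms recovered: "
      f"{len(pos & truth.covid_assoc_terms)}/{len(truth.covid_assoc_terms)}")

shift = tp.estimate_shift(
    assessments, "GAD7",
    baseline_window=(cfg.start_date, dt.date(2020, 3, 14)),
    comparison_window=(dt.date(2020, 3, 15), cfg.end_date),
    n_boot=10_000, seed=7,
)
print(f"GAD-7 intake shift: {shift.delta:+.2f} "
      f"(95% CI {shift.ci_low:.2f} to {shift.ci_high:.2f}; P={shift.p_value:.2e})")
```

prints

```
transcripts mentioning the pandemic: 174/200 (87.0%)
terms tested: 19990, positive: 14, negative: 37 at q=0.01
planted covid-associated terms recovered: 10/10
GAD-7 intake shift: +1.53 (95% CI 0.86 to 2.19; P=1.07e-05)
```

87% of synthetic transcripts mention the event (the generator's
post-onset mention probability is high and episodes straddle the onset);
all 10 planted covid-associated terms are recovered in the positive
partition out of ~20,000 tested n-grams, and the estimated intake shift
+1.53 covers the planted total-score shift of 1.4 (7 items × 0.2).

The same run is available end-to-end as a pipeline:

```python
report = tp.run_pipeline(tp.PipelineConfig(simulate=cfg, out_dir="run", seed=7))
```

or from the shell: `textpheno run --config config.yaml`, with per-stage
subcommands `simulate`, `screen`, `trends`, `screen-terms`, `categorize`,
`icd10` operating on the intermediate files.

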