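"""Synthetic therapy-message corpus and intake-assessment generator.

The generator produces the statistical structure the downstream analysis
assumes, together with the planted ground truth needed to score recovery:

* a message corpus whose per-day proportion of pandemic-mentioning messages
  is ``mention_prob_pre`` before a changepoint date and ramps linearly to
  ``mention_prob_post`` over ``ramp_days`` calendar days;
* three disjoint vocabulary strata — terms whose usage positively tracks the
  mention signal (boosted in mention-mode messages), terms whose usage is
  suppressed in mention-mode messages, and neutral filler whose expected
  share is identical in both modes;
* per-patient GAD-7 and PHQ-9 intake assessments dated at the patient's
  first message, with a configurable post-changepoint mean shift.

Messages are bag-of-words: the analysis consumes counts only, so no grammar
is modelled.  Every mention-mode message carries exactly one literal seed
keyword ("corona", "virus", "covid" or "pandemic"), which makes the keyword
screen's ground truth exact.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

SEED_KEYWORDS = ("corona", "virus", "covid", "pandemic")

MESSAGE_COLUMNS = ["message_id", "transcript_id", "patient_id", "timestamp", "text"]
ASSESSMENT_COLUMNS = ["patient_id", "instrument"] + [f"item_{i}" for i in range(1, 10)] + ["date"]


class GeneratorConfig(BaseModel):
    """Parameters of the synthetic corpus / assessment generator.

    Defaults emulate a mid-sized tele-therapy cohort observed across a
    pandemic onset: ~200 patients enrolling uniformly over the study period,
    each active for a ~90-day treatment episode, with the mention probability
    ramping from 0 to 0.6 over two weeks after the changepoint and a planted
    GAD-7 intake shift of 0.2 points per item (1.4 total-score points) and no
    PHQ-9 shift.
    """

    n_patients: int = Field(default=200, ge=0)
    start_date: dt.date = dt.date(2019, 12, 1)
    changepoint_date: dt.date = dt.date(2020, 3, 15)
    end_date: dt.date = dt.date(2020, 6, 9)
    episode_days: int = Field(default=90, ge=1)
    messages_per_patient_day: float = Field(default=0.6, ge=0.0)
    words_per_message: float = Field(default=25.0, gt=0.0)
    vocab_sizes: tuple[int, int, int] = (10, 30, 110)
    mention_prob_pre: float = Field(default=0.0, ge=0.0, le=1.0)
    mention_prob_post: float = Field(default=0.6, ge=0.0, le=1.0)
    ramp_days: int = Field(default=14, ge=0)
    assoc_boost: float = Field(default=8.0, gt=1.0)
    anti_suppress: float = Field(default=0.125, ge=0.0, lt=1.0)
    gad7_baseline_mean: float = Field(default=1.43, ge=0.0, le=3.0)
    gad7_shift: float = 0.2
    phq9_baseline_mean: float = Field(default=1.2, ge=0.0, le=3.0)
    phq9_shift: float = 0.0
    seed: int = 0

    @model_validator(mode="after")
    def _check_dates_and_probs(self) -> "GeneratorConfig":
        if not self.start_date < self.end_date:
            raise ValueError("start_date must precede end_date")
        if self.changepoint_date <= self.start_date:
            raise ValueError("changepoint_date must follow start_date")
        if self.mention_prob_pre > self.mention_prob_post:
            raise ValueError("mention_prob_pre must not exceed mention_prob_post")
        if any(s < 0 for s in self.vocab_sizes) or sum(self.vocab_sizes) == 0:
            raise ValueError("vocab_sizes must be nonnegative with at least one term")
        return self


@dataclass
class GroundTruth:
    """Planted structure of one simulated corpus, for recovery scoring."""

    covid_assoc_terms: frozenset
    anti_assoc_terms: frozenset
    neutral_terms: frozenset
    planted_gad7_shift: float  # total-score scale (7 x item shift)
    planted_phq9_shift: float  # total-score scale (9 x item shift)
    per_message_mention_flag: list = field(default_factory=list)

    def __post_init__(self):
        sets = [self.covid_assoc_terms, self.anti_assoc_terms, self.neutral_terms]
        total = sum(len(s) for s in sets)
        if len(frozenset().union(*sets)) != total:
            raise ValueError("vocabulary strata must be pairwise disjoint")


def _rngs(config: GeneratorConfig) -> dict[str, np.random.Generator]:
    """One RNG stream per logical component, all derived from the master seed.

    Enrollment gets its own stream so corpus and assessment generation agree
    on each patient's first-activity date, and adding messages never perturbs
    assessment draws.
    """
    children = np.random.SeedSequence(config.seed).spawn(3)
    return {
        "enroll": np.random.default_rng(children[0]),
        "corpus": np.random.default_rng(children[1]),
        "assess": np.random.default_rng(children[2]),
    }


def _vocabulary(config: GeneratorConfig) -> tuple[list, list, list]:
    n_a, n_x, n_n = config.vocab_sizes
    assoc = [f"assocterm{i:03d}" for i in range(n_a)]
    anti = [f"antiterm{i:03d}" for i in range(n_x)]
    neutral = [f"fillerterm{i:03d}" for i in range(n_n)]
    return assoc, anti, neutral


def _enrollment_dates(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Uniform enrollment day offset per patient over the whole study span."""
    n_days = (config.end_date - config.start_date).days + 1
    return rng.integers(0, n_days, size=config.n_patients)


def mention_probability(config: GeneratorConfig, day: dt.date) -> float:
    """Expected probability that a message sent on ``day`` is mention-mode.

    Constant at ``mention_prob_pre`` before the changepoint, then a linear
    ramp reaching ``mention_prob_post`` after ``ramp_days`` calendar days
    (immediately, when ``ramp_days`` is 0).
    """
    t = (day - config.changepoint_date).days
    if t < 0:
        return config.mention_prob_pre
    if config.ramp_days == 0 or t + 1 >= config.ramp_days:
        return config.mention_prob_post
    frac = (t + 1) / config.ramp_days
    return config.mention_prob_pre + frac * (config.mention_prob_post - config.mention_prob_pre)


def _token_probs(config: GeneratorConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-token sampling probabilities for plain and mention-mode messages.

    Base draw is uniform over the whole vocabulary.  In mention mode the
    probability mass of the associated and anti-associated strata is
    reweighted by ``assoc_boost`` / ``anti_suppress`` and renormalised
    *within those two strata only*, so the neutral stratum's expected share
    is exactly unchanged — "neutral" terms are independent of the mention
    signal by construction.
    """
    n_a, n_x, n_n = config.vocab_sizes
    total = n_a + n_x + n_n
    base = np.full(total, 1.0 / total)
    mention = base.copy()
    signal_mass = (n_a + n_x) / total
    if signal_mass > 0:
        raw_a = (n_a / total) * config.assoc_boost
        raw_x = (n_x / total) * config.anti_suppress
        scale = signal_mass / (raw_a + raw_x) if (raw_a + raw_x) > 0 else 0.0
        if n_a:
            mention[:n_a] = raw_a * scale / n_a
        if n_x:
            mention[n_a : n_a + n_x] = raw_x * scale / n_x
    return base, mention


def simulate_corpus(config: GeneratorConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a message corpus and its planted ground truth.

    Returns a DataFrame with columns ``message_id, transcript_id, patient_id,
    timestamp, text`` (one row per message, exactly one transcript per
    patient) and the :class:`GroundTruth`.  Identical config and seed give
    byte-identical output.
    """
    rngs = _rngs(config)
    assoc, anti, neutral = _vocabulary(config)
    vocab = np.array(assoc + anti + neutral)
    base_p, mention_p = _token_probs(config)
    base_cdf, mention_cdf = np.cumsum(base_p), np.cumsum(mention_p)
    enroll = _enrollment_dates(config, rngs["enroll"])
    rng = rngs["corpus"]
    n_days_total = (config.end_date - config.start_date).days + 1

    rows: list[tuple] = []
    flags: list[bool] = []
    msg_idx = 0
    for p in range(config.n_patients):
        first = int(enroll[p])
        last = min(first + config.episode_days - 1, n_days_total - 1)
        n_active = last - first + 1
        counts = rng.poisson(config.messages_per_patient_day, size=n_active)
        if config.messages_per_patient_day > 0 and counts[0] == 0:
            counts[0] = 1  # intake day always produces the first message
        for offset, n_msgs in zip(range(first, last + 1), counts):
            if n_msgs == 0:
                continue
            day = config.start_date + dt.timedelta(days=offset)
            p_mention = mention_probability(config, day)
            for _ in range(int(n_msgs)):
                is_mention = bool(rng.random() < p_mention)
                n_words = max(1, int(rng.poisson(config.words_per_message)))
                cdf = mention_cdf if is_mention else base_cdf
                tokens = list(vocab[np.searchsorted(cdf, rng.random(n_words))])
                if is_mention:
                    seed_word = SEED_KEYWORDS[int(rng.integers(len(SEED_KEYWORDS)))]
                    tokens.insert(int(rng.integers(len(tokens) + 1)), seed_word)
                ts = dt.datetime.combine(day, dt.time()) + dt.timedelta(
                    seconds=int(rng.integers(86400))
                )
                rows.append(
                    (
                        f"m{msg_idx:07d}",
                        f"t{p:05d}",
                        f"p{p:05d}",
                        ts.isoformat(),
                        " ".join(tokens),
                    )
                )
                flags.append(is_mention)
                msg_idx += 1

    messages = pd.DataFrame(rows, columns=MESSAGE_COLUMNS)
    truth = GroundTruth(
        covid_assoc_terms=frozenset(assoc),
        anti_assoc_terms=frozenset(anti),
        neutral_terms=frozenset(neutral),
        planted_gad7_shift=7 * config.gad7_shift,
        planted_phq9_shift=9 * config.phq9_shift,
        per_message_mention_flag=flags,
    )
    return messages, truth


def simulate_assessments(config: GeneratorConfig) -> pd.DataFrame:
    """Generate one GAD-7 and one PHQ-9 intake record per patient.

    Each record is dated at the patient's first message date (the enrollment
    date, shared with :func:`simulate_corpus` through a dedicated RNG
    stream).  Item responses are Binomial(3, mean/3) integers in 0-3, so the
    expected total score is ``n_items * item_mean``; the configured shift is
    added to the item mean for intakes on or after the changepoint date.
    """
    rngs = _rngs(config)
    enroll = _enrollment_dates(config, rngs["enroll"])
    rng = rngs["assess"]
    dates = [config.start_date + dt.timedelta(days=int(d)) for d in enroll]
    post = np.array([d >= config.changepoint_date for d in dates])

    rows = []
    for instrument, n_items, mean, shift in (
        ("GAD7", 7, config.gad7_baseline_mean, config.gad7_shift),
        ("PHQ9", 9, config.phq9_baseline_mean, config.phq9_shift),
    ):
        means = np.where(post, mean + shift, mean)
        probs = np.clip(means / 3.0, 0.0, 1.0)
        items = rng.binomial(3, probs[:, None], size=(config.n_patients, n_items))
        for p in range(config.n_patients):
            vals = list(items[p]) + [np.nan] * (9 - n_items)
            rows.append([f"p{p:05d}", instrument, *vals, dates[p].isoformat()])
    return pd.DataFrame(rows, columns=ASSESSMENT_COLUMNS)
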