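"""Seed-keyword screening of pandemic-mentioning messages.

Flags each message for a small set of literal seed patterns ("corona",
"virus", "covid", "pandemic" by default) and derives the three summaries the
rest of the analysis consumes: a monthly incidence table, the per-transcript
mention rate, and the daily mention-proportion signal.

Matching is case-insensitive plain-substring by default, so "corona" and
"virus" both hit "coronavirus"; an optional word-boundary mode anchors each
pattern at word boundaries instead.
"""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass, field

import pandas as pd
from sklearn.base import BaseEstimator

from ._util import as_date, round_half_away

DEFAULT_PATTERNS = ("corona", "virus", "covid", "pandemic")


@dataclass(frozen=True)
class SeedLexicon:
    """Ordered list of lowercase literal substring patterns."""

    patterns: tuple = field(default=DEFAULT_PATTERNS)

    def __post_init__(self):
        if not self.patterns:
            raise ValueError("seed lexicon must contain at least one pattern")
        for p in self.patterns:
            if not p or p != p.lower():
                raise ValueError(f"patterns must be nonempty lowercase strings: {p!r}")


class KeywordScreen(BaseEstimator):
    """Screen messages for seed-keyword mentions.

    Parameters
    ----------
    patterns : tuple of str
        Lowercase literal patterns; a message is flagged for a pattern iff it
        occurs as a case-insensitive substring of the text.
    word_boundary : bool
        Anchor patterns at word boundaries instead of plain substrings.

    After :meth:`flag`, per-message boolean flags are in ``flags_`` (one
    column per pattern plus ``any``, indexed by message_id).
    """

    def __init__(self, patterns: tuple = DEFAULT_PATTERNS, word_boundary: bool = False):
        self.patterns = patterns
        self.word_boundary = word_boundary

    def flag(self, messages: pd.DataFrame) -> pd.DataFrame:
        lexicon = SeedLexicon(tuple(self.patterns))
        texts = messages["text"].fillna("").str.lower()
        flags = pd.DataFrame(index=pd.Index(messages["message_id"], name="message_id"))
        for pat in lexicon.patterns:
            if self.word_boundary:
                hit = texts.str.contains(rf"\b{re.escape(pat)}\b", regex=True)
            else:
                hit = texts.str.contains(pat, regex=False)
            flags[pat] = hit.to_numpy()
        flags["any"] = flags[list(lexicon.patterns)].any(axis=1)
        self.flags_ = flags
        return flags


def flag_messages(messages: pd.DataFrame, lexicon: SeedLexicon | None = None,
                  word_boundary: bool = False) -> pd.DataFrame:
    """Per-message, per-pattern boolean flags plus an ``any`` column."""
    lexicon = lexicon or SeedLexicon()
    return KeywordScreen(lexicon.patterns, word_boundary).flag(messages)


def _month_keys(messages: pd.DataFrame) -> list:
    ts = pd.to_datetime(messages["timestamp"])
    return [ts.dt.year.to_numpy(), ts.dt.month.to_numpy()]


def monthly_incidence(messages: pd.DataFrame, flags: pd.DataFrame) -> pd.DataFrame:
    """Percentage of messages per (year, month) containing each pattern.

    Cells carry 4 decimals; months with zero messages are absent rather than
    reported as zero.
    """
    patterns = [c for c in flags.columns if c != "any"]
    if messages.empty:
        return pd.DataFrame(
            columns=patterns,
            index=pd.MultiIndex.from_arrays([[], []], names=["year", "month"]),
        )
    per_msg = flags.loc[messages["message_id"], patterns].set_axis(messages.index)
    pct = per_msg.groupby(_month_keys(messages)).mean() * 100.0
    pct.index.names = ["year", "month"]
    return pct.sort_index().map(lambda v: round_half_away(v, 4))


def transcript_mention_rate(messages: pd.DataFrame, flags: pd.DataFrame) -> tuple[int, int, float]:
    """(n_mentioning, n_total, rate_pct): transcripts with >=1 flagged message.

    The headline rate is rounded half-away-from-zero to 1 decimal.
    """
    if messages.empty:
        raise ValueError("mention rate is undefined for a corpus with zero transcripts")
    any_flag = flags.loc[messages["message_id"], "any"].set_axis(messages.index)
    per_transcript = any_flag.groupby(messages["transcript_id"]).any()
    n_total = int(per_transcript.size)
    n_mentioning = int(per_transcript.sum())
    return n_mentioning, n_total, round_half_away(100.0 * n_mentioning / n_total, 1)


def daily_mention_proportion(
    messages: pd.DataFrame,
    flags: pd.DataFrame,
    window: tuple | None = None,
) -> pd.Series:
    """Per-day proportion of messages whose any-pattern flag is true.

    Only days with at least one message appear; a zero-message day is
    missing, not zero, so it cannot inject artificial signal into the
    downstream correlations.  ``window`` is an inclusive (start, end) date
    pair restricting the analysis days.
    """
    if messages.empty:
        return pd.Series(dtype=float, name="mention_proportion")
    days = pd.to_datetime(messages["timestamp"]).dt.date
    any_flag = flags.loc[messages["message_id"], "any"].set_axis(messages.index)
    if window is not None:
        start, end = as_date(window[0]), as_date(window[1])
        if start > end:
            raise ValueError("window start must not follow window end")
        keep = (days >= start) & (days <= end)
        days, any_flag = days[keep], any_flag[keep]
    prop = any_flag.groupby(days).mean().sort_index()
    prop.name = "mention_proportion"
    prop.index.name = "date"
    return prop.astype(float)
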