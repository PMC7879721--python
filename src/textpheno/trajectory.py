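"""Day-by-term TF-IDF trajectories, per-term correlation, and FDR selection.

Pipeline: pool all messages of each calendar day into one "text day"
document, count unigrams-through-``n_max``-grams, weight with a smoothed
log-idf TF-IDF (raw count x ``1 + ln((1+N)/(1+df))``, no per-day
normalisation so trajectories stay on a count-proportional scale), then
correlate every term's trajectory with the daily mention-proportion signal
(Pearson r, two-sided p from the exact t transform) and keep terms passing
Benjamini-Hochberg at the configured FDR level, partitioned by correlation
sign.
"""

from __future__ import annotations

import datetime as dt
import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.feature_extraction.text import CountVectorizer, TfidfTransformer
from statsmodels.stats.multitest import multipletests

from ._util import as_date

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def tokenize_ngrams(text: str, n_max: int = 2) -> list:
    """Lowercased, punctuation-stripped unigrams through ``n_max``-grams.

    Tokens are maximal runs of ASCII letters/digits; n-grams are adjacent
    tokens joined by single spaces.  Returns the term multiset as a list.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    tokens = _TOKEN_RE.findall(str(text).lower()) if text else []
    terms = []
    for n in range(1, n_max + 1):
        terms.extend(" ".join(tokens[i : i + n]) for i in range(len(tokens) - n + 1))
    return terms


@dataclass
class DailyTermMatrix:
    """Sparse day-by-term count (or weight) matrix over an analysis window."""

    days: list  # calendar days with >=1 message, strictly increasing
    terms: np.ndarray  # vocabulary, alphabetical
    counts: sp.csr_matrix  # shape (n_days, n_terms)

    @property
    def n_days(self) -> int:
        return len(self.days)

    @property
    def df(self) -> np.ndarray:
        """Per-term document frequency: number of days with count > 0."""
        return np.asarray((self.counts != 0).sum(axis=0)).ravel()


class DailyTermVectorizer(BaseEstimator):
    """Build the day-by-term count matrix from a message corpus.

    All messages of a calendar day are pooled into one document ("text
    day"); terms occurring on fewer than ``min_df`` days are dropped.
    Fitted attributes: ``days_``, ``terms_``, ``matrix_``.
    """

    def __init__(self, window=None, n_max: int = 2, min_df: int = 3):
        self.window = window
        self.n_max = n_max
        self.min_df = min_df

    def fit_transform(self, messages: pd.DataFrame) -> DailyTermMatrix:
        days = pd.to_datetime(messages["timestamp"]).dt.date
        texts = messages["text"].fillna("")
        if self.window is not None:
            start, end = as_date(self.window[0]), as_date(self.window[1])
            if start > end:
                raise ValueError("empty analysis window")
            keep = (days >= start) & (days <= end)
            days, texts = days[keep], texts[keep]
        docs = texts.groupby(days).agg(" ".join).sort_index()
        if docs.empty:
            empty = DailyTermMatrix([], np.array([], dtype=object),
                                    sp.csr_matrix((0, 0), dtype=np.int64))
            self.days_, self.terms_, self.matrix_ = [], empty.terms, empty
            return empty
        vec = CountVectorizer(
            analyzer=lambda doc: tokenize_ngrams(doc, self.n_max),
            min_df=self.min_df,
            lowercase=False,
            dtype=np.int64,
        )
        try:
            counts = vec.fit_transform(docs.to_numpy())
            terms = vec.get_feature_names_out()
        except ValueError:  # min_df prunes the whole vocabulary
            counts = sp.csr_matrix((len(docs), 0), dtype=np.int64)
            terms = np.array([], dtype=object)
        matrix = DailyTermMatrix(list(docs.index), terms, sp.csr_matrix(counts))
        self.days_, self.terms_, self.matrix_ = matrix.days, matrix.terms, matrix
        return matrix


def build_daily_matrix(
    messages: pd.DataFrame, window=None, n_max: int = 2, min_df: int = 3
) -> DailyTermMatrix:
    """Day-by-term counts pooling each calendar day's messages into one document."""
    return DailyTermVectorizer(window=window, n_max=n_max, min_df=min_df).fit_transform(messages)


def tfidf_transform(matrix: DailyTermMatrix) -> DailyTermMatrix:
    """Weight counts by smoothed log idf: ``count x (1 + ln((1+N)/(1+df)))``.

    No per-day (row) normalisation is applied, so a day's weights scale
    linearly with its counts and the sparsity pattern is preserved exactly.
    """
    if matrix.n_days == 0 or matrix.terms.size == 0:
        return DailyTermMatrix(matrix.days, matrix.terms,
                               sp.csr_matrix(matrix.counts, dtype=float))
    tfidf = TfidfTransformer(norm=None, smooth_idf=True, sublinear_tf=False)
    weights = tfidf.fit_transform(matrix.counts)
    return DailyTermMatrix(matrix.days, matrix.terms, sp.csr_matrix(weights))


def correlate_terms(tfidf: DailyTermMatrix, signal: pd.Series) -> pd.DataFrame:
    """Pearson r of each term's trajectory against the daily mention signal.

    Days are aligned on the intersection of the matrix's day axis and the
    signal's index; at least 3 paired days are required.  Zero-variance
    terms (or a zero-variance signal) are skipped with a warning, since r is
    undefined there.  Returns columns ``term, r, p, n`` with two-sided
    p-values from the exact t transform of r on n-2 degrees of freedom.
    """
    signal_days = {as_date(d) for d in signal.index}
    shared = [i for i, d in enumerate(tfidf.days) if d in signal_days]
    if len(shared) < 3:
        raise ValueError("need at least 3 paired days to correlate trajectories")
    X = np.asarray(tfidf.counts[shared, :].todense(), dtype=float)
    y = signal.loc[[tfidf.days[i] for i in shared]].to_numpy(float)
    n = len(shared)

    yc = y - y.mean()
    sy = np.sqrt((yc**2).sum())
    Xc = X - X.mean(axis=0)
    sx = np.sqrt((Xc**2).sum(axis=0))
    ok = sx > 0
    if sy == 0:
        warnings.warn("mention signal has zero variance; all terms skipped")
        ok = np.zeros_like(ok)
    n_skipped = int((~ok).sum())
    if n_skipped and sy > 0:
        warnings.warn(f"skipped {n_skipped} zero-variance term trajectories")

    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc.T @ yc) / (sx * sy)
    r = np.clip(r[ok], -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 0.0))
    p = np.where(np.abs(r) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), n - 2))
    return pd.DataFrame(
        {"term": tfidf.terms[ok], "r": r, "p": np.minimum(p, 1.0), "n": n}
    ).reset_index(drop=True)


@dataclass
class SelectionResult:
    """Terms surviving FDR selection, partitioned by correlation sign."""

    positive_terms: pd.DataFrame  # columns term, r, p, p_adjusted
    negative_terms: pd.DataFrame
    q_threshold: float
    n_tested: int

    @property
    def table(self) -> pd.DataFrame:
        """Full per-term table: term, r, p, p_adjusted, selected, sign."""
        return self._table


def bh_select(correlations: pd.DataFrame, q: float = 0.01) -> SelectionResult:
    """Benjamini-Hochberg step-up selection at FDR level ``q``.

    Survivors are partitioned by the sign of r.  Ties in p follow the
    standard step-up rule: everything at or below the largest passing rank
    is selected.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    if correlations.empty:
        raise ValueError("need at least one correlation record")
    reject, p_adj, _, _ = multipletests(correlations["p"].to_numpy(), alpha=q, method="fdr_bh")
    table = correlations.copy()
    table["p_adjusted"] = p_adj
    table["selected"] = reject
    table["sign"] = np.sign(table["r"]).astype(int)
    pos = table[reject & (table["r"] > 0)].reset_index(drop=True)
    neg = table[reject & (table["r"] < 0)].reset_index(drop=True)
    result = SelectionResult(
        positive_terms=pos, negative_terms=neg, q_threshold=q, n_tested=len(table)
    )
    result._table = table
    return result


class TrajectoryScreen(BaseEstimator):
    """End-to-end term-trajectory screen: counts -> TF-IDF -> Pearson -> BH.

    Parameters
    ----------
    window : (date, date) or None
        Inclusive analysis window over calendar days.
    n_max : int
        Maximum n-gram order (default unigrams + bigrams).
    min_df : int
        Minimum number of distinct days a term must occur on.
    q : float
        FDR level for Benjamini-Hochberg selection.

    Fitted attributes: ``matrix_``, ``tfidf_``, ``correlations_``,
    ``selection_``.
    """

    def __init__(self, window=None, n_max: int = 2, min_df: int = 3, q: float = 0.01):
        self.window = window
        self.n_max = n_max
        self.min_df = min_df
        self.q = q

    def fit(self, messages: pd.DataFrame, signal: pd.Series) -> "TrajectoryScreen":
        self.matrix_ = build_daily_matrix(messages, self.window, self.n_max, self.min_df)
        self.tfidf_ = tfidf_transform(self.matrix_)
        self.correlations_ = correlate_terms(self.tfidf_, signal)
        self.selection_ = bh_select(self.correlations_, self.q)
        return self

    def get_support(self, sign: int = 0) -> np.ndarray:
        """Selected terms: all (sign=0), positive (1), or negative (-1)."""
        sel = self.selection_
        if sign > 0:
            return sel.positive_terms["term"].to_numpy()
        if sign < 0:
            return sel.negative_terms["term"].to_numpy()
        return np.concatenate(
            [sel.positive_terms["term"].to_numpy(), sel.negative_terms["term"].to_numpy()]
        )
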