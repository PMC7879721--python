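"""GAD-7 / PHQ-9 scoring, rolling intake series, and shift estimation.

The intake-severity analysis compares the mean total score of intakes
falling in a comparison window against a baseline window (e.g. the same
calendar span of prior years).  The point estimate is the difference in
means; its 95% CI comes from a percentile bootstrap over patients and the
p-value from Welch's unequal-variance two-sample t test — standard,
documented defaults, since a mean difference with CI does not pin down a
procedure by itself.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from ._util import as_date

INSTRUMENT_ITEMS = {"GAD7": 7, "PHQ9": 9}
INSTRUMENT_MAX = {"GAD7": 21, "PHQ9": 27}


def score_instrument(items, instrument: str) -> int:
    """Total score = sum of item responses (the instruments' published rule)."""
    if instrument not in INSTRUMENT_ITEMS:
        raise ValueError(f"unknown instrument {instrument!r}")
    items = list(items)
    if len(items) != INSTRUMENT_ITEMS[instrument]:
        raise ValueError(
            f"{instrument} expects {INSTRUMENT_ITEMS[instrument]} items, got {len(items)}"
        )
    total = 0
    for v in items:
        iv = int(v)
        if iv != v or not 0 <= iv <= 3:
            raise ValueError(f"item responses must be integers in 0-3, got {v!r}")
        total += iv
    return total


def intake_totals(assessments: pd.DataFrame, instrument: str) -> pd.DataFrame:
    """Per-intake total scores: columns patient_id, date, total.

    Records with missing or out-of-range items are excluded (incomplete
    questionnaires are dropped, not imputed).
    """
    n_items = INSTRUMENT_ITEMS[instrument]
    sub = assessments[assessments["instrument"] == instrument]
    cols = [f"item_{i}" for i in range(1, n_items + 1)]
    items = sub[cols].apply(pd.to_numeric, errors="coerce").to_numpy(float)
    valid = (
        np.isfinite(items).all(axis=1)
        & (items == np.round(items)).all(axis=1)
        & (items >= 0).all(axis=1)
        & (items <= 3).all(axis=1)
    )
    ok = sub[valid]
    return pd.DataFrame(
        {
            "patient_id": ok["patient_id"].to_numpy(),
            "date": [as_date(d) for d in ok["date"]],
            "total": items[valid].sum(axis=1).astype(int),
        }
    )


def rolling_intake_series(
    assessments: pd.DataFrame, instrument: str, window_days: int = 14
) -> pd.DataFrame:
    """Trailing pooled mean intake score per day.

    For each calendar day ``d`` with at least one intake in the trailing
    window ``(d - window_days, d]``, the mean of *all* totals in that window
    (every intake weighted equally) and the contributing count ``n``.
    """
    if window_days < 1:
        raise ValueError("window_days must be >= 1")
    totals = intake_totals(assessments, instrument)
    if totals.empty:
        return pd.DataFrame(columns=["date", "mean", "n"])
    idx = pd.to_datetime(totals["date"])
    daily = totals.groupby(idx)["total"].agg(["sum", "count"])
    full = daily.reindex(pd.date_range(idx.min(), idx.max(), freq="D"), fill_value=0)
    roll = full.rolling(window=window_days, min_periods=1).sum()
    out = roll[roll["count"] > 0]
    return pd.DataFrame(
        {
            "date": [d.date() for d in out.index],
            "mean": (out["sum"] / out["count"]).to_numpy(),
            "n": out["count"].astype(int).to_numpy(),
        }
    ).reset_index(drop=True)


@dataclass
class ShiftEstimate:
    """Mean intake-score difference (comparison minus baseline) with 95% CI."""

    delta: float
    ci_low: float
    ci_high: float
    p_value: float
    n_baseline: int
    n_comparison: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


class ShiftEstimator(BaseEstimator):
    """Estimate the shift in mean intake severity between two date windows.

    Parameters
    ----------
    baseline_window, comparison_window : (date, date)
        Inclusive date ranges selecting intakes by date; must be disjoint.
    n_boot : int
        Percentile-bootstrap resamples (over patients) for the 95% CI.
    seed : int
        Bootstrap RNG seed.

    Fitted attributes: ``delta_``, ``ci_``, ``p_value_``, ``estimate_``.
    """

    def __init__(self, baseline_window=None, comparison_window=None,
                 n_boot: int = 10_000, seed: int = 0):
        self.baseline_window = baseline_window
        self.comparison_window = comparison_window
        self.n_boot = n_boot
        self.seed = seed

    def fit(self, assessments: pd.DataFrame, instrument: str = "GAD7") -> "ShiftEstimator":
        b0, b1 = map(as_date, self.baseline_window)
        c0, c1 = map(as_date, self.comparison_window)
        if b0 > b1 or c0 > c1:
            raise ValueError("window start must not follow window end")
        if not (b1 < c0 or c1 < b0):
            raise ValueError("baseline and comparison windows must be disjoint")
        totals = intake_totals(assessments, instrument)
        dates = totals["date"]
        base = totals.loc[(dates >= b0) & (dates <= b1), "total"].to_numpy(float)
        comp = totals.loc[(dates >= c0) & (dates <= c1), "total"].to_numpy(float)
        if len(base) < 2 or len(comp) < 2:
            raise ValueError("each window needs at least 2 complete intakes")

        delta = comp.mean() - base.mean()
        rng = np.random.default_rng(self.seed)
        boot_b = base[rng.integers(0, len(base), size=(self.n_boot, len(base)))].mean(axis=1)
        boot_c = comp[rng.integers(0, len(comp), size=(self.n_boot, len(comp)))].mean(axis=1)
        ci_low, ci_high = np.percentile(boot_c - boot_b, [2.5, 97.5])
        p = float(stats.ttest_ind(comp, base, equal_var=False).pvalue)

        self.delta_ = float(delta)
        self.ci_ = (float(ci_low), float(ci_high))
        self.p_value_ = p
        self.estimate_ = ShiftEstimate(
            delta=float(delta), ci_low=float(ci_low), ci_high=float(ci_high),
            p_value=p, n_baseline=len(base), n_comparison=len(comp),
        )
        return self


def estimate_shift(
    assessments: pd.DataFrame,
    instrument: str,
    baseline_window,
    comparison_window,
    n_boot: int = 10_000,
    seed: int = 0,
) -> ShiftEstimate:
    """Mean-difference shift estimate with percentile-bootstrap 95% CI and Welch p."""
    est = ShiftEstimator(baseline_window, comparison_window, n_boot=n_boot, seed=seed)
    return est.fit(assessments, instrument).estimate_


def plot_rolling_series(series_by_label: dict, instrument: str, path) -> None:
    """Plot one or more rolling intake series (e.g. prior-year overlays)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    for label, series in series_by_label.items():
        ax.plot(pd.to_datetime(series["date"]), series["mean"], label=str(label))
    ax.set_xlabel("date")
    ax.set_ylabel(f"{instrument} rolling mean intake score")
    ax.legend()
    fig.autofmt_xdate()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
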