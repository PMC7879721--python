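"""Tokenizer, day-term matrix, TF-IDF, Pearson screen, and BH selection."""

import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from textpheno import (
    bh_select,
    build_daily_matrix,
    correlate_terms,
    tfidf_transform,
    tokenize_ngrams,
)
from textpheno.trajectory import DailyTermMatrix

from conftest import make_messages


def day_matrix(days, terms, dense):
    return DailyTermMatrix(days, np.array(terms, dtype=object), sp.csr_matrix(np.array(dense)))


def signal_for(days, values):
    return pd.Series(np.asarray(values, float), index=list(days))


DAYS4 = [dt.date(2020, 3, d) for d in (1, 2, 3, 4)]


class TestTokenizer:
    def test_unigrams(self):
        assert sorted(tokenize_ngrams("I feel anxious", 1)) == ["anxious", "feel", "i"]

    def test_empty_text(self):
        assert tokenize_ngrams("", 3) == []

    def test_bigram_multiset(self):
        terms = tokenize_ngrams("so so tired", 2)
        assert terms.count("so") == 2 and terms.count("tired") == 1
        assert terms.count("so so") == 1 and terms.count("so tired") == 1

    def test_punctuation_is_stripped(self):
        assert tokenize_ngrams("COVID-19, update!", 1) == ["covid", "19", "update"]

    def test_invalid_order_rejected(self):
        with pytest.raises(ValueError):
            tokenize_ngrams("x", 0)


class TestDailyMatrix:
    def test_counts_pool_one_day(self):
        msgs = make_messages([("m0", "t0", "p0", "2020-03-01T09:00:00", "a b a")])
        m = build_daily_matrix(msgs, n_max=1, min_df=1)
        counts = dict(zip(m.terms, np.asarray(m.counts.todense()).ravel()))
        assert counts == {"a": 2, "b": 1}

    def test_min_df_saturation_empties_vocabulary(self):
        msgs = make_messages([("m0", "t0", "p0", "2020-03-01T09:00:00", "a b")])
        assert build_daily_matrix(msgs, n_max=1, min_df=5).terms.size == 0

    def test_disjoint_days_with_min_df_two(self):
        msgs = make_messages(
            [("m0", "t0", "p0", "2020-03-01T09:00:00", "alpha beta"),
             ("m1", "t0", "p0", "2020-03-02T09:00:00", "gamma delta")]
        )
        assert build_daily_matrix(msgs, n_max=1, min_df=2).terms.size == 0

    def test_day_axis_strictly_increasing_and_df_floor(self):
        msgs = make_messages(
            [("m0", "t0", "p0", "2020-03-02T09:00:00", "b a"),
             ("m1", "t1", "p1", "2020-03-01T09:00:00", "a c"),
             ("m2", "t1", "p1", "2020-03-03T09:00:00", "a c")]
        )
        m = build_daily_matrix(msgs, n_max=1, min_df=1)
        assert m.days == sorted(m.days)
        assert (m.df >= 1).all()
        assert dict(zip(m.terms, m.df))["a"] == 3


class TestTfidf:
    def test_closed_form_weight(self):
        """count 2, df 1 of N=4 days: 2 * (1 + ln(5/2))."""
        m = day_matrix(DAYS4, ["x"], [[2], [0], [0], [0]])
        w = tfidf_transform(m).counts.todense()
        assert w[0, 0] == pytest.approx(2 * (1 + math.log(5 / 2)), abs=1e-12)

    def test_saturated_df_reduces_to_raw_counts(self):
        m = day_matrix(DAYS4, ["x"], [[1], [2], [3], [4]])
        w = np.asarray(tfidf_transform(m).counts.todense()).ravel()
        assert w == pytest.approx([1, 2, 3, 4])

    def test_sparsity_pattern_preserved(self):
        dense = [[2, 0], [0, 1], [3, 0], [0, 0]]
        m = day_matrix(DAYS4, ["x", "y"], dense)
        w = np.asarray(tfidf_transform(m).counts.todense())
        assert ((w == 0) == (np.array(dense) == 0)).all()

    def test_scaling_one_day_scales_its_weights(self):
        base = [[2, 1], [1, 4], [3, 2], [1, 1]]
        scaled = [r[:] for r in base]
        scaled[2] = [3 * v for v in base[2]]
        w_base = np.asarray(tfidf_transform(day_matrix(DAYS4, ["x", "y"], base)).counts.todense())
        w_scaled = np.asarray(
            tfidf_transform(day_matrix(DAYS4, ["x", "y"], scaled)).counts.todense()
        )
        assert w_scaled[2] == pytest.approx(3 * w_base[2])
        assert w_scaled[0] == pytest.approx(w_base[0])


class TestCorrelation:
    def test_self_correlation_is_one(self):
        sig = signal_for(DAYS4, [0.1, 0.2, 0.3, 0.5])
        m = day_matrix(DAYS4, ["x"], [[0.1], [0.2], [0.3], [0.5]])
        out = correlate_terms(m, sig)
        assert out.loc[0, "r"] == pytest.approx(1.0)
        assert out.loc[0, "p"] == pytest.approx(0.0, abs=1e-12)

    def test_negated_shifted_signal_gives_minus_one(self):
        sig = signal_for(DAYS4, [0.1, 0.2, 0.3, 0.5])
        m = day_matrix(DAYS4, ["x"], [[0.9], [0.8], [0.7], [0.5]])
        assert correlate_terms(m, sig).loc[0, "r"] == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        traj = [1.0, 2.0, 3.0, 4.0]
        sig_vals = [0.1, 0.2, 0.3, 0.5]
        out = correlate_terms(
            day_matrix(DAYS4, ["x"], [[v] for v in traj]), signal_for(DAYS4, sig_vals)
        )
        r_ref, p_ref = stats.pearsonr(traj, sig_vals)
        assert out.loc[0, "r"] == pytest.approx(r_ref, abs=1e-12)
        assert out.loc[0, "p"] == pytest.approx(p_ref, abs=1e-12)

    def test_zero_variance_term_skipped_with_warning(self):
        m = day_matrix(DAYS4, ["flat", "x"], [[1, 1], [1, 2], [1, 3], [1, 5]])
        with pytest.warns(UserWarning, match="zero-variance"):
            out = correlate_terms(m, signal_for(DAYS4, [0.1, 0.2, 0.4, 0.3]))
        assert list(out["term"]) == ["x"]

    def test_insufficient_paired_days_errors(self):
        m = day_matrix(DAYS4[:2], ["x"], [[1], [2]])
        with pytest.raises(ValueError, match="3 paired days"):
            correlate_terms(m, signal_for(DAYS4[:2], [0.1, 0.2]))

    def test_invariant_to_affine_signal_rescaling(self):
        rng = np.random.default_rng(0)
        dense = rng.poisson(3.0, size=(8, 5)).astype(float)
        days = [dt.date(2020, 3, 1) + dt.timedelta(days=i) for i in range(8)]
        m = day_matrix(days, [f"t{i}" for i in range(5)], dense)
        sig = signal_for(days, rng.random(8))
        a = correlate_terms(m, sig)
        b = correlate_terms(m, 0.25 * sig + 3.0)
        assert a["r"].to_numpy() == pytest.approx(b["r"].to_numpy(), abs=1e-12)


def brute_force_bh(pvals, q):
    """Exhaustive step-up: largest k with p_(k) <= qk/m; select all p <= that."""
    m = len(pvals)
    order = np.argsort(pvals, kind="mergesort")
    k_star = 0
    for k in range(1, m + 1):
        if pvals[order[k - 1]] <= q * k / m:
            k_star = k
    selected = np.zeros(m, dtype=bool)
    if k_star:
        selected[order[:k_star]] = True
    return selected


class TestBHSelect:
    def make_corr(self, pvals, rs=None):
        rs = rs if rs is not None else np.linspace(-1, 1, len(pvals))
        return pd.DataFrame({"term": [f"t{i}" for i in range(len(pvals))],
                             "r": rs, "p": pvals, "n": 10})

    def test_all_pvalues_one_selects_nothing(self):
        res = bh_select(self.make_corr([1.0, 1.0, 1.0]), q=0.01)
        assert res.positive_terms.empty and res.negative_terms.empty

    def test_single_term_reduces_to_raw_threshold(self):
        assert len(bh_select(self.make_corr([0.005], rs=[0.4]), q=0.01).positive_terms) == 1
        res = bh_select(self.make_corr([0.02], rs=[0.4]), q=0.01)
        assert res.positive_terms.empty

    def test_hand_case_matches_step_up_oracle(self):
        pvals = [0.001, 0.002, 0.009, 0.04, 0.2]
        res = bh_select(self.make_corr(pvals), q=0.01)
        expected = brute_force_bh(np.array(pvals), 0.01)
        got = res.table["selected"].to_numpy()
        assert (got == expected).all()

    def test_sign_partition_matches_r(self):
        res = bh_select(self.make_corr([0.0001, 0.0002], rs=[0.8, -0.7]), q=0.05)
        assert list(res.positive_terms["term"]) == ["t0"]
        assert list(res.negative_terms["term"]) == ["t1"]

    def test_selected_raw_p_never_exceeds_stepup_bound(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            m = int(rng.integers(1, 13))
            pvals = np.round(rng.random(m), 3)
            res = bh_select(self.make_corr(pvals), q=0.05)
            table = res.table.sort_values("p").reset_index(drop=True)
            for rank, row in table.iterrows():
                if row["selected"]:
                    assert row["p"] <= 0.05 * (rank + 1) / m + 1e-12

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            bh_select(self.make_corr([0.1]), q=0.0)
        with pytest.raises(ValueError):
            bh_select(pd.DataFrame(columns=["term", "r", "p"]), q=0.01)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=12),
    st.sampled_from([0.01, 0.05, 0.1]),
)
def test_bh_matches_brute_force_on_short_vectors(pvals, q):
    corr = pd.DataFrame({"term": [f"t{i}" for i in range(len(pvals))],
                         "r": np.ones(len(pvals)), "p": pvals, "n": 10})
    got = bh_select(corr, q=q).table["selected"].to_numpy()
    assert (got == brute_force_bh(np.array(pvals), q)).all()
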