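"""End-to-end orchestration: simulate/load -> screen -> trends -> select -> map.

One config drives every stage; all randomness flows from a single master
seed through named substreams, so identical config + seed gives a
byte-identical report.  Each stage's outputs are flushed to the run
directory as soon as the stage completes, and stage failures propagate with
the stage name attached.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .categories import assign_categories, category_percentages, load_category_lexicon
from .icd10 import load_symptom_lexicon, match_symptoms
from .io import read_assessments, read_messages, write_assessments, write_ground_truth, write_messages
from .keywords import DEFAULT_PATTERNS, SeedLexicon, daily_mention_proportion, flag_messages, monthly_incidence, transcript_mention_rate
from .scores import estimate_shift, rolling_intake_series
from .simulate import GeneratorConfig, simulate_assessments, simulate_corpus
from .trajectory import TrajectoryScreen

logger = logging.getLogger("textpheno")


class PipelineConfig(BaseModel):
    """Configuration for one end-to-end run.

    Exactly one of ``simulate`` (a generator config) or the
    ``messages_path``/``assessments_path`` pair must be provided.
    """

    simulate: GeneratorConfig | None = None
    messages_path: str | None = None
    assessments_path: str | None = None
    window: tuple[dt.date, dt.date] = (dt.date(2020, 3, 1), dt.date(2020, 6, 9))
    seed_patterns: tuple[str, ...] = DEFAULT_PATTERNS
    word_boundary: bool = False
    window_days: int = Field(default=14, ge=1)
    baseline_window: tuple[dt.date, dt.date] | None = None
    comparison_window: tuple[dt.date, dt.date] | None = None
    n_boot: int = Field(default=10_000, ge=1)
    n_max: int = Field(default=2, ge=1)
    min_df: int = Field(default=3, ge=1)
    q: float = Field(default=0.01, gt=0.0, lt=1.0)
    category_lexicon_path: str | None = None
    icd10_lexicon_path: str | None = None
    out_dir: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _check(self) -> "PipelineConfig":
        has_paths = self.messages_path is not None and self.assessments_path is not None
        if (self.simulate is None) == (not has_paths):
            raise ValueError("provide exactly one of: a simulate block, or both input paths")
        if self.window[0] > self.window[1]:
            raise ValueError("analysis window dates must be ordered")
        return self


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage(name):
    """Context manager logging stage timing and re-raising with stage context."""

    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done in %.2fs", name, time.perf_counter() - self.t0)
            return False

    return _Ctx()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the consolidated report dict.

    When ``config.out_dir`` is set, intermediate tables and the report are
    written there (CSV/JSON); completed stages are flushed even if a later
    stage fails.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir) if config.out_dir else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    seeds = [int(s) for s in np.random.SeedSequence(config.seed).generate_state(3) % (2**31)]
    report: dict = {
        "provenance": {
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "versions": _versions(),
        }
    }

    with _stage("ingest"):
        if config.simulate is not None:
            gen_cfg = config.simulate.model_copy(update={"seed": seeds[0]})
            messages, truth = simulate_corpus(gen_cfg)
            assessments = simulate_assessments(gen_cfg)
            if out is not None:
                write_messages(messages, out / "messages.jsonl")
                write_assessments(assessments, out / "assessments.csv")
                write_ground_truth(truth, out / "ground_truth.json")
        else:
            messages = read_messages(config.messages_path)
            assessments = read_assessments(config.assessments_path)
        logger.info("ingest: %d messages, %d assessment records", len(messages), len(assessments))

    with _stage("keyword_screen"):
        lexicon = SeedLexicon(tuple(config.seed_patterns))
        flags = flag_messages(messages, lexicon, word_boundary=config.word_boundary)
        incidence = monthly_incidence(messages, flags)
        signal = daily_mention_proportion(messages, flags, window=config.window)
        if messages.empty:
            mention = {"n_mentioning": 0, "n_total": 0, "rate_pct": None}
        else:
            n_m, n_t, pct = transcript_mention_rate(messages, flags)
            mention = {"n_mentioning": n_m, "n_total": n_t, "rate_pct": pct}
        if out is not None:
            incidence.to_csv(out / "monthly_incidence.csv")
            signal.to_csv(out / "daily_mention_signal.csv")
        report["keyword_screen"] = {
            "n_messages": int(len(messages)),
            "transcript_mention": mention,
            "monthly_incidence": _incidence_records(incidence),
            "n_signal_days": int(signal.size),
        }

    with _stage("score_trends"):
        trends = {}
        for instrument in ("GAD7", "PHQ9"):
            rolling = rolling_intake_series(assessments, instrument, config.window_days)
            baseline, comparison = _shift_windows(config)
            entry = {"n_rolling_days": int(len(rolling))}
            if baseline is not None:
                try:
                    shift = estimate_shift(
                        assessments, instrument, baseline, comparison,
                        n_boot=config.n_boot, seed=seeds[1],
                    )
                    entry["shift"] = json.loads(shift.to_json())
                except ValueError as err:
                    entry["shift"] = {"error": str(err)}
            if out is not None:
                rolling.to_csv(out / f"rolling_{instrument.lower()}.csv", index=False)
            trends[instrument] = entry
        report["score_trends"] = trends

    with _stage("trajectory_screen"):
        screen = TrajectoryScreen(
            window=config.window, n_max=config.n_max, min_df=config.min_df, q=config.q
        )
        selection = None
        if signal.size >= 3 and not messages.empty:
            try:
                screen.fit(messages, signal)
                selection = screen.selection_
            except ValueError as err:
                logger.warning("trajectory screen skipped: %s", err)
        if selection is not None:
            pos = list(selection.positive_terms["term"])
            neg = list(selection.negative_terms["term"])
            n_tested = selection.n_tested
            if out is not None:
                selection.table.to_csv(out / "term_selection.csv", index=False)
        else:
            pos, neg, n_tested = [], [], 0
        report["trajectory_screen"] = {
            "n_tested": int(n_tested),
            "n_positive": len(pos),
            "n_negative": len(neg),
            "q": config.q,
        }

    with _stage("category_assign"):
        cat_lexicon = load_category_lexicon(config.category_lexicon_path)
        breakdowns = {}
        for name, terms in (("positive", pos), ("negative", neg)):
            if terms:
                assignments = assign_categories(terms, cat_lexicon)
                table = category_percentages(assignments)
                breakdowns[name] = table.to_dict(orient="records")
                if out is not None:
                    table.to_csv(out / f"category_breakdown_{name}.csv", index=False)
            else:
                breakdowns[name] = []
        report["categories"] = breakdowns

    with _stage("icd10_map"):
        sym_lexicon = load_symptom_lexicon(config.icd10_lexicon_path)
        sym_report = match_symptoms(pos + neg, sym_lexicon)
        report["icd10"] = sym_report.to_dict()
        if out is not None:
            (out / "icd10_report.json").write_text(
                json.dumps(sym_report.to_dict(), sort_keys=True, indent=1)
            )

    if out is not None:
        (out / "report.json").write_text(json.dumps(report, sort_keys=True, indent=1))
    return report


def _shift_windows(config: PipelineConfig):
    if config.baseline_window is not None and config.comparison_window is not None:
        return tuple(config.baseline_window), tuple(config.comparison_window)
    if config.simulate is not None:
        sim = config.simulate
        cp = sim.changepoint_date
        if sim.start_date < cp <= sim.end_date:
            return (sim.start_date, cp - dt.timedelta(days=1)), (cp, sim.end_date)
    return None, None


def _incidence_records(incidence: pd.DataFrame) -> list:
    records = []
    for (year, month), row in incidence.iterrows():
        rec = {"year": int(year), "month": int(month)}
        rec.update({str(k): float(v) for k, v in row.items()})
        records.append(rec)
    return records


def _versions() -> dict:
    import scipy
    import sklearn
    import statsmodels

    return {
        "textpheno": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "scikit-learn": sklearn.__version__,
        "statsmodels": statsmodels.__version__,
    }
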