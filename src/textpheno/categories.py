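"""Lexicon-based topical categorization of selected terms.

Each term is assigned to at most one topical category by counting how many
of a category's cue words prefix-stem-match any token of the term (cue
"lone" matches "lonely" and "loneliness").  The packaged default lexicon is
a transparent, editable JSON file covering the eleven topics the analysis
reports (confusion/negative emotions, health/medical emergencies, ...);
an embedding-derived categorizer with the same single-category output
contract can be swapped in behind this interface.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import pandas as pd
from sklearn.base import BaseEstimator

from ._util import round_half_away

UNASSIGNED = "unassigned"


def load_category_lexicon(path=None) -> dict:
    """Category -> cue list mapping; packaged default when ``path`` is None."""
    if path is None:
        raw = resources.files("textpheno.data").joinpath("category_lexicon.json").read_text()
    else:
        raw = Path(path).read_text()
    lexicon = json.loads(raw)
    _validate_lexicon(lexicon)
    return {cat: [c.lower() for c in cues] for cat, cues in lexicon.items()}


def _validate_lexicon(lexicon: dict) -> None:
    if not lexicon:
        raise ValueError("category lexicon must contain at least one category")
    for cat, cues in lexicon.items():
        if not cues:
            raise ValueError(f"category {cat!r} has an empty cue set")


class CategoryAssigner(BaseEstimator):
    """Assign each input term to its best-matching topical category.

    A category's score for a term is the number of its cue words that are a
    prefix of at least one of the term's whitespace tokens.  The max-scoring
    category wins; score 0 everywhere means unassigned; ties break to the
    lexicographically first category name, which keeps assignment
    deterministic and order-invariant.
    """

    def __init__(self, lexicon: dict | None = None):
        self.lexicon = lexicon

    def transform(self, terms) -> dict:
        lexicon = self.lexicon if self.lexicon is not None else load_category_lexicon()
        _validate_lexicon(lexicon)
        assignments = {}
        for term in terms:
            tokens = str(term).lower().split()
            best_cat, best_score = None, 0
            for cat in sorted(lexicon):
                score = sum(
                    1 for cue in lexicon[cat] if any(tok.startswith(cue) for tok in tokens)
                )
                if score > best_score:
                    best_cat, best_score = cat, score
            assignments[str(term)] = best_cat
        self.assignments_ = assignments
        return assignments


def assign_categories(terms, lexicon: dict | None = None) -> dict:
    """Per-term category (or None when no cue matches)."""
    return CategoryAssigner(lexicon).transform(terms)


def category_percentages(assignments: dict) -> pd.DataFrame:
    """Category breakdown: count and integer percentage of the input terms.

    Percentages are over the full input size (assigned + unassigned),
    rounded half-away-from-zero to the nearest integer; unmatched terms are
    reported in an ``unassigned`` bucket.
    """
    if not assignments:
        raise ValueError("cannot break down an empty assignment")
    total = len(assignments)
    counts: dict = {}
    for cat in assignments.values():
        key = cat if cat is not None else UNASSIGNED
        counts[key] = counts.get(key, 0) + 1
    rows = [
        (cat, n, round_half_away(100.0 * n / total, 0))
        for cat, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["category", "count", "percent"])
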