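"""Mapping of screened terms onto ICD-10 symptom descriptors.

Selected terms are compared against a packaged, editable dictionary of
ICD-10 symptom descriptions (acute stress F43.0, PTSD F43.1, paranoia F22,
grief Z63.4, insomnia G47.00, panic F41.0, agoraphobia F40.00, nonsuicidal
self-injury Z91.5, obsession-compulsion F42.9, hypochondriasis F45.21,
unspecified anxiety F41.9, plus a pandemic-specific bucket).  A term
supports a code iff any of its tokens stem-matches a content token of any
descriptor phrase; a term may support several codes (acute stress and PTSD
share phenomenology, for example).  Terms supporting no code are returned
as an unmatched list for human inspection — the package does not diagnose.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from sklearn.base import BaseEstimator

_TOKEN_RE = re.compile(r"[a-z0-9]+")

# function words excluded from descriptor content tokens; prevents vacuous
# matches on "the", "about", "of" and similar
_STOPWORDS = frozenset(
    """a an and are as at about be being been by do does for from get had has have
    having if in into is it its may might must not of on one oneself ones or out
    over so some such than that the their them they this to too was were when
    where whether which who will with without you your""".split()
)
_MIN_STEM = 4  # shortest shared prefix accepted as a stem match


def load_symptom_lexicon(path=None) -> dict:
    """Code -> {label, phrases} mapping; packaged default when path is None."""
    if path is None:
        raw = resources.files("textpheno.data").joinpath("icd10_symptoms.json").read_text()
    else:
        raw = Path(path).read_text()
    lexicon = json.loads(raw)
    if not lexicon:
        raise ValueError("symptom lexicon must contain at least one code")
    for code, entry in lexicon.items():
        if not entry.get("phrases"):
            raise ValueError(f"code {code!r} has no descriptor phrases")
    return lexicon


def _content_tokens(phrase: str) -> list:
    return [t for t in _TOKEN_RE.findall(phrase.lower())
            if t not in _STOPWORDS and len(t) >= 3]


def _stem_match(a: str, b: str) -> bool:
    """True when one token is a prefix of the other and the shared stem is
    long enough to be meaningful ("asleep"~"asleep", "nightmare"~"nightmares")."""
    if a == b:
        return True
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    return len(short) >= _MIN_STEM and long_.startswith(short)


@dataclass
class SymptomMatchReport:
    """Per-code supporting terms plus the terms matching no descriptor."""

    matches: dict  # code -> {"label": str, "terms": [..], "count": int}
    unmatched: list
    best_descriptor: dict = field(default_factory=dict)  # term -> (code, phrase)

    def to_dict(self) -> dict:
        return {
            "matches": self.matches,
            "unmatched": list(self.unmatched),
            "best_descriptor": {t: list(v) for t, v in self.best_descriptor.items()},
        }


class SymptomMatcher(BaseEstimator):
    """Match terms against ICD-10 symptom-descriptor phrases.

    ``transform(terms)`` returns a :class:`SymptomMatchReport`; the per-term
    best descriptor is the phrase sharing the most stem-matched content
    tokens (first in lexicon order on ties).
    """

    def __init__(self, lexicon: dict | None = None):
        self.lexicon = lexicon

    def transform(self, terms) -> SymptomMatchReport:
        lexicon = self.lexicon if self.lexicon is not None else load_symptom_lexicon()
        if not lexicon:
            raise ValueError("symptom lexicon must contain at least one code")
        matches = {
            code: {"label": entry["label"], "terms": [], "count": 0}
            for code, entry in sorted(lexicon.items())
        }
        unmatched, best = [], {}
        for term in sorted(str(t) for t in set(terms)):
            tokens = _TOKEN_RE.findall(term.lower())
            hit_any = False
            best_score = 0
            for code in sorted(lexicon):
                supported = False
                for phrase in lexicon[code]["phrases"]:
                    content = _content_tokens(phrase)
                    n_hits = sum(
                        1 for tok in tokens if any(_stem_match(tok, c) for c in content)
                    )
                    if n_hits > 0:
                        supported = True
                        if n_hits > best_score:
                            best_score = n_hits
                            best[term] = (code, phrase)
                if supported:
                    matches[code]["terms"].append(term)
                    matches[code]["count"] += 1
                    hit_any = True
            if not hit_any:
                unmatched.append(term)
        report = SymptomMatchReport(matches=matches, unmatched=unmatched, best_descriptor=best)
        self.report_ = report
        return report


def match_symptoms(terms, lexicon: dict | None = None) -> SymptomMatchReport:
    """Per-code supporting terms and unmatched-term list for an input term set."""
    return SymptomMatcher(lexicon).transform(terms)
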