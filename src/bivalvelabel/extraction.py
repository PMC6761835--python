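"""Field extraction from raw OCR text.

OCR output from a label is noisy and interleaved with irrelevant material
(lot codes, weights, marketing text).  Extraction matches the normalized
text against the controlled vocabularies using a normalized Levenshtein
similarity over sliding token windows, pulls packaging-date candidates with
the three separator dialects (``/``, ``-``, ``.``), and detects purification
mentions with a stricter threshold.

The similarity between two normalized strings is

    sim(a, b) = 1 - levenshtein(a, b) / max(|a|, |b|)

with ``sim("", "") = 1``.  A vocabulary field is accepted when the best
window similarity reaches the acceptance threshold (default 0.6); below it
the candidate carries the sentinel value ``"unmatched"`` together with the
best similarity actually observed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib

from bivalvelabel.ocr import RawText
from bivalvelabel.vocab import Vocabulary, normalize_text

UNMATCHED = "unmatched"

#: Default acceptance threshold for vocabulary fields.
FIELD_THRESHOLD = 0.6
#: Stricter threshold for the binary purification mention, chosen to keep
#: false positives out even under heavy corruption.
PURIFICATION_THRESHOLD = 0.85

_DATE_RE = re.compile(
    r"(?<!\d)(\d{1,2})([/\-.])(\d{1,2})(?:([/\-.])(\d{4}|\d{2}))?(?!\d)"
)


def similarity(a: str, b: str) -> float:
    """Normalized Levenshtein similarity in [0, 1] between normalized strings."""
    if not a and not b:
        return 1.0
    if not a or not b:
        return 0.0
    dist = edlib.align(a, b)["editDistance"]
    return 1.0 - dist / max(len(a), len(b))


@dataclass(frozen=True)
class FieldCandidate:
    """Best fuzzy match of one variant's text against one vocabulary."""

    variable_id: str
    value: str
    similarity: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.similarity <= 1.0:
            raise ValueError(f"similarity must be in [0, 1], got {self.similarity}")

    @property
    def matched(self) -> bool:
        return self.value != UNMATCHED


@dataclass(frozen=True)
class DateCandidate:
    """One day/month(/year) pattern found in the text, in reading order."""

    day: int
    month: int
    explicit_year: int | None
    separator: str

    def __post_init__(self) -> None:
        if not 1 <= self.day <= 31:
            raise ValueError(f"day out of range: {self.day}")
        if not 1 <= self.month <= 12:
            raise ValueError(f"month out of range: {self.month}")
        if self.separator not in "/-.":
            raise ValueError(f"unknown separator {self.separator!r}")


@dataclass(frozen=True)
class VariantExtraction:
    """Everything extracted from one preprocessed variant's text."""

    variant_tag: str
    fields: dict[str, FieldCandidate]
    date_candidates: tuple[DateCandidate, ...] = ()
    purification_detected: bool = False

    @property
    def date_vote(self) -> DateCandidate | None:
        """This variant's vote: the first date in reading order, if any.

        Packaging dates are conventionally printed before lot codes, so the
        first candidate is the likeliest; cross-variant voting resolves
        disagreement.
        """
        return self.date_candidates[0] if self.date_candidates else None


def _token_windows(tokens: list[str], size: int) -> list[str]:
    if size <= 0:
        return []
    if len(tokens) <= size:
        return [" ".join(tokens)] if tokens else []
    return [" ".join(tokens[i : i + size]) for i in range(len(tokens) - size + 1)]


def _best_window_similarity(tokens: list[str], phrase: str) -> float:
    size = len(phrase.split())
    best = 0.0
    for window in _token_windows(tokens, size):
        best = max(best, similarity(window, phrase))
        if best == 1.0:
            break
    return best


def match_field(
    text: RawText, vocabulary: Vocabulary, threshold: float = FIELD_THRESHOLD
) -> FieldCandidate:
    """Best vocabulary entry over all synonym × token-window pairs.

    Each synonym is compared against every window of consecutive normalized
    tokens of its own token count.  If the best similarity reaches the
    threshold the entry's canonical value is returned; otherwise the
    sentinel ``"unmatched"`` with the best sub-threshold similarity.
    """
    tokens = normalize_text(text.text).split()
    best_value, best_sim = UNMATCHED, 0.0
    for entry in vocabulary:
        for syn in entry.synonyms:
            sim = _best_window_similarity(tokens, syn)
            if sim > best_sim:
                best_value, best_sim = entry.canonical_value, sim
    if best_sim < threshold:
        return FieldCandidate(vocabulary.variable_id, UNMATCHED, best_sim)
    return FieldCandidate(vocabulary.variable_id, best_value, best_sim)


def find_date_candidates(text: RawText) -> tuple[DateCandidate, ...]:
    """All well-formed date patterns, in reading order.

    Accepts ``d{1,2} sep d{1,2}`` optionally followed by the same separator
    and a 2- or 4-digit year; the day must be 1–31 and the month 1–12.
    Mixed-separator forms (``05/12-17``) and patterns glued to further
    separator+digit material are rejected outright rather than truncated —
    they are likelier lot codes than dates.  Two-digit years map to 2000+yy.
    """
    out: list[DateCandidate] = []
    raw = text.text
    for m in _DATE_RE.finditer(raw):
        day, sep, month = int(m.group(1)), m.group(2), int(m.group(3))
        year_sep, year_str = m.group(4), m.group(5)
        if year_str is not None and year_sep != sep:
            continue  # mixed separators
        tail = raw[m.end() : m.end() + 2]
        if len(tail) == 2 and tail[0] in "/-." and tail[1].isdigit():
            continue  # glued to more separated digits: not a clean date
        if not (1 <= day <= 31 and 1 <= month <= 12):
            continue
        year = None
        if year_str is not None:
            year = int(year_str)
            if len(year_str) == 2:
                year += 2000
        out.append(DateCandidate(day, month, year, sep))
    return tuple(out)


def detect_purification(
    text: RawText,
    keywords: tuple[str, ...],
    threshold_purif: float = PURIFICATION_THRESHOLD,
) -> bool:
    """True iff any purification keyword fuzzily appears in the text."""
    if not keywords:
        raise ValueError("purification keyword list is empty")
    tokens = normalize_text(text.text).split()
    return any(
        _best_window_similarity(tokens, kw) >= threshold_purif for kw in keywords
    )


@dataclass(frozen=True)
class ExtractionThresholds:
    field: float = FIELD_THRESHOLD
    purification: float = PURIFICATION_THRESHOLD

    def __post_init__(self) -> None:
        for name in ("field", "purification"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"threshold {name} must be in [0, 1], got {v}")


def extract_all(
    text: RawText,
    vocabularies: dict[str, Vocabulary],
    purification_keywords: tuple[str, ...],
    thresholds: ExtractionThresholds = ExtractionThresholds(),
) -> VariantExtraction:
    """Full extraction for one variant: all fields, dates, purification."""
    fields = {
        vid: match_field(text, vocab, thresholds.field)
        for vid, vocab in vocabularies.items()
    }
    return VariantExtraction(
        variant_tag=text.variant_tag,
        fields=fields,
        date_candidates=find_date_candidates(text),
        purification_detected=detect_purification(
            text, purification_keywords, thresholds.purification
        ),
    )
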