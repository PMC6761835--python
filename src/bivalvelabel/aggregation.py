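"""Merging the three variant extractions into one label reading.

Each preprocessed variant (greyscale, sharpened, blurred) decodes the label
independently; this module combines them.  Categorical fields take the
candidate with the highest similarity; day and month are each decided by
plurality vote over the variants that produced a date; the year is taken
from print when present, else inferred from a caller-supplied reference
date under the rule that a packaging date is never in the future (a
December date read in January belongs to the previous year).  Purification
is merged by logical OR — it is binary and the strict per-variant threshold
already guards false positives.

Ties — in the categorical merge and in the vote — are broken by a fixed
variant precedence: greyscale > sharpened > blurred.
"""

from __future__ import annotations

import datetime
from collections import Counter
from dataclasses import dataclass

from bivalvelabel.extraction import UNMATCHED, FieldCandidate, VariantExtraction

#: Merge precedence: earlier wins ties.
VARIANT_PRECEDENCE = ("greyscale", "sharpened", "blurred")

YEAR_PRINTED = "printed"
YEAR_INFERRED_CURRENT = "inferred_current"
YEAR_INFERRED_PREVIOUS = "inferred_previous"

#: Fields required on the label by food-labelling rules; a reading that
#: decodes them all is 'complete'.
REQUIRED_FIELDS = ("species", "method", "country")


class AggregationError(ValueError):
    pass


@dataclass(frozen=True)
class ReadDate:
    day: int
    month: int
    year: int
    year_source: str
    valid: bool = True


@dataclass(frozen=True)
class LabelReading:
    """The final decode of one label photograph.

    ``complete`` — all regulation-required fields (species, production
    method, country, packaging date) were decoded.  ``extra`` — consumer-
    usable non-required data was decoded: a classified production-area code
    or a purification mention.
    """

    fields: dict[str, FieldCandidate]
    purification: bool
    date: ReadDate | None
    complete: bool
    extra: bool

    def value(self, variable_id: str) -> str:
        return self.fields[variable_id].value


def _precedence(tag: str) -> int:
    return VARIANT_PRECEDENCE.index(tag)


def merge_categorical(candidates: dict[str, FieldCandidate]) -> FieldCandidate:
    """Highest-similarity merge of one field across the three variants.

    Matched candidates always beat unmatched ones; among equals the variant
    precedence decides.  All-unmatched merges to unmatched, keeping the best
    similarity seen.
    """
    if len(candidates) != 3 or set(candidates) != set(VARIANT_PRECEDENCE):
        raise AggregationError(
            f"expected one candidate per variant {VARIANT_PRECEDENCE}, got {sorted(candidates)}"
        )
    ids = {c.variable_id for c in candidates.values()}
    if len(ids) != 1:
        raise AggregationError(f"mixed variable_ids in merge: {sorted(ids)}")
    best = max(
        candidates.items(),
        key=lambda kv: (kv[1].matched, kv[1].similarity, -_precedence(kv[0])),
    )
    return best[1]


def vote_date(
    votes: dict[str, tuple[int, int] | None],
) -> tuple[int, int] | None:
    """Plurality vote on day and month, independently, over present votes.

    Day and month are voted separately, so the winning pair may mix
    variants.  A tie goes to the value voted by the highest-precedence
    variant among the tied values; all-absent yields absent.
    """
    present = [
        (tag, dm) for tag in VARIANT_PRECEDENCE if (dm := votes.get(tag)) is not None
    ]
    if not present:
        return None

    def elect(index: int) -> int:
        counts = Counter(dm[index] for _, dm in present)
        top = max(counts.values())
        tied = {value for value, n in counts.items() if n == top}
        for tag, dm in present:  # precedence order
            if dm[index] in tied:
                return dm[index]
        raise AssertionError("unreachable")

    return elect(0), elect(1)


def _valid_date(day: int, month: int, year: int) -> bool:
    try:
        datetime.date(year, month, day)
        return True
    except ValueError:
        return False


def infer_year(
    day: int,
    month: int,
    explicit_year: int | None,
    reference_date: datetime.date,
) -> tuple[int, str, bool]:
    """Resolve the packaging year for a day/month reading.

    A printed year always wins.  Otherwise the reference year is assumed,
    except when that would place the packaging date in the future — then the
    previous year is used (a December date read in January).  Returns
    ``(year, year_source, valid)``; ``valid`` is False when the day/month
    pair exists in no candidate year (e.g. 31/02).
    """
    if not (1 <= day <= 31 and 1 <= month <= 12):
        raise ValueError(f"invalid day/month: {day}/{month}")
    if explicit_year is not None:
        return explicit_year, YEAR_PRINTED, _valid_date(day, month, explicit_year)
    year = reference_date.year
    if _valid_date(day, month, year) and datetime.date(year, month, day) <= reference_date:
        return year, YEAR_INFERRED_CURRENT, True
    if _valid_date(day, month, year - 1):
        return year - 1, YEAR_INFERRED_PREVIOUS, True
    # Future-only or calendar-impossible in both candidate years.
    if _valid_date(day, month, year):
        return year - 1, YEAR_INFERRED_PREVIOUS, False
    return year, YEAR_INFERRED_CURRENT, False


def aggregate(
    extractions: list[VariantExtraction] | tuple[VariantExtraction, ...],
    reference_date: datetime.date,
) -> LabelReading:
    """Combine the three variant extractions into the final reading."""
    tags = [e.variant_tag for e in extractions]
    if sorted(tags) != sorted(VARIANT_PRECEDENCE):
        raise AggregationError(f"need the three distinct variants, got {tags}")
    by_tag = {e.variant_tag: e for e in extractions}

    variable_ids = extractions[0].fields.keys()
    fields = {
        vid: merge_categorical({tag: by_tag[tag].fields[vid] for tag in by_tag})
        for vid in variable_ids
    }
    purification = any(e.purification_detected for e in extractions)

    date: ReadDate | None = None
    day_month = vote_date(
        {
            tag: (v.day, v.month) if (v := by_tag[tag].date_vote) is not None else None
            for tag in by_tag
        }
    )
    if day_month is not None:
        day, month = day_month
        # The printed year follows the same merge logic: the year printed on
        # the highest-precedence variant whose vote survived.
        explicit = None
        for tag in VARIANT_PRECEDENCE:
            v = by_tag[tag].date_vote
            if v is not None and v.explicit_year is not None:
                explicit = v.explicit_year
                break
        year, source, valid = infer_year(day, month, explicit, reference_date)
        date = ReadDate(day, month, year, source, valid)

    complete = (
        all(fields[vid].matched for vid in REQUIRED_FIELDS if vid in fields)
        and date is not None
        and date.valid
    )
    extra = ("zone" in fields and fields["zone"].matched) or purification
    return LabelReading(fields, purification, date, complete, extra)
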