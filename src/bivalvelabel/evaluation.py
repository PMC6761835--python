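"""Scoring pipeline readings and auditing label completeness.

Two report families:

* :func:`score_batch` compares pipeline readings with ground truth and
  yields per-field exact-match accuracies, the date scored both as
  components (day and month pooled separately) and as a whole (both
  correct), and an overall micro-average over all evaluable field
  instances (the date contributes its two components).  Fields absent from
  a truth record — a label that never printed a zone code — are excluded
  from that field's denominator: missing data is not a wrong read.
* :func:`completeness_audit` cross-tabulates decoded records by country of
  origin, presence of a classified-production-area code and purification
  mention, and derives the headline shares a labelling audit reports: how
  many labels carry consumer-usable extra information.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from bivalvelabel.aggregation import LabelReading
from bivalvelabel.labelgen import LabelGroundTruth

CATEGORICAL_FIELDS = ("species", "zone", "method", "country")


@dataclass(frozen=True)
class FieldScore:
    n_evaluable: int
    n_correct: int

    @property
    def accuracy_pct(self) -> float | None:
        if self.n_evaluable == 0:
            return None
        return 100.0 * self.n_correct / self.n_evaluable


@dataclass(frozen=True)
class EvaluationReport:
    """Per-field and aggregate accuracies for one batch of readings."""

    fields: dict[str, FieldScore]
    date_components: FieldScore
    date_whole: FieldScore
    purification: FieldScore
    overall: FieldScore

    @property
    def overall_pct(self) -> float | None:
        return self.overall.accuracy_pct

    def to_frame(self) -> pd.DataFrame:
        rows = {vid: s for vid, s in self.fields.items()}
        rows["date_components"] = self.date_components
        rows["date_whole"] = self.date_whole
        rows["purification"] = self.purification
        rows["overall"] = self.overall
        return pd.DataFrame(
            {
                "n_evaluable": {k: s.n_evaluable for k, s in rows.items()},
                "n_correct": {k: s.n_correct for k, s in rows.items()},
                "accuracy_pct": {k: s.accuracy_pct for k, s in rows.items()},
            }
        )


def _truth_value(truth: LabelGroundTruth, vid: str) -> str | None:
    if vid == "species":
        return truth.species
    if vid == "zone":
        return truth.zone_code
    if vid == "method":
        return truth.method
    if vid == "country":
        return truth.country
    raise KeyError(vid)


def score_batch(
    readings: list[LabelReading], truths: list[LabelGroundTruth]
) -> EvaluationReport:
    """Exact-match scoring of aligned readings against ground truth."""
    if len(readings) != len(truths):
        raise ValueError(
            f"readings ({len(readings)}) and truths ({len(truths)}) must align one-to-one"
        )
    field_scores = {vid: [0, 0] for vid in CATEGORICAL_FIELDS}
    day = [0, 0]
    month = [0, 0]
    whole = [0, 0]
    purif = [0, 0]

    for reading, truth in zip(readings, truths):
        for vid in CATEGORICAL_FIELDS:
            expected = _truth_value(truth, vid)
            if expected is None:
                continue
            field_scores[vid][0] += 1
            cand = reading.fields.get(vid)
            if cand is not None and cand.matched and cand.value == expected:
                field_scores[vid][1] += 1
        day[0] += 1
        month[0] += 1
        whole[0] += 1
        got = reading.date
        day_ok = got is not None and got.day == truth.pack_day
        month_ok = got is not None and got.month == truth.pack_month
        day[1] += day_ok
        month[1] += month_ok
        whole[1] += day_ok and month_ok
        purif[0] += 1
        purif[1] += reading.purification == truth.purified

    fields = {vid: FieldScore(*field_scores[vid]) for vid in CATEGORICAL_FIELDS}
    date_components = FieldScore(day[0] + month[0], day[1] + month[1])
    date_whole = FieldScore(whole[0], whole[1])
    purification = FieldScore(*purif)
    overall = FieldScore(
        sum(s.n_evaluable for s in fields.values())
        + date_components.n_evaluable
        + purification.n_evaluable,
        sum(s.n_correct for s in fields.values())
        + date_components.n_correct
        + purification.n_correct,
    )
    return EvaluationReport(fields, date_components, date_whole, purification, overall)


def separator_accuracy(
    readings: list[LabelReading], truths: list[LabelGroundTruth]
) -> dict[str, float]:
    """Whole-date accuracy stratified by the printed separator dialect.

    Separators with no labels in the batch are omitted, never reported as
    0% — absence is not failure.
    """
    if len(readings) != len(truths):
        raise ValueError("readings and truths must align one-to-one")
    totals: dict[str, list[int]] = {}
    for reading, truth in zip(readings, truths):
        bucket = totals.setdefault(truth.date_separator, [0, 0])
        bucket[0] += 1
        got = reading.date
        bucket[1] += (
            got is not None
            and got.day == truth.pack_day
            and got.month == truth.pack_month
        )
    return {sep: 100.0 * ok / n for sep, (n, ok) in sorted(totals.items())}


def variant_table(
    per_variant_readings: dict[str, list[LabelReading]],
    combined_readings: list[LabelReading],
    truths: list[LabelGroundTruth],
) -> pd.DataFrame:
    """Accuracy table with one column per variant plus the combined column."""
    columns = {}
    for tag, readings in per_variant_readings.items():
        columns[tag] = score_batch(readings, truths).to_frame()["accuracy_pct"]
    columns["combined"] = score_batch(combined_readings, truths).to_frame()["accuracy_pct"]
    return pd.DataFrame(columns)


@dataclass(frozen=True)
class CompletenessReport:
    """Cross-tabulation of decoded labels by origin, zone and purification."""

    table: pd.DataFrame
    n_labels: int
    zone_presence_pct: float
    usable_extra_pct: float
    origin_shares_pct: dict[str, float]
    zone_presence_by_country_pct: dict[str, float]

    @property
    def non_portugal_pct(self) -> float:
        return 100.0 - self.origin_shares_pct.get("portugal", 0.0)


def completeness_audit(records: list[LabelGroundTruth]) -> CompletenessReport:
    """Audit what information the labels actually carry.

    A record counts as having consumer-usable extra information iff it
    carries a classified-production-area code or mentions purification;
    with the packaging date (always required), either suffices to look up
    official monitoring results for the product.
    """
    if not records:
        raise ValueError("cannot audit an empty record collection")
    rows = []
    for r in records:
        has_zone = r.zone_code is not None
        rows.append(
            {
                "country": r.country,
                "has_zone": has_zone,
                "purified": r.purified,
                "extra": has_zone or r.purified,
            }
        )
    df = pd.DataFrame(rows)
    table = (
        df.groupby(["country", "has_zone", "purified"])
        .size()
        .unstack(["has_zone", "purified"], fill_value=0)
        .sort_index()
    )
    n = len(df)
    by_country = df.groupby("country")
    return CompletenessReport(
        table=table,
        n_labels=n,
        zone_presence_pct=100.0 * df["has_zone"].mean(),
        usable_extra_pct=100.0 * df["extra"].mean(),
        origin_shares_pct={c: 100.0 * len(g) / n for c, g in by_country},
        zone_presence_by_country_pct={
            c: 100.0 * g["has_zone"].mean() for c, g in by_country
        },
    )
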