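import datetime

import pytest
from hypothesis import settings

from bivalvelabel.extraction import ExtractionThresholds, FieldCandidate
from bivalvelabel.aggregation import LabelReading, ReadDate
from bivalvelabel.vocab import load_default_vocabularies, load_purification_keywords

settings.register_profile("ci", derandomize=True, max_examples=200)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def vocabularies():
    return load_default_vocabularies()


@pytest.fixture(scope="session")
def purification_keywords():
    return load_purification_keywords()


@pytest.fixture(scope="session")
def thresholds():
    return ExtractionThresholds()


@pytest.fixture(scope="session")
def reference_date():
    # End of the collection window: every sampled packaging date is in the past.
    return datetime.date(2017, 12, 31)


def perfect_reading(truth, reference_date=datetime.date(2017, 12, 31)):
    """Hand-built reading equal to a ground-truth record (for scorer tests)."""
    fields = {
        "species": FieldCandidate("species", truth.species, 1.0),
        "zone": FieldCandidate("zone", truth.zone_code, 1.0)
        if truth.zone_code
        else FieldCandidate("zone", "unmatched", 0.0),
        "method": FieldCandidate("method", truth.method, 1.0),
        "country": FieldCandidate("country", truth.country, 1.0),
    }
    printed = truth.printed_year_style != "none"
    date = ReadDate(
        truth.pack_day,
        truth.pack_month,
        truth.pack_year,
        "printed" if printed else "inferred_current",
    )
    return LabelReading(
        fields=fields,
        purification=truth.purified,
        date=date,
        complete=True,
        extra=truth.zone_code is not None or truth.purified,
    )
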