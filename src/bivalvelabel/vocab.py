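"""Controlled vocabularies for label field extraction.

Each extractable categorical variable (species, classified production area,
production method, country of production) is matched against a small
controlled vocabulary.  An entry maps a canonical value to the surface forms
that may appear in print — e.g. a species has both its Portuguese common name
and its Latin binomial.

Vocabulary files are UTF-8, tab-separated, one entry per line::

    canonical_value<TAB>synonym<TAB>synonym...

Blank lines and lines starting with ``#`` are ignored.  Synonyms are stored
pre-normalized (see :func:`normalize_text`); two entries may never share a
normalized synonym, since matching would then be ambiguous.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

VARIABLE_IDS = ("species", "zone", "method", "country")

_NON_ALNUM = re.compile(r"[^0-9a-z]+")


class VocabularyError(ValueError):
    """Raised for malformed or inconsistent vocabulary configuration."""


def normalize_text(raw: str) -> str:
    """Normalize text for fuzzy matching.

    Lowercases, strips diacritics via Unicode decomposition, collapses every
    run of punctuation or whitespace to a single space and trims the ends.
    OCR output is inconsistent on case and accents, so matching happens in
    this normalized space.  The function is idempotent.
    """
    decomposed = unicodedata.normalize("NFKD", raw.lower())
    stripped = "".join(c for c in decomposed if not unicodedata.combining(c))
    return _NON_ALNUM.sub(" ", stripped).strip()


@dataclass(frozen=True)
class VocabularyEntry:
    """One canonical value with its printable surface forms.

    ``synonyms`` are the normalized forms used for matching;
    ``surface_forms`` keep the original spelling (case, diacritics) for
    rendering and round-tripping.
    """

    canonical_value: str
    synonyms: tuple[str, ...]
    surface_forms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.surface_forms:
            object.__setattr__(self, "surface_forms", self.synonyms)
        if not self.synonyms:
            raise VocabularyError(
                f"entry {self.canonical_value!r} has no synonyms"
            )
        if any(not s for s in self.synonyms):
            raise VocabularyError(
                f"entry {self.canonical_value!r} has an empty synonym after normalization"
            )


@dataclass(frozen=True)
class Vocabulary:
    """An ordered, collision-free set of entries for one variable."""

    variable_id: str
    entries: tuple[VocabularyEntry, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.entries:
            raise VocabularyError(f"vocabulary {self.variable_id!r} is empty")
        seen: dict[str, str] = {}
        for entry in self.entries:
            for syn in entry.synonyms:
                if syn in seen and seen[syn] != entry.canonical_value:
                    raise VocabularyError(
                        f"vocabulary {self.variable_id!r}: synonym {syn!r} is shared "
                        f"by entries {seen[syn]!r} and {entry.canonical_value!r}"
                    )
                seen[syn] = entry.canonical_value

    @property
    def canonical_values(self) -> tuple[str, ...]:
        return tuple(e.canonical_value for e in self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


def _parse_lines(lines: Iterable[str], variable_id: str) -> Vocabulary:
    entries: list[VocabularyEntry] = []
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = [p for p in line.split("\t") if p.strip()]
        if len(parts) < 2:
            raise VocabularyError(
                f"vocabulary {variable_id!r} line {lineno}: expected "
                f"'canonical<TAB>synonym...', got {line!r}"
            )
        canonical = parts[0].strip()
        surfaces = tuple(dict.fromkeys(p.strip() for p in parts[1:]))
        synonyms = tuple(dict.fromkeys(normalize_text(p) for p in surfaces))
        entries.append(VocabularyEntry(canonical, synonyms, surfaces))
    if not entries:
        raise VocabularyError(f"vocabulary {variable_id!r} has no entries")
    return Vocabulary(variable_id, tuple(entries))


def load_vocabulary(source: str | Path, variable_id: str) -> Vocabulary:
    """Load a vocabulary from a file path or from raw config text.

    ``source`` may be a :class:`~pathlib.Path` (read as UTF-8) or a string;
    a string containing no tab and naming an existing file is also treated
    as a path.  Entry order is the file order.
    """
    if isinstance(source, Path):
        text = source.read_text(encoding="utf-8")
    elif "\t" not in source and "\n" not in source and Path(source).is_file():
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = source
    return _parse_lines(text.splitlines(), variable_id)


def dump_vocabulary(vocabulary: Vocabulary) -> str:
    """Serialize a vocabulary back to the config format (round-trips)."""
    lines = [
        "\t".join((entry.canonical_value, *entry.surface_forms))
        for entry in vocabulary.entries
    ]
    return "\n".join(lines) + "\n"


def bundled_vocabulary_path(variable_id: str) -> Path:
    """Path of the vocabulary file shipped with the package."""
    base = resources.files("bivalvelabel").joinpath("data", "vocab")
    return Path(str(base.joinpath(f"{variable_id}.tsv")))


def load_default_vocabularies() -> dict[str, Vocabulary]:
    """Load the bundled vocabularies for all four categorical variables.

    The species list covers the nine taxa found on Portuguese retail bivalve
    labels, each with a Portuguese common name and a Latin binomial.  The
    zone list is a plausible set of Portuguese/Galician classified
    production-area codes; real deployments supply their own zone file.
    """
    return {
        vid: load_vocabulary(bundled_vocabulary_path(vid), vid)
        for vid in VARIABLE_IDS
    }


def load_purification_keywords() -> tuple[str, ...]:
    """Normalized keywords whose presence indicates a purification mention."""
    base = resources.files("bivalvelabel").joinpath("data", "vocab")
    text = base.joinpath("purification.txt").read_text(encoding="utf-8")
    keywords = tuple(
        normalize_text(line)
        for line in text.splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    )
    if not keywords:
        raise VocabularyError("purification keyword list is empty")
    return keywords
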