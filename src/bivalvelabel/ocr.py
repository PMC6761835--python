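"""Pluggable OCR stage.

Two backends share one contract:

* :class:`TesseractBackend` adapts the real Tesseract engine (Portuguese
  language pack, sparse-text page segmentation, alphabet whitelist).  It is
  optional: constructing it without ``pytesseract`` installed raises an
  explicit environment error, never a silent empty result.
* :class:`SimulatedBackend` replays a known ground-truth text through a
  seeded character-level error model (substitutions from a confusion table,
  deletions, insertions).  It makes every downstream stage — extraction,
  aggregation, evaluation — testable with no engine installed and with
  exactly controlled noise.

Both return text restricted to the configured alphabet plus whitespace.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Portuguese alphabet (both cases, accented vowels and ç), digits and the
#: three date separators.
PORTUGUESE_ALPHABET = (
    "abcdefghijklmnopqrstuvwxyz"
    "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    "áàâãéêíóôõúçÁÀÂÃÉÊÍÓÔÕÚÇ"
    "0123456789"
    "/-.:,"
)

#: Misreads an OCR engine plausibly makes on printed labels.
DEFAULT_CONFUSION = {
    "l": "1i",
    "1": "li",
    "i": "1l",
    "o": "0",
    "0": "oO",
    "O": "0",
    "s": "5",
    "S": "5",
    "5": "sS",
    "b": "6",
    "B": "8",
    "8": "B",
    "g": "9",
    "z": "2",
    "Z": "2",
    "e": "c",
    "c": "e",
    "u": "v",
    "v": "u",
    "m": "n",
    "n": "m",
    "/": "-.",
    "-": "/.",
    ".": "/-",
}


class OCREnvironmentError(RuntimeError):
    """The requested OCR engine is not available in this environment."""


@dataclass(frozen=True)
class OCREngineConfig:
    """Engine configuration shared by all backends."""

    allowed_alphabet: str = PORTUGUESE_ALPHABET
    layout_mode: str = "sparse_text"
    language: str = "por"

    def __post_init__(self) -> None:
        if not self.allowed_alphabet:
            raise ValueError("allowed_alphabet must be non-empty")
        if self.layout_mode not in ("sparse_text", "block_text"):
            raise ValueError(f"unknown layout_mode {self.layout_mode!r}")


@dataclass(frozen=True)
class RawText:
    """Recognized text from one preprocessed variant."""

    text: str
    variant_tag: str

    def __post_init__(self) -> None:
        if self.variant_tag not in ("greyscale", "sharpened", "blurred"):
            raise ValueError(f"unknown variant_tag {self.variant_tag!r}")


@dataclass(frozen=True)
class ErrorModel:
    """Character-level OCR noise: substitution, deletion, insertion.

    Substituted characters are drawn from the confusion table when the
    character has plausible misreads, otherwise uniformly from the alphabet.
    Whitespace is never substituted (layout survives; characters do not).
    All corruption is reproducible from ``seed``.
    """

    substitution_rate: float = 0.0
    deletion_rate: float = 0.0
    insertion_rate: float = 0.0
    confusion_table: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_CONFUSION))
    alphabet: str = PORTUGUESE_ALPHABET
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "deletion_rate", "insertion_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {rate}")

    @classmethod
    def from_cer(cls, cer: float, seed: int = 0) -> "ErrorModel":
        """Model with total character error rate ``cer``: 60% substitutions,
        20% deletions, 20% insertions."""
        return cls(
            substitution_rate=0.6 * cer,
            deletion_rate=0.2 * cer,
            insertion_rate=0.2 * cer,
            seed=seed,
        )

    def with_seed(self, seed: int) -> "ErrorModel":
        return ErrorModel(
            self.substitution_rate,
            self.deletion_rate,
            self.insertion_rate,
            self.confusion_table,
            self.alphabet,
            seed,
        )

    def derive(self, tag: str) -> "ErrorModel":
        """Variant-specific sub-model so the three variants err independently."""
        return self.with_seed((self.seed * 1000003 + zlib.crc32(tag.encode())) % (2**31))


def simulate_ocr(truth_text: str, model: ErrorModel, variant_tag: str = "greyscale") -> RawText:
    """Corrupt ``truth_text`` character-wise per the error model.

    Deterministic given ``(truth_text, model)``: the generator is seeded from
    the model seed and a hash of the text.
    """
    seed = (model.seed * 2654435761 + zlib.crc32(truth_text.encode())) % (2**31)
    rng = np.random.default_rng(seed)
    alphabet = list(model.alphabet)
    out: list[str] = []
    for ch in truth_text:
        if model.deletion_rate and rng.random() < model.deletion_rate:
            continue
        if (
            not ch.isspace()
            and model.substitution_rate
            and rng.random() < model.substitution_rate
        ):
            options = model.confusion_table.get(ch)
            if options:
                ch = options[rng.integers(len(options))]
            else:
                ch = alphabet[rng.integers(len(alphabet))]
        out.append(ch)
        if model.insertion_rate and rng.random() < model.insertion_rate:
            out.append(alphabet[rng.integers(len(alphabet))])
    return RawText("".join(out), variant_tag)


def _filter_alphabet(text: str, config: OCREngineConfig) -> str:
    allowed = set(config.allowed_alphabet)
    return "".join(c for c in text if c in allowed or c.isspace())


class SimulatedBackend:
    """OCR stand-in that replays a ground-truth text through an error model.

    The backend does not perform recognition on pixels: it is constructed
    with the text truly present on the label (the renderer's ``layout_text``
    or a sidecar file) and returns it corrupted per the model, independently
    per variant.  ``truth_text=None`` recognizes everything as empty (a blank
    image).
    """

    name = "simulated"

    def __init__(self, truth_text: str | None, model: ErrorModel | None = None):
        self.truth_text = truth_text
        self.model = model if model is not None else ErrorModel()

    def recognize_text(self, image: np.ndarray, variant_tag: str) -> str:
        if self.truth_text is None:
            return ""
        return simulate_ocr(self.truth_text, self.model.derive(variant_tag), variant_tag).text


class TesseractBackend:
    """Adapter for the Tesseract engine via pytesseract.

    Maps ``sparse_text`` to page-segmentation mode 11 and ``block_text`` to
    mode 6, and enforces the alphabet via the engine whitelist.
    """

    name = "tesseract"
    _PSM = {"sparse_text": 11, "block_text": 6}

    def __init__(self, config: OCREngineConfig):
        try:
            import pytesseract  # type: ignore[import-not-found]
        except ImportError as exc:  # pragma: no cover - engine not in test env
            raise OCREnvironmentError(
                "OCR backend 'tesseract' requires the pytesseract package and a "
                "tesseract installation with the Portuguese language pack"
            ) from exc
        self._pytesseract = pytesseract
        self.config = config

    def recognize_text(self, image: np.ndarray, variant_tag: str) -> str:  # pragma: no cover
        from PIL import Image

        psm = self._PSM[self.config.layout_mode]
        whitelist = self.config.allowed_alphabet.replace('"', "")
        tess_config = f'--psm {psm} -c tessedit_char_whitelist="{whitelist} "'
        return self._pytesseract.image_to_string(
            Image.fromarray(image), lang=self.config.language, config=tess_config
        )


def recognize(
    image: np.ndarray,
    config: OCREngineConfig,
    backend,
    variant_tag: str = "greyscale",
) -> RawText:
    """Run one preprocessed variant through an OCR backend.

    Output contains only characters from the allowed alphabet plus
    whitespace, whichever backend produced it.  An empty recognition on a
    non-empty image is logged as a warning.
    """
    text = _filter_alphabet(backend.recognize_text(image, variant_tag), config)
    if not text.strip():
        logger.warning("OCR produced no text for variant %s", variant_tag)
    return RawText(text, variant_tag)
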