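"""Text preprocessing: normalization, tokenization, stopword removal,
lemmatization.

The chain lowercases, strips punctuation and digit characters, collapses
whitespace, splits on whitespace, drops stopwords and maps each surviving
token through a static English lemma table (dictionary lookup; tokens
without an entry pass through unchanged, as do non-string elements). The
chain is idempotent and never injects vocabulary that was not derivable
from the input.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .synthetic import MedicineRecord

__all__ = [
    "TokenSequence",
    "DEFAULT_STOPWORDS",
    "DEFAULT_LEMMAS",
    "normalize_text",
    "tokenize",
    "remove_stopwords",
    "lemmatize",
    "preprocess_text",
    "preprocess_record",
    "load_stoplist",
    "TextPreprocessor",
]


@dataclass
class TokenSequence:
    """Ordered cleaned tokens from one text field."""

    tokens: list
    source_field: str = ""

    def __iter__(self):
        return iter(self.tokens)

    def __len__(self):
        return len(self.tokens)

    def __eq__(self, other):
        if isinstance(other, TokenSequence):
            return self.tokens == other.tokens
        return self.tokens == other


# A compact standard English stoplist; must cover at least the canonical
# examples "the", "or", "is".
DEFAULT_STOPWORDS = frozenset("""
a about above after again all am an and any are as at be because been
before being below between both but by could did do does doing down
during each few for from further had has have having he her here hers
him his how i if in into is it its itself just me more most my no nor
not now of off on once only or other our ours out over own same she so
some such than that the their theirs them then there these they this
those through to too under until up very was we were what when where
which while who whom why will with you your yours
""".split())

# Static lemma table: inflected form -> lemma. Built from a base vocabulary
# of domain-relevant nouns/verbs plus regular plural rules, so tests are
# hermetic (no model download).
_LEMMA_BASES = [
    "headache", "pain", "fever", "infection", "treatment", "tablet",
    "symptom", "cough", "disease", "drug", "medicine", "medication",
    "condition", "reaction", "effect", "dose", "cream", "syrup",
    "capsule", "vaccine", "injection", "allergy", "wound", "tumour",
    "relief", "cancer", "chill", "rash", "migraine", "antibiotic",
]

_IRREGULAR_LEMMAS = {
    "allergies": "allergy",
    "treated": "treat",
    "treats": "treat",
    "relieves": "relieve",
    "relieved": "relieve",
    "used": "use",
    "uses": "use",
    "reduces": "reduce",
    "reduced": "reduce",
}


def _build_default_lemmas() -> dict:
    table = dict(_IRREGULAR_LEMMAS)
    for base in _LEMMA_BASES:
        table[base + "s"] = base
        if base.endswith(("s", "x", "z", "ch", "sh")):
            table[base + "es"] = base
    return table


DEFAULT_LEMMAS: Mapping[str, str] = _build_default_lemmas()


def normalize_text(raw):
    """Lowercase, strip punctuation and digits, collapse whitespace.

    Hyphens inside words become spaces (conservative compound splitting).
    Non-string input is passed through unchanged.
    """
    if not isinstance(raw, str):
        return raw
    out = []
    for ch in raw.lower():
        if ch == "-":
            out.append(" ")
        elif ch.isdigit():
            continue
        elif unicodedata.category(ch).startswith("P"):
            continue
        else:
            out.append(ch)
    return " ".join("".join(out).split())


def tokenize(text: str, source_field: str = "") -> TokenSequence:
    """Whitespace tokenization of normalized text; order preserved."""
    if not isinstance(text, str) or not text:
        return TokenSequence([], source_field)
    return TokenSequence(text.split(), source_field)


def remove_stopwords(
    seq: TokenSequence | Sequence,
    stoplist: Iterable[str] = DEFAULT_STOPWORDS,
) -> TokenSequence:
    stop = set(stoplist)
    tokens = [t for t in seq if not (isinstance(t, str) and t in stop)]
    src = seq.source_field if isinstance(seq, TokenSequence) else ""
    return TokenSequence(tokens, src)


def lemmatize(
    seq: TokenSequence | Sequence,
    lexicon: Mapping[str, str] = DEFAULT_LEMMAS,
) -> TokenSequence:
    """Dictionary lemmatization; unknown tokens and non-string elements
    pass through unchanged."""
    out = []
    for t in seq:
        if isinstance(t, str):
            out.append(lexicon.get(t, t))
        else:
            out.append(t)
    src = seq.source_field if isinstance(seq, TokenSequence) else ""
    return TokenSequence(out, src)


def preprocess_text(
    raw: str,
    stoplist: Iterable[str] = DEFAULT_STOPWORDS,
    lexicon: Mapping[str, str] = DEFAULT_LEMMAS,
    source_field: str = "",
) -> TokenSequence:
    """Full chain: normalize -> tokenize -> stopwords -> lemmatize."""
    return lemmatize(
        remove_stopwords(
            tokenize(normalize_text(raw), source_field), stoplist),
        lexicon)


def preprocess_record(
    record: MedicineRecord,
    stoplist: Iterable[str] = DEFAULT_STOPWORDS,
    lexicon: Mapping[str, str] = DEFAULT_LEMMAS,
    process_side_effects: bool = False,
    process_composition: bool = False,
) -> MedicineRecord:
    """Replace the Uses field (and optionally Side_effects / Composition)
    with space-joined cleaned tokens; all other fields untouched."""
    if not isinstance(record.uses, str) or not record.uses.strip():
        raise ValueError(
            f"record {record.record_id}: Uses field is missing or empty")
    updates = {
        "uses": " ".join(preprocess_text(record.uses, stoplist, lexicon)),
    }
    if process_side_effects:
        updates["side_effects"] = " ".join(
            preprocess_text(record.side_effects, stoplist, lexicon))
    if process_composition:
        updates["composition"] = " ".join(
            preprocess_text(record.composition, stoplist, lexicon))
    return record.replace(**updates)


def load_stoplist(path) -> frozenset:
    """One lowercase word per line, UTF-8."""
    words = Path(path).read_text(encoding="utf-8").split()
    return frozenset(w.strip().lower() for w in words if w.strip())


class TextPreprocessor:
    """Transformer mapping raw strings to cleaned token lists.

    scikit-learn style: stateless apart from its parameters, so ``fit`` is
    a no-op; composes with downstream vectorizers.
    """

    def __init__(self, stoplist=DEFAULT_STOPWORDS, lexicon=DEFAULT_LEMMAS):
        self.stoplist = stoplist
        self.lexicon = lexicon

    def fit(self, X=None, y=None):
        return self

    def transform(self, X: Sequence[str]) -> list:
        return [
            list(preprocess_text(x, self.stoplist, self.lexicon)) for x in X
        ]

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)

    def get_params(self, deep=True):
        return {"stoplist": self.stoplist, "lexicon": self.lexicon}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self
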