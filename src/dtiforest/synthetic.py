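"""Synthetic medicine corpora and numeric feature tables with known ground truth.

The generator emulates the schema of a tabular medicine catalogue (name,
composition, free-text uses / side-effects, manufacturer, review-percentage
triplet) and plants class-informative tokens into the text fields so that
every downstream stage — preprocessing, n-gram featurization, wrapper
feature selection and hybrid classification — can be exercised against a
recoverable ground truth.
"""

from __future__ import annotations

import dataclasses
import string
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MedicineRecord",
    "CorpusSpec",
    "TableSpec",
    "generate_corpus",
    "generate_feature_table",
    "corpus_to_dataframe",
    "write_corpus_csv",
    "read_corpus_csv",
    "CLASS_NAMES",
]

#: Condition classes mirrored by the generator's label space.
CLASS_NAMES = ("cough", "pain", "cancer", "fever", "infections")

# Planted vocabulary themed on frequent drug-description terms; sets for
# distinct classes must stay disjoint (checked at generation time).
_THEME_WORDS = {
    "cough": [
        "cough", "bronchitis", "expectorant", "mucus", "syrup",
        "congestion", "throat", "wheezing", "phlegm", "respiratory",
        "inhaler", "asthma",
    ],
    "pain": [
        "pain", "relief", "headache", "analgesic", "neuropathic",
        "migraine", "arthritis", "backache", "inflammation", "sprain",
        "muscular", "toothache",
    ],
    "cancer": [
        "cancer", "tumour", "chemotherapy", "oncology", "carcinoma",
        "leukemia", "metastasis", "malignant", "lymphoma", "radiation",
        "biopsy", "remission",
    ],
    "fever": [
        "fever", "antipyretic", "temperature", "chills", "paracetamol",
        "malaria", "typhoid", "sweating", "influenza", "shivering",
        "dengue", "pyrexia",
    ],
    "infections": [
        "infection", "antibiotic", "bacterial", "fungal", "antiseptic",
        "wound", "sepsis", "antiviral", "microbial", "abscess",
        "penicillin", "dermatitis",
    ],
}

_MANUFACTURERS = (
    "Sun Pharma", "Cipla Ltd", "Zydus Healthcare", "Alkem Labs",
    "Mankind Pharma", "Abbott",
)

_SIDE_EFFECT_WORDS = (
    "nausea", "dizziness", "vomiting", "drowsiness", "rash",
    "fatigue", "constipation", "insomnia",
)

_COMPOSITION_STEMS = (
    "paracetamol", "diclofenac", "aceclofenac", "cetirizine",
    "amoxycillin", "azithromycin", "pregabalin", "metformin",
)

# Exact column headers of the emulated catalogue CSV; `label` is an extra,
# optional column the reader tolerates being absent.
CSV_COLUMNS = (
    "Medicine Name", "Composition", "Uses", "Side_effects",
    "Image URL", "Manufacturer", "Excellent Review %",
    "Average Review %", "Poor Review %",
)


@dataclass
class MedicineRecord:
    """One row of the medicine catalogue."""

    record_id: int
    medicine_name: str
    composition: str
    uses: str
    side_effects: str
    manufacturer: str
    excellent_pct: float
    average_pct: float
    poor_pct: float
    image_url: str = ""
    label: Optional[int] = None

    def replace(self, **kwargs) -> "MedicineRecord":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class CorpusSpec:
    """Configuration for a synthetic medicine corpus.

    ``planted_token_prob`` is the per-token inclusion probability of each
    class-specific planted token in a document of that class; it is the
    separability dial of the corpus. ``noise_token_rate`` is the expected
    number of noise tokens per document (Poisson).
    """

    n_documents: int = 1000
    n_classes: int = 5
    planted_tokens_per_class: int = 3
    noise_vocab_size: int = 200
    planted_token_prob: float = 0.9
    noise_token_rate: float = 12.0
    inject_numerals_punct: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.n_classes > len(CLASS_NAMES):
            raise ValueError(
                f"n_classes must be <= {len(CLASS_NAMES)} (themed classes)")
        if self.planted_tokens_per_class < 1:
            raise ValueError("planted_tokens_per_class must be >= 1")
        if not (0.0 < self.planted_token_prob <= 1.0):
            raise ValueError("planted_token_prob must be in (0, 1]")
        if self.noise_token_rate < 0:
            raise ValueError("noise_token_rate must be >= 0")
        if self.n_documents < self.n_classes:
            raise ValueError("need at least one document per class")


@dataclass(frozen=True)
class TableSpec:
    """Configuration for a numeric feature table with planted informative
    columns, used to probe selector recovery."""

    n_samples: int = 800
    n_features: int = 50
    n_informative: int = 5
    effect_size: float = 3.0
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_informative > self.n_features:
            raise ValueError("n_informative must be <= n_features")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def planted_tokens(spec: CorpusSpec) -> list[list[str]]:
    """Disjoint planted-token sets, one list per class."""
    rng = np.random.default_rng(spec.seed + 1)
    out: list[list[str]] = []
    used: set[str] = set()
    for c in range(spec.n_classes):
        theme = CLASS_NAMES[c]
        words = list(_THEME_WORDS[theme])
        while len(words) < spec.planted_tokens_per_class:
            words.append(theme + _random_word(rng, 4))
        toks = words[: spec.planted_tokens_per_class]
        if used.intersection(toks):
            raise AssertionError("planted token sets must be disjoint")
        used.update(toks)
        out.append(toks)
    return out


def _random_word(rng: np.random.Generator, n: int) -> str:
    letters = np.array(list(string.ascii_lowercase))
    return "".join(rng.choice(letters, size=n))


def _noise_vocab(spec: CorpusSpec, reserved: set[str]) -> list[str]:
    rng = np.random.default_rng(spec.seed + 2)
    vocab: list[str] = []
    seen = set(reserved)
    while len(vocab) < spec.noise_vocab_size:
        w = _random_word(rng, int(rng.integers(4, 9)))
        if w not in seen:
            seen.add(w)
            vocab.append(w)
    return vocab


def _review_triplet(rng: np.random.Generator) -> tuple[int, int, int]:
    # Two uniform cutpoints on 0..100 -> three nonnegative parts summing to 100.
    a, b = sorted(rng.integers(0, 101, size=2))
    return int(a), int(b - a), int(100 - b)


def generate_corpus(spec: CorpusSpec) -> tuple[list[MedicineRecord], np.ndarray]:
    """Generate a labelled synthetic medicine corpus.

    Returns (records, labels). Labels are balanced across classes (counts
    differ by at most one) and each class's documents contain that class's
    planted tokens independently with probability ``planted_token_prob``.
    Identical specs produce identical corpora.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    planted = planted_tokens(spec)
    noise = _noise_vocab(spec, {t for toks in planted for t in toks})

    labels = np.array(
        [c % spec.n_classes for c in range(spec.n_documents)], dtype=int)
    rng.shuffle(labels)

    records: list[MedicineRecord] = []
    for i in range(spec.n_documents):
        c = int(labels[i])
        keep = rng.random(len(planted[c])) < spec.planted_token_prob
        tokens = [t for t, k in zip(planted[c], keep) if k]
        n_noise = int(rng.poisson(spec.noise_token_rate))
        if n_noise:
            tokens.extend(rng.choice(noise, size=n_noise).tolist())
        if not tokens:  # Uses must be nonempty
            tokens.append("treatment")
        order = rng.permutation(len(tokens))
        tokens = [tokens[j] for j in order]
        uses = " ".join(tokens)
        if spec.inject_numerals_punct:
            uses = f"Treatment of {uses}, 500 mg dose!"

        side = " ".join(
            rng.choice(_SIDE_EFFECT_WORDS,
                       size=int(rng.integers(1, 4)), replace=False))
        stem = str(rng.choice(_COMPOSITION_STEMS))
        dose = int(rng.choice([100, 250, 325, 500]))
        composition = f"{stem.title()} ({dose}mg)"
        name = f"{stem.title()}-{i} Tablet"
        exc, avg, poor = _review_triplet(rng)
        records.append(MedicineRecord(
            record_id=i,
            medicine_name=name,
            composition=composition,
            uses=uses,
            side_effects=side.capitalize(),
            manufacturer=str(rng.choice(_MANUFACTURERS)),
            excellent_pct=float(exc),
            average_pct=float(avg),
            poor_pct=float(poor),
            image_url=f"https://example.org/img/{i}.jpg",
            label=c,
        ))
    return records, labels


def generate_feature_table(
    spec: TableSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Numeric table with a planted logistic signal.

    X is standard-normal; y is Bernoulli with log-odds given by a logistic
    model on exactly ``n_informative`` columns whose coefficients have
    magnitude ``effect_size`` and random sign. Returns
    (X, y, informative_idx).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    X = rng.standard_normal((spec.n_samples, spec.n_features))
    informative = np.sort(rng.choice(
        spec.n_features, size=spec.n_informative, replace=False))
    signs = rng.choice([-1.0, 1.0], size=spec.n_informative)
    coef = signs * spec.effect_size
    logits = X[:, informative] @ coef
    if spec.noise_sd > 0:
        logits = logits + rng.normal(0.0, spec.noise_sd, size=spec.n_samples)
    p = 1.0 / (1.0 + np.exp(-logits))
    y = (rng.random(spec.n_samples) < p).astype(int)
    return X, y, informative


def corpus_to_dataframe(records: Sequence[MedicineRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "Medicine Name": r.medicine_name,
            "Composition": r.composition,
            "Uses": r.uses,
            "Side_effects": r.side_effects,
            "Image URL": r.image_url,
            "Manufacturer": r.manufacturer,
            "Excellent Review %": r.excellent_pct,
            "Average Review %": r.average_pct,
            "Poor Review %": r.poor_pct,
            "label": r.label,
        })
    return pd.DataFrame(rows)


def write_corpus_csv(records: Sequence[MedicineRecord], path) -> None:
    corpus_to_dataframe(records).to_csv(path, index=False)


def read_corpus_csv(path) -> tuple[list[MedicineRecord], Optional[np.ndarray]]:
    """Read a catalogue CSV; the `label` column is optional."""
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"corpus CSV missing columns: {missing}")
    has_label = "label" in df.columns
    records = []
    for i, row in df.iterrows():
        records.append(MedicineRecord(
            record_id=int(i),
            medicine_name=str(row["Medicine Name"]),
            composition=str(row["Composition"]),
            uses=str(row["Uses"]),
            side_effects=str(row["Side_effects"]),
            manufacturer=str(row["Manufacturer"]),
            excellent_pct=float(row["Excellent Review %"]),
            average_pct=float(row["Average Review %"]),
            poor_pct=float(row["Poor Review %"]),
            image_url=str(row.get("Image URL", "")),
            label=int(row["label"]) if has_label and pd.notna(row["label"]) else None,
        ))
    labels = None
    if has_label and all(r.label is not None for r in records):
        labels = np.array([r.label for r in records], dtype=int)
    return records, labels
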