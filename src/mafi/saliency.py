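"""Visual-saliency coding of phonemes and visemes, and informativeness loads.

Two levels of coding:

* phoneme features — frontness (bilabials /b p m/ and labio-dentals
  /f v/) and roundness (/r w u o ɔ/ plus any segment whose table "round"
  feature is +1, so length-marked and variant rounded vowels qualify);
* viseme classes — groups of phonemes that are visually indistinguishable
  on the mouth, each flagged with the lip gestures that make it salient:
  lower lip tuck ({f} = /f v/), protrusion ({ch} = /ʃ tʃ dʒ/ and
  {w} = /w/), labial closure ({p} = /b p m/), lip rounding ({j} = /j/,
  {r} = /r ɹ/, {w} = /w/).

A word's informativeness load is the number of salient segments divided by
its total segment count, computed separately at the phoneme and the viseme
level.
"""

from __future__ import annotations

import csv
import unicodedata
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .phonfeatures import Segment, Transcription

__all__ = [
    "SALIENCY_FEATURES",
    "FRONT_PHONEMES",
    "ROUND_PHONEMES",
    "VisemeInventory",
    "WordFeatureProfile",
    "load_viseme_inventory",
    "default_viseme_inventory",
    "phoneme_saliency",
    "viseme_of",
    "word_profile",
]

SALIENCY_FEATURES = frozenset(
    {"lower_lip_tuck", "protrusion", "labial_closure", "lip_rounding"}
)

FRONT_PHONEMES = frozenset("bpmfv")
ROUND_PHONEMES = frozenset({"r", "ɹ", "w", "u", "o", "ɔ"})

_LENGTH_MARKS = "ːˑ"


@dataclass(frozen=True)
class VisemeInventory:
    """Viseme classes and the saliency features each class carries."""

    classes: dict[str, frozenset[str]]  # viseme label -> member phonemes
    class_features: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for label, members in self.classes.items():
            for ph in members:
                if ph in seen:
                    raise ValueError(
                        f"phoneme {ph!r} in both {seen[ph]!r} and {label!r}"
                    )
                seen[ph] = label
        bad = set().union(*self.class_features.values()) - SALIENCY_FEATURES
        if bad:
            raise ValueError(f"unknown saliency feature(s): {sorted(bad)}")

    def label_of(self, symbol: str) -> str | None:
        for label, members in self.classes.items():
            if symbol in members:
                return label
        return None

    def salient_symbols(self) -> frozenset[str]:
        """Phonemes belonging to a class with at least one saliency feature."""
        out: set[str] = set()
        for label, members in self.classes.items():
            if self.class_features.get(label):
                out |= members
        return frozenset(out)


@dataclass(frozen=True)
class WordFeatureProfile:
    word: str
    has_frontness: bool
    has_roundness: bool
    has_lower_lip_tuck: bool
    has_protrusion: bool
    has_labial_closure: bool
    has_lip_rounding: bool
    load_phoneme: float
    load_viseme: float


def default_viseme_inventory() -> VisemeInventory:
    """The bundled default inventory (see module docstring)."""
    with resources.as_file(resources.files("mafi.data") / "visemes.csv") as fp:
        return load_viseme_inventory(fp)


def load_viseme_inventory(path: str | Path) -> VisemeInventory:
    """Read a viseme inventory from CSV (columns viseme,phoneme,features;
    features semicolon-separated)."""
    classes: dict[str, set[str]] = {}
    feats: dict[str, set[str]] = {}
    with open(path, encoding="utf-8-sig", newline="") as fh:
        for row in csv.DictReader(fh):
            label = row["viseme"].strip()
            ph = unicodedata.normalize("NFC", row["phoneme"].strip())
            classes.setdefault(label, set()).add(ph)
            fset = {
                f.strip() for f in (row.get("features") or "").split(";") if f.strip()
            }
            feats.setdefault(label, set()).update(fset)
    return VisemeInventory(
        classes={k: frozenset(v) for k, v in classes.items()},
        class_features={k: frozenset(v) for k, v in feats.items()},
    )


def _base_symbol(symbol: str) -> str:
    return symbol.rstrip(_LENGTH_MARKS)


def phoneme_saliency(seg: Segment, round_feature_value: int | None = None) -> dict:
    """Frontness/roundness flags for one segment.

    A segment is front iff its base symbol is a bilabial or labio-dental
    consonant; round iff its base symbol is in the listed rounded set or
    ``round_feature_value`` (the table's "round" feature) is +1. Unknown
    symbols are simply neither.
    """
    base = _base_symbol(seg.symbol)
    return {
        "front": base in FRONT_PHONEMES,
        "round": base in ROUND_PHONEMES or round_feature_value == 1,
    }


def viseme_of(seg: Segment, inv: VisemeInventory) -> str | None:
    """Viseme class label of a segment, or None if unclassified."""
    return inv.label_of(_base_symbol(seg.symbol))


def word_profile(
    t: Transcription,
    inv: VisemeInventory | None = None,
    round_feature_index: int | None = None,
) -> WordFeatureProfile:
    """Saliency profile and informativeness loads for one word.

    ``round_feature_index`` optionally points at the "round" feature in
    the segments' vectors so table-rounded vowels count as round.
    """
    if len(t) == 0:
        raise ValueError("cannot profile an empty transcription")
    inv = inv if inv is not None else default_viseme_inventory()

    n_front = n_round = 0
    feature_flags = {f: False for f in SALIENCY_FEATURES}
    n_salient_viseme = 0
    for seg in t:
        rv = seg.vector[round_feature_index] if round_feature_index is not None else None
        sal = phoneme_saliency(seg, rv)
        n_front += sal["front"]
        n_round += sal["round"]
        label = viseme_of(seg, inv)
        if label is not None:
            cls_feats = inv.class_features.get(label, frozenset())
            if cls_feats:
                n_salient_viseme += 1
                for f in cls_feats:
                    feature_flags[f] = True

    n = len(t)
    return WordFeatureProfile(
        word=t.word,
        has_frontness=n_front > 0,
        has_roundness=n_round > 0,
        has_lower_lip_tuck=feature_flags["lower_lip_tuck"],
        has_protrusion=feature_flags["protrusion"],
        has_labial_closure=feature_flags["labial_closure"],
        has_lip_rounding=feature_flags["lip_rounding"],
        load_phoneme=min(1.0, (n_front + n_round) / n),
        load_viseme=n_salient_viseme / n,
    )
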