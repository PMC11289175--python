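"""Articulatory feature system: feature tables, segments, and IPA tokenization.

An IPA segment is represented by a vector of ternary articulatory feature
values (+1 / 0 / -1) over a fixed feature inventory (syllabic, sonorant,
consonantal, continuant, voice, anterior, labial, high, back, round, ...).
Each feature carries a non-negative cost weight reflecting its phonological
class and variability; these weights drive the substitution costs used by
the distance module. A small table covering the English segment inventory
ships with the package, together with its weight file.
"""

from __future__ import annotations

import csv
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

__all__ = [
    "FeatureTable",
    "Segment",
    "Transcription",
    "load_feature_table",
    "default_feature_table",
    "tokenize_ipa",
]

_VALUE_MAP = {
    "+": 1,
    "-": -1,
    "−": -1,  # U+2212 minus sign
    "–": -1,  # en dash, seen in hand-edited tables
    "0": 0,
}


def _nfc(s: str) -> str:
    return unicodedata.normalize("NFC", s)


@dataclass(frozen=True)
class Segment:
    """One IPA segment with its articulatory feature vector."""

    symbol: str
    vector: tuple[int, ...]  # aligned with FeatureTable.features

    def __len__(self) -> int:  # number of features
        return len(self.vector)


@dataclass
class FeatureTable:
    """Feature inventory, per-segment vectors, and per-feature cost weights.

    Attributes
    ----------
    features : ordered feature names.
    segments : NFC-normalized IPA symbol -> Segment.
    weights : per-feature weight vector aligned with ``features``.
    """

    features: tuple[str, ...]
    segments: dict[str, Segment]
    weights: tuple[float, ...]
    _max_key_len: int = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.features):
            raise ValueError("one weight per feature required")
        if any(w < 0 for w in self.weights):
            raise ValueError("feature weights must be non-negative")
        for seg in self.segments.values():
            if len(seg.vector) != len(self.features):
                raise ValueError(
                    f"segment {seg.symbol!r} has {len(seg.vector)} values "
                    f"for {len(self.features)} features"
                )
        self._max_key_len = max((len(k) for k in self.segments), default=0)

    def weight(self, feature: str) -> float:
        return self.weights[self.features.index(feature)]

    def segment(self, symbol: str) -> Segment:
        return self.segments[_nfc(symbol)]

    def __contains__(self, symbol: str) -> bool:
        return _nfc(symbol) in self.segments

    @property
    def null_vector(self) -> tuple[int, ...]:
        return (0,) * len(self.features)


@dataclass(frozen=True)
class Transcription:
    """An ordered sequence of segments for one orthographic word."""

    word: str
    segments: tuple[Segment, ...]

    @property
    def ipa(self) -> str:
        """Concatenation of segment symbols; round-trips tokenization."""
        return "".join(s.symbol for s in self.segments)

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)


def _read_rows(path: str | Path) -> list[dict[str, str]]:
    with open(path, encoding="utf-8-sig", newline="") as fh:
        return list(csv.DictReader(fh))


def load_feature_table(path: str | Path, weights_path: str | Path) -> FeatureTable:
    """Load a feature table from a segments CSV and a weights CSV.

    The segments file has a first column ``ipa`` and one column per feature
    with values in {+, -, 0}; the weights file has columns
    ``feature,weight``. Features are reconciled by name, so the two files
    may list them in different orders, but the sets must agree.

    Raises
    ------
    ValueError
        On duplicate segments, wrong-arity rows, unparsable values, or a
        feature missing from either file.
    """
    seg_rows = _read_rows(path)
    if not seg_rows:
        raise ValueError(f"empty feature table: {path}")
    features = tuple(k for k in seg_rows[0].keys() if k != "ipa")

    weight_map: dict[str, float] = {}
    for row in _read_rows(weights_path):
        w = float(row["weight"])
        weight_map[row["feature"].strip()] = w
    missing = set(features) - set(weight_map)
    if missing:
        raise ValueError(f"missing weight for feature(s): {sorted(missing)}")
    extra = set(weight_map) - set(features)
    if extra:
        raise ValueError(f"weight file lists unknown feature(s): {sorted(extra)}")

    segments: dict[str, Segment] = {}
    for row in seg_rows:
        symbol = _nfc(row["ipa"].strip())
        if not symbol:
            raise ValueError("feature table row with empty ipa symbol")
        if symbol in segments:
            raise ValueError(f"duplicate segment row: {symbol!r}")
        vals = []
        for f in features:
            raw = (row[f] or "").strip()
            if raw not in _VALUE_MAP:
                raise ValueError(
                    f"segment {symbol!r}: bad value {raw!r} for feature {f!r}"
                )
            vals.append(_VALUE_MAP[raw])
        if None in row.values() or any(k is None for k in row):
            raise ValueError(f"segment {symbol!r}: wrong number of columns")
        segments[symbol] = Segment(symbol, tuple(vals))

    weights = tuple(weight_map[f] for f in features)
    return FeatureTable(features=features, segments=segments, weights=weights)


def default_feature_table() -> FeatureTable:
    """The bundled English feature table and weight file."""
    pkg = resources.files("mafi.data")
    with resources.as_file(pkg / "feature_table.csv") as fp, resources.as_file(
        pkg / "feature_weights.csv"
    ) as wp:
        return load_feature_table(fp, wp)


def tokenize_ipa(ipa: str, table: FeatureTable) -> Transcription:
    """Segment an IPA string by greedy longest match against the table.

    Affricates (tʃ) and base+length combinations (uː) that exist as table
    keys are kept as single segments. The concatenation of the output
    symbols reproduces the (NFC-normalized) input.

    Raises
    ------
    ValueError
        If some position cannot be matched by any table key; the message
        names the offending character and its position.
    """
    s = _nfc(ipa)
    segs: list[Segment] = []
    i = 0
    n = len(s)
    max_len = table._max_key_len
    while i < n:
        for length in range(min(max_len, n - i), 0, -1):
            cand = s[i : i + length]
            if cand in table.segments:
                segs.append(table.segments[cand])
                i += length
                break
        else:
            raise ValueError(
                f"unrecognized IPA at position {i}: {s[i]!r} (in {ipa!r})"
            )
    return Transcription(word=ipa, segments=tuple(segs))
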