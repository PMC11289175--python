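"""End-to-end norming pipeline: raw speechreading responses -> MaFI norms.

Input is a delimited table of typed guesses (one row per participant x
target word), plus a pronunciation lexicon mapping orthographic words to
IPA. Each transcribable (target, response) pair is scored with the
weighted feature edit distance and companion metrics; per-word norms
average over responses, and the MaFI score is the negated mean normalized
distance — 0 for a word every participant speechread perfectly, more
negative the less informative the word's mouth and facial movements are.

Words guessed in more than one study are first averaged within study and
the study-level means are then averaged, so no single large study
dominates a duplicate word's norm.
"""

from __future__ import annotations

import unicodedata
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .distance import DistanceResult, score_pair
from .phonfeatures import FeatureTable, Transcription, tokenize_ipa

__all__ = [
    "ResponseRecord",
    "WordNorm",
    "ScoredResponse",
    "SkipReport",
    "load_responses",
    "load_lexicon",
    "default_lexicon",
    "clean_responses",
    "transcribe",
    "score_responses",
    "aggregate_norms",
    "write_norms",
    "run_pipeline",
]

_REQUIRED_COLUMNS = ("participant", "target", "response")


@dataclass(frozen=True)
class ResponseRecord:
    participant_id: str
    target_word: str
    response_word: str | None  # None = missing (no guess typed)
    study_id: str = ""


@dataclass(frozen=True)
class ScoredResponse:
    record: ResponseRecord
    result: DistanceResult


@dataclass(frozen=True)
class WordNorm:
    word: str
    mafi: float
    mean_distance: float
    mean_accuracy: float
    mean_pct_phonemes: float
    mean_levenshtein: float
    n_responses: int


@dataclass
class SkipReport:
    """Words that could not be transcribed, and the responses they cost."""

    missing_words: set[str] = field(default_factory=set)
    n_skipped_responses: int = 0

    def add(self, word: str) -> None:
        self.missing_words.add(word)
        self.n_skipped_responses += 1


def load_responses(path: str | Path) -> list[ResponseRecord]:
    """Parse a CSV/TSV response table (delimiter auto-detected).

    Required columns: participant, target, response; optional: study.
    Values are whitespace-stripped and lowercased; an empty response cell
    becomes a missing response. Duplicate (participant, study, target)
    rows keep the first occurrence with a warning.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"response table {path} lacks column(s): {missing}")
    if "study" not in df.columns:
        df["study"] = ""

    records: list[ResponseRecord] = []
    seen: set[tuple[str, str, str]] = set()
    for row in df.itertuples(index=False):
        participant = str(row.participant).strip()
        target = str(row.target).strip().lower()
        if not target:
            raise ValueError("response table contains an empty target word")
        response = str(row.response).strip().lower()
        study = str(row.study).strip()
        key = (participant, study, target)
        if key in seen:
            warnings.warn(
                f"duplicate response for participant={participant!r} "
                f"target={target!r}; keeping first",
                stacklevel=2,
            )
            continue
        seen.add(key)
        records.append(
            ResponseRecord(
                participant_id=participant,
                target_word=target,
                response_word=response or None,
                study_id=study,
            )
        )
    return records


def load_lexicon(path: str | Path) -> dict[str, str]:
    """Load a word -> IPA pronunciation lexicon from TSV."""
    lex: dict[str, str] = {}
    with open(path, encoding="utf-8-sig") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            word, ipa = line.split("\t")
            lex[word.strip().lower()] = unicodedata.normalize("NFC", ipa.strip())
    return lex


def default_lexicon() -> dict[str, str]:
    """Small bundled demo lexicon (British-leaning transcriptions)."""
    with resources.as_file(resources.files("mafi.data") / "lexicon_demo.tsv") as fp:
        return load_lexicon(fp)


def clean_responses(
    records: list[ResponseRecord],
) -> tuple[list[ResponseRecord], float]:
    """Drop missing responses; return kept records and removed fraction.

    Typos are deliberately not auto-corrected; supply a pre-edited
    response column if manual correction was applied upstream.
    """
    kept = [r for r in records if r.response_word is not None]
    frac = 1.0 - len(kept) / len(records) if records else 0.0
    if records and not kept:
        warnings.warn("all responses missing; nothing to score", stacklevel=2)
    return kept, frac


def transcribe(
    word: str, lexicon: dict[str, str], table: FeatureTable
) -> Transcription | None:
    """Lexicon lookup (case-insensitive) followed by IPA tokenization.

    Returns None for out-of-lexicon words; multi-word phrases are looked
    up whole (spaces intact) and only scored if the lexicon has them.
    """
    ipa = lexicon.get(word.strip().lower())
    if ipa is None:
        return None
    t = tokenize_ipa(ipa.replace(" ", ""), table)
    return Transcription(word=word.strip().lower(), segments=t.segments)


def score_responses(
    records: list[ResponseRecord],
    lexicon: dict[str, str],
    table: FeatureTable,
    indel_constant: float | None = None,
) -> tuple[list[ScoredResponse], SkipReport]:
    """Score every transcribable (target, response) pair."""
    report = SkipReport()
    cache: dict[str, Transcription | None] = {}

    def lookup(word: str) -> Transcription | None:
        if word not in cache:
            cache[word] = transcribe(word, lexicon, table)
        return cache[word]

    scored: list[ScoredResponse] = []
    for rec in records:
        if rec.response_word is None:
            continue
        tgt = lookup(rec.target_word)
        rsp = lookup(rec.response_word)
        if tgt is None or rsp is None:
            report.add(rec.target_word if tgt is None else rec.response_word)
            continue
        scored.append(
            ScoredResponse(rec, score_pair(tgt, rsp, table, indel_constant))
        )
    return scored, report


def aggregate_norms(scored: list[ScoredResponse]) -> list[WordNorm]:
    """Per-word norms: mean metrics, MaFI = -(mean normalized distance).

    Means are taken within each (study, word) cell first; a word's norm is
    the mean of its study-level means.
    """
    if not scored:
        return []
    df = pd.DataFrame(
        {
            "word": s.record.target_word,
            "study": s.record.study_id,
            "normalized": s.result.normalized,
            "accuracy": float(s.result.exact),
            "pct_phonemes": s.result.pct_phonemes,
            "levenshtein": s.result.levenshtein,
        }
        for s in scored
    )
    metric_cols = ["normalized", "accuracy", "pct_phonemes", "levenshtein"]
    per_study = df.groupby(["word", "study"], sort=True).agg(
        **{c: (c, "mean") for c in metric_cols}, n=("normalized", "size")
    )
    merged = per_study.groupby(level="word").agg(
        {**{c: "mean" for c in metric_cols}, "n": "sum"}
    )

    return [
        WordNorm(
            word=word,
            mafi=-row["normalized"],
            mean_distance=row["normalized"],
            mean_accuracy=row["accuracy"],
            mean_pct_phonemes=row["pct_phonemes"],
            mean_levenshtein=row["levenshtein"],
            n_responses=int(row["n"]),
        )
        for word, row in merged.iterrows()
    ]


def norms_frame(norms: list[WordNorm]) -> pd.DataFrame:
    """Norms as a DataFrame, alphabetical by word, 4-decimal rounding."""
    df = pd.DataFrame(
        {
            "word": n.word,
            "mafi": round(n.mafi + 0.0, 4),  # +0.0 avoids "-0.0"
            "mean_accuracy": round(n.mean_accuracy, 4),
            "mean_pct_phonemes": round(n.mean_pct_phonemes, 4),
            "mean_levenshtein": round(n.mean_levenshtein, 4),
            "n_responses": n.n_responses,
        }
        for n in norms
    )
    if df.empty:
        df = pd.DataFrame(
            columns=[
                "word",
                "mafi",
                "mean_accuracy",
                "mean_pct_phonemes",
                "mean_levenshtein",
                "n_responses",
            ]
        )
    return df.sort_values("word", kind="stable").reset_index(drop=True)


def write_norms(norms: list[WordNorm], path: str | Path) -> None:
    """Write norms to UTF-8 CSV, deterministically ordered and rounded."""
    norms_frame(norms).to_csv(path, index=False, encoding="utf-8", lineterminator="\n")


def run_pipeline(
    responses_path: str | Path,
    lexicon_path: str | Path,
    table: FeatureTable,
    out_path: str | Path | None = None,
) -> tuple[list[WordNorm], SkipReport, float]:
    """Full pipeline; returns (norms, skip report, missing fraction)."""
    records = load_responses(responses_path)
    lexicon = load_lexicon(lexicon_path)
    kept, missing_frac = clean_responses(records)
    scored, report = score_responses(kept, lexicon, table)
    norms = aggregate_norms(scored)
    if out_path is not None:
        write_norms(norms, out_path)
    return norms, report, missing_frac
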