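"""Synthetic speechreading corpora with viseme-confusion structure.

Speechreaders rarely recover a word verbatim: segments sharing a viseme
class (e.g. /b p m/) look alike on the mouth and are exchanged for one
another far more often than segments from different classes. The
generator operationalizes that as an independent per-segment channel:

* with probability ``p_correct`` the segment is perceived veridically;
* with probability ``p_delete`` it is dropped;
* otherwise it is substituted — by a same-viseme-class neighbour with
  probability ``p_within_viseme`` when the segment belongs to a class
  with other members, else by a uniformly random segment of the same
  broad category (consonant vs vowel, per the table's "consonantal" and
  "syllabic" features).

Defaults mirror a realistic silent-speechreading setting: ten guesses per
word, well-below-chance per-segment identification (40% veridical),
occasional deletions, and strongly viseme-bound confusions.
Coarticulation, lexical-candidate competition, and participant skill
differences are deliberately not modeled; responses are generated at the
IPA level and injected into the working lexicon as pseudo-words so the
norming pipeline can transcribe them.

``synthetic_lexicon`` builds matched pseudo-word targets: 4-12 segments
long with a consonant-biased CV skeleton, and a per-word saliency
propensity drawn from a bimodal Beta(0.2, 0.2) so the target set spans
words composed almost entirely of visually salient consonants down to
words with none — the spread of visual informativeness real word norms
exhibit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .norming import ResponseRecord
from .phonfeatures import FeatureTable, Segment, Transcription, tokenize_ipa
from .saliency import VisemeInventory, default_viseme_inventory

__all__ = [
    "ConfusionModel",
    "simulate_response",
    "simulate_corpus",
    "synthetic_lexicon",
]

DEFAULT_N_PARTICIPANTS = 10


@dataclass(frozen=True)
class ConfusionModel:
    """Per-segment perception channel for simulated speechreading."""

    p_correct: float = 0.4
    p_within_viseme: float = 0.9
    p_delete: float = 0.05
    p_insert: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_correct", "p_within_viseme", "p_delete", "p_insert"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.p_correct + self.p_delete > 1.0 + 1e-12:
            raise ValueError("p_correct + p_delete must not exceed 1")


def _category_pools(
    table: FeatureTable,
) -> tuple[list[str], list[str]]:
    """(consonant symbols, vowel symbols) from the table, sorted for
    deterministic sampling."""
    cons_i = table.features.index("cons")
    syl_i = table.features.index("syl")
    consonants, vowels = [], []
    for sym in sorted(table.segments):
        vec = table.segments[sym].vector
        (vowels if vec[syl_i] == 1 else consonants).append(sym)
    return consonants, vowels


def _substitute(
    seg: Segment,
    model: ConfusionModel,
    inv: VisemeInventory,
    table: FeatureTable,
    pools: tuple[list[str], list[str]],
    rng: np.random.Generator,
) -> str:
    label = inv.label_of(seg.symbol.rstrip("ːˑ"))
    if label is not None:
        mates = sorted(inv.classes[label] - {seg.symbol})
        mates = [m for m in mates if m in table]
        if mates and rng.random() < model.p_within_viseme:
            return mates[rng.integers(len(mates))]
    syl_i = table.features.index("syl")
    pool = pools[1] if seg.vector[syl_i] == 1 else pools[0]
    pool = [p for p in pool if p != seg.symbol]
    return pool[rng.integers(len(pool))]


def simulate_response(
    target: Transcription,
    model: ConfusionModel,
    inv: VisemeInventory | None = None,
    table: FeatureTable | None = None,
    rng: np.random.Generator | None = None,
) -> Transcription:
    """One simulated guess for one target word.

    Deterministic given ``model.seed`` (or an explicit ``rng``).
    """
    if len(target) == 0:
        raise ValueError("cannot simulate a response to an empty target")
    if table is None:
        from .phonfeatures import default_feature_table

        table = default_feature_table()
    inv = inv if inv is not None else default_viseme_inventory()
    rng = rng if rng is not None else np.random.default_rng(model.seed)
    pools = _category_pools(table)

    out: list[Segment] = []
    for seg in target:
        u = rng.random()
        if u < model.p_correct:
            out.append(seg)
        elif u < model.p_correct + model.p_delete:
            continue
        else:
            out.append(table.segment(_substitute(seg, model, inv, table, pools, rng)))
        if model.p_insert > 0 and rng.random() < model.p_insert:
            pool = pools[0] + pools[1]
            out.append(table.segment(pool[rng.integers(len(pool))]))
    return Transcription(word="".join(s.symbol for s in out), segments=tuple(out))


def synthetic_lexicon(
    n_words: int = 100,
    seed: int = 0,
    min_len: int = 4,
    max_len: int = 12,
    saliency_concentration: float = 0.2,
    consonant_bias: float = 0.7,
    table: FeatureTable | None = None,
    inv: VisemeInventory | None = None,
) -> dict[str, str]:
    """Generate pseudo-word targets spanning the visual-saliency range.

    Each word gets a saliency propensity q ~ Beta(c, c) (small c = bimodal,
    so some words are packed with viseme-class consonants and others have
    none), a length uniform on [min_len, max_len], and a CV skeleton in
    which a vowel is always followed by a consonant and a consonant is
    followed by another consonant with probability ``consonant_bias``.
    Returns word -> IPA; deterministic given ``seed``.
    """
    if table is None:
        from .phonfeatures import default_feature_table

        table = default_feature_table()
    inv = inv if inv is not None else default_viseme_inventory()
    rng = np.random.default_rng(seed)
    consonants, vowels = _category_pools(table)
    salient = sorted(s for s in inv.salient_symbols() if s in table)
    plain = [c for c in consonants if c not in salient]

    lex: dict[str, str] = {}
    used: set[str] = set()
    while len(lex) < n_words:
        length = int(rng.integers(min_len, max_len + 1))
        q = rng.beta(saliency_concentration, saliency_concentration)
        segs: list[str] = []
        prev_was_vowel = True  # force consonant onset
        for _ in range(length):
            is_cons = True if prev_was_vowel else rng.random() < consonant_bias
            if is_cons:
                pool = salient if rng.random() < q else plain
            else:
                pool = vowels
            prev_was_vowel = not is_cons
            segs.append(pool[rng.integers(len(pool))])
        ipa = "".join(segs)
        # adjacent draws like t+ʃ would re-tokenize as one affricate;
        # keep only words whose segment count survives tokenization
        if ipa not in used and len(tokenize_ipa(ipa, table)) == length:
            used.add(ipa)
            lex[f"w{len(lex):03d}"] = ipa
    return lex


def simulate_corpus(
    targets: list[str],
    lexicon: dict[str, str],
    model: ConfusionModel,
    n_participants: int = DEFAULT_N_PARTICIPANTS,
    inv: VisemeInventory | None = None,
    table: FeatureTable | None = None,
    study_id: str = "sim",
) -> tuple[list[ResponseRecord], dict[str, str]]:
    """Simulate ``n_participants`` guesses for every target word.

    Returns the response records and a working lexicon that includes one
    pseudo-word entry per distinct simulated response IPA, so the norming
    pipeline can transcribe everything. Deterministic given the model
    seed.
    """
    if table is None:
        from .phonfeatures import default_feature_table

        table = default_feature_table()
    inv = inv if inv is not None else default_viseme_inventory()
    missing = [t for t in targets if t.strip().lower() not in lexicon]
    if missing:
        raise KeyError(f"target word(s) absent from lexicon: {missing}")

    rng = np.random.default_rng(model.seed)
    working_lex = dict(lexicon)
    records: list[ResponseRecord] = []

    # reverse index so identical response IPA re-uses one pseudo-word
    rev: dict[str, str] = {}
    for w, ipa in working_lex.items():
        rev.setdefault(ipa, w)

    for word in targets:
        word = word.strip().lower()
        target_t = tokenize_ipa(lexicon[word], table)
        for p in range(n_participants):
            resp_t = simulate_response(target_t, model, inv, table, rng)
            ipa = resp_t.ipa
            if len(resp_t) == 0:
                response: str | None = None  # fully deleted -> missing guess
            elif ipa in rev:
                response = rev[ipa]
            else:
                response = f"sim:{ipa}"
                working_lex[response] = ipa
                rev[ipa] = response
            records.append(
                ResponseRecord(
                    participant_id=f"{study_id}-p{p:03d}",
                    target_word=word,
                    response_word=response,
                    study_id=study_id,
                )
            )
    return records, working_lex
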