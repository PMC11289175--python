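# Methods

## The distance model

A word's visual informativeness is estimated from how close speechreaders'
guesses land in articulatory feature space. Both target and guess are
tokenized into IPA segments (greedy longest match against the feature
table, after NFC Unicode normalization, so affricates like /tʃ/ and
length-marked vowels like /uː/ are single segments). The distance is the
minimum-cost alignment under:

- substitution: Σ_f w_f · |v_f(a) − v_f(b)| over the table's features,
  values in {+1, 0, −1}. A full polarity flip on one feature costs twice
  its weight; a ±1↔0 change costs the weight once.
- insertion/deletion: the segment's feature mass Σ_f w_f · |v_f(a)| —
  i.e. substitution against an all-zero null segment. A constant
  per-segment penalty is available as a configuration escape hatch, since
  feature-mass indels penalize feature-rich segments more, which is a
  modeling choice rather than a fact about speechreading.

The total cost is divided by the segment count of the longer word, making
short and long words comparable; the per-word MaFI score is the negated
mean over guesses. Internally everything is full floating point; rounding
(4 decimals in CSV output, 2 in displays) happens only at serialization.

Assumptions worth stating: alignment costs are additive and
position-independent (no extra weight for word onsets, although visual
information early in a word is known to matter more); feature weights
encode visual confusability only through phonological class; and guesses
are treated as independent draws per participant.

### Feature table and weights

The bundled table covers the English segment inventory (~50 segments, 21
ternary features) with one weight per feature in a two-tier scheme: major
class features (syllabic, sonorant, consonantal) weigh 1, continuant 0.5,
place/height/rounding features (anterior, labial, high, low, back, round,
tense, delayed-release, lateral, nasal) 0.25, and low-variability or
low-visibility features (voice, strident, spread/constricted glottis,
coronal, distributed) 0.125; vowel length weighs 0.05. Under these weights
the canonical contrasts come out as: /b/→/p/ (voicing only) = 0.25 and
/b/→/k/ (voicing + anterior + labial + high + back) = 2.25. Users can
substitute their own table and weight CSVs; the loader reconciles feature
order by name and rejects duplicate or malformed rows.

### Companion metrics

- segment-level Levenshtein distance (unit costs);
- percent phonemes correct: identical aligned pairs / target length,
  maximized over minimum-unit-cost alignments (the lexicographic DP makes
  the tie-break deterministic);
- accuracy: exact transcription match.

## Norming pipeline

Responses arrive as delimited text (participant, target, response, and
optionally study). Cleaning drops missing responses and reports the
fraction; typos are never auto-corrected (silent data mutation is worse
than a slightly noisier norm — supply a pre-edited column if manual
correction was done). Transcription is lexicon lookup (case-insensitive)
followed by tokenization; out-of-lexicon words are skip-reported and their
responses excluded rather than maximally penalized, so users can see
exactly what to add to the lexicon. Aggregation averages within each
(study, word) cell first and then across studies, so a word normed in two
studies is not dominated by the larger one. Output is deterministic:
alphabetical rows, fixed rounding, byte-identical across reruns.

## Saliency coding

Phoneme level: frontness = bilabial or labio-dental base symbol
(/b p m f v/); roundness = base symbol in /r ɹ w u o ɔ/ or the table's
"round" feature equal to +1. The feature-OR rule exists because lexicons
for different English variants transcribe rounded vowels differently
(/əʊ/ vs /o/, /ʊ/, length-marked forms); a segment is counted once per
property and the phoneme load is capped at 1. Viseme level: the six
default classes ({f} lower lip tuck; {ch} and {w} protrusion; {p} labial
closure; {j}, {r}, {w} lip rounding) are loaded from a CSV and can be
overridden, since viseme boundaries are speaker- and context-dependent.
Loads divide the count of qualifying segments by the word's segment
count. Position within the word is deliberately ignored.

## Statistical analyses

The validation analyses are nested OLS fits on per-word norms: a baseline
with the four lexical covariates (log frequency, age of acquisition,
phonological neighborhood density, phoneme count; standardized, listwise
deletion for missing values with the dropped words reported) against a
target adding either dummy-coded saliency flags or a standardized
informativeness load. Models are compared with the Gaussian
likelihood-ratio test, 2·ΔLL ~ χ²(Δk) — the same comparison R's `anova()`
performs on two `lm` fits. "Hierarchical" here means this
baseline-then-target nesting, not multilevel random-effects modeling. No
multiple-testing correction is applied. Cross-variant consistency is a
Pearson correlation over shared words with a Fisher-z 95% CI.
Neighborhood density is an input covariate; the bundled
one-edit-neighbor counter exists for building synthetic covariate tables,
not as a replacement for published norms.

## Synthetic data generator

The generator exists so every pipeline stage and statistical property can
be exercised without human data. It emulates a speechreading experiment
as an independent per-segment channel: keep with `p_correct` = 0.4,
delete with `p_delete` = 0.05, otherwise substitute — within the same
viseme class with `p_within_viseme` = 0.9 when the segment has
classmates, else uniformly within its broad category (consonant/vowel).
Ten simulated participants guess each word, matching the floor of the
norming studies this mirrors. The defaults encode two robust findings
from the speechreading literature: per-phoneme identification is well
below chance, and errors are overwhelmingly viseme-bound. Insertions are
off by default (`p_insert` = 0).

Target words come from `synthetic_lexicon`: pseudo-words of 4–12
segments with a consonant-biased CV skeleton and a per-word saliency
propensity q ~ Beta(0.2, 0.2). The bimodal propensity makes the target
set span words packed with viseme-class consonants down to words with
none — the wide between-word spread of visual informativeness that real
word norms show, and the reason ten-response norms can be reliable at
all. With a homogeneous word set, between-word variance in expected
distance is small relative to response noise and no 10-guess norm would
replicate across simulated speakers; with this spread, two independently
simulated speakers correlate at r ≈ 0.65–0.75 over 100 words.

What the generator does **not** emulate: coarticulation (errors are
independent across positions), lexical-candidate competition (guesses are
pseudo-words, not real-word neighbors), participant skill differences,
orthographic rendering and typos, and any speaker variability beyond the
seed. Passing tests therefore show that the pipeline and analyses behave
correctly under viseme-structured noise — not that the norms' empirical
values for human data are reproduced.

## Numerical and design notes

- Alignment DP is exact (no heuristics); symmetry holds because all edit
  costs are symmetric. Tie-breaks among equal-cost alignments do not
  affect costs; for percent phonemes correct the alignment maximizing
  identical matches among minimum-cost alignments is chosen.
- Degenerate inputs: empty-vs-empty distance is 0 but normalized distance
  is undefined (error); empty targets cannot be profiled or scored for
  phoneme accuracy; fully deleted simulated responses become missing
  guesses rather than empty strings.
- A constant covariate column is a hard scaling error for the lexical
  covariates; a constant informativeness load is left unscaled (it will
  surface as rank deficiency only if actually entered into a model).
- Rank-deficient designs raise an error naming the collinear columns
  rather than silently dropping one.
- Test problem sizes (100-word lexica, 10 guesses per word, 200 LRT
  replicates at n = 100–150) were chosen as the smallest sets at which
  the distributional properties under test are stable across seeds.

## Known limitations

- The bundled feature table covers English only; other languages need a
  user-supplied table and lexicon.
- Feature-mass indel costs make deletions of feature-rich segments
  expensive; there is no empirical calibration of indel costs against
  human deletion confusions.
- MaFI from open-ended typing conflates visual informativeness with
  lexical guessing biases; the regression controls mitigate but cannot
  remove this.
- The simulator's independence assumptions understate the correlated
  errors coarticulation produces in real responses.
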