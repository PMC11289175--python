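# mafi — mouth and facial informativeness norms for spoken words

`mafi` quantifies how much a silently spoken word reveals through the
speaker's mouth and facial movements. It is aimed at researchers in
audiovisual speech perception and psycholinguistics who need a per-word,
continuous measure of visual speech informativeness — e.g. as a control or
predictor variable in experiments with video stimuli.

## The measure

Given a speechreading task (participants watch muted videos and type their
guess), each guess *r* is compared with its target *t* after both are
rendered as IPA segment sequences. The phonological distance is a weighted
feature edit distance normalized by word length:

    d(t, r) = min-cost alignment(t, r) / max(|t|, |r|)

where the cost of substituting segment *a* for segment *b* is

    cost(a, b) = Σ_f  w_f · |v_f(a) − v_f(b)|,

with ternary articulatory feature values v_f ∈ {+1, 0, −1} and per-feature
weights w_f (voicing 0.125; anterior, labial, high, back 0.25; ...).
Insertions and deletions cost a segment's weighted feature mass. A word's
**MaFI score** is the negated mean distance over all guesses:

    MaFI(t) = − mean_r d(t, r)   ∈ [−max distance, 0]

0 means every participant speechread the word perfectly; more negative
means less visually informative articulation. Because substitution costs
are feature-weighted, visually indistinguishable confusions are cheap
(/b/→/p/ differ only in voicing: cost 0.25) while visually distinct ones
are expensive (/b/→/k/: cost 2.25), so the score rewards guesses that look
like the target even when they are wrong.

Companion modules:

- `saliency` — codes frontness/roundness of phonemes, viseme classes
  ({p} = /b p m/, {f} = /f v/, {ch} = /ʃ tʃ dʒ/, {w}, {j}, {r}) with their
  lip-gesture features, and per-word informativeness loads;
- `stats` — the validation analyses: OLS feature regressions with lexical
  covariates, likelihood-ratio comparison against a lexical baseline, and
  Pearson correlations between norm sets (Fisher-z CIs);
- `simulate` — a seeded viseme-confusion response generator plus a
  synthetic pseudo-word lexicon, so the full pipeline is testable without
  human data.

## Worked example

```bash
$ mafi score --target bat --response pat --lexicon lex.tsv
{"target": "bat", "response": "pat", "raw_cost": 0.25, "normalized_distance": 0.0833,
 "mafi_single_response": -0.0833, "levenshtein": 1, "pct_phonemes_correct": 0.6667,
 "exact_match": false}
$ mafi score --target bat --response cat --lexicon lex.tsv
{"target": "bat", "response": "cat", "raw_cost": 2.25, "normalized_distance": 0.75,
 "mafi_single_response": -0.75, "levenshtein": 1, "pct_phonemes_correct": 0.6667,
 "exact_match": false}
```

"pat" and "cat" both get 2 of 3 target phonemes right (0.67) and one
Levenshtein edit, yet "pat" is nearly indistinguishable from "bat" on the
lips (distance 0.08) while "cat" is visually far (0.75) — the contrast the
weighted distance exists to capture.

Running the norming pipeline over a response table:

```bash
$ mafi norm --responses responses.csv --lexicon lex.tsv --out norms.csv
wrote 2 word norms to norms.csv (missing responses removed: 0.0%; untranscribable responses skipped: 0)
$ cat norms.csv
word,mafi,mean_accuracy,mean_pct_phonemes,mean_levenshtein,n_responses
bat,-0.2778,0.3333,0.7778,0.6667,3
moon,-0.875,0.5,0.6667,1.0,2
```

Here "bat" (guessed as pat, cat, bat) averages to MaFI −0.28; a word whose
every guess was exact would score 0. `mafi simulate`, `mafi analyze` and
`mafi correlate` generate synthetic corpora, run the feature regressions,
and compare norm sets; the same functionality is available as a library
(`import mafi`).

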