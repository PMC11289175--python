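"""Feature regressions, nested model comparison, and cross-variant correlations.

The norming analyses ask whether visually salient phoneme/viseme features
predict MaFI over and above lexical covariates (log word frequency, age of
acquisition, phonological neighborhood density, phoneme count). Saliency
predictors are dummy coded (word has the feature vs not, or a continuous
informativeness load); continuous covariates are standardized; models are
ordinary least squares fit on per-word norms; the target model (lexical
covariates + saliency features) is compared with the lexical baseline by a
likelihood-ratio test, 2*(LL_target - LL_baseline) ~ chi2(df = number of
added predictors) under Gaussian errors — equivalent to R's anova() on two
nested lm fits.

Cross-variant validation correlates two sets of per-word MaFI norms
(Pearson r with a Fisher-z 95% CI) on the words they share.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .norming import WordNorm
from .saliency import WordFeatureProfile

__all__ = [
    "LEXICAL_COVARIATES",
    "RegressionSpec",
    "ModelFit",
    "prepare_design",
    "fit_ols",
    "compare_models",
    "correlate_norms",
    "neighborhood_density",
]

LEXICAL_COVARIATES = ("log_frequency", "aoa", "phon_neighborhood", "n_phonemes")

_BOOL_PROFILE_COLS = {
    "frontness": "has_frontness",
    "roundness": "has_roundness",
    "lower_lip_tuck": "has_lower_lip_tuck",
    "protrusion": "has_protrusion",
    "labial_closure": "has_labial_closure",
    "lip_rounding": "has_lip_rounding",
}


@dataclass(frozen=True)
class RegressionSpec:
    """A target model and its nested lexical baseline."""

    response: str
    predictors: tuple[str, ...]
    baseline_predictors: tuple[str, ...] = LEXICAL_COVARIATES

    def __post_init__(self) -> None:
        if not set(self.baseline_predictors) <= set(self.predictors):
            raise ValueError("baseline predictors must nest within predictors")


@dataclass(frozen=True)
class ModelFit:
    coefficients: dict[str, tuple[float, float, float, float]]  # beta, SE, t, p
    r_squared: float
    log_likelihood: float
    n: int
    predictors: tuple[str, ...]


def prepare_design(
    norms: list[WordNorm],
    profiles: list[WordFeatureProfile],
    covariates: pd.DataFrame,
) -> tuple[pd.DataFrame, list[str]]:
    """Join norms, saliency profiles, and lexical covariates on word.

    Boolean saliency flags become 0/1 dummies; informativeness loads and
    continuous covariates are standardized to mean 0, SD 1 (population
    SD, like R's scale() up to the n-1 convention — we use ddof=1).
    Words missing any covariate are dropped and reported.

    Returns the design table and the list of dropped words.
    """
    ndf = pd.DataFrame({"word": n.word, "mafi": n.mafi} for n in norms)
    pdf = pd.DataFrame(
        {
            "word": p.word,
            **{col: float(getattr(p, attr)) for col, attr in _BOOL_PROFILE_COLS.items()},
            "load_phoneme": p.load_phoneme,
            "load_viseme": p.load_viseme,
        }
        for p in profiles
    )
    cov = covariates.copy()
    cov.columns = [c.strip().lower() for c in cov.columns]
    missing_cols = [c for c in LEXICAL_COVARIATES if c not in cov.columns]
    if missing_cols:
        raise ValueError(f"covariate table lacks column(s): {missing_cols}")
    cov["word"] = cov["word"].astype(str).str.strip().str.lower()

    merged = ndf.merge(pdf, on="word", how="inner").merge(cov, on="word", how="left")
    complete = merged.dropna(subset=list(LEXICAL_COVARIATES))
    dropped = sorted(set(merged["word"]) - set(complete["word"]))
    design = complete.reset_index(drop=True).copy()
    if design.empty:
        raise ValueError("no words left after joining norms, profiles, covariates")

    for col in LEXICAL_COVARIATES:
        sd = design[col].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"cannot scale covariate {col!r}: zero variance")
        design[col] = (design[col] - design[col].mean()) / sd
    for col in ("load_phoneme", "load_viseme"):
        sd = design[col].std(ddof=1)
        if np.isfinite(sd) and sd > 0:  # constant loads stay unscaled
            design[col] = (design[col] - design[col].mean()) / sd
    return design, dropped


def fit_ols(design: pd.DataFrame, spec: RegressionSpec) -> ModelFit:
    """Ordinary least squares with intercept; Gaussian log-likelihood."""
    y = design[spec.response].to_numpy(dtype=float)
    X = sm.add_constant(design[list(spec.predictors)].astype(float), has_constant="add")
    if len(y) <= X.shape[1]:
        raise ValueError("more predictors than observations")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = design[list(spec.predictors)].astype(float).corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        collinear = sorted(corr.columns[(corr > 0.999999).any()].tolist())
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")
    res = sm.OLS(y, X).fit()
    coeffs = {
        name: (
            float(res.params[name]),
            float(res.bse[name]),
            float(res.tvalues[name]),
            float(res.pvalues[name]),
        )
        for name in X.columns
    }
    return ModelFit(
        coefficients=coeffs,
        r_squared=float(res.rsquared),
        log_likelihood=float(res.llf),
        n=int(res.nobs),
        predictors=tuple(spec.predictors),
    )


def compare_models(baseline: ModelFit, target: ModelFit) -> dict[str, float]:
    """Likelihood-ratio test of nested OLS fits.

    chi2 = 2*(LL_target - LL_baseline), df = difference in predictor
    count, p from the chi-square upper tail. Clipped at 0 so numerically
    identical models give chi2 = 0, p = 1.
    """
    if baseline.n != target.n:
        raise ValueError("models fit on different numbers of rows")
    if not set(baseline.predictors) <= set(target.predictors):
        raise ValueError("baseline model is not nested in target model")
    df = len(target.predictors) - len(baseline.predictors)
    chi2 = max(0.0, 2.0 * (target.log_likelihood - baseline.log_likelihood))
    p = float(sps.chi2.sf(chi2, df)) if df > 0 else 1.0
    return {"chi2": chi2, "df": df, "p": p}


def correlate_norms(
    norms_a: list[WordNorm], norms_b: list[WordNorm]
) -> dict[str, object]:
    """Pearson correlation of two MaFI norm sets on their shared words."""
    a = {n.word: n.mafi for n in norms_a}
    b = {n.word: n.mafi for n in norms_b}
    shared = sorted(set(a) & set(b))
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared words, got {len(shared)}")
    x = np.array([a[w] for w in shared])
    y = np.array([b[w] for w in shared])
    r, p = sps.pearsonr(x, y)
    n = len(shared)
    # Fisher z 95% CI
    if abs(r) < 1.0 and n > 3:
        z = np.arctanh(r)
        se = 1.0 / np.sqrt(n - 3)
        lo, hi = np.tanh(z - 1.959963984540054 * se), np.tanh(z + 1.959963984540054 * se)
    else:
        lo = hi = r
    return {"r": float(r), "n": n, "ci95": (float(lo), float(hi)), "p": float(p)}


def neighborhood_density(word: str, lexicon: dict[str, str]) -> int:
    """Count of lexicon words whose IPA differs from ``word``'s by one
    segment-level edit (substitution, insertion, or deletion).

    A convenience for building synthetic covariate tables; real analyses
    should supply normed neighborhood densities as inputs.
    """
    # character-level Levenshtein on IPA strings (length marks travel with
    # their vowel, so this approximates segment edits well for English)
    target_ipa = lexicon.get(word.strip().lower())
    if target_ipa is None:
        raise KeyError(word)

    def char_lev(s1: str, s2: str) -> int:
        prev = list(range(len(s2) + 1))
        for i, c1 in enumerate(s1, 1):
            cur = [i]
            for j, c2 in enumerate(s2, 1):
                cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (c1 != c2)))
            prev = cur
        return prev[-1]

    return sum(
        1
        for w, ipa in lexicon.items()
        if w != word.strip().lower() and char_lev(target_ipa, ipa) == 1
    )
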