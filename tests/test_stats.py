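"""Design preparation, OLS fitting, model comparison, correlations."""

import numpy as np
import pandas as pd
import pytest

from mafi.norming import WordNorm
from mafi.saliency import WordFeatureProfile
from mafi.stats import (
    LEXICAL_COVARIATES,
    ModelFit,
    RegressionSpec,
    compare_models,
    correlate_norms,
    fit_ols,
    neighborhood_density,
    prepare_design,
)


def make_norm(word, mafi):
    return WordNorm(word, mafi, -mafi, 0.0, 0.0, 0.0, 10)


def make_profile(word, front=False, round_=False, lp=0.0, lv=0.0):
    return WordFeatureProfile(
        word, front, round_, False, False, front, round_, lp, lv
    )


def make_covariates(words, rng):
    return pd.DataFrame(
        {
            "word": words,
            "log_frequency": rng.normal(8, 2, len(words)),
            "aoa": rng.normal(6, 2, len(words)),
            "phon_neighborhood": rng.poisson(5, len(words)).astype(float),
            "n_phonemes": rng.integers(2, 10, len(words)).astype(float),
        }
    )


@pytest.fixture()
def small_design(rng):
    words = [f"w{i}" for i in range(10)]
    norms = [make_norm(w, -rng.random()) for w in words]
    profiles = [
        make_profile(w, front=i % 2 == 0, lp=(i % 3) / 3) for i, w in enumerate(words)
    ]
    cov = make_covariates(words, rng)
    design, dropped = prepare_design(norms, profiles, cov)
    assert dropped == []
    return design


class TestPrepareDesign:
    def test_scaled_columns_standardized(self, small_design):
        for col in LEXICAL_COVARIATES:
            assert small_design[col].mean() == pytest.approx(0.0, abs=1e-10)
            assert small_design[col].std(ddof=1) == pytest.approx(1.0)

    def test_dummies_are_binary(self, small_design):
        assert set(small_design["frontness"].unique()) <= {0.0, 1.0}

    def test_word_missing_covariate_dropped_and_reported(self, rng):
        words = ["w0", "w1", "w2", "w3", "w4"]
        norms = [make_norm(w, -0.5) for w in words]
        profiles = [make_profile(w) for w in words]
        cov = make_covariates(words, rng)
        cov.loc[cov["word"] == "w2", "aoa"] = np.nan
        design, dropped = prepare_design(norms, profiles, cov)
        assert dropped == ["w2"]
        assert len(design) == 4

    def test_zero_variance_covariate_is_error(self, rng):
        words = [f"w{i}" for i in range(5)]
        norms = [make_norm(w, -0.5) for w in words]
        profiles = [make_profile(w) for w in words]
        cov = make_covariates(words, rng)
        cov["aoa"] = 3.0
        with pytest.raises(ValueError, match="aoa"):
            prepare_design(norms, profiles, cov)


class TestFitOLS:
    def test_matches_normal_equations(self, small_design):
        """Independent oracle: solve X'X beta = X'y explicitly."""
        spec = RegressionSpec("mafi", ("frontness",) + LEXICAL_COVARIATES)
        fit = fit_ols(small_design, spec)
        X = np.column_stack(
            [np.ones(len(small_design))]
            + [small_design[c].to_numpy() for c in spec.predictors]
        )
        y = small_design["mafi"].to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        names = ["const"] + list(spec.predictors)
        for name, b in zip(names, beta):
            assert fit.coefficients[name][0] == pytest.approx(b)

    def test_perfect_fit(self, small_design):
        design = small_design.copy()
        design["mafi"] = design["aoa"]
        fit = fit_ols(design, RegressionSpec("mafi", ("aoa",), ("aoa",)))
        assert fit.coefficients["aoa"][0] == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_rank_deficient_names_collinear_columns(self, small_design):
        design = small_design.copy()
        design["aoa_copy"] = design["aoa"]
        spec = RegressionSpec(
            "mafi", ("aoa", "aoa_copy"), baseline_predictors=("aoa",)
        )
        with pytest.raises(ValueError, match="aoa"):
            fit_ols(design, spec)

    def test_parameter_recovery_known_effects(self, rng):
        """Synthetic norms with injected frontness/roundness effects are
        recovered within 2 SE at n = 500."""
        n = 500
        words = [f"w{i}" for i in range(n)]
        front = rng.random(n) < 0.5
        round_ = rng.random(n) < 0.5
        a_true, b_true = 0.5, 0.3
        mafi = -1.0 + a_true * front + b_true * round_ + rng.normal(0, 0.3, n)
        norms = [make_norm(w, m) for w, m in zip(words, mafi)]
        profiles = [
            make_profile(w, f, r) for w, f, r in zip(words, front, round_)
        ]
        design, _ = prepare_design(norms, profiles, make_covariates(words, rng))
        fit = fit_ols(
            design, RegressionSpec("mafi", ("frontness", "roundness") + LEXICAL_COVARIATES)
        )
        for name, truth in (("frontness", a_true), ("roundness", b_true)):
            beta, se, _, _ = fit.coefficients[name]
            assert abs(beta - truth) < 2 * se


class TestCompareModels:
    def test_identical_models(self, small_design):
        base = fit_ols(small_design, RegressionSpec("mafi", LEXICAL_COVARIATES))
        out = compare_models(base, base)
        assert out["chi2"] == 0.0
        assert out["df"] == 0
        assert out["p"] == 1.0

    def test_chi2_nonnegative_and_df(self, small_design):
        base = fit_ols(small_design, RegressionSpec("mafi", LEXICAL_COVARIATES))
        target = fit_ols(
            small_design,
            RegressionSpec("mafi", ("frontness", "load_phoneme") + LEXICAL_COVARIATES),
        )
        out = compare_models(base, target)
        assert out["chi2"] >= 0.0
        assert out["df"] == 2
        assert 0.0 <= out["p"] <= 1.0

    def test_non_nested_is_error(self, small_design):
        a = fit_ols(small_design, RegressionSpec("mafi", ("aoa",), ("aoa",)))
        b = fit_ols(
            small_design, RegressionSpec("mafi", ("log_frequency",), ("log_frequency",))
        )
        with pytest.raises(ValueError):
            compare_models(a, b)

    def test_strong_effect_detected(self, rng):
        n = 300
        words = [f"w{i}" for i in range(n)]
        front = rng.random(n) < 0.5
        mafi = -1.0 + 0.8 * front + rng.normal(0, 0.3, n)
        norms = [make_norm(w, m) for w, m in zip(words, mafi)]
        profiles = [make_profile(w, f) for w, f in zip(words, front)]
        design, _ = prepare_design(norms, profiles, make_covariates(words, rng))
        base = fit_ols(design, RegressionSpec("mafi", LEXICAL_COVARIATES))
        target = fit_ols(
            design, RegressionSpec("mafi", ("frontness",) + LEXICAL_COVARIATES)
        )
        assert compare_models(base, target)["p"] < 0.001

    def test_null_lrt_p_uniform(self, rng):
        """Under the null (no feature effect), LRT p-values over
        replicates are approximately Uniform(0, 1)."""
        from scipy.stats import kstest

        pvals = []
        for _ in range(200):
            n = 150
            y = rng.normal(size=n)
            x_lex = rng.normal(size=n)
            x_null = rng.random(n) < 0.5
            df = pd.DataFrame(
                {"mafi": y, "lex": x_lex, "feat": x_null.astype(float)}
            )
            base = fit_ols(df, RegressionSpec("mafi", ("lex",), ("lex",)))
            tgt = fit_ols(df, RegressionSpec("mafi", ("feat", "lex"), ("lex",)))
            pvals.append(compare_models(base, tgt)["p"])
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestCorrelateNorms:
    def test_self_correlation(self):
        norms = [make_norm(f"w{i}", -i / 10) for i in range(10)]
        out = correlate_norms(norms, norms)
        assert out["r"] == pytest.approx(1.0)
        assert out["n"] == 10

    def test_antisymmetry(self):
        a = [make_norm(f"w{i}", -i / 10) for i in range(10)]
        b = [make_norm(f"w{i}", i / 10) for i in range(10)]
        assert correlate_norms(a, b)["r"] == pytest.approx(-1.0)

    def test_intersection_only(self):
        a = [make_norm(w, -0.1 * i) for i, w in enumerate("abcdef")]
        b = [make_norm(w, -0.1 * i) for i, w in enumerate("defghi")]
        assert correlate_norms(a, b)["n"] == 3

    def test_too_few_shared_words(self):
        a = [make_norm("a", -0.1), make_norm("b", -0.2)]
        with pytest.raises(ValueError):
            correlate_norms(a, a)

    def test_ci_contains_r(self):
        rng = np.random.default_rng(3)
        a = [make_norm(f"w{i}", v) for i, v in enumerate(-rng.random(50))]
        b = [
            make_norm(f"w{i}", n.mafi + rng.normal(0, 0.1))
            for i, n in enumerate(a)
        ]
        out = correlate_norms(a, b)
        lo, hi = out["ci95"]
        assert lo < out["r"] < hi


def test_neighborhood_density(lexicon):
    # bat (bæt) has one-edit IPA neighbours pat, cat, mat, rat, hat ...
    assert neighborhood_density("bat", lexicon) >= 5
    with pytest.raises(KeyError):
        neighborhood_density("zzz", lexicon)
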