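import numpy as np
import pandas as pd
import pytest

from readrel.corpus import (
    CorpusConfig,
    EffectSpec,
    default_effect_specs,
    default_predictor_correlation,
    generate_predictors,
    generate_scanpath,
    sample_random_effects,
    simulate_responses,
    write_corpus,
)
from readrel.measures import compute_word_measures
from readrel.model import ModelSpec, build_design
from conftest import single_predictor_specs


class TestGeneratePredictors:
    def test_identity_correlation_gives_uncorrelated_columns(self):
        df = generate_predictors(8000, np.eye(5), seed=1)
        z = df[[c for c in df.columns if c.endswith("_z")]].to_numpy()
        corr = np.corrcoef(z, rowvar=False)
        off = corr[~np.eye(5, dtype=bool)]
        assert np.abs(off).max() < 0.08

    def test_zscored_columns_standardized(self):
        df = generate_predictors(4000, seed=2)
        for c in ("wl_z", "freq_z", "surp_z"):
            assert df[c].mean() == pytest.approx(0.0, abs=1e-9)
            assert df[c].std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_configured_correlation_recovered(self):
        corr = default_predictor_correlation()
        df = generate_predictors(10000, corr, seed=3)
        got = np.corrcoef(df["wl"], df["freq"])[0, 1]
        assert got == pytest.approx(-0.6, abs=0.05)

    def test_non_positive_definite_correlation_rejected(self):
        bad = np.full((5, 5), 0.99)
        np.fill_diagonal(bad, 1.0)
        bad[0, 1] = bad[1, 0] = -0.99
        with pytest.raises(ValueError):
            generate_predictors(100, bad, seed=0)

    def test_partial_predictors_have_undefined_entries(self):
        df = generate_predictors(2000, seed=4)
        assert df["depdist"].isna().any() and df["nleftdep"].isna().any()
        # undefined words sit at the mean (zero) of the z-scored column
        assert (df.loc[df["depdist"].isna(), "depdist_z"] == 0.0).all()


class TestSampleRandomEffects:
    def test_degenerate_perfect_correlation(self):
        spec = (EffectSpec("wl", 0.0, 0.05, 0.05, 1.0),)
        b = sample_random_effects(200, spec, seed=1)["wl"]
        assert np.allclose(b[:, 0], b[:, 1], atol=1e-10)

    def test_zero_correlation(self):
        spec = (EffectSpec("wl", 0.0, 0.1, 0.1, 0.0),)
        b = sample_random_effects(5000, spec, seed=2)["wl"]
        assert abs(np.corrcoef(b.T)[0, 1]) < 0.05

    def test_target_correlation_recovered(self):
        spec = (EffectSpec("wl", 0.0, 0.05, 0.05, 0.7),)
        b = sample_random_effects(5000, spec, seed=3)["wl"]
        assert np.corrcoef(b.T)[0, 1] == pytest.approx(0.7, abs=0.03)

    def test_blocks_are_independent(self):
        specs = (
            EffectSpec("a", 0.0, 0.1, 0.1, 0.9),
            EffectSpec("b", 0.0, 0.1, 0.1, 0.9),
        )
        eff = sample_random_effects(4000, specs, seed=4)
        assert abs(np.corrcoef(eff["a"][:, 0], eff["b"][:, 0])[0, 1]) < 0.05


class TestSimulateResponses:
    def test_degenerate_lognormal_recovers_intercept(self):
        specs = tuple(
            EffectSpec(s.name, 0.0, 0.0, 0.0, 0.0) for s in default_effect_specs()
        )
        cfg = CorpusConfig(
            n_subjects=10,
            words_per_session=(200, 200),
            beta0=5.5,
            session_effect=0.0,
            sigma=0.44,
            effect_specs=specs,
            seed=5,
        )
        trials, _ = simulate_responses(cfg)
        mean_log = np.log(trials["response"]).mean()
        se = 0.44 / np.sqrt(len(trials))
        assert abs(mean_log - 5.5) < 4 * se

    def test_bernoulli_rate_matches_inverse_logit(self):
        specs = tuple(
            EffectSpec(s.name, 0.0, 0.0, 0.0, 0.0) for s in default_effect_specs()
        )
        cfg = CorpusConfig(
            n_subjects=20,
            words_per_session=(200, 200),
            family="bernoulli",
            sigma=None,
            beta0=-2.43,
            session_effect=0.0,
            effect_specs=specs,
            seed=6,
        )
        trials, _ = simulate_responses(cfg)
        rate = trials["response"].mean()
        p = 1 / (1 + np.exp(2.43))
        se = np.sqrt(p * (1 - p) / len(trials))
        assert rate == pytest.approx(p, abs=4 * se)
        assert p == pytest.approx(0.08, abs=0.005)

    def test_zip_degenerate_mixture(self):
        specs = tuple(
            EffectSpec(s.name, 0.0, 0.0, 0.0, 0.0) for s in default_effect_specs()
        )
        cfg = CorpusConfig(
            n_subjects=5,
            words_per_session=(50, 50),
            family="zip",
            sigma=None,
            beta0=0.5,
            session_effect=0.0,
            zip_zero_prob=0.999,
            effect_specs=specs,
            seed=7,
        )
        trials, _ = simulate_responses(cfg)
        assert (trials["response"] == 0).mean() > 0.99

    def test_family_parameter_mismatch_rejected(self):
        with pytest.raises(ValueError):
            CorpusConfig(family="bernoulli", sigma=0.4)
        with pytest.raises(ValueError):
            CorpusConfig(family="zip", sigma=None)
        with pytest.raises(ValueError):
            CorpusConfig(family="lognormal", sigma=None)

    def test_output_passes_design_validation_unchanged(self):
        cfg = CorpusConfig(
            n_subjects=6,
            words_per_session=(40, 40),
            effect_specs=single_predictor_specs(),
            seed=8,
        )
        trials, _ = simulate_responses(cfg)
        spec = ModelSpec(
            family="lognormal", predictors=("wl", "freq", "surp")
        )
        bundle = build_design(trials, spec)
        assert bundle.n_rows == 6 * 80
        assert bundle.n_subjects == 6

    def test_reproducible_from_seed(self):
        cfg = CorpusConfig(n_subjects=4, words_per_session=(20, 20), seed=9)
        t1, _ = simulate_responses(cfg)
        t2, _ = simulate_responses(cfg)
        pd.testing.assert_frame_equal(t1, t2)

    def test_spillover_columns_and_truth(self):
        spill = (EffectSpec("wl_prev", 0.0, 0.03, 0.03, 0.5),)
        cfg = CorpusConfig(
            n_subjects=4,
            words_per_session=(60, 60),
            effect_specs=single_predictor_specs(),
            spillover_specs=spill,
            screen_size=20,
            seed=10,
        )
        trials, truth = simulate_responses(cfg)
        assert "wl_prev_z" in trials.columns
        assert "wl_prev" in truth["effects"]
        # screen starts carry no spillover contribution
        first = trials[trials.word_index % 20 == 0]
        assert (first["wl_prev_z"] == 0.0).all()

    def test_write_corpus_artifacts(self, tmp_path):
        cfg = CorpusConfig(n_subjects=3, words_per_session=(10, 10), seed=11)
        paths = write_corpus(cfg, tmp_path)
        assert (tmp_path / "trials.csv").exists()
        assert (tmp_path / "truth.json").exists()
        df = pd.read_csv(paths["trials"])
        assert len(df) == 3 * 20


class TestGenerateScanpath:
    def test_deterministic_progressive_reading(self):
        seq, truth = generate_scanpath(
            6, regression_prob=0, skip_prob=0, refix_prob=0, seed=1
        )
        assert list(seq.word_index) == list(range(6))
        for m in truth:
            assert m.FPRT == m.TFT == m.RPD and m.FPReg == 0.0

    def test_all_skipped(self):
        seq, truth = generate_scanpath(
            5, regression_prob=0.5, skip_prob=1.0, refix_prob=0.5, seed=2
        )
        assert len(seq) == 0
        assert all(m.SKIP == 1 for m in truth)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            generate_scanpath(5, skip_prob=1.5)

    @pytest.mark.parametrize("seed", range(40))
    def test_by_construction_truth_matches_computed_measures(self, seed):
        seq, truth = generate_scanpath(
            10,
            regression_prob=0.3,
            skip_prob=0.25,
            refix_prob=0.3,
            seed=seed,
        )
        got = compute_word_measures(seq, 10)
        for g, t in zip(got, truth):
            assert vars(g) == pytest.approx(vars(t), nan_ok=True), (
                seed,
                vars(g),
                vars(t),
            )
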