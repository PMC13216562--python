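"""Tests of the synthetic-cohort generator: generative probabilities,
item-bank structure, latent sampling and parameter recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from truthsdt import (CohortConfig, TraitSpec, d_prime, criterion,
                      generate_cohort, generate_item_bank, load_cohort,
                      response_probability, sample_latents,
                      sample_participant_params, score_cohort, write_cohort)
from truthsdt.exceptions import ConfigurationError, ValidationError


def _config(**kw):
    base = dict(n_per_group=10, items_per_cell=20, traits=(), seed=0)
    base.update(kw)
    return CohortConfig(**base)


class TestResponseProbability:
    def test_symmetric_null(self):
        assert response_probability(0, 0, True) == pytest.approx(0.5)

    def test_inverse_cdf_oracle(self):
        # d chosen so that d/2 = z(0.8)
        d = 2 * norm.ppf(0.8)
        assert response_probability(d, 0, True) == pytest.approx(0.8, abs=1e-4)
        assert response_probability(d, 0, False) == pytest.approx(0.2, abs=1e-4)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValidationError):
            response_probability(np.inf, 0, True)

    @given(st.floats(-3, 3), st.floats(-3, 3))
    @settings(max_examples=100)
    def test_inversion_identity(self, d, c):
        """Scoring the exact generative rates returns (d, c) to >= 10 digits."""
        H = response_probability(d, c, True)
        FA = response_probability(d, c, False)
        assert 0.0 < H < 1.0 and 0.0 < FA < 1.0
        assert d_prime(H, FA) == pytest.approx(d, rel=1e-10, abs=1e-10)
        assert criterion(H, FA) == pytest.approx(c, rel=1e-10, abs=1e-10)


class TestItemBank:
    def test_default_size_and_cells(self):
        bank = generate_item_bank(20, seed=1)
        assert len(bank) == 80
        cells = bank.groupby(["veracity", "slant"]).size()
        assert (cells == 20).all()

    def test_minimal_bank(self):
        assert len(generate_item_bank(1, seed=0)) == 4

    def test_determinism(self):
        pd.testing.assert_frame_equal(generate_item_bank(5, seed=9),
                                      generate_item_bank(5, seed=9))

    def test_order_is_contiguous_permutation(self):
        bank = generate_item_bank(7, seed=3)
        assert sorted(bank["order_index"]) == list(range(1, 29))

    def test_invalid_count(self):
        with pytest.raises(ConfigurationError):
            generate_item_bank(0)


class TestLatentSampling:
    def test_degenerate_sds_give_means(self):
        cfg = _config(dprime_dist=(1.0, 0.0), criterion_dist=(0.3, 0.0),
                      myside_dist=(0.6, 0.0))
        lat = sample_latents(cfg, np.random.default_rng(0), 50)
        assert (lat["d_true"] == 1.0).all()
        assert (lat["c_base"] == 0.3).all()
        assert (lat["m_true"] == 0.6).all()

    def test_perfect_correlation_is_affine(self):
        trait = TraitSpec("proxy", mean=0.0, sd=2.0, r_dprime=1.0)
        cfg = _config(traits=(trait,), dprime_dist=(0.5, 1.0))
        lat = sample_latents(cfg, np.random.default_rng(1), 200)
        # equal z-scores up to the affine map between the two marginals
        z_d = (lat["d_true"] - 0.5) / 1.0
        z_t = lat["proxy"] / 2.0
        assert np.abs(z_d - z_t).max() < 1e-10

    def test_monte_carlo_correlation_target(self):
        trait = TraitSpec("t", mean=0.0, sd=1.0, r_dprime=0.3)
        cfg = _config(traits=(trait,))
        lat = sample_latents(cfg, np.random.default_rng(2), 10_000)
        r = np.corrcoef(lat["t"], lat["d_true"])[0, 1]
        assert r == pytest.approx(0.3, abs=0.03)

    def test_non_psd_target_rejected(self):
        traits = tuple(TraitSpec(f"t{i}", 0.0, 1.0, r_dprime=0.8)
                       for i in range(3))
        with pytest.raises(ConfigurationError):
            _config(traits=traits)

    def test_single_draw_api(self):
        p = sample_participant_params(_config(), np.random.default_rng(0))
        assert p.c_incongruent - p.c_congruent == pytest.approx(p.m_true)


class TestGenerateCohort:
    def test_study_scale_shapes(self):
        cohort = generate_cohort(CohortConfig(seed=0))
        assert len(cohort.participants) == 300
        assert cohort.judgments.shape == (300, 80)
        assert cohort.participants["group"].value_counts().tolist() == [150, 150]

    def test_chance_responding(self):
        cfg = _config(dprime_dist=(0.0, 0.0), criterion_dist=(0.0, 0.0),
                      myside_dist=(0.0, 0.0), n_per_group=50)
        cohort = generate_cohort(cfg)
        pooled = cohort.judgments.to_numpy().mean()
        assert pooled == pytest.approx(0.5, abs=0.02)

    def test_high_sensitivity_hit_rate(self):
        cfg = _config(dprime_dist=(3.0, 0.0), criterion_dist=(0.0, 0.0),
                      myside_dist=(0.0, 0.0), items_per_cell=200,
                      n_per_group=5)
        cohort = generate_cohort(cfg)
        true_items = cohort.bank.loc[cohort.bank["veracity"], "item_id"]
        hit_rates = cohort.judgments[true_items].mean(axis=1)
        assert np.abs(hit_rates - norm.cdf(1.5)).max() < 0.05

    def test_same_seed_byte_identical(self):
        a = generate_cohort(CohortConfig(seed=42, n_per_group=20))
        b = generate_cohort(CohortConfig(seed=42, n_per_group=20))
        pd.testing.assert_frame_equal(a.judgments, b.judgments)
        pd.testing.assert_frame_equal(a.participants, b.participants)
        pd.testing.assert_frame_equal(a.latents, b.latents)

    def test_recovery_error_shrinks_with_items(self):
        errs = []
        for ipc in (100, 1600):
            cfg = _config(dprime_dist=(1.0, 0.0), criterion_dist=(0.3, 0.0),
                          myside_dist=(0.6, 0.0), items_per_cell=ipc,
                          n_per_group=15, seed=5)
            cohort = generate_cohort(cfg)
            s = score_cohort(cohort.judgments, cohort.bank,
                             cohort.participants["group"])
            mae = (abs(s["d_prime"] - 1.0).mean()
                   + abs(s["c_overall"] - 0.3).mean()
                   + abs(s["myside"] - 0.6).mean())
            errs.append(mae)
        assert errs[1] < errs[0]

    def test_trait_correlation_recovery(self):
        """Estimated corr(trait, estimated d') approaches the configured
        latent correlation when items are plentiful and the trait is used
        at perfect reliability."""
        trait = TraitSpec("t", 0.0, 1.0, r_dprime=0.3)
        cfg = _config(traits=(trait,), items_per_cell=1000, n_per_group=1000,
                      seed=7)
        cohort = generate_cohort(cfg)
        s = score_cohort(cohort.judgments, cohort.bank,
                         cohort.participants["group"])
        r = np.corrcoef(cohort.latents["t"], s["d_prime"])[0, 1]
        assert r == pytest.approx(0.3, abs=0.05)

    def test_exclusion_flags(self):
        cfg = _config(n_per_group=150, n_attention_failures=21,
                      n_inconsistent=5)
        cohort = generate_cohort(cfg)
        p = cohort.participants
        assert (~p["attention_passed"]).sum() == 21
        inconsistent = p["attention_passed"] & (p["group"] != p["prescreen_group"])
        assert inconsistent.sum() == 5


class TestRoundTripIO:
    def test_write_load(self, tmp_path):
        cohort = generate_cohort(_config(n_per_group=5, items_per_cell=2,
                                         traits=(TraitSpec("aot", 4.6, 0.7),)))
        write_cohort(cohort, tmp_path)
        loaded = load_cohort(tmp_path)
        pd.testing.assert_frame_equal(loaded.judgments, cohort.judgments,
                                      check_names=False)
        assert loaded.config == cohort.config

    def test_incomplete_import_rejected(self, tmp_path):
        cohort = generate_cohort(_config(n_per_group=3, items_per_cell=2))
        write_cohort(cohort, tmp_path)
        long = pd.read_csv(tmp_path / "judgments.csv")
        long.iloc[:-1].to_csv(tmp_path / "judgments.csv", index=False)
        with pytest.raises(ValidationError):
            load_cohort(tmp_path)
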