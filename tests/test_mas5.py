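"""Unit and property tests for the MAS5-style engine."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gliascope.mas5 import (Mas5Params, detection_call, detection_pvalue,
                            ideal_mismatch, normalize_dataset, probeset_signal,
                            scale_array, specific_background, trimmed_mean,
                            tukey_biweight)
from gliascope.synthetic_data import (NoiseParams, generate_tissue_samples,
                                      generate_celltype_profiles,
                                      CONTROL_COMPOSITION)

from conftest import biweight_oracle, signed_rank_oracle


class TestTukeyBiweight:
    @pytest.mark.parametrize("values, expected", [
        ([7.0] * 5, 7.0),               # constant vector
        ([3.25], 3.25),                 # single value
    ])
    def test_degenerate_vectors(self, values, expected):
        assert tukey_biweight(values) == pytest.approx(expected)

    def test_outlier_downweighted(self):
        # median 3, MAD 1: the 100 gets |u| > 1 hence zero weight
        result = tukey_biweight([1, 2, 3, 4, 100], c=5.0, epsilon=1e-4)
        assert result == pytest.approx(2.602, abs=5e-4)
        assert result == pytest.approx(
            biweight_oracle([1, 2, 3, 4, 100]), abs=1e-12)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 25))
            x = rng.normal(0, 3, n) + rng.exponential(5, n)
            assert tukey_biweight(x) == pytest.approx(
                biweight_oracle(x), rel=1e-9, abs=1e-12)

    def test_axis_version_agrees_with_per_row(self, rng):
        x = rng.lognormal(2.0, 1.0, (50, 11))
        rows = tukey_biweight(x, axis=1)
        for i in range(50):
            assert rows[i] == pytest.approx(tukey_biweight(x[i]), rel=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            tukey_biweight([])


class TestIdealMismatch:
    def test_informative_mm_is_used(self):
        assert ideal_mismatch([1000.0], [200.0])[0] == 200.0

    def test_large_specific_background_branch(self):
        im = ideal_mismatch([100.0], [150.0], sb=2.0, contrast_tau=0.03)
        assert im[0] == pytest.approx(100.0 / 2 ** 2.0)

    def test_small_specific_background_branch(self):
        sb, ct, stau = 0.01, 0.03, 10.0
        im = ideal_mismatch([100.0], [150.0], sb=sb, contrast_tau=ct,
                            scale_tau=stau)
        expected = 100.0 / 2 ** (ct / (1 + (ct - sb) / stau))
        assert im[0] == pytest.approx(expected)

    def test_im_below_pm_always(self, rng):
        pm = rng.lognormal(5, 1, 200) + 1.0
        mm = rng.lognormal(5, 1.2, 200) + 1.0
        im = ideal_mismatch(pm, mm)
        assert np.all(im < pm)
        assert np.all(im[mm < pm] == mm[mm < pm])


class TestProbesetSignal:
    def test_single_pair_is_pm_minus_mm(self):
        assert probeset_signal([1000.0], [200.0]) == pytest.approx(800.0)

    def test_identical_pairs(self):
        # pm - mm = 64 for every pair -> signal 64
        assert probeset_signal([100.0] * 6, [36.0] * 6) == pytest.approx(64.0)

    def test_heterogeneous_pairs_match_bruteforce(self, rng):
        import math
        for _ in range(50):
            n = int(rng.integers(2, 16))
            pm = rng.lognormal(6, 1, n) + 1
            mm = pm * rng.uniform(0.05, 1.3, n)
            sb = biweight_oracle([math.log2(p / m) for p, m in zip(pm, mm)])
            vs = []
            for p, m in zip(pm, mm):
                if m < p:
                    im = m
                elif sb > 0.03:
                    im = p / 2 ** sb
                else:
                    im = p / 2 ** (0.03 / (1 + (0.03 - sb) / 10.0))
                vs.append(math.log2(max(p - im, 2.0 ** -20)))
            expected = 2 ** biweight_oracle(vs)
            assert probeset_signal(pm, mm) == pytest.approx(expected, rel=1e-9)


class TestDetection:
    def test_exact_p_all_positive(self):
        # all discrimination scores far above tau: p = 1 / 2^n
        assert detection_pvalue([1000.0] * 4, [10.0] * 4) == pytest.approx(1 / 16)
        assert detection_pvalue([1000.0] * 5, [10.0] * 5) == pytest.approx(1 / 32)

    def test_all_scores_at_tau_gives_one(self):
        # R = 6/400 = 0.015 = tau exactly: every pair is dropped
        assert detection_pvalue([203.0] * 6, [197.0] * 6, tau=0.015) == 1.0

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(150):
            n = int(rng.integers(1, 13))
            pm = rng.lognormal(5, 1, n) + 1
            mm = pm * rng.uniform(0.1, 1.5, n)
            assert detection_pvalue(pm, mm) == pytest.approx(
                signed_rank_oracle(pm, mm), abs=1e-12)

    def test_monotone_in_pm(self, rng):
        for _ in range(30):
            n = int(rng.integers(3, 12))
            pm = rng.lognormal(5, 1, n) + 1
            mm = pm * rng.uniform(0.3, 1.4, n)
            p0 = detection_pvalue(pm, mm)
            i = int(rng.integers(n))
            pm2 = pm.copy()
            pm2[i] *= rng.uniform(1.1, 3.0)
            assert detection_pvalue(pm2, mm) <= p0 + 1e-12

    def test_normal_approximation_near_exact_at_crossover(self, rng):
        # n = 12 is the last exact size; the approximation must be close
        for _ in range(40):
            pm = rng.lognormal(5, 1, 12) + 1
            mm = pm * rng.uniform(0.3, 1.4, 12)
            exact = detection_pvalue(pm, mm, exact_limit=12)
            approx = detection_pvalue(pm, mm, exact_limit=0)
            assert abs(exact - approx) <= 0.01

    def test_zero_total_intensity_rejected(self):
        with pytest.raises(ValueError):
            detection_pvalue([0.0, 10.0], [0.0, 5.0])


class TestDetectionCall:
    @pytest.mark.parametrize("p, expected", [
        (0.03125, "P"),
        (0.0625, "A"),
        (0.05, "M"),
    ])
    def test_thresholds(self, p, expected):
        assert detection_call(p, alpha1=0.04, alpha2=0.06) == expected

    def test_invalid_alphas(self):
        with pytest.raises(ValueError):
            detection_call(0.05, alpha1=0.06, alpha2=0.04)


class TestScaling:
    def test_factor_and_mean(self):
        scaled, factor = scale_array([100, 200, 300, 400, 500], target=500.0,
                                     trim=0.02)
        assert factor == pytest.approx(5 / 3)
        assert scaled.mean() == pytest.approx(500.0)

    def test_identity_when_at_target(self):
        x = np.array([400.0, 500.0, 600.0])
        scaled, factor = scale_array(x, target=500.0, trim=0.0)
        assert factor == pytest.approx(1.0)
        assert np.allclose(scaled, x)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_trimmed_mean_hits_target(self, seed):
        x = np.random.default_rng(seed).lognormal(5, 1.5, 200)
        scaled, _ = scale_array(x, target=500.0, trim=0.02)
        assert trimmed_mean(scaled, 0.02) == pytest.approx(500.0, rel=1e-6)
        # order statistics preserved
        assert np.array_equal(np.argsort(scaled), np.argsort(x))


def _small_dataset(seed=0, n_genes=60, cv=0.2, n_replicates=3):
    profiles = generate_celltype_profiles(n_genes, 0.2, 5.0, seed=seed)
    ds = generate_tissue_samples(profiles, CONTROL_COMPOSITION,
                                 n_replicates=n_replicates,
                                 noise=NoiseParams(cv=cv, background=30.0),
                                 probes_per_set=11, seed=seed)
    return ds


class TestNormalizeDataset:
    def test_probe_order_permutation_invariance(self):
        ds = _small_dataset(seed=1)
        em1 = normalize_dataset(ds.intensities, ds.layout)
        shuffled = ds.layout.table.sample(frac=1.0, random_state=0)
        from gliascope.synthetic_data import ChipLayout
        em2 = normalize_dataset(ds.intensities, ChipLayout(table=shuffled))
        pd.testing.assert_frame_equal(em1.signals, em2.signals)
        pd.testing.assert_frame_equal(em1.pvalues, em2.pvalues)

    def test_per_array_invariance_under_dataset_growth(self):
        # adding samples never changes samples already analyzed
        ds = _small_dataset(seed=2, n_replicates=6)
        full = normalize_dataset(ds.intensities, ds.layout)
        first3 = normalize_dataset(ds.intensities.iloc[:, :3], ds.layout)
        pd.testing.assert_frame_equal(full.signals.iloc[:, :3], first3.signals)
        pd.testing.assert_series_equal(full.scale_factors.iloc[:3],
                                       first3.scale_factors)

    def test_scaled_signals_invariant_to_sample_rescaling(self):
        ds = _small_dataset(seed=3)
        em1 = normalize_dataset(ds.intensities, ds.layout)
        bumped = ds.intensities.copy()
        bumped.iloc[:, 0] *= 7.5
        em2 = normalize_dataset(bumped, ds.layout)
        # unscaled signal ~ 7.5x -> factor ~ /7.5 -> scaled unchanged
        np.testing.assert_allclose(em2.signals.iloc[:, 0],
                                   em1.signals.iloc[:, 0], rtol=1e-6)
        assert em2.scale_factors.iloc[0] == pytest.approx(
            em1.scale_factors.iloc[0] / 7.5, rel=1e-6)

    def test_matches_per_probeset_functions(self):
        params = Mas5Params()
        ds = _small_dataset(seed=4, n_genes=20)
        em = normalize_dataset(ds.intensities, ds.layout, params)
        table = ds.layout.table
        ps = em.probesets[5]
        rows = table[table["probeset_id"] == ps].sort_values("pair_index")
        sample = em.samples[0]
        pm = ds.intensities.loc[rows[rows.role == "PM"]["probe_id"], sample]
        mm = ds.intensities.loc[rows[rows.role == "MM"]["probe_id"], sample]
        unscaled = em.signals.loc[ps, sample] / em.scale_factors[sample]
        assert unscaled == pytest.approx(
            probeset_signal(pm.to_numpy(), mm.to_numpy(), params), rel=1e-9)
        assert em.pvalues.loc[ps, sample] == pytest.approx(
            detection_pvalue(pm.to_numpy(), mm.to_numpy(), params.tau),
            abs=1e-12)

    def test_missing_probe_rejected(self):
        ds = _small_dataset(seed=5, n_genes=15)
        with pytest.raises(ValueError, match="missing from the intensity"):
            normalize_dataset(ds.intensities.iloc[5:], ds.layout)

    def test_duplicate_layout_entry_rejected(self):
        ds = _small_dataset(seed=6, n_genes=15)
        from gliascope.synthetic_data import ChipLayout
        dup = pd.concat([ds.layout.table, ds.layout.table.iloc[:1]])
        with pytest.raises(ValueError, match="duplicated probe_id"):
            normalize_dataset(ds.intensities, ChipLayout(table=dup))


def test_specific_background_is_biweight_of_log_ratios(rng):
    pm = rng.lognormal(6, 1, 11) + 1
    mm = pm * rng.uniform(0.2, 1.2, 11)
    assert specific_background(pm, mm) == pytest.approx(
        biweight_oracle(np.log2(pm / mm)), rel=1e-12)
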