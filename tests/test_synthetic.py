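"""Tests of the synthetic-data generator and its closed-form oracles."""

import numpy as np
import pandas as pd
import pytest

from gliascope.celltypes import CELL_TYPES, UNCLASSIFIED
from gliascope.synthetic_data import (CONTROL_COMPOSITION, GLIOSIS_COMPOSITION,
                                      CompositionVector, DiseaseEffect,
                                      NoiseParams, SyntheticTruth,
                                      expected_isolated_abundance,
                                      expected_mixture_abundance,
                                      generate_celltype_profiles,
                                      generate_isolated_celltype_samples,
                                      generate_tissue_samples,
                                      validate_disease_shift,
                                      validate_effects)

NOISE_FREE = NoiseParams(cv=0.0, background=0.0)


class TestProfiles:
    def test_planted_counts(self):
        prof = generate_celltype_profiles(100, enriched_fraction=0.2,
                                          enrichment_factor=5.0, seed=0)
        enriched = prof.planted_class != UNCLASSIFIED
        assert int(enriched.sum()) == 20
        assert int((~enriched).sum()) == 80

    def test_zero_fraction_all_unclassified(self):
        prof = generate_celltype_profiles(50, enriched_fraction=0.0, seed=1)
        assert (prof.planted_class == UNCLASSIFIED).all()

    def test_enriched_ratio_exact_and_others_below_four(self):
        prof = generate_celltype_profiles(200, 0.3, enrichment_factor=5.0,
                                          seed=2)
        expr = prof.expression
        for gene, cls in prof.planted_class.items():
            row = expr.loc[gene].to_numpy()
            if cls == UNCLASSIFIED:
                assert row.max() / row.min() < 4.0
            else:
                j = CELL_TYPES.index(cls)
                others = np.delete(row, j)
                assert row[j] == pytest.approx(5.0 * others.max(), rel=1e-12)

    @pytest.mark.parametrize("kwargs", [
        {"n_genes": 9},
        {"n_genes": 100, "enrichment_factor": 0.5},
        {"n_genes": 100, "enriched_fraction": 1.5},
    ])
    def test_invalid_arguments(self, kwargs):
        with pytest.raises(ValueError):
            generate_celltype_profiles(**kwargs)


class TestComposition:
    def test_weights_must_sum_to_one(self):
        w = dict(CONTROL_COMPOSITION.weights)
        w["microglia"] += 0.01
        with pytest.raises(ValueError, match="sum"):
            CompositionVector(w)

    def test_disease_shift_validation(self):
        validate_disease_shift(CONTROL_COMPOSITION, GLIOSIS_COMPOSITION)
        bad = CompositionVector(dict(CONTROL_COMPOSITION.weights), "disease")
        with pytest.raises(ValueError):
            validate_disease_shift(CONTROL_COMPOSITION, bad)


class TestTissueSamples:
    def test_noise_free_matches_mixture_oracle(self):
        prof = generate_celltype_profiles(40, 0.25, 5.0, seed=3)
        effects = [DiseaseEffect("g00001", "microglia", 3.0)]
        comp = CompositionVector(dict(GLIOSIS_COMPOSITION.weights), "disease")
        ds = generate_tissue_samples(prof, comp, effects, n_replicates=2,
                                     noise=NOISE_FREE, seed=3, cross_hyb=0.0)
        expected = expected_mixture_abundance(prof, comp, effects)
        pm_t = ds.layout.table[ds.layout.table.role == "PM"]
        gene_of = ds.annotation.set_index("probeset_id")["gene_id"]
        pm = ds.intensities.loc[pm_t["probe_id"], ds.intensities.columns[0]]
        implied = pm.to_numpy() / pm_t["affinity"].to_numpy()
        want = expected.loc[gene_of.loc[pm_t["probeset_id"]]].to_numpy()
        np.testing.assert_allclose(implied, want, rtol=1e-9)
        # cross_hyb 0, background 0 -> MM identically zero
        mm_ids = ds.layout.table.loc[ds.layout.table.role == "MM", "probe_id"]
        assert (ds.intensities.loc[mm_ids] == 0.0).all().all()

    def test_null_case_expected_fold_change_is_one(self):
        prof = generate_celltype_profiles(30, 0.2, 5.0, seed=4)
        ctl = expected_mixture_abundance(prof, CONTROL_COMPOSITION)
        dis = expected_mixture_abundance(
            prof, CompositionVector(dict(CONTROL_COMPOSITION.weights),
                                    "disease"), ())
        np.testing.assert_allclose((dis / ctl).to_numpy(), 1.0, rtol=1e-12)

    def test_composition_amplifies_glial_effect(self):
        # strongly microglia-enriched gene, 3-fold microglial induction,
        # microgliosis composition -> tissue-level FC exceeds 3
        prof = generate_celltype_profiles(20, 0.0, seed=5)
        expr = prof.expression.copy()
        expr.loc["g00000"] = [1.0, 1.0, 1.0, 500.0, 1.0]
        prof.expression = expr
        effects = [DiseaseEffect("g00000", "microglia", 3.0)]
        ctl = expected_mixture_abundance(prof, CONTROL_COMPOSITION)
        dis = expected_mixture_abundance(prof, GLIOSIS_COMPOSITION, effects)
        fc = dis["g00000"] / ctl["g00000"]
        assert fc > 3.0

    def test_marker_shift_signature(self):
        # with the constrained composition shift and no planted effects,
        # motor-neuron markers fall and glial markers rise
        for seed in range(5):
            prof = generate_celltype_profiles(60, 0.3, 8.0, seed=seed)
            ctl = expected_mixture_abundance(prof, CONTROL_COMPOSITION)
            dis = expected_mixture_abundance(prof, GLIOSIS_COMPOSITION, ())
            fc = dis / ctl
            cls = prof.planted_class
            assert (fc[cls == "motor_neuron"] < 1.0).all()
            assert (fc[cls == "microglia"] > 1.0).all()
            assert (fc[cls == "astrocyte"] > 1.0).all()

    def test_seed_determinism(self):
        prof = generate_celltype_profiles(25, 0.2, 5.0, seed=6)
        a = generate_tissue_samples(prof, CONTROL_COMPOSITION, seed=99)
        b = generate_tissue_samples(prof, CONTROL_COMPOSITION, seed=99)
        pd.testing.assert_frame_equal(a.intensities, b.intensities)
        pd.testing.assert_frame_equal(a.layout.table, b.layout.table)

    def test_replicate_count_validated(self):
        prof = generate_celltype_profiles(25, 0.2, 5.0, seed=7)
        with pytest.raises(ValueError):
            generate_tissue_samples(prof, CONTROL_COMPOSITION, n_replicates=1)


class TestIsolatedSamples:
    def test_zero_contamination_is_pure_profile(self):
        prof = generate_celltype_profiles(30, 0.2, 5.0, seed=8)
        ab = expected_isolated_abundance(prof, "astrocyte", 0.0)
        np.testing.assert_allclose(ab.to_numpy(),
                                   prof.expression["astrocyte"].to_numpy())

    def test_contamination_mixture_arithmetic(self):
        # a pure foreign marker leaks in proportionally to contamination
        prof = generate_celltype_profiles(20, 0.0, seed=9)
        expr = prof.expression.copy()
        expr.loc["g00000"] = [1e-6, 1e-6, 1e-6, 1000.0, 1e-6]  # microglial
        prof.expression = expr
        ab = expected_isolated_abundance(prof, "astrocyte", 0.1)
        # 0.1 contamination spread uniformly over 4 foreign types
        assert ab["g00000"] == pytest.approx(0.1 / 4 * 1000.0, rel=1e-6)

    def test_ectopic_induction_beats_contamination_markers(self):
        # a 50-fold astrocytic induction of a microglia-class gene produces
        # a far larger apparent FC than pure microglial markers leak in
        prof = generate_celltype_profiles(40, 0.5, 5.0, seed=10,
                                          class_weights={"microglia": 1.0})
        mg = prof.planted_class.index[prof.planted_class == "microglia"]
        ectopic, marker = mg[0], mg[1]
        effects = [DiseaseEffect(ectopic, "astrocyte", 50.0, ectopic=True),
                   DiseaseEffect(marker, "microglia", 8.5)]
        validate_effects(effects, prof.planted_class)
        ctl = expected_isolated_abundance(prof, "astrocyte", 0.1, (), "control")
        dis = expected_isolated_abundance(prof, "astrocyte", 0.1, effects,
                                          "disease")
        fc = dis / ctl
        assert fc[ectopic] > 5 * fc[marker]

    def test_contamination_bound(self):
        prof = generate_celltype_profiles(20, 0.2, 5.0, seed=11)
        with pytest.raises(ValueError):
            generate_isolated_celltype_samples(prof, "microglia", 0.5)

    def test_ectopic_flag_requires_foreign_class(self):
        prof = generate_celltype_profiles(30, 0.5, 5.0, seed=12,
                                          class_weights={"microglia": 1.0})
        mg = prof.planted_class.index[prof.planted_class == "microglia"][0]
        bad = [DiseaseEffect(mg, "microglia", 5.0, ectopic=True)]
        with pytest.raises(ValueError, match="ectopic"):
            validate_effects(bad, prof.planted_class)


def test_truth_round_trips_losslessly():
    truth = SyntheticTruth(
        seed=7, planted_deg_genes=frozenset({"g1", "g2"}),
        planted_class={"g1": "microglia", "g2": UNCLASSIFIED},
        planted_ectopic=frozenset({("g1", "astrocyte")}),
        compositions={"control": dict(CONTROL_COMPOSITION.weights)},
        noise=NoiseParams(cv=0.15, background=50.0))
    assert SyntheticTruth.from_json(truth.to_json()) == truth
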