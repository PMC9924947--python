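"""Synthetic cohort generator: determinism, calibration, count model."""

import numpy as np
import pandas as pd
import pytest

from stresslink.simulate import (SimConfig, generate_cohort,
                                 generate_survival_times, survival_records)
from stresslink.survival import logrank_test


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        {"n_worms_per_assay_arm": 0},
        {"n_genes": -5},
        {"censor_rate": 1.0},
        {"weibull_shape": 0.0},
        {"wt_lifespan_mean": -1.0},
        {"n_rnaseq_replicates": 0},
    ])
    def test_invalid_sizes_rejected(self, kw):
        with pytest.raises(ValueError):
            SimConfig(**kw)

    def test_module_sizes_must_fit_in_genome(self):
        with pytest.raises(ValueError, match="module sizes"):
            SimConfig(n_genes=100, n_shared_driver=80, n_lifespan_only=80)

    def test_global_shared_weight_overrides_assays(self):
        cfg = SimConfig(shared_weight=1.0)
        assert all(a.shared_weight == 1.0 for a in cfg.stress_assays)


class TestSurvivalTimes:
    def test_no_censoring_all_events(self, rng):
        _, events = generate_survival_times(10.0, 200, 0.0, rng)
        assert events.all()

    def test_censored_fraction_tracks_rate(self, rng):
        _, events = generate_survival_times(10.0, 5000, 0.3, rng)
        assert (events == 0).mean() == pytest.approx(0.3, abs=0.02)

    def test_exponential_mean_identity(self, rng):
        # shape 1 reduces to the exponential with mean = scale
        times, _ = generate_survival_times(10.0, 50000, 0.0, rng, shape=1.0)
        assert times.mean() == pytest.approx(10.0, rel=0.02)

    def test_times_strictly_positive(self, rng):
        times, _ = generate_survival_times(5.0, 1000, 0.5, rng)
        assert (times > 0).all()

    def test_nonpositive_n_rejected(self, rng):
        with pytest.raises(ValueError):
            generate_survival_times(10.0, 0, 0.0, rng)
        with pytest.raises(ValueError):
            generate_survival_times(-1.0, 10, 0.0, rng)

    def test_two_fold_scale_separable_by_logrank(self):
        ta, ea = generate_survival_times(10.0, 1000, 0.0, 1)
        tb, eb = generate_survival_times(20.0, 1000, 0.0, 2)
        recs = lambda t, e: survival_records(pd.DataFrame({
            "strain": "s", "assay": "a", "replicate": "r",
            "time": t, "event": e, "control_group": "c"}))
        assert logrank_test(recs(ta, ea), recs(tb, eb)).p_value < 1e-10


class TestDeterminism:
    def test_identical_config_identical_outputs(self):
        cfg = SimConfig(seed=7, n_genes=120, n_shared_driver=10,
                        n_lifespan_only=5, n_stress_specific=5,
                        n_worms_per_assay_arm=20)
        s1, c1, m1, g1, t1 = generate_cohort(cfg)
        s2, c2, m2, g2, t2 = generate_cohort(cfg)
        pd.testing.assert_frame_equal(s1, s2)
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_frame_equal(m1, m2)
        assert g1 == g2
        assert t1.gene_module == t2.gene_module

    def test_seed_changes_output(self):
        kw = dict(n_genes=120, n_shared_driver=10, n_lifespan_only=5,
                  n_stress_specific=5, n_worms_per_assay_arm=20)
        s1, *_ = generate_cohort(SimConfig(seed=1, **kw))
        s2, *_ = generate_cohort(SimConfig(seed=2, **kw))
        assert not s1["time"].equals(s2["time"])


class TestCohortStructure:
    def test_every_arm_fully_populated(self, small_cohort):
        cfg, (surv, counts, meta, gsets, truth) = small_cohort
        arm_sizes = surv.groupby(["strain", "assay"]).size()
        assert (arm_sizes == cfg.n_worms_per_assay_arm).all()
        n_assays = len(cfg.stress_assays) + 1
        assert len(arm_sizes) == len(cfg.all_strains) * n_assays

    def test_alternate_temperature_control_present(self, small_cohort):
        cfg, (surv, *_rest) = small_cohort
        ctrl = surv.loc[surv["strain"] == cfg.alt_temp_strain,
                        "control_group"].unique()
        assert list(ctrl) == ["WT-25C"]
        assert "WT-25C" in set(surv["strain"])

    def test_counts_are_nonnegative_integers(self, small_cohort):
        _, (_, counts, meta, _, _) = small_cohort
        arr = counts.to_numpy()
        assert (arr >= 0).all() and np.issubdtype(arr.dtype, np.integer)
        assert counts.shape[1] == len(meta)

    def test_batches_round_robin_across_replicates(self, small_cohort):
        cfg, (_, _, meta, _, _) = small_cohort
        per_strain = meta.groupby("strain")["batch"].value_counts().unstack()
        assert (per_strain.max(axis=1) - per_strain.min(axis=1) <= 1).all()

    def test_every_gene_has_one_module_and_nulls_uncoupled(self, small_cohort):
        cfg, (_, counts, _, _, truth) = small_cohort
        assert set(truth.gene_module) == set(counts.index)
        for g in truth.module_genes("null"):
            assert truth.coupling_lifespan[g] == 0.0
            assert all(v == 0.0 for v in truth.coupling_stress[g].values())


class TestCalibration:
    def test_lifespan_extension_recovered(self):
        # a strain with a 0.5 longevity effect should show ~50% extension
        cfg = SimConfig(seed=3, strain_longevity_effects={"m": 0.5},
                        alt_temp_strain=None, n_worms_per_assay_arm=2000,
                        censor_rate=0.0, n_genes=10, n_shared_driver=0,
                        n_lifespan_only=0, n_stress_specific=1)
        surv, *_ = generate_cohort(cfg)
        ls = surv[surv["assay"] == "lifespan"]
        mean_wt = ls.loc[ls["strain"] == "WT", "time"].mean()
        mean_m = ls.loc[ls["strain"] == "m", "time"].mean()
        ext = 100 * (mean_m - mean_wt) / mean_wt
        assert ext == pytest.approx(50.0, rel=0.05)

    def test_planted_fold_change_realized(self):
        # beta=1 with traits {0,1} and near-zero dispersion: log2 FC = 1
        cfg = SimConfig(seed=5, strain_longevity_effects={"m": 1.0},
                        alt_temp_strain=None, shared_weight=1.0,
                        nb_dispersion=1e-12, n_rnaseq_replicates=6,
                        n_genes=60, n_shared_driver=20, n_lifespan_only=0,
                        n_stress_specific=0, batch_count=1,
                        n_worms_per_assay_arm=5)
        _, counts, meta, _, truth = generate_cohort(cfg)
        shared = sorted(truth.module_genes("shared_driver"))
        m_cols = meta.index[meta["strain"] == "m"]
        wt_cols = meta.index[meta["strain"] == "WT"]
        lfc = (np.log2(counts.loc[shared, m_cols].mean(axis=1))
               - np.log2(counts.loc[shared, wt_cols].mean(axis=1)))
        assert lfc.mean() == pytest.approx(1.0, abs=0.05)

    def test_near_zero_dispersion_is_poisson_like(self):
        cfg = SimConfig(seed=9, strain_longevity_effects={"m": 0.0},
                        alt_temp_strain=None, nb_dispersion=0.0,
                        effect_size=0.0, n_rnaseq_replicates=50,
                        n_genes=200, n_shared_driver=0, n_lifespan_only=0,
                        n_stress_specific=0, batch_count=1,
                        n_worms_per_assay_arm=5)
        _, counts, meta, _, _ = generate_cohort(cfg)
        wt = counts[meta.index[meta["strain"] == "WT"]]
        mu = wt.mean(axis=1)
        var = wt.var(axis=1)
        big = mu > 20
        ratio = (var[big] / mu[big])
        assert ratio.mean() == pytest.approx(1.0, abs=0.1)
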