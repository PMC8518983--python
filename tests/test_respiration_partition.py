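"""Tissue-class volume partitioning, the respiration regression and SRR_R."""

import numpy as np
import pandas as pd
import pytest

from rootecon import (
    broad_sense_h2,
    fit_partition_model,
    fit_rcbd_reml,
    partition_volumes,
    residual_trait,
    simulate_root_system,
    stepwise_aic,
)
from rootecon.respiration_partition import PREDICTORS
from rootecon.synthetic_data import (
    SRR_AXIAL_DEFAULT,
    SRR_LATERAL_AXIS_DEFAULT,
    SRR_TIP_DEFAULT,
)


def features_frame(tips, lrv, arv=244.0):
    return pd.DataFrame(
        {"sample_id": [f"S{i}" for i in range(len(tips))],
         "tips": tips, "lrv_mm3": lrv, "arv_mm3": arv}
    )


class TestPartitionVolumes:
    def test_seminal_subtraction_and_tip_volume(self):
        v = partition_volumes(features_frame([404.0], [85.59]))
        assert v["n_lateral_tips"].iloc[0] == 400
        assert v["tip_volume_mm3"].iloc[0] == pytest.approx(4.00)

    def test_panel_mean_tip_count(self):
        v = partition_volumes(features_frame([399.61], [85.59]))
        assert v["tip_volume_mm3"].iloc[0] == pytest.approx(3.9561)
        assert v["lateral_axis_volume_mm3"].iloc[0] == pytest.approx(81.6339)

    def test_fewer_tips_than_seminal_clamped(self):
        v = partition_volumes(features_frame([2.0], [5.0]))
        assert v["n_lateral_tips"].iloc[0] == 0
        assert v["tip_volume_mm3"].iloc[0] == 0
        assert bool(v["clamped"].iloc[0])

    def test_negative_lateral_axis_clamped_and_flagged(self):
        v = partition_volumes(features_frame([500.0], [1.0]))
        assert v["lateral_axis_volume_mm3"].iloc[0] == 0.0
        assert bool(v["clamped"].iloc[0])

    def test_no_clamping_on_well_formed_data(self):
        feats, _ = simulate_root_system(n_samples=200, seed=3)
        v = partition_volumes(feats)
        assert int(v["clamped"].sum()) == 0


def fit_simulated(n, noise_sd, seed=0, rates=None):
    params = {"resp_noise_sd": noise_sd}
    kwargs = dict(zip(("srr_axial", "srr_lateral_axis", "srr_tip"), rates)) if rates else {}
    feats, resp = simulate_root_system(
        architecture_params=params, n_samples=n, seed=seed, **kwargs
    )
    vols = partition_volumes(feats)
    flux = pd.DataFrame({"sample_id": feats["sample_id"], "flux_nmol_s": resp})
    return vols, flux, fit_partition_model(vols, flux)


class TestFitPartitionModel:
    def test_noiseless_exact_recovery(self):
        _, _, m = fit_simulated(10, 0.0)
        assert m.r_squared == pytest.approx(1.0, abs=1e-10)
        assert m.params["axial_volume_mm3"] == pytest.approx(SRR_AXIAL_DEFAULT, abs=1e-12)
        assert m.params["lateral_axis_volume_mm3"] == pytest.approx(
            SRR_LATERAL_AXIS_DEFAULT, abs=1e-12
        )
        assert m.params["tip_volume_mm3"] == pytest.approx(SRR_TIP_DEFAULT, abs=1e-12)
        assert m.ratio_tip_axial == pytest.approx(30.5, abs=1e-9)
        assert m.ratio_tip_lateral == pytest.approx(8.1, abs=1e-9)

    def test_ratio_recovery_under_measurement_noise(self):
        _, _, m = fit_simulated(1000, 0.02, seed=1)
        assert m.ratio_tip_axial == pytest.approx(30.5, rel=0.15)
        assert m.ratio_tip_lateral == pytest.approx(8.1, rel=0.15)

    def test_equal_rates_give_indistinguishable_slopes(self):
        _, _, m = fit_simulated(800, 0.02, seed=4, rates=(0.005, 0.005, 0.005))
        for a in PREDICTORS:
            for b in PREDICTORS:
                gap = abs(m.params[a] - m.params[b])
                assert gap < 4 * np.hypot(m.bse[a], m.bse[b])

    def test_permuted_response_collapses_r2(self, rng):
        vols, flux, m = fit_simulated(500, 0.02, seed=6)
        assert m.r_squared > 0.5
        shuffled = flux.copy()
        shuffled["flux_nmol_s"] = rng.permutation(shuffled["flux_nmol_s"].to_numpy())
        m_null = fit_partition_model(vols, shuffled)
        assert m_null.r_squared < 0.05

    def test_rank_deficient_design_names_columns(self):
        feats, resp = simulate_root_system(n_samples=30, seed=2)
        vols = partition_volumes(feats)
        vols["lateral_axis_volume_mm3"] = 2.0 * vols["axial_volume_mm3"]
        flux = pd.DataFrame({"sample_id": feats["sample_id"], "flux_nmol_s": resp})
        with pytest.raises(ValueError, match="axial_volume_mm3"):
            fit_partition_model(vols, flux)

    def test_too_few_cases_is_error(self):
        feats, resp = simulate_root_system(n_samples=4, seed=2)
        vols = partition_volumes(feats)
        flux = pd.DataFrame({"sample_id": feats["sample_id"], "flux_nmol_s": resp})
        with pytest.raises(ValueError, match=">= 5"):
            fit_partition_model(vols, flux)


class TestStepwiseAic:
    def test_strong_effects_keep_full_model(self):
        vols, flux, _ = fit_simulated(400, 0.02, seed=8)
        data = vols.merge(flux, on="sample_id").rename(columns={"flux_nmol_s": "trr"})
        selected, trace = stepwise_aic(data, "trr")
        assert sorted(selected) == sorted(PREDICTORS)
        assert trace[0]["action"] == "start"

    def test_null_term_usually_dropped(self, rng):
        drops = 0
        for seed in range(11):
            local = np.random.default_rng(seed)
            n = 600
            x1 = local.normal(0, 1, n)
            x2 = local.normal(0, 1, n)  # true zero effect
            y = 1.0 + 0.5 * x1 + local.normal(0, 1, n)
            data = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
            selected, _ = stepwise_aic(data, "y", terms=["x1", "x2"])
            drops += "x2" not in selected
        assert drops > 5  # dropped with probability > 0.5

    def test_single_predictor_selected_when_effective(self, rng):
        x = rng.normal(0, 1, 200)
        y = 2.0 + 1.5 * x + rng.normal(0, 0.5, 200)
        data = pd.DataFrame({"y": y, "x": x})
        selected, _ = stepwise_aic(data, "y", terms=["x"])
        assert selected == ["x"]


class TestResidualTrait:
    def test_fitting_set_mean_zero(self):
        vols, flux, m = fit_simulated(300, 0.02, seed=9)
        resid = residual_trait(m, vols, flux)
        assert abs(resid["SRR_R"].mean()) < 1e-10

    def test_sample_respiring_as_predicted_has_zero_residual(self):
        vols, flux, m = fit_simulated(50, 0.0, seed=10)
        resid = residual_trait(m, vols, flux)
        assert np.allclose(resid["SRR_R"], 0.0, atol=1e-10)

    def test_orthogonal_to_volume_predictors(self):
        vols, flux, m = fit_simulated(300, 0.02, seed=12)
        resid = residual_trait(m, vols, flux)
        for c in PREDICTORS:
            r = np.corrcoef(resid["SRR_R"], vols[c])[0, 1]
            assert abs(r) < 1e-8

    def test_heritability_rises_with_planted_metabolic_offsets(self):
        """Genotype-specific offsets make SRR_R heritable."""
        h2 = {}
        for offset_sd in (0.0, 0.10):
            rng = np.random.default_rng(77)
            n_g, n_b = 80, 4
            offsets = rng.normal(0, offset_sd, n_g)
            frames = []
            for j in range(n_b):
                feats, resp = simulate_root_system(
                    architecture_params={"resp_noise_sd": 0.0},
                    n_samples=n_g, seed=1000 + j,
                )
                resp = resp + offsets + rng.normal(0, 0.05, n_g)
                feats = feats.copy()
                feats["sample_id"] = [f"G{i}_B{j}" for i in range(n_g)]
                feats["genotype_id"] = [f"G{i}" for i in range(n_g)]
                feats["block_id"] = f"B{j}"
                feats["flux_nmol_s"] = resp
                frames.append(feats)
            allf = pd.concat(frames, ignore_index=True)
            vols = partition_volumes(allf)
            flux = allf[["sample_id", "flux_nmol_s"]]
            model = fit_partition_model(vols, flux)
            resid = residual_trait(model, vols, flux).merge(
                allf[["sample_id", "genotype_id", "block_id"]], on="sample_id"
            )
            vc = fit_rcbd_reml(resid, value_col="SRR_R")
            h2[offset_sd] = broad_sense_h2(vc)
        assert h2[0.10] > h2[0.0]
        assert h2[0.10] > 0.3
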