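"""Synthetic cohort generators: determinism, inversion, distribution recovery."""

from dataclasses import replace

import numpy as np
import pytest

import capsulemech as cm


class TestDeterminism:
    def test_sweep_bit_identical(self, configs):
        cfg = configs["Fb-P"]
        meta = cm.SampleMeta("Fb-P", 1, 2, seed=99)
        a = cm.gen_oscillation_sweep(cfg, meta, "low")
        b = cm.gen_oscillation_sweep(cfg, meta, "low")
        for ra, rb in zip(a.records, b.records):
            assert np.array_equal(ra.tau, rb.tau)

    def test_curve_and_plate_and_mask_identical(self, configs):
        cfg = configs["Fb-P"]
        meta = cm.SampleMeta("Fb-P", 0, 1, seed=42)
        assert np.array_equal(cm.gen_compression_curve(cfg, meta).sigma,
                              cm.gen_compression_curve(cfg, meta).sigma)
        plate_a = cm.gen_assay_plate(configs, [meta])
        plate_b = cm.gen_assay_plate(configs, [meta])
        assert plate_a.samples[0]["A513"] == plate_b.samples[0]["A513"]
        ma = cm.gen_section_mask(cfg, "cross", meta)
        mb = cm.gen_section_mask(cfg, "cross", meta)
        assert np.array_equal(ma.mask, mb.mask)

    def test_different_seeds_differ(self, configs):
        cfg = configs["Fb-P"]
        a = cm.gen_compression_curve(cfg, cm.SampleMeta("Fb-P", 0, 0, seed=1))
        b = cm.gen_compression_curve(cfg, cm.SampleMeta("Fb-P", 0, 0, seed=2))
        assert not np.array_equal(a.sigma, b.sigma)


class TestOscillationSweep:
    def test_waveform_shape_invariants(self, configs):
        sweep = cm.gen_oscillation_sweep(
            configs["Fb-P"], cm.SampleMeta("Fb-P", 0, 0, seed=3), "low")
        for rec in sweep.records:
            n_cycles = len(rec.t) * (rec.t[1] - rec.t[0]) * rec.omega / (2 * np.pi)
            assert n_cycles == pytest.approx(5.0, rel=1e-9)
            assert len(rec.t) / 5 >= 64

    def test_flat_noiseless_sweep_hits_group_mean(self, configs):
        """b=0, no noise, no biological spread: G'' = 390 Pa at every omega."""
        cfg = configs["Fb-PECM"]
        cfg0 = replace(cfg, rheo=replace(cfg.rheo, Gpp_low_sd_bio=0.0,
                                         power_exponent=0.0))
        meta = cm.SampleMeta("Fb-PECM", 0, 0, seed=7)
        spec = cm.analyze_sweep(
            cm.gen_oscillation_sweep(cfg0, meta, "low", noise=cm.NO_NOISE))
        assert np.allclose(spec.table["G_loss"], 390.0, rtol=1e-9)

    def test_delta_45_makes_moduli_equal(self, configs):
        cfg = configs["Fb-P"]
        cfg45 = replace(cfg, rheo=replace(cfg.rheo, delta_low_deg=45.0))
        meta = cm.SampleMeta("Fb-P", 0, 0, seed=7)
        spec = cm.analyze_sweep(
            cm.gen_oscillation_sweep(cfg45, meta, "low", noise=cm.NO_NOISE))
        assert np.allclose(spec.table["G_storage"], spec.table["G_loss"],
                           rtol=1e-9)

    def test_high_strain_delta_in_band(self, configs):
        cfg = configs["Fb-P"]
        for animal in range(4):
            meta = cm.SampleMeta("Fb-P", animal, 0, seed=31)
            spec = cm.analyze_sweep(
                cm.gen_oscillation_sweep(cfg, meta, "high", noise=cm.NO_NOISE))
            assert ((spec.table["delta"] >= 49.0 - 1e-6)
                    & (spec.table["delta"] <= 67.0 + 1e-6)).all()

    def test_invalid_strain_level(self, configs):
        with pytest.raises(ValueError, match="strain_level"):
            cm.gen_oscillation_sweep(configs["Fb-P"],
                                     cm.SampleMeta("Fb-P", 0, 0, seed=1),
                                     "medium")


class TestCompressionCurveGen:
    def test_equal_moduli_give_linear_curve(self, configs):
        cfg = configs["Fb-P"]
        cfg_lin = replace(cfg, comp=replace(cfg.comp, E_low=500.0,
                                            E_high_mean=500.0,
                                            E_high_sd_bio=0.0))
        meta = cm.SampleMeta("Fb-P", 0, 0, seed=5)
        curve = cm.gen_compression_curve(cfg_lin, meta, noise=cm.NO_NOISE)
        assert np.allclose(curve.sigma, 500.0 * curve.eps, rtol=1e-12)

    def test_noiseless_high_window_recovers_configured_mean(self, configs):
        cfg = configs["Fb-P"]
        cfg0 = replace(cfg, comp=replace(cfg.comp, E_high_sd_bio=0.0))
        meta = cm.SampleMeta("Fb-P", 0, 0, seed=5)
        curve = cm.gen_compression_curve(cfg0, meta, noise=cm.NO_NOISE)
        assert cm.window_modulus(curve, 0.30, 0.40) == pytest.approx(2042.0,
                                                                     rel=1e-9)

    def test_model_based_is_passthrough(self, configs, fbpecm_model_params):
        meta = cm.SampleMeta("Fb-PECM", 0, 0, seed=5)
        curve = cm.gen_compression_curve(
            configs["Fb-PECM"], meta, mode="model_based",
            model_params=fbpecm_model_params, noise=cm.NO_NOISE)
        sim = cm.simulate_compression(fbpecm_model_params)
        assert np.array_equal(curve.sigma, sim.sigma)

    def test_model_based_requires_params(self, configs):
        with pytest.raises(ValueError, match="model_params"):
            cm.gen_compression_curve(configs["Fb-PECM"],
                                     cm.SampleMeta("Fb-PECM", 0, 0, seed=1),
                                     mode="model_based")


class TestAssayPlateGen:
    def test_noiseless_skin_inversion(self, configs):
        """Known ratio in, same ratio out through calibration + quantify."""
        cfgs = configs
        skin0 = replace(cfgs["skin"],
                        assay=replace(cfgs["skin"].assay, sd_bio=0.0))
        metas = [cm.SampleMeta("skin", 0, 0, seed=9)]
        plate = cm.gen_assay_plate({"skin": skin0}, metas, noise=cm.NO_NOISE)
        cal = cm.fit_standards(plate.standards)
        ratio = cm.quantify(plate.samples[0], cal)
        assert ratio == pytest.approx(3.5, rel=1e-9)

    def test_zero_standard_reads_blank(self, configs):
        plate = cm.gen_assay_plate(configs, [cm.SampleMeta("skin", 0, 0, seed=9)],
                                   blank=0.05, noise=cm.NO_NOISE)
        zero = [s for s in plate.standards if s["mass_ug"] == 0.0][0]
        assert zero["A513"] == pytest.approx(0.05, abs=1e-12)

    def test_monte_carlo_recovery_fbp(self, configs):
        """Mean recovered ratio over many samples stays within 5% of 3.15."""
        cfg = configs["Fb-P"]
        metas = [cm.SampleMeta("Fb-P", a, 0, seed=13) for a in range(500)]
        plate = cm.gen_assay_plate(configs, metas)
        cal = cm.fit_standards(plate.standards)
        ratios = [cm.quantify(s, cal) for s in plate.samples]
        assert np.mean(ratios) == pytest.approx(3.15, rel=0.05)


class TestSectionMaskGen:
    def test_target_fraction_matched(self, configs):
        """Measured in-ROI fraction sits within 0.2pp of the animal's target
        plus slide background (the stamping stopping rule)."""
        cfg = configs["Fb-P"]
        meta = cm.SampleMeta("Fb-P", 0, 0, seed=21)
        sec = cm.gen_section_mask(cfg, "cross", meta)
        animal = cm.draw_animal_params(cfg, 0, 21)
        raw = cm.area_ratio(sec.mask, sec.roi)
        neg = cm.area_ratio(sec.neg_mask, sec.roi)
        corrected = cm.corrected_ratio(sec)
        assert abs(corrected - animal["histo_frac"]["cross"]) <= 0.004
        assert raw > neg > 0

    def test_zero_target_blank_mask(self, configs):
        cfg = configs["dermis"]
        zero = replace(cfg, histo=replace(cfg.histo,
                                          area_frac={"cross": 0.0},
                                          background_frac=0.0))
        sec = cm.gen_section_mask(zero, "cross",
                                  cm.SampleMeta("dermis", 0, 0, seed=3))
        assert sec.mask.sum() == 0

    def test_unreachable_target_rejected(self, configs):
        cfg = configs["Fb-P"]
        hot = replace(cfg, histo=replace(
            cfg.histo, area_frac={**cfg.histo.area_frac, "cross": 0.95},
            area_frac_sd_bio={**cfg.histo.area_frac_sd_bio, "cross": 0.0}))
        with pytest.raises(ValueError, match="unreachable"):
            cm.gen_section_mask(hot, "cross",
                                cm.SampleMeta("Fb-P", 0, 0, seed=3))

    def test_roi_covers_most_of_frame(self, configs):
        sec = cm.gen_section_mask(configs["Fb-P"], "mid",
                                  cm.SampleMeta("Fb-P", 0, 0, seed=3))
        inside = cm.roi_mask(sec.roi, sec.mask.shape)
        assert inside.mean() >= 0.80

    def test_small_size_rejected(self, configs):
        with pytest.raises(ValueError, match="256"):
            cm.gen_section_mask(configs["Fb-P"], "cross",
                                cm.SampleMeta("Fb-P", 0, 0, seed=3),
                                size=(128, 128))


class TestDistributionRecovery:
    """1000-draw Monte-Carlo over animals: means within 3 SE, SDs within 10%."""

    @pytest.mark.parametrize("group, key, mean, sd", [
        ("Fb-P", "Gpp_sweep_mean", 541.0, 54.0),
        ("Fb-PECM", "Gpp_sweep_mean", 390.0, 40.0),
        ("Fb-P", "E_high", 2042.0, 442.0),
        ("Fb-P", "assay_ratio", 3.15, 0.90),
        ("Fb-PECM", "assay_ratio", 1.92, 0.33),
    ])
    def test_animal_draws(self, configs, group, key, mean, sd):
        draws = np.array([
            cm.draw_animal_params(configs[group], a, 12345)[key]
            for a in range(1000)
        ])
        se = sd / np.sqrt(len(draws))
        assert abs(draws.mean() - mean) <= 3 * se
        assert draws.std(ddof=1) == pytest.approx(sd, rel=0.10)

    def test_histo_fraction_draws(self, configs):
        draws = np.array([
            cm.draw_animal_params(configs["Fb-P"], a, 777)["histo_frac"]["cross"]
            for a in range(1000)
        ])
        se = 0.011 / np.sqrt(len(draws))
        assert abs(draws.mean() - 0.132) <= 3 * se
        assert draws.std(ddof=1) == pytest.approx(0.011, rel=0.10)


def test_default_configs_paper_anchors(configs):
    """Spot-check the printed group statistics wired into the defaults."""
    assert configs["Fb-P"].comp.E_high_mean == 2042.0
    assert configs["Fb-P"].comp.E_high_sd_bio == 442.0
    assert configs["Fb-PECM"].rheo.Gpp_low_mean == 390.0
    assert configs["skin"].assay.true_ratio_mean == 3.5
    assert configs["Fb-P"].histo.area_frac["cross"] == 0.132
    assert configs["Fb-PECM"].histo.area_frac["mid"] == 0.062
    # derived dermis references reproduce the dermis-relative ratios
    assert 0.132 / configs["Fb-P"].histo.dermis_frac["cross"] == pytest.approx(1.49)
    assert 0.126 / configs["Fb-P"].histo.dermis_frac["mid"] == pytest.approx(1.43)


def test_config_validation():
    with pytest.raises(ValueError, match="n_tech"):
        cm.GroupConfig(group_id="x", n_bio=2, n_tech=2)
    with pytest.raises(ValueError, match="n_bio"):
        cm.GroupConfig(group_id="x", n_bio=0, n_tech=3)
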