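"""Phantom geometry, forward models, noise and cohort-generator properties."""

import numpy as np
import pytest

from mpmri.curves import AifModel
from mpmri.io import TIMEPOINTS, ValidationError
from mpmri.phantom import (
    DEFAULT_BASELINE,
    STUDY_GROUP_SIZES,
    GeometryError,
    GroupEffectProfile,
    PhantomTruth,
    default_group_profiles,
    default_truth,
    dsc_concentration_fine,
    make_geometry,
    rician_noise,
    simulate_cohort,
    simulate_dce,
    simulate_dsc,
    simulate_dwi,
    tofts_concentration_fine,
)


class TestGeometry:
    def test_rim_and_core_partition_tumor(self, small_masks):
        rim = small_masks.region_mask("viable_rim")
        core = small_masks.region_mask("necrotic_core")
        tumor = small_masks.region_mask("tumor")
        assert np.array_equal(tumor, rim | core)
        assert not (rim & core).any()

    def test_rim_thickness_must_be_below_min_radius(self):
        with pytest.raises(GeometryError, match="rim thickness"):
            make_geometry((32, 32, 8), (1, 1, 2.2), (16, 16, 8.8),
                          (6, 6, 6), rim_thickness=6.0)

    def test_tumor_must_fit_in_grid(self):
        with pytest.raises(GeometryError, match="does not fit"):
            make_geometry((16, 16, 4), (1, 1, 2.2), (8, 8, 4.4),
                          (10, 10, 3), rim_thickness=1.0)

    def test_tiny_region_rejected(self):
        # a 1.2 mm core on a 1 mm grid digitizes to < 10 voxels
        with pytest.raises(GeometryError, match="at least 10"):
            make_geometry((32, 32, 8), (1, 1, 2.2), (16, 16, 8.8),
                          (3.0, 3.0, 3.0), rim_thickness=1.8)

    def test_digitized_ellipsoid_volume_matches_analytic(self):
        # 8 mm sphere on a 0.5 mm isotropic grid vs (4/3)π r³
        masks, counts = make_geometry(
            (64, 64, 64), (0.5, 0.5, 0.5), (16, 16, 16), (8, 8, 8),
            rim_thickness=2.0,
        )
        digitized = counts["tumor"] * 0.5**3
        analytic = 4.0 / 3.0 * np.pi * 8.0**3
        assert abs(digitized / analytic - 1) < 0.05


class TestDwiForward:
    def test_noiseless_closed_form(self, small_masks, noiseless_truth, meta):
        series = simulate_dwi(small_masks, noiseless_truth, meta)
        rim = small_masks.region_mask("viable_rim")
        b1000 = series.data[..., -1][rim]
        expected = 1000.0 * np.exp(-1000.0 * 0.9e-3)
        np.testing.assert_allclose(b1000, expected, rtol=1e-12)

    def test_b0_plane_equals_s0(self, small_masks, noiseless_truth, meta):
        series = simulate_dwi(small_masks, noiseless_truth, meta)
        np.testing.assert_array_equal(series.data[..., 0], noiseless_truth.s0_map)

    def test_same_seed_bit_identical(self, small_masks, meta):
        truth = default_truth(small_masks, noise_sigma=20.0, seed=3)
        a = simulate_dwi(small_masks, truth, meta)
        b = simulate_dwi(small_masks, truth, meta)
        np.testing.assert_array_equal(a.data, b.data)

    def test_negative_noise_sigma_rejected(self, small_masks):
        with pytest.raises(ValidationError, match="noise_sigma"):
            default_truth(small_masks, noise_sigma=-1.0)

    def test_noise_calibration_far_from_floor(self, rng):
        # Rician sd approaches the channel sigma when A >> sigma
        sigma = 15.0
        sample = rician_noise(np.full(20000, 1000.0), sigma, rng)
        assert abs(sample.std() / sigma - 1) < 0.05


class TestDceForward:
    def test_prebolus_frames_at_baseline(self, small_masks, noiseless_truth, meta):
        series = simulate_dce(small_masks, noiseless_truth, meta)
        pre = series.data[..., : meta.baseline_frames]
        np.testing.assert_allclose(
            pre, noiseless_truth.s0_map[..., None] * np.ones(meta.baseline_frames),
            rtol=1e-12,
        )

    def test_zero_ktrans_keeps_baseline_signal(self, small_masks, meta):
        truth = default_truth(small_masks, region_truth={
            "viable_rim": (0.9e-3, 1000.0, 0.0, 0.35, 1.5, 4.0),
            "necrotic_core": (2.2e-3, 1000.0, 0.0, 0.6, 0.05, 10.0),
            "liver": (1.1e-3, 1000.0, 0.0, 0.25, 1.0, 6.0),
        })
        series = simulate_dce(small_masks, truth, meta)
        tumor = small_masks.region_mask("tumor")
        np.testing.assert_allclose(series.data[tumor], 1000.0, rtol=1e-12)

    def test_aorta_carries_aif_signal(self, small_masks, noiseless_truth, meta):
        series = simulate_dce(small_masks, noiseless_truth, meta)
        aorta = small_masks.region_mask("aorta")
        cp = noiseless_truth.aif_params.plasma_concentration(
            meta.frame_times("dce"), meta.dce_frame_duration
        )
        expected = np.broadcast_to(1000.0 * (1 + cp), series.data[aorta].shape)
        np.testing.assert_allclose(series.data[aorta], expected, rtol=1e-12)

    def test_ve_zero_with_transfer_rejected(self, small_masks, meta):
        truth = default_truth(small_masks)
        truth.ve_map[small_masks.region_mask("viable_rim")] = 0.0
        with pytest.raises(ValidationError, match="kernel undefined"):
            simulate_dce(small_masks, truth, meta)

    def test_fine_convolution_matches_riemann_oracle(self, meta):
        # independent brute-force Riemann sum at dt/10
        aif = AifModel()
        kt, ve = 0.25, 0.35
        ct = tofts_concentration_fine(kt, ve, aif, meta)
        dt = meta.dce_frame_duration
        dtf = dt / 10
        tf = np.arange(dtf / 2, meta.n_frames * dt, dtf)
        cp = aif.plasma_concentration(tf, dt)
        kep = (kt / ve) / 60.0
        times = meta.frame_times("dce")
        oracle = np.array(
            [np.sum(cp[tf <= t] * np.exp(-kep * (t - tf[tf <= t]))) * dtf for t in times]
        ) * (kt / 60.0)
        assert np.abs(ct - oracle).max() / oracle.max() < 0.005


class TestDscForward:
    def test_unperfused_voxels_flat(self, small_masks, noiseless_truth, meta):
        series = simulate_dsc(small_masks, noiseless_truth, meta)
        core = small_masks.region_mask("necrotic_core")
        # core flow is 0.05 but background flow is 0 — use background inside grid
        bg = small_masks.labels == 0
        assert np.ptp(series.data[bg], axis=-1).max() == 0.0
        assert series.data[core].min() > 0

    def test_central_volume_theorem(self, meta):
        # ∫C dt / ∫AIF dt = F·MTT for a boxcar residue (noiseless, full window)
        from mpmri.curves import DSC_DEFAULT_AIF

        times = meta.frame_times("dsc")
        cp = DSC_DEFAULT_AIF.plasma_concentration(times, meta.dsc_frame_duration)
        for flow, mtt in [(1.5, 4.0), (0.8, 8.0)]:
            ct = dsc_concentration_fine(flow, mtt, DSC_DEFAULT_AIF, meta)
            ratio = np.trapezoid(ct, times) / np.trapezoid(cp, times)
            assert abs(ratio / (flow * mtt) - 1) < 0.01

    def test_signal_dips_after_bolus(self, small_masks, noiseless_truth, meta):
        series = simulate_dsc(small_masks, noiseless_truth, meta)
        rim = small_masks.region_mask("viable_rim")
        curve = series.data[rim].mean(axis=0)
        assert curve[meta.baseline_frames + 3] < curve[: meta.baseline_frames].mean()

    def test_unknown_residue_model_rejected(self, small_masks, noiseless_truth, meta):
        with pytest.raises(ValidationError, match="residue"):
            simulate_dsc(small_masks, noiseless_truth, meta, residue_model="gamma")

    def test_same_seed_bit_identical(self, small_masks, meta):
        truth = default_truth(small_masks, noise_sigma=5.0, seed=11)
        a = simulate_dsc(small_masks, truth, meta)
        b = simulate_dsc(small_masks, truth, meta)
        np.testing.assert_array_equal(a.data, b.data)


class TestTruthInvariants:
    def test_central_volume_consistency_enforced(self, small_masks):
        truth = default_truth(small_masks)
        np.testing.assert_allclose(truth.bv_map, truth.flow_map * truth.mtt_map)
        bad_bv = truth.bv_map.copy()
        bad_bv[small_masks.region_mask("viable_rim")] *= 2.0
        with pytest.raises(ValidationError, match="central-volume"):
            PhantomTruth(
                adc_map=truth.adc_map, s0_map=truth.s0_map,
                ktrans_map=truth.ktrans_map, ve_map=truth.ve_map,
                flow_map=truth.flow_map, mtt_map=truth.mtt_map, bv_map=bad_bv,
            )

    def test_ve_above_one_rejected(self, small_masks):
        truth = default_truth(small_masks)
        with pytest.raises(ValidationError, match="ve_map"):
            PhantomTruth(
                adc_map=truth.adc_map, s0_map=truth.s0_map,
                ktrans_map=truth.ktrans_map, ve_map=truth.ve_map + 1.0,
                flow_map=truth.flow_map, mtt_map=truth.mtt_map,
            )


def _flat_profiles(cv):
    flat = {tp: {} for tp in TIMEPOINTS}
    return [GroupEffectProfile(g, flat, cv) for g in STUDY_GROUP_SIZES]


class TestCohort:
    def test_all_factors_one_cv_zero_reproduces_baseline(self):
        records, truth = simulate_cohort(_flat_profiles(0.0), 3, seed=0)
        for rec in records:
            assert rec.tumor_volume == pytest.approx(DEFAULT_BASELINE["tumor_volume"])
            assert rec.ktrans == pytest.approx(DEFAULT_BASELINE["ktrans"])
            assert rec.radc == pytest.approx(
                DEFAULT_BASELINE["tumor_adc"] / DEFAULT_BASELINE["liver_adc"]
            )

    def test_study_group_sizes_give_220_records(self):
        records, _ = simulate_cohort(
            default_group_profiles(), STUDY_GROUP_SIZES, seed=1
        )
        assert len(records) == 44 * 5
        counts = {g: 0 for g in STUDY_GROUP_SIZES}
        for rec in records:
            if rec.timepoint == "pre":
                counts[rec.group] += 1
        assert counts == STUDY_GROUP_SIZES

    def test_missing_timepoint_rejected(self):
        factors = {tp: {} for tp in TIMEPOINTS if tp != "6d"}
        with pytest.raises(ValidationError, match="6d"):
            GroupEffectProfile("control", factors)

    def test_pre_factors_must_be_one(self):
        factors = {tp: {} for tp in TIMEPOINTS}
        factors["pre"] = {"volume": 1.2}
        with pytest.raises(ValidationError, match="pre-treatment"):
            GroupEffectProfile("control", factors)

    def test_group_mean_tracks_effect_factor(self):
        # Monte-Carlo mean of the lognormal model: Zd 4h rBV factor 0.3 vs
        # control 1.0 recovers a 0.3 group-mean ratio
        factors = {tp: {} for tp in TIMEPOINTS}
        zd_factors = {tp: ({"rbv": 0.3} if tp == "4h" else {}) for tp in TIMEPOINTS}
        zd_factors["pre"] = {}
        profiles = [
            GroupEffectProfile("control", factors, cv=0.15),
            GroupEffectProfile("Zd", zd_factors, cv=0.15),
            GroupEffectProfile("Tha", factors, cv=0.15),
            GroupEffectProfile("ZdTha", factors, cv=0.15),
        ]
        zd_sum = ctrl_sum = 0.0
        n_rep = 200
        for rep in range(n_rep):
            records, _ = simulate_cohort(profiles, {"control": 11, "Zd": 11,
                                                    "Tha": 2, "ZdTha": 2}, seed=rep)
            zd = [r.rbv for r in records if r.group == "Zd" and r.timepoint == "4h"]
            ct = [r.rbv for r in records if r.group == "control" and r.timepoint == "4h"]
            zd_sum += np.mean(zd)
            ctrl_sum += np.mean(ct)
        assert abs((zd_sum / ctrl_sum) / 0.3 - 1) < 0.02

    def test_marginal_convergence_at_large_n(self):
        # sample mean per group/timepoint converges to baseline × factor
        profiles = default_group_profiles(cv=0.15)
        records, truth = simulate_cohort(profiles, {"control": 2500, "Zd": 2,
                                                    "Tha": 2, "ZdTha": 2}, seed=5)
        vols = np.array([
            r.tumor_volume for r in records
            if r.group == "control" and r.timepoint == "12d"
        ])
        expected = DEFAULT_BASELINE["tumor_volume"] * 6.5
        assert abs(vols.mean() / expected - 1) < 0.02

    def test_default_profiles_encode_reported_dynamics(self):
        # vascular shutdown at 4 h under the VDA, rebound by 2 d under the VDA
        # alone but not under the combination; growth delay under ZdTha
        by_group = {p.group: p for p in default_group_profiles()}
        assert by_group["Zd"].factor_row("4h")["rbv"] < 0.5
        assert by_group["ZdTha"].factor_row("4h")["rbv"] < 0.5
        assert by_group["Zd"].factor_row("2d")["rbv"] > 0.8
        assert by_group["ZdTha"].factor_row("2d")["rbv"] < 0.6
        assert by_group["ZdTha"].factor_row("12d")["volume"] < \
            by_group["control"].factor_row("12d")["volume"] / 2
        assert by_group["ZdTha"].factor_row("2d")["adc"] > 1.1
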