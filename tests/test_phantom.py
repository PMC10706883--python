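"""Phantom and cohort generator: ground truth, determinism, noise model."""

import numpy as np
import pytest

from renal_mpmri.asl import ASLConstants, compute_delta_m
from renal_mpmri.clinical import egfr_ckdepi2009
from renal_mpmri.phantom import (
    PAPER_B_VALUES,
    PAPER_TE_MS,
    PAPER_TI_MS,
    CohortSpec,
    PhantomSpec,
    make_phantom,
    simulate_asl_pairs,
    simulate_cohort,
    simulate_dwi_series,
    simulate_ir_series,
    simulate_mfe_series,
)
from conftest import ZERO_SD


def test_protocol_defaults_match_acquisition_design():
    assert len(PAPER_TI_MS) == 13 and PAPER_TI_MS[0] == 200 and PAPER_TI_MS[-1] == 1500
    assert len(PAPER_B_VALUES) == 11 and PAPER_B_VALUES[-1] == 500
    assert len(PAPER_TE_MS) == 12 and PAPER_TE_MS[0] == 5 and PAPER_TE_MS[1] == 8


class TestMakePhantom:
    def test_zero_dispersion_gives_exact_table_values(self, noiseless_phantom):
        spec, masks, maps = noiseless_phantom
        assert np.all(maps["t1"].data[masks.cortex]
                      == spec.tissue_params["cortex"]["t1"])
        assert np.all(maps["t1"].data[masks.medulla]
                      == spec.tissue_params["medulla"]["t1"])
        assert np.all(maps["m0"].data[~masks.kidney] == 0)

    def test_same_seed_bit_identical(self):
        a_masks, a_maps = make_phantom(PhantomSpec(seed=42))
        b_masks, b_maps = make_phantom(PhantomSpec(seed=42))
        assert np.array_equal(a_masks.cortex, b_masks.cortex)
        for name in a_maps:
            assert np.array_equal(a_maps[name].data, b_maps[name].data)

    def test_mask_invariants_and_volume(self, noiseless_phantom):
        spec, masks, _ = noiseless_phantom
        assert not np.any(masks.cortex & masks.medulla)
        assert np.all(masks.kidney[masks.cortex]) and np.all(masks.kidney[masks.medulla])
        # voxelised TKV close to the analytic ellipsoid-pair volume
        analytic = spec.analytic_kidney_volume_ml()
        assert masks.volume_ml("kidney") == pytest.approx(analytic, rel=0.03)

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError, match="at least 8"):
            PhantomSpec(shape=(4, 48, 16))

    def test_oversized_kidney_rejected(self):
        spec = PhantomSpec(size_scale=5.0)
        with pytest.raises(ValueError, match="do not fit"):
            make_phantom(spec)


class TestSignalSimulators:
    def test_ir_null_point_and_full_recovery(self, noiseless_phantom):
        _, masks, maps = noiseless_phantom
        t1 = maps["t1"].data[masks.cortex][0]  # 1500 ms
        null_ti = t1 * np.log(2)
        ser = simulate_ir_series(maps, ti_ms=[null_ti, 50 * t1])
        sig = ser.data[masks.cortex][0]
        assert sig[0] == pytest.approx(0.0, abs=1e-9)
        assert sig[1] == pytest.approx(maps["m0"].data[masks.cortex][0], rel=1e-12)

    def test_dwi_b0_equals_s0_and_closed_form_ratio(self, noiseless_phantom):
        _, masks, maps = noiseless_phantom
        ser = simulate_dwi_series(maps, b_values=[0.0, 500.0])
        vox = ser.data[masks.cortex][0]
        s0 = maps["m0"].data[masks.cortex][0]
        b = ser.params["b_s_mm2"]
        assert np.all(vox[b == 0] == s0)
        adc = maps["adc"].data[masks.cortex][0]  # 2.2e-3
        assert vox[b == 500][0] / s0 == pytest.approx(np.exp(-500 * adc), rel=1e-12)

    def test_mfe_closed_form_and_short_list_rejected(self, noiseless_phantom):
        _, masks, maps = noiseless_phantom
        ser = simulate_mfe_series(maps, te_ms=[5.0, 8.0, 11.0])
        vox = ser.data[masks.medulla][0]
        t2s = maps["t2star"].data[masks.medulla][0]
        s0 = maps["m0"].data[masks.medulla][0]
        assert vox[0] / s0 == pytest.approx(np.exp(-5.0 / t2s), rel=1e-12)
        with pytest.raises(ValueError, match="3 echoes"):
            simulate_mfe_series(maps, te_ms=[5.0, 8.0])

    def test_asl_zero_perfusion_gives_zero_difference(self, noiseless_phantom):
        spec, masks, _ = noiseless_phantom
        params = {t: dict(p) for t, p in spec.tissue_params.items()}
        for tissue in ("cortex", "medulla"):
            params[tissue]["perfusion"] = 1e-300  # effectively zero flow
        _, maps0 = make_phantom(
            PhantomSpec(tissue_params=params, intra_tissue_sd=dict(ZERO_SD)))
        ser, _ = simulate_asl_pairs(maps0)
        dm = compute_delta_m(ser)
        for vol in dm.values():
            assert np.allclose(vol, 0.0, atol=1e-250)

    def test_asl_no_signal_before_bolus_arrival(self, noiseless_phantom):
        _, masks, maps = noiseless_phantom
        # cortex transit time is 400 ms; a 300 ms PLD precedes arrival
        ser, _ = simulate_asl_pairs(maps, pld_scheme={300: 2})
        dm = compute_delta_m(ser)
        assert np.allclose(dm[300.0][masks.cortex], 0.0)

    def test_gaussian_noise_mean_converges_to_noiseless(self, noiseless_phantom):
        _, masks, maps = noiseless_phantom
        clean = simulate_mfe_series(maps, te_ms=[5.0, 8.0, 11.0])
        idx = np.argwhere(masks.cortex)[0]
        draws = []
        for seed in range(100):  # 100 series x 3 echoes at one voxel
            noisy = simulate_mfe_series(maps, te_ms=[5.0, 8.0, 11.0],
                                        noise_sd=2.0, seed=seed)
            draws.append(noisy.data[tuple(idx)])
        mean = np.mean(draws, axis=0)
        se = 2.0 / np.sqrt(len(draws))
        assert np.all(np.abs(mean - clean.data[tuple(idx)]) < 4 * se)
        rel = np.abs(mean - clean.data[tuple(idx)]) / clean.data[tuple(idx)]
        assert np.all(rel < 0.01 * np.sqrt(1e4 / len(draws)))  # 1% at 10^4 draws

    def test_rician_noise_is_nonnegative(self, noiseless_phantom):
        _, _, maps = noiseless_phantom
        ser = simulate_ir_series(maps, noise_sd=5.0, noise_model="rician", seed=3)
        assert np.all(ser.data >= 0)

    def test_series_determinism(self, noiseless_phantom):
        _, _, maps = noiseless_phantom
        a = simulate_ir_series(maps, noise_sd=1.0, seed=9)
        b = simulate_ir_series(maps, noise_sd=1.0, seed=9)
        assert np.array_equal(a.data, b.data)


class TestCohort:
    def test_degenerate_slopes_classify_deterministically(self):
        base = dict(
            n_progressor=4, n_stable=4, creatinine_cv=0.0, seed=0,
            # fixed intercept high enough that the eGFR floor never engages
            egfr_intercept={"stable": (40.0, 0.0), "progressor": (40.0, 0.0)})
        all_prog = simulate_cohort(CohortSpec(
            egfr_slope={"stable": (-6.0, 0.0), "progressor": (-6.0, 0.0)}, **base))
        assert all(s.group_realized == "progressor" for s in all_prog.subjects)
        all_stable = simulate_cohort(CohortSpec(
            egfr_slope={"stable": (-4.0, 0.0), "progressor": (-4.0, 0.0)}, **base))
        assert all(s.group_realized == "stable" for s in all_stable.subjects)

    def test_realized_mean_slope_near_intended(self):
        spec = CohortSpec(n_progressor=100, n_stable=100, seed=21)
        cohort = simulate_cohort(spec)
        prog = [s.egfr_slope_realized for s in cohort.subjects
                if s.group_intended == "progressor"]
        mu, sd = spec.egfr_slope["progressor"]
        se = np.std(prog, ddof=1) / np.sqrt(len(prog))
        assert abs(np.mean(prog) - mu) < 3 * se + 3 * sd / np.sqrt(len(prog))

    def test_back_computed_creatinine_reproduces_egfr(self):
        spec = CohortSpec(creatinine_cv=0.0, seed=4)
        cohort = simulate_cohort(spec)
        s = cohort.subjects[0]
        t_yr = np.asarray(spec.clinical_visit_days, dtype=float) / 365.25
        expected = np.maximum(s.egfr_intercept + s.egfr_slope_true * t_yr, 5.0)
        got = egfr_ckdepi2009(
            s.record.visits["creatinine_umol_L"].to_numpy(),
            s.record.visits["age"].to_numpy(),
            np.full(t_yr.size, s.sex), black=np.full(t_yr.size, s.ethnicity_black))
        assert np.allclose(got, expected, rtol=1e-10)

    def test_visit_schedule_must_increase(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            CohortSpec(clinical_visit_days=(0, 10, 10))

    def test_cohort_determinism(self):
        a = simulate_cohort(CohortSpec(seed=5)).summary_table()
        b = simulate_cohort(CohortSpec(seed=5)).summary_table()
        assert a.equals(b)
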