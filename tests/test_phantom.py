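"""Rician noise model, ROI curve generator, volumetric phantom and cohort."""

import numpy as np
import pytest

from dcerrm import (AifSpec, CohortSpec, PhantomSpec, TissueKinetics,
                    add_rician_noise, fit_rrm, simulate_cohort,
                    simulate_phantom, simulate_roi_curves, snr)
from dcerrm.phantom import RR_LABEL, TOI_LABEL


class TestRicianNoise:
    def test_zero_sigma_is_identity(self):
        v = np.array([0.0, 1.0, 100.0])
        np.testing.assert_array_equal(add_rician_noise(v, 0.0), v)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            add_rician_noise(np.ones(3), -1.0)

    def test_background_becomes_rayleigh(self, rng):
        """Zero-signal voxels get Rayleigh magnitudes whose measured std,
        divided by 0.655, recovers the per-channel sigma (1%, n = 1e6)."""
        sigma = 3.0
        mags = add_rician_noise(np.zeros(10 ** 6), sigma, rng)
        assert mags.std(ddof=1) / 0.655 == pytest.approx(sigma, rel=0.01)

    def test_high_snr_bias_is_negligible(self, rng):
        """At v = 100, sigma = 1 the Rician mean is ~100.005."""
        mags = add_rician_noise(np.full(10 ** 6, 100.0), 1.0, rng)
        assert mags.mean() == pytest.approx(100.005, abs=0.005)


class TestRoiCurves:
    def test_equal_kinetics_give_identical_series(self, protocol, muscle, aif):
        c = simulate_roi_curves(protocol, muscle, muscle, 0.82, 0.82, aif)
        np.testing.assert_array_equal(c.s_dce_rr.values, c.s_dce_toi.values)

    def test_noise_free_recovery(self, protocol, muscle, aif):
        kin = TissueKinetics(0.2, 0.3)
        c = simulate_roi_curves(protocol, muscle, kin, 0.82, 1.0, aif)
        fit = fit_rrm(c.truth["r1_toi"], c.truth["r1_rr"], 1.0, 0.82, muscle)
        assert fit.kinetics.ktrans == pytest.approx(0.2, rel=0.02)
        assert fit.kinetics.ve == pytest.approx(0.3, rel=0.02)

    def test_baseline_frames_are_pre_contrast(self, protocol, muscle, aif):
        c = simulate_roi_curves(protocol, muscle, TissueKinetics(0.2, 0.3),
                                0.82, 1.0, aif)
        base = c.truth["ct_toi"].values[: protocol.n_baseline]
        np.testing.assert_array_equal(base, 0.0)

    def test_early_arrival_rejected(self, protocol, muscle, aif):
        early = AifSpec(arrival_time=10.0)
        with pytest.raises(ValueError):
            simulate_roi_curves(protocol, muscle, muscle, 0.82, 1.0, early)

    def test_tofts_concentration_bound(self, protocol, muscle):
        """Conservation: Ct never exceeds ve * max(Cp) in any simulated tissue."""
        for aif in (AifSpec(), AifSpec(model="parker")):
            for kt, ve in [(0.05, 0.15), (0.2, 0.3), (0.4, 0.5)]:
                c = simulate_roi_curves(protocol, muscle, TissueKinetics(kt, ve),
                                        0.82, 1.0, aif)
                cp_max = c.truth["cp"].values.max()
                assert c.truth["ct_toi"].values.max() <= ve * cp_max * (1 + 1e-9)


class TestPhantom:
    def test_same_seed_bit_identical(self):
        spec = PhantomSpec(shape=(16, 16, 2), target_snr=80.0, seed=11)
        a, b = simulate_phantom(spec), simulate_phantom(spec)
        np.testing.assert_array_equal(a.dynamic, b.dynamic)
        np.testing.assert_array_equal(a.reference, b.reference)

    def test_mask_roundtrips_through_nifti(self, tmp_path):
        import nibabel as nib

        spec = PhantomSpec(shape=(16, 16, 2))
        ds = simulate_phantom(spec)
        paths = ds.save(tmp_path)
        loaded = np.asarray(nib.load(paths["mask"]).get_fdata()).astype(int)
        np.testing.assert_array_equal(loaded, ds.mask)
        assert paths["provenance"].exists() and paths["truth"].exists()

    def test_labels_and_background(self):
        ds = simulate_phantom(PhantomSpec(shape=(16, 16, 2)))
        assert set(np.unique(ds.mask)) == {0, RR_LABEL, TOI_LABEL}
        assert np.all(ds.dynamic[ds.mask == 0] == 0)  # noise-free background

    def test_overlapping_rois_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(shape=(16, 16, 2), rr_box=(1, 8, 1, 15, 0, 2),
                        toi_box=(6, 14, 1, 15, 0, 2))

    def test_snr_closure(self):
        """snr() measured on the phantom (tissue baseline mean vs background
        std) recovers the target within 5%, and the generating per-channel
        sigma within 2% given >= 1e5 background samples."""
        spec = PhantomSpec(shape=(32, 32, 4), target_snr=80.0, seed=5,
                           rr_box=(2, 8, 2, 12, 0, 4), toi_box=(12, 18, 2, 12, 0, 4))
        ds = simulate_phantom(spec)
        bg = ds.dynamic[ds.mask == 0]          # (n_vox, n_t) Rayleigh samples
        assert bg.size >= 10 ** 5
        sigma_rayleigh = float(bg.std(ddof=1))
        mu = float(ds.dynamic[ds.mask == RR_LABEL][:, : spec.protocol.n_baseline].mean())
        assert snr(mu, sigma_rayleigh) == pytest.approx(80.0, rel=0.05)
        assert sigma_rayleigh / 0.655 == pytest.approx(ds.sigma, rel=0.02)


class TestCohort:
    def test_zero_cv_collapses_onto_day_means(self):
        spec = CohortSpec(n_animals=3, days=(1, 7), ktrans_cv=0.0, ve_cv=0.0,
                          target_snr=None, seed=3)
        coh = simulate_cohort(spec)
        for day in (1, 7):
            vals = {r.kinetics_true.ktrans for r in coh.records if r.day == day}
            assert vals == {spec.ktrans_means[day]}

    def test_seed_reproducibility(self):
        a = simulate_cohort(CohortSpec(seed=9))
        b = simulate_cohort(CohortSpec(seed=9))
        assert a.truth_table.equals(b.truth_table)
        np.testing.assert_array_equal(a.records[0].curves.s_dce_toi.values,
                                      b.records[0].curves.s_dce_toi.values)

    def test_design_shape(self):
        coh = simulate_cohort(CohortSpec(seed=2))
        assert len(coh.records) == 5 * 7
        assert sorted(coh.truth_table["day"].unique()) == [1, 3, 7, 14, 28, 42, 82]

    @pytest.mark.parametrize("kwargs", [
        dict(n_animals=1),
        dict(days=(7, 3)),
        dict(days=(1, 99)),           # no mean for day 99
        dict(ktrans_cv=-0.1),
    ])
    def test_config_errors(self, kwargs):
        with pytest.raises(ValueError):
            CohortSpec(**kwargs)
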