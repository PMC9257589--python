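"""Digital image correlation: matching, strain operator, profiles, QC."""

import numpy as np
import pandas as pd
import pytest

from irismech.dic import (
    DisplacementField,
    StrainProfile,
    TrackingLostError,
    _grid_points,
    compute_strain_field,
    correlate_incremental,
    extract_profile,
    hausdorff_outlier,
    virtual_tensometer,
)


def square_roi(shape, margin=25):
    roi = np.zeros(shape, bool)
    roi[margin:shape[0] - margin, margin:shape[1] - margin] = True
    return roi


class TestCorrelation:
    def test_identical_frames_zero_displacement(self, contraction):
        _, seq, _, _ = contraction
        f = seq[0]
        roi = square_roi(f.shape, 40)
        out = correlate_incremental([f, f], roi, subset=17, step=8)
        assert out.valid.sum() > 50
        assert np.abs(out.displacement[out.valid]).max() < 1e-6
        assert out.residual[out.valid].max() < 1e-3

    def test_integer_shift_recovered_subpixel(self, contraction):
        cfg, seq, _, geo = contraction
        f = seq[0]
        g = np.roll(f, 3, axis=1)      # features move +3 px in x
        h, w = f.shape
        yy, xx = np.mgrid[0:h, 0:w]
        rad = np.hypot(xx - geo["cx"], yy - geo["cy"])
        # textured annulus only: flat pupil/sclera subsets carry no
        # displacement information
        roi = (rad > geo["rp0_px"] + 10) & (rad < geo["rl_px"] - 10)
        out = correlate_incremental([f, g], roi, subset=17, step=8)
        u = out.displacement[out.valid]
        assert np.abs(u[:, 0] - 3.0).max() < 0.05
        assert np.abs(u[:, 1]).max() < 0.05

    def test_contraction_displacement_matches_kinematic_map(
            self, contraction, dic_run):
        cfg, seq, gt, geo = contraction
        field, idxs, _ = dic_run
        t_end = seq.times[idxs[-1]]
        ugt, vgt = gt.displacement_px(field.points[:, 0] - geo["cx"],
                                      field.points[:, 1] - geo["cy"], t_end)
        err = np.hypot(field.displacement[:, 0] - ugt,
                       field.displacement[:, 1] - vgt)[field.valid]
        assert field.valid.sum() > 300
        assert np.sqrt(np.mean(err ** 2)) < 0.2

    def test_incremental_matches_direct_for_small_motion(self, contraction):
        cfg, seq, _, geo = contraction
        i0 = int(np.searchsorted(seq.times, cfg.acclim_end_s))
        triple = [seq[i0], seq[i0 + 5], seq[i0 + 10]]
        h, w = triple[0].shape
        yy, xx = np.mgrid[0:h, 0:w]
        rad = np.hypot(xx - geo["cx"], yy - geo["cy"])
        roi = (rad > geo["rp0_px"] + 8) & (rad < geo["rl_px"] - 8)
        inc = correlate_incremental(triple, roi, subset=17, step=8)
        direct = correlate_incremental([triple[0], triple[2]], roi,
                                       subset=17, step=8)
        both = inc.valid & direct.valid
        diff = np.hypot(*(inc.displacement[both]
                          - direct.displacement[both]).T)
        assert both.sum() > 50
        assert np.median(diff) < 0.1

    def test_strains_invariant_under_global_translation(self, contraction):
        cfg, seq, _, geo = contraction
        i0 = int(np.searchsorted(seq.times, cfg.acclim_end_s))
        a, b = seq[i0], seq[i0 + 10]
        h, w = a.shape
        yy, xx = np.mgrid[0:h, 0:w]
        rad = np.hypot(xx - geo["cx"], yy - geo["cy"])
        roi = (rad > geo["rp0_px"] + 8) & (rad < geo["rl_px"] - 8)

        def median_E_rr(fa, fb, mask, cx, cy):
            f = correlate_incremental([fa, fb], mask, subset=17, step=4)
            sf = compute_strain_field(f, filter_size=5, center=(cx, cy))
            return np.nanmedian(sf.E_rr[sf.valid])

        base = median_E_rr(a, b, roi, geo["cx"], geo["cy"])
        dy, dx = 2, 3
        shifted = median_E_rr(np.roll(a, (dy, dx), (0, 1)),
                              np.roll(b, (dy, dx), (0, 1)),
                              np.roll(roi, (dy, dx), (0, 1)),
                              geo["cx"] + dx, geo["cy"] + dy)
        assert shifted == pytest.approx(base, abs=1e-3)

    def test_decorrelated_target_loses_tracking(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0.3, 0.7, (120, 120))
        b = rng.uniform(0.3, 0.7, (120, 120))
        with pytest.raises(TrackingLostError) as exc:
            correlate_incremental([a, b], square_roi(a.shape, 30),
                                  subset=17, step=8)
        assert exc.value.increment == 0

    def test_excluded_blink_frames_are_skipped(self, contraction):
        _, seq, _, _ = contraction
        f = seq[0]
        blink = np.zeros_like(f)
        roi = square_roi(f.shape, 40)
        out = correlate_incremental([f, blink, f], roi, subset=17, step=8,
                                    exclude=[1])
        assert np.abs(out.displacement[out.valid]).max() < 1e-6


class TestStrainOperator:
    def _field(self, disp_fn, shape=(200, 200), step=8):
        roi = square_roi(shape, 25)
        pts, ins, gs = _grid_points(roi, 17, step)
        disp = disp_fn(pts)
        return DisplacementField(points=pts, displacement=disp, valid=ins,
                                 residual=np.zeros(len(pts)),
                                 grid_shape=gs, subset=17, step=step)

    def test_uniform_translation_gives_zero_strain(self):
        f = self._field(lambda p: np.tile([2.5, -1.0], (len(p), 1)))
        sf = compute_strain_field(f, filter_size=5)
        assert np.nanmax(np.abs(sf.E_xx[sf.valid])) < 1e-12
        assert np.nanmax(np.abs(sf.E_yy[sf.valid])) < 1e-12
        assert np.nanmax(np.abs(sf.E_xy[sf.valid])) < 1e-12

    def test_affine_field_exact(self):
        f = self._field(lambda p: np.column_stack(
            [0.1 * p[:, 0], np.zeros(len(p))]))
        sf = compute_strain_field(f, filter_size=5)
        assert np.nanmax(np.abs(sf.E_xx[sf.valid] - 0.105)) < 1e-12
        assert np.nanmax(np.abs(sf.E_yy[sf.valid])) < 1e-12
        assert np.nanmax(np.abs(sf.E_xy[sf.valid])) < 1e-12

    def test_contraction_strain_recovers_uniform_radial_strain(
            self, contraction, dic_run):
        cfg, seq, gt, geo = contraction
        field, idxs, _ = dic_run
        sf = compute_strain_field(field, filter_size=5,
                                  center=(geo["cx"], geo["cy"]))
        lam = float(gt.radial_stretch(seq.times[idxs[-1]]))
        truth = 0.5 * (lam ** 2 - 1.0)
        med = np.nanmedian(sf.E_rr[sf.valid])
        assert med == pytest.approx(truth, rel=0.1)

    def test_insufficient_neighbours_invalidated(self):
        f = self._field(lambda p: np.zeros((len(p), 2)))
        f.valid[:] = False
        f.valid[0] = True
        sf = compute_strain_field(f, filter_size=5, min_points=9)
        assert not sf.valid.any()


class TestProfile:
    def _uniform_strain_field(self, c=0.25):
        from irismech.dic import StrainField

        ny, nx = 41, 41
        x, y = np.meshgrid(np.arange(nx) * 4.0, np.arange(ny) * 4.0)
        ones = np.full((ny, nx), c)
        zeros = np.zeros((ny, nx))
        return StrainField(x=x, y=y, E_xx=ones, E_yy=zeros, E_xy=zeros,
                           E_rr=ones, E_tt=zeros, E_rt=zeros,
                           valid=np.ones((ny, nx), bool), center=(80.0, 80.0))

    def test_uniform_field_gives_flat_profile_with_zero_iqr(self):
        sf = self._uniform_strain_field(0.25)
        prof = extract_profile(sf, (80.0, 80.0), 20.0, 75.0)
        assert np.allclose(prof.component("E_rr"), 0.25, atol=1e-12)
        iqr = prof.data["E_rr_q3"] - prof.data["E_rr_q1"]
        assert np.allclose(iqr, 0.0, atol=1e-12)

    def test_box_outside_grid_rejected(self):
        sf = self._uniform_strain_field()
        with pytest.raises(ValueError):
            extract_profile(sf, (1000.0, 1000.0), 20.0, 75.0)

    def test_contraction_profile_flat_and_shear_free(self, contraction,
                                                     dic_run):
        cfg, seq, gt, geo = contraction
        field, idxs, _ = dic_run
        sf = compute_strain_field(field, filter_size=5,
                                  center=(geo["cx"], geo["cy"]))
        prof = extract_profile(sf, (geo["cx"], geo["cy"]),
                               geo["rp0_px"], geo["rl_px"], n_bins=10)
        lam = float(gt.radial_stretch(seq.times[idxs[-1]]))
        truth = 0.5 * (lam ** 2 - 1.0)
        med = prof.component("E_rr")
        assert np.nanmax(np.abs(med - truth)) / abs(truth) < 0.1
        assert np.nanmax(np.abs(prof.component("E_rt"))) < 0.02


class TestHausdorffScreen:
    def _profile(self, values):
        x = np.linspace(0, 1, 20)
        df = pd.DataFrame({"x_bar": x})
        for comp in ("E_rr", "E_tt", "E_rt"):
            df[f"{comp}_median"] = values
            df[f"{comp}_q1"] = values - 0.01
            df[f"{comp}_q3"] = values + 0.01
        return StrainProfile(df)

    def test_identical_curves_all_kept(self):
        profs = [self._profile(np.full(20, 0.4)) for _ in range(5)]
        kept, excl = hausdorff_outlier(profs)
        assert len(excl) == 0

    def test_offset_curve_excluded(self):
        profs = [self._profile(np.full(20, 0.4)) for _ in range(6)]
        profs.append(self._profile(np.full(20, 1.4)))
        kept, excl = hausdorff_outlier(profs)
        assert list(excl) == [6]

    def test_two_curves_skipped_with_warning(self):
        profs = [self._profile(np.full(20, 0.4)),
                 self._profile(np.full(20, 5.0))]
        with pytest.warns(UserWarning):
            _, excl = hausdorff_outlier(profs)
        assert len(excl) == 0


class TestVirtualTensometer:
    def test_zero_displacement_zero_strain(self):
        pts = np.array([[50.0, 100.0], [150.0, 100.0]])
        f = DisplacementField(points=pts, displacement=np.zeros((2, 2)),
                              valid=np.ones(2, bool), residual=np.zeros(2),
                              grid_shape=(1, 2))
        eps = virtual_tensometer(f, (100.0, 100.0), 45.0)
        assert eps == pytest.approx(0.0, abs=1e-12)

    def test_contraction_margin_strain(self, contraction, dic_run):
        cfg, seq, gt, geo = contraction
        field, idxs, _ = dic_run
        eps = virtual_tensometer(field, (geo["cx"], geo["cy"]),
                                 geo["rp0_px"], band_px=14.0)
        # ground-truth hoop strain at the radius of the chosen chord
        # (same selection rule as the tensometer)
        rel = field.points - np.array([geo["cx"], geo["cy"]])
        rad = np.hypot(rel[:, 0], rel[:, 1])
        band = field.valid & (rad >= geo["rp0_px"]) & \
            (rad <= geo["rp0_px"] + 14.0)
        picks = []
        for side in (rel[:, 0] < 0, rel[:, 0] > 0):
            cand = np.where(band & side)[0]
            picks.append(cand[np.argmin(np.abs(rel[cand, 1]))])
        R_mm = rad[picks].mean() * cfg.mm_per_px
        truth = float(gt.strain_tt(R_mm, seq.times[idxs[-1]]))
        assert eps == pytest.approx(truth, rel=0.1)

    def test_empty_band_fails(self):
        pts = np.array([[50.0, 100.0], [150.0, 100.0]])
        f = DisplacementField(points=pts, displacement=np.zeros((2, 2)),
                              valid=np.zeros(2, bool), residual=np.zeros(2),
                              grid_shape=(1, 2))
        with pytest.raises(TrackingLostError):
            virtual_tensometer(f, (100.0, 100.0), 45.0)
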