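"""TFM pipeline: registration, PIV, Kriging, FTTC inversion, strain energy."""

import numpy as np
import pytest

from phagokit import synthgen as sg
from phagokit import traction as tr
from phagokit.core import ImageStack


def _field_from_truth(gt):
    return tr.DisplacementField(x_um=gt.x_um, y_um=gt.y_um,
                                u_um=gt.displacement_um, spacing_um=gt.spacing_um)


class TestRegistration:
    def test_programmed_shifts_recovered(self, speckle_pair):
        cfg, base, _, _ = speckle_pair
        frames = [base,
                  sg.warp_image(base, shift_px=(-3, 2)),   # integer (dx, dy)
                  sg.warp_image(base, shift_px=(0.25, 0.5))]
        stack = ImageStack(np.stack(frames), cfg.pixel_size_um, 1.0)
        _, drift = tr.register_series(stack, (slice(20, 140), slice(20, 140)))
        np.testing.assert_allclose(drift[["dy_px", "dx_px"]].iloc[1], [2, -3],
                                   atol=1e-9)
        np.testing.assert_allclose(drift[["dy_px", "dx_px"]].iloc[2], [0.5, 0.25],
                                   atol=0.1)

    def test_aligned_stack_reports_zero_drift(self, speckle_pair):
        cfg, base, _, _ = speckle_pair
        stack = ImageStack(np.stack([base, base]), cfg.pixel_size_um, 1.0)
        _, drift = tr.register_series(stack, (slice(20, 140), slice(20, 140)))
        np.testing.assert_allclose(drift[["dy_px", "dx_px"]].iloc[1], [0, 0],
                                   atol=1e-9)

    def test_featureless_roi_rejected(self):
        stack = ImageStack(np.zeros((2, 64, 64)), 0.1, 1.0)
        with pytest.raises(ValueError, match="featureless"):
            tr.register_series(stack, (slice(0, 32), slice(0, 32)))


class TestPiv:
    def test_reference_against_itself_is_zero(self, speckle_pair):
        cfg, ref, _, _ = speckle_pair
        f = tr.piv_displacement(ref, ref, cfg.pixel_size_um)
        assert np.abs(f.u_um).max() < 1e-12

    def test_uniform_warp_recovered_within_tenth_pixel(self, speckle_pair):
        cfg, ref, warped, (dx, dy) = speckle_pair
        f = tr.piv_displacement(warped, ref, cfg.pixel_size_um)
        assert f.valid.all()
        err_x = np.abs(f.u_um[..., 0] / cfg.pixel_size_um - dx)
        err_y = np.abs(f.u_um[..., 1] / cfg.pixel_size_um - dy)
        assert max(err_x.max(), err_y.max()) < 0.1

    def test_pure_noise_pair_is_mostly_masked(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, (256, 256)), rng.normal(0, 1, (256, 256))
        f = tr.piv_displacement(b, a, pixel_size_um=0.108)
        assert f.valid.mean() < 0.5
        assert np.all(f.u_um[~f.valid] == 0)

    def test_window_larger_than_image_rejected(self):
        img = np.zeros((16, 16))
        with pytest.raises(ValueError, match="window"):
            tr.piv_displacement(img, img, pixel_size_um=0.1, window_um=3.46)


class TestFilterAndKrige:
    @staticmethod
    def _smooth_field(ny=24, nx=24):
        gy, gx = np.mgrid[0:ny, 0:nx]
        u = np.stack([0.5 * np.sin(gx / 6.0), 0.5 * np.cos(gy / 7.0)], axis=-1)
        return tr.DisplacementField(x_um=np.arange(nx) * 1.73,
                                    y_um=np.arange(ny) * 1.73,
                                    u_um=u, spacing_um=1.73)

    def test_spike_outlier_removed_and_reestimated(self):
        f = self._smooth_field()
        true_val = f.u_um[7, 7].copy()
        f.u_um[7, 7] += [3.0, -2.0]
        out = tr.filter_and_krige(f)
        assert out.valid.all()
        np.testing.assert_allclose(out.u_um[7, 7], true_val,
                                   atol=0.1 * max(np.abs(true_val).max(), 0.1))

    def test_fully_valid_smooth_field_unchanged(self):
        f = self._smooth_field()
        out = tr.filter_and_krige(f)
        np.testing.assert_allclose(out.u_um, f.u_um, atol=1e-9)

    def test_constant_field_gaps_filled_exactly(self):
        f = self._smooth_field()
        f.u_um[...] = [0.3, -0.2]
        f.valid[4:8, 10:14] = False
        out = tr.filter_and_krige(f)
        np.testing.assert_allclose(out.u_um[..., 0], 0.3, atol=1e-9)
        np.testing.assert_allclose(out.u_um[..., 1], -0.2, atol=1e-9)

    def test_mostly_invalid_field_rejected(self):
        f = self._smooth_field()
        f.valid[:16] = False
        with pytest.raises(ValueError, match="50"):
            tr.filter_and_krige(f)


class TestFttc:
    def test_zero_displacement_gives_zero_traction(self):
        f = tr.DisplacementField(x_um=np.arange(32) * 1.73, y_um=np.arange(32) * 1.73,
                                 u_um=np.zeros((32, 32, 2)), spacing_um=1.73)
        out = tr.fttc(f, tr.ElasticSubstrate(), lam=1e-4)
        assert np.abs(out.t_pa).max() < 1e-12

    def test_noiseless_round_trip_recovers_traction(self, tfm_truth):
        substrate, _, gt = tfm_truth
        out = tr.fttc(_field_from_truth(gt), substrate, lam=1e-9)
        rel = np.linalg.norm(out.t_pa - gt.traction_pa) / np.linalg.norm(gt.traction_pa)
        assert rel < 0.05
        peak = np.abs(out.t_pa).max()
        assert peak == pytest.approx(np.abs(gt.traction_pa).max(), rel=0.05)

    def test_traction_norm_vanishes_for_large_lambda(self, tfm_truth):
        substrate, _, gt = tfm_truth
        field = _field_from_truth(gt)
        norms = [np.linalg.norm(tr.fttc(field, substrate, lam).t_pa)
                 for lam in (1e-4, 1e-2, 1.0, 100.0)]
        assert np.all(np.diff(norms) < 0)
        assert norms[-1] < 1e-3 * norms[0]

    def test_net_force_free_gauge(self, tfm_truth):
        substrate, _, gt = tfm_truth
        out = tr.fttc(_field_from_truth(gt), substrate, lam=1e-9)
        net = np.abs(out.t_pa.sum(axis=(0, 1))).max()
        assert net < 1e-6 * np.abs(out.t_pa).sum()

    def test_negative_lambda_rejected(self, tfm_truth):
        substrate, _, gt = tfm_truth
        with pytest.raises(ValueError):
            tr.fttc(_field_from_truth(gt), substrate, lam=-1.0)

    def test_incomplete_grid_rejected(self, tfm_truth):
        substrate, _, gt = tfm_truth
        f = _field_from_truth(gt)
        f.valid[3, 3] = False
        with pytest.raises(ValueError, match="invalid nodes"):
            tr.fttc(f, substrate, lam=1e-4)


class TestChooseLambda:
    def test_noiseless_corner_sits_in_flat_low_lambda_regime(self, tfm_truth):
        substrate, _, gt = tfm_truth
        field = _field_from_truth(gt)
        lam_star, curve = tr.choose_lambda(field, substrate)
        t0 = tr.fttc(field, substrate, 1e-9).t_pa
        t_star = tr.fttc(field, substrate, lam_star).t_pa
        assert np.linalg.norm(t_star - t0) / np.linalg.norm(t0) < 0.10
        assert {"lam", "residual_norm", "solution_norm", "curvature"} <= set(curve.columns)
        assert np.all(np.diff(curve["residual_norm"]) >= -1e-6 * curve["residual_norm"].max())
        assert np.all(np.diff(curve["solution_norm"]) <= 1e-6 * curve["solution_norm"].max())

    def test_inadequate_lambda_grid_rejected(self, tfm_truth):
        substrate, _, gt = tfm_truth
        field = _field_from_truth(gt)
        with pytest.raises(ValueError):
            tr.choose_lambda(field, substrate, lambdas=np.array([1e-4]))
        with pytest.raises(ValueError):
            tr.choose_lambda(field, substrate, lambdas=np.logspace(-4, -3, 25))


class TestStrainEnergy:
    def test_zero_fields_store_zero_energy(self):
        z = np.zeros((16, 16, 2))
        grid = dict(x_um=np.arange(16.0), y_um=np.arange(16.0), spacing_um=1.0)
        tf = tr.TractionField(t_pa=z, **grid)
        df = tr.DisplacementField(u_um=z + 1.0, **grid)
        assert tr.strain_energy(tf, df).u_joules == 0.0

    def test_recovered_energy_matches_sidecar(self, tfm_truth):
        substrate, _, gt = tfm_truth
        field = _field_from_truth(gt)
        out = tr.fttc(field, substrate, lam=1e-9)
        u = tr.strain_energy(out, field).u_joules
        assert u == pytest.approx(gt.strain_energy_j, rel=0.02)

    def test_bilinearity_doubling_displacement_doubles_energy(self, tfm_truth):
        substrate, _, gt = tfm_truth
        grid = dict(x_um=gt.x_um, y_um=gt.y_um, spacing_um=gt.spacing_um)
        tf = tr.TractionField(t_pa=gt.traction_pa, **grid)
        u1 = tr.strain_energy(tf, tr.DisplacementField(u_um=gt.displacement_um, **grid))
        u2 = tr.strain_energy(tf, tr.DisplacementField(u_um=2 * gt.displacement_um, **grid))
        assert u2.u_joules == pytest.approx(2 * u1.u_joules, rel=1e-12)

    def test_energy_invariant_under_rigid_translation(self, tfm_truth):
        """Shifting both fields by the same grid offset leaves U unchanged."""
        substrate, _, gt = tfm_truth
        grid = dict(x_um=gt.x_um, y_um=gt.y_um, spacing_um=gt.spacing_um)
        u1 = tr.strain_energy(
            tr.TractionField(t_pa=gt.traction_pa, **grid),
            tr.DisplacementField(u_um=gt.displacement_um, **grid)).u_joules
        u2 = tr.strain_energy(
            tr.TractionField(t_pa=np.roll(gt.traction_pa, (5, -3), axis=(0, 1)), **grid),
            tr.DisplacementField(u_um=np.roll(gt.displacement_um, (5, -3), axis=(0, 1)),
                                 **grid)).u_joules
        assert u2 == pytest.approx(u1, rel=1e-12)

    def test_grid_mismatch_rejected(self, tfm_truth):
        _, _, gt = tfm_truth
        tf = tr.TractionField(x_um=gt.x_um, y_um=gt.y_um, t_pa=gt.traction_pa,
                              spacing_um=gt.spacing_um)
        small = tr.DisplacementField(x_um=gt.x_um[:32], y_um=gt.y_um[:32],
                                     u_um=gt.displacement_um[:32, :32],
                                     spacing_um=gt.spacing_um)
        with pytest.raises(ValueError, match="grid"):
            tr.strain_energy(tf, small)

    def test_per_area_value_from_cell_mask(self, tfm_truth):
        substrate, _, gt = tfm_truth
        grid = dict(x_um=gt.x_um, y_um=gt.y_um, spacing_um=gt.spacing_um)
        mask = np.ones(gt.traction_pa.shape[:2], dtype=bool)
        res = tr.strain_energy(tr.TractionField(t_pa=gt.traction_pa, **grid),
                               tr.DisplacementField(u_um=gt.displacement_um, **grid),
                               cell_mask=mask)
        assert res.cell_area_um2 == pytest.approx(64 * 64 * 1.73 ** 2)
        assert res.u_per_area == pytest.approx(res.u_joules / res.cell_area_um2)
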