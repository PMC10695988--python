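"""Registration, PIV, Boussinesq forward/inverse, and force balance."""

import numpy as np
import pytest
from scipy import ndimage

from oracles import axisymmetric_mean_stress_oracle
from tensionmap import mechanics as mech, synthetic as syn
from tensionmap.types import MechTruth, TractionField


@pytest.fixture(scope="module")
def bead_scene():
    m = MechTruth(traction_field=np.zeros((8, 8, 2)), grid_spacing=8.0,
                  bead_density=0.02)
    return m


def make_pair(mech_truth, u_fn, seed):
    return syn.simulate_bead_pair(mech_truth, image_shape=(256, 256),
                                  seed=seed, displacement=u_fn)


class TestRegistration:
    def test_known_integer_shift(self, bead_scene):
        pair = make_pair(bead_scene,
                         lambda y, x: (np.zeros_like(y), np.zeros_like(x)), 0)
        shifted = ndimage.shift(pair.reference, (3, -2), order=3)
        (dy, dx), corrected = mech.register_drift(shifted, pair.reference)
        assert abs(dy - 3) < 0.05 and abs(dx + 2) < 0.05
        # corrected image matches the reference away from the borders
        res = np.abs(corrected - pair.reference)[10:-10, 10:-10]
        assert res.mean() < 0.05 * pair.reference.max()

    def test_identical_images_zero_shift(self, bead_scene):
        pair = make_pair(bead_scene,
                         lambda y, x: (np.zeros_like(y), np.zeros_like(x)), 1)
        (dy, dx), _ = mech.register_drift(pair.reference, pair.reference)
        assert dy == 0.0 and dx == 0.0

    def test_subpixel_shift(self, bead_scene):
        pair = make_pair(bead_scene,
                         lambda y, x: (np.zeros_like(y), np.zeros_like(x)), 2)
        shifted = ndimage.shift(pair.reference, (0.5, 0.0), order=3)
        (dy, dx), _ = mech.register_drift(shifted, pair.reference)
        assert abs(dy - 0.5) < 0.1 and abs(dx) < 0.1


class TestPIV:
    def test_rigid_translation_recovered(self, bead_scene):
        pair = make_pair(bead_scene,
                         lambda y, x: (np.zeros_like(y), np.full_like(x, 2.0)), 1)
        d = mech.piv_displacements(pair.reference, pair.deformed, 16.0,
                                   window=32, pixel_size=1.0)
        assert np.abs(d.u[..., 0] - 2.0).mean() < 0.1
        assert np.abs(d.u[..., 1]).mean() < 0.1

    def test_smooth_field_rms(self, bead_scene):
        def u_fn(y, x):
            return (1.5 * np.sin(2 * np.pi * y / 256),
                    2.0 * np.sin(2 * np.pi * x / 256))
        pair = make_pair(bead_scene, u_fn, 2)
        d = mech.piv_displacements(pair.reference, pair.deformed, 16.0,
                                   window=32, pixel_size=1.0)
        yy, xx = np.meshgrid(d.y, d.x, indexing="ij")
        tuy, tux = u_fn(yy, xx)
        rms = np.sqrt(np.mean((d.u[..., 0] - tux) ** 2
                              + (d.u[..., 1] - tuy) ** 2))
        assert rms < 0.15

    def test_zero_displacement_noise_floor(self, bead_scene):
        pair = make_pair(bead_scene,
                         lambda y, x: (np.zeros_like(y), np.zeros_like(x)), 3)
        d = mech.piv_displacements(pair.reference, pair.deformed, 16.0,
                                   window=32, pixel_size=1.0)
        assert np.sqrt(np.mean(d.u ** 2)) < 0.05

    def test_empty_window_flagged(self):
        ref = np.zeros((128, 128))
        ref[60:68, 60:68] = 100.0    # signal only in the centre
        d = mech.piv_displacements(ref, ref, 32.0, window=32, pixel_size=1.0)
        assert d.replaced.any()


class TestBoussinesq:
    def _tf(self, T, h=2.0):
        ny, nx = T.shape[:2]
        return TractionField(x=np.arange(nx) * h, y=np.arange(ny) * h, T=T,
                             grid_spacing=h, E_gel=2800.0, nu=0.5)

    def test_zero_traction_zero_displacement(self):
        d = mech.forward_boussinesq(self._tf(np.zeros((32, 32, 2))))
        assert np.all(d.u == 0.0)

    def test_displacement_decays_with_distance(self):
        # localized force: |u| decreases monotonically away from it
        T = np.zeros((128, 128, 2))
        T[64, 64, 0] = 100.0
        d = mech.forward_boussinesq(self._tf(T))
        mags = [np.hypot(*d.u[64, 64 + r]) for r in (4, 8, 16, 32)]
        assert all(b < a for a, b in zip(mags, mags[1:]))
        # roughly 1/r in the near field (periodic images soften the tail)
        assert mags[0] / mags[1] > 1.5

    def test_antisymmetric_force_pair(self):
        # equal and opposite point forces placed symmetrically about a grid
        # line: ux is antisymmetric, uy symmetric under that reflection
        n = 64
        T = np.zeros((n, n, 2))
        T[32, 24, 0] = 100.0
        T[32, 40, 0] = -100.0
        d = mech.forward_boussinesq(self._tf(T))
        idx = (n - np.arange(n)) % n
        np.testing.assert_allclose(d.u[..., 0], -d.u[..., 0][:, idx], atol=1e-14)
        np.testing.assert_allclose(d.u[..., 1], d.u[..., 1][:, idx], atol=1e-14)


class TestFTTC:
    def _roundtrip(self, lam):
        T = syn.gaussian_traction_patch((64, 64), 2.0, magnitude=200,
                                        sigma_um=8.0, separation_um=30.0)
        tf = TractionField(x=np.arange(64) * 2.0, y=np.arange(64) * 2.0,
                           T=T, grid_spacing=2.0, E_gel=2800.0, nu=0.5)
        disp = mech.forward_boussinesq(tf)
        rec = mech.fttc_tractions(disp, 2800.0, 0.5, lam=lam)
        return T, rec

    def test_zero_displacement_zero_traction(self):
        from tensionmap.types import DisplacementField
        d = DisplacementField(x=np.arange(16) * 2.0, y=np.arange(16) * 2.0,
                              u=np.zeros((16, 16, 2)),
                              quality=np.ones((16, 16)),
                              replaced=np.zeros((16, 16), bool),
                              grid_spacing=2.0)
        rec = mech.fttc_tractions(d)
        assert np.allclose(rec.T, 0.0)

    def test_oracle_roundtrip_small_lambda(self):
        T, rec = self._roundtrip(lam=1e-8)
        rel = np.linalg.norm(rec.T - T) / np.linalg.norm(T)
        assert rel < 0.10
        # net force and torque vanish
        assert np.allclose(rec.net_force, 0.0, atol=1e-12)
        yy, xx = np.mgrid[0:64, 0:64].astype(float) * 2.0
        torque = np.sum(xx * rec.T[..., 1] - yy * rec.T[..., 0])
        assert abs(torque) / (np.abs(rec.T).sum() * 64) < 1e-6

    def test_regularization_monotonicity(self):
        norms = []
        for lam in [1e-8, 1e-5, 1e-3]:
            _, rec = self._roundtrip(lam)
            norms.append(np.linalg.norm(rec.T))
        assert norms[0] >= norms[1] >= norms[2]

    def test_negative_lambda_rejected(self):
        from tensionmap.types import DisplacementField
        d = DisplacementField(x=np.arange(16), y=np.arange(16),
                              u=np.zeros((16, 16, 2)),
                              quality=np.ones((16, 16)),
                              replaced=np.zeros((16, 16), bool),
                              grid_spacing=1.0)
        with pytest.raises(ValueError):
            mech.fttc_tractions(d, lam=-1.0)

    def test_small_grid_rejected(self):
        from tensionmap.types import DisplacementField
        d = DisplacementField(x=np.arange(4), y=np.arange(4),
                              u=np.zeros((4, 4, 2)),
                              quality=np.ones((4, 4)),
                              replaced=np.zeros((4, 4), bool),
                              grid_spacing=1.0)
        with pytest.raises(ValueError, match="grid"):
            mech.fttc_tractions(d)


class TestForceBalance:
    def _ring_setup(self, gn=64, gh=1.0, mag=100.0):
        T = syn.inward_traction_ring((gn, gn), gh, magnitude=mag,
                                     r0_um=20.0, width_um=3.0)
        yy, xx = np.mgrid[0:gn, 0:gn].astype(float) * gh
        c = (gn - 1) * gh / 2
        rr = np.hypot(yy - c, xx - c)
        mask = rr <= 28.0
        tf = TractionField(x=np.arange(gn) * gh, y=np.arange(gn) * gh, T=T,
                           grid_spacing=gh)
        return tf, mask, rr

    def test_zero_traction_zero_force(self):
        tf, mask, _ = self._ring_setup(mag=0.0)
        tf.T[:] = 0.0
        fmap = mech.internal_force_balance(tf, mask)
        assert np.allclose(fmap.F, 0.0, atol=1e-9)

    def test_axisymmetric_oracle_within_two_percent(self):
        tf, mask, rr = self._ring_setup()
        fmap = mech.internal_force_balance(tf, mask)
        # oracle: load on the cell is the reaction -T_r (outward-positive)
        t_r = lambda s: 100.0 * np.exp(-((s - 20.0) ** 2) / (2 * 3.0 ** 2))
        oracle = axisymmetric_mean_stress_oracle(t_r, 28.0)
        scale = abs(oracle(0.5))
        for r in [0.5, 5.0, 10.0, 15.0]:
            sel = mask & (np.abs(rr - r) < 0.5)
            assert abs(fmap.F[sel].mean() - abs(oracle(r))) / scale < 0.02

    def test_center_exceeds_periphery_for_inward_ring(self):
        tf, mask, rr = self._ring_setup()
        fmap = mech.internal_force_balance(tf, mask)
        center = fmap.F[mask & (rr < 5)].mean()
        edge = fmap.F[mask & (rr > 24)].mean()
        assert center > edge

    def test_linearity(self):
        tf, mask, _ = self._ring_setup(gn=32)
        f1 = mech.internal_force_balance(tf, mask)
        tf2 = TractionField(x=tf.x, y=tf.y, T=2.0 * tf.T,
                            grid_spacing=tf.grid_spacing)
        f2 = mech.internal_force_balance(tf2, mask)
        np.testing.assert_allclose(f2.F, 2.0 * f1.F, rtol=1e-8, atol=1e-10)

    def test_rotational_equivariance_quarter_turn(self):
        gn = 32
        T = syn.gaussian_traction_patch((gn, gn), 1.0, magnitude=50,
                                        sigma_um=4.0, separation_um=12.0)
        yy, xx = np.mgrid[0:gn, 0:gn].astype(float)
        c = (gn - 1) / 2
        mask = np.hypot(yy - c, xx - c) <= 13.0
        tf = TractionField(x=np.arange(gn) * 1.0, y=np.arange(gn) * 1.0, T=T,
                           grid_spacing=1.0)
        f0 = mech.internal_force_balance(tf, mask)
        # rotate the traction field by 90 deg CCW: (Tx,Ty) -> (-Ty,Tx)
        Trot = np.stack([-np.rot90(T[..., 1]), np.rot90(T[..., 0])], axis=-1)
        tfr = TractionField(x=tf.x, y=tf.y, T=Trot, grid_spacing=1.0)
        fr = mech.internal_force_balance(tfr, np.rot90(mask))
        np.testing.assert_allclose(fr.F, np.rot90(f0.F), atol=1e-8)

    def test_unbalanced_input_rejected(self):
        gn = 32
        T = np.zeros((gn, gn, 2))
        T[..., 0] = 50.0     # uniform unidirectional traction: unbalanced
        yy, xx = np.mgrid[0:gn, 0:gn].astype(float)
        mask = np.hypot(yy - 15.5, xx - 15.5) <= 13.0
        tf = TractionField(x=np.arange(gn) * 1.0, y=np.arange(gn) * 1.0, T=T,
                           grid_spacing=1.0)
        with pytest.raises(ValueError, match="unbalanced"):
            mech.internal_force_balance(tf, mask)

    def test_non_simply_connected_mask_warns(self):
        gn = 32
        tf, mask, rr = self._ring_setup(gn=gn, gh=1.0)
        mask = rr <= 14.0
        mask[(rr < 3.0)] = False     # punch a hole
        with pytest.warns(UserWarning, match="simply connected"):
            mech.internal_force_balance(tf, mask)
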