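"""Three-cube FRET quantification: corrections, calibration, efficiency, FRAP."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tensionmap import fret, synthetic as syn


class TestCorrectedFret:
    def test_identity_when_no_bleedthrough(self, rng):
        I = rng.random((10, 10)) * 100
        np.testing.assert_array_equal(
            fret.corrected_fret(I * 0 + 1, I * 0 + 1, I, a=0.0, d=0.0), I)

    def test_hand_arithmetic(self):
        # 100 - 0.045*200 - 0.045*200 = 82
        out = fret.corrected_fret(np.array([[200.0]]), np.array([[200.0]]),
                                  np.array([[100.0]]), a=0.045, d=0.045)
        assert np.isclose(out[0, 0], 82.0)

    def test_exact_bleedthrough_gives_zero(self, rng):
        I_DD = rng.random((20, 20)) * 500
        I_AA = rng.random((20, 20)) * 500
        I_DA = 0.045 * I_AA + 0.045 * I_DD
        out = fret.corrected_fret(I_DD, I_AA, I_DA)
        np.testing.assert_allclose(out, 0.0, atol=1e-10)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fret.corrected_fret(np.zeros((3, 3)), np.zeros((3, 3)),
                                np.zeros((4, 4)))


class TestFretIndex:
    @pytest.mark.parametrize("fc,iaa,expected", [(0.0, 200.0, 0.0),
                                                 (50.0, 200.0, 0.25)])
    def test_values(self, fc, iaa, expected):
        out = fret.fret_index(np.array([[fc]]), np.array([[iaa]]))
        assert np.isclose(out[0, 0], expected)

    def test_invalid_pixels_become_nan_and_excluded(self):
        fc = np.array([[50.0, 50.0]])
        iaa = np.array([[200.0, 1.0]])
        valid = np.array([[True, False]])
        out = fret.fret_index(fc, iaa, valid)
        assert np.isnan(out[0, 1]) and np.isclose(out[0, 0], 0.25)
        m, _, n = fret.mean_fret(out)
        assert n == 1 and np.isclose(m, 0.25)


class TestFretEfficiency:
    @pytest.mark.parametrize("fc,idd,G,expected", [
        (0.0, 100.0, 2.0, 0.0),
        (100.0, 100.0, 1.0, 0.5),
        (60.0, 70.0, 2.0, 0.30),
    ])
    def test_values(self, fc, idd, G, expected):
        out = fret.fret_efficiency(np.array([[fc]]), np.array([[idd]]), G)
        assert np.isclose(out[0, 0], expected)

    def test_nonpositive_denominator_is_nan(self):
        out = fret.fret_efficiency(np.array([[-50.0]]), np.array([[10.0]]), 1.0)
        assert np.isnan(out[0, 0])

    def test_monotone_in_corrected_fret(self):
        fc = np.linspace(0, 100, 50)
        E = fret.fret_efficiency(fc, np.full(50, 80.0), 2.0)
        assert np.all(np.diff(E) > 0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(scale=st.floats(0.1, 100.0),
           E0=st.floats(0.01, 0.8))
    def test_scale_invariance(self, scale, E0):
        """Multiplying all channels by a constant leaves index and E fixed."""
        S = np.array([[2.0, 3.0], [1.0, 4.0]])
        I_DD = 100 * S * (1 - E0)
        I_AA = 100 * S
        fc = 2.0 * 100 * S * E0
        I_DA = fc + 0.045 * I_AA + 0.045 * I_DD
        base_fc = fret.corrected_fret(I_DD, I_AA, I_DA)
        E1 = fret.fret_efficiency(base_fc, I_DD, 2.0)
        idx1 = fret.fret_index(base_fc, I_AA)
        fc2 = fret.corrected_fret(I_DD * scale, I_AA * scale, I_DA * scale)
        E2 = fret.fret_efficiency(fc2, I_DD * scale, 2.0)
        idx2 = fret.fret_index(fc2, I_AA * scale)
        np.testing.assert_allclose(E1, E2, rtol=1e-9)
        np.testing.assert_allclose(idx1, idx2, rtol=1e-9)

    def test_index_monotone_in_E_at_fixed_stoichiometry(self):
        """Index and E rank identically across a synthetic E sweep."""
        Es, idxs = [], []
        for E0 in np.linspace(0.05, 0.6, 10):
            S = 3.0
            I_DD = 100 * S * (1 - E0)
            I_AA = 100 * S
            fc = 2.0 * 100 * S * E0
            Es.append(fret.fret_efficiency(np.array([fc]), np.array([I_DD]), 2.0)[0])
            idxs.append(fret.fret_index(np.array([fc]), np.array([I_AA]))[0])
        assert np.all(np.diff(Es) > 0) and np.all(np.diff(idxs) > 0)


class TestBleedthrough:
    def test_exact_recovery_noise_free(self):
        stk = syn.simulate_donor_only((100, 100), d=0.045, seed=0)
        d, se = fret.estimate_bleedthrough(stk, "donor")
        assert abs(d - 0.045) < 1e-12

    def test_zero_cross_excitation(self):
        stk = syn.simulate_acceptor_only((100, 100), a=0.0, seed=1)
        a, se = fret.estimate_bleedthrough(stk, "acceptor")
        assert abs(a) < 1e-12

    def test_noisy_recovery_within_two_percent(self):
        errs = []
        for seed in range(5):
            stk = syn.simulate_donor_only((316, 316), d=0.045, seed=seed,
                                          noise="gaussian", noise_scale=0.01)
            d, _ = fret.estimate_bleedthrough(stk, "donor")
            errs.append(abs(d - 0.045) / 0.045)
        assert max(errs) < 0.02

    def test_multi_cell_averaging(self):
        stacks = [syn.simulate_donor_only((50, 50), d=0.045, seed=s,
                                          noise="gaussian", noise_scale=0.01)
                  for s in range(4)]
        d, se = fret.estimate_bleedthrough(stacks, "donor")
        assert abs(d - 0.045) < 0.01 and se > 0

    def test_bad_mode_rejected(self):
        stk = syn.simulate_donor_only((50, 50))
        with pytest.raises(ValueError):
            fret.estimate_bleedthrough(stk, "both")

    def test_low_dynamic_range_rejected(self):
        from tensionmap.types import ChannelStack
        flat = np.full((50, 50), 100.0)
        stk = ChannelStack(I_DD=flat, I_AA=flat, I_DA=flat * 0.045)
        with pytest.raises(ValueError, match="dynamic range"):
            fret.estimate_bleedthrough(stk, "donor")


class TestGFactor:
    def test_exact_recovery(self):
        hi, lo = syn.simulate_g_pair((100, 100), G=2.0, E_high=0.33, E_low=0.12)
        G, se = fret.estimate_g_factor(hi, lo)
        assert abs(G - 2.0) < 1e-9

    def test_unity_g(self):
        hi, lo = syn.simulate_g_pair((80, 80), G=1.0, E_high=0.4, E_low=0.1)
        G, _ = fret.estimate_g_factor(hi, lo)
        assert abs(G - 1.0) < 1e-10

    def test_identical_constructs_degenerate(self):
        hi, lo = syn.simulate_g_pair((60, 60), G=2.0, E_high=0.25, E_low=0.25)
        with pytest.raises(ValueError, match="indistinguishable"):
            fret.estimate_g_factor(hi, lo)


class TestMeanAndDelta:
    def test_uniform_mean(self):
        m, sd, n = fret.mean_fret(np.full((10, 10), 0.2))
        assert np.isclose(m, 0.2) and sd < 1e-12 and n == 100

    def test_half_half(self):
        E = np.concatenate([np.full(50, 0.1), np.full(50, 0.3)])
        m, _, _ = fret.mean_fret(E)
        assert np.isclose(m, 0.2)

    def test_checkerboard_with_nans(self):
        E = np.array([[0.1, np.nan], [np.nan, 0.3]])
        m, _, n = fret.mean_fret(E)
        assert n == 2 and np.isclose(m, 0.2)

    @pytest.mark.parametrize("Es,Er,expected", [
        (0.20, 0.20, 0.0),
        (0.18, 0.20, -0.10),   # net tension
        (0.21, 0.20, +0.05),   # net relaxation
    ])
    def test_delta_fret(self, Es, Er, expected):
        assert np.isclose(fret.delta_fret(Es, Er), expected)

    def test_delta_fret_requires_positive_reference(self):
        with pytest.raises(ValueError):
            fret.delta_fret(0.1, 0.0)


class TestFrap:
    def test_noise_free_exact(self):
        t, y = syn.simulate_frap_trace(tau=20.0, a=1.0, b=-0.6, dt=1.0, T=100.0)
        res = fret.fit_frap(t, y)
        assert abs(res.tau - 20.0) < 1e-6
        assert res.identifiable

    def test_flat_trace_unidentifiable(self):
        t, y = syn.simulate_frap_trace(tau=20.0, a=1.0, b=0.0)
        res = fret.fit_frap(t, y)
        assert not res.identifiable

    def test_noisy_tau_within_ten_percent(self):
        taus = []
        for seed in range(20):
            t, y = syn.simulate_frap_trace(tau=20.0, a=1.0, b=-0.6, dt=2.0,
                                           T=100.0, noise_sd=0.02, seed=seed)
            taus.append(fret.fit_frap(t, y).tau)
        rel = np.abs(np.array(taus) - 20.0) / 20.0
        assert np.median(rel) < 0.10

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fret.fit_frap([0, 1, 2], [1, 2, 3])

    def test_summary_mentions_tau(self):
        t, y = syn.simulate_frap_trace(tau=10.0)
        s = fret.fit_frap(t, y).summary()
        assert "tau" in s
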