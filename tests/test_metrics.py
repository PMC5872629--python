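import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from gfadwi import (
    TensorSpec,
    adc_profile,
    add_rician_noise,
    fa_from_eigenvalues,
    fit_tensor,
    gfa_from_adc_profile,
    make_scheme,
    mean_diffusivity,
    metric_map,
    tensor_signal,
)
from conftest import SINGLE_FIBER, SINGLE_FIBER_FA

nonneg_profiles = hnp.arrays(
    float,
    st.integers(min_value=2, max_value=40),
    elements=st.floats(min_value=0.0, max_value=3e-3, allow_nan=False),
)


def gfa_two_pass(psi):
    """Independent oracle: literal sample-std over root-mean-square.

    Rescaled by the max entry first (the ratio is scale-invariant), so
    the oracle stays finite on profiles near the float underflow limit.
    """
    psi = np.asarray(psi, dtype=float)
    psi = psi / np.max(np.abs(psi))
    return np.std(psi, ddof=1) / np.sqrt(np.mean(psi**2))


class TestAdcProfile:
    def test_model_inversion(self, scheme21):
        sig = np.full(22, 1000.0 * np.exp(-1.0))
        sig[0] = 1000.0
        prof = adc_profile(sig, scheme21)
        np.testing.assert_allclose(prof.values, 1e-3, rtol=1e-12)
        assert prof.n_s == 21

    def test_unattenuated_signal_gives_zero_adc(self, scheme21):
        sig = np.full(22, 500.0)
        np.testing.assert_array_equal(adc_profile(sig, scheme21).values, 0.0)

    def test_noise_overshoot_clamped_to_zero(self, scheme21):
        sig = np.full(22, 1000.0)
        sig[1:] = 1100.0  # S_i > S0: negative raw ADC
        prof = adc_profile(sig, scheme21)
        assert prof.values[0] == 0.0
        raw = adc_profile(sig, scheme21, clamp=False)
        assert np.all(raw.values < 0.0)

    def test_dead_b0_marks_voxel_undefined(self, scheme21):
        sig = np.zeros(22)
        with pytest.raises(ValueError, match="undefined"):
            adc_profile(sig, scheme21)


class TestGfa:
    def test_constant_profile_is_isotropic(self):
        assert gfa_from_adc_profile(np.full(21, 1.3e-3)) == pytest.approx(0.0, abs=1e-12)

    def test_single_nonzero_profile_attains_one(self):
        # hand algebra: for (0, 0, 1), std = rms = 1/sqrt(3)
        assert gfa_from_adc_profile(np.array([0.0, 0.0, 1.0])) == pytest.approx(1.0)

    def test_hand_evaluated_profile_123(self):
        # sqrt(3 * 2 / (2 * 14)) evaluated by hand
        assert gfa_from_adc_profile(np.array([1.0, 2.0, 3.0])) == pytest.approx(
            0.46291004988627577, abs=1e-12
        )

    def test_all_zero_profile_is_undefined_not_zero(self):
        assert np.isnan(gfa_from_adc_profile(np.zeros(21)))

    @settings(deadline=None, derandomize=True)
    @given(nonneg_profiles)
    def test_matches_two_pass_oracle_and_stays_in_unit_interval(self, psi):
        got = gfa_from_adc_profile(psi)
        if np.all(psi == 0):
            assert np.isnan(got)
        else:
            assert got == pytest.approx(gfa_two_pass(psi), abs=1e-12)
            assert -1e-12 <= got <= 1.0 + 1e-12

    @settings(deadline=None, derandomize=True)
    @given(nonneg_profiles, st.floats(min_value=1e-6, max_value=1e6))
    def test_scale_invariance(self, psi, c):
        if np.all(psi == 0):
            return
        assert gfa_from_adc_profile(c * psi) == pytest.approx(
            gfa_from_adc_profile(psi), rel=1e-9
        )


class TestFa:
    @pytest.mark.parametrize(
        "lams, expected",
        [
            ((1.0, 1.0, 1.0), 0.0),
            ((1.0, 0.0, 0.0), 1.0),
            (SINGLE_FIBER, SINGLE_FIBER_FA),
        ],
    )
    def test_closed_form_values(self, lams, expected):
        assert fa_from_eigenvalues(*lams) == pytest.approx(expected, abs=1e-12)

    def test_all_zero_eigenvalues_undefined(self):
        assert np.isnan(fa_from_eigenvalues(0.0, 0.0, 0.0))

    @settings(deadline=None, derandomize=True)
    @given(
        st.tuples(
            st.floats(min_value=0.0, max_value=3e-3),
            st.floats(min_value=0.0, max_value=3e-3),
            st.floats(min_value=0.0, max_value=3e-3),
        ),
        st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_scale_invariance_and_bounds(self, lams, c):
        lams = tuple(sorted(lams, reverse=True))
        if sum(lams) == 0:
            return
        fa = fa_from_eigenvalues(*lams)
        assert 0.0 <= fa <= 1.0 + 1e-12
        assert fa_from_eigenvalues(*(c * l for l in lams)) == pytest.approx(fa, rel=1e-9)


class TestFitTensor:
    def test_recovers_diagonal_tensor_exactly(self, scheme21, single_fiber_spec):
        sig = tensor_signal(single_fiber_spec, scheme21, S0=1000.0)
        t = fit_tensor(sig, scheme21)
        np.testing.assert_allclose(t.eigenvalues, SINGLE_FIBER, atol=1e-12)

    def test_isotropic_eigenvalues_equal(self, scheme21):
        sig = tensor_signal(TensorSpec((0.7e-3, 0.7e-3, 0.7e-3)), scheme21, S0=900.0)
        lam = fit_tensor(sig, scheme21).eigenvalues
        np.testing.assert_allclose(lam, 0.7e-3, atol=1e-12)

    def test_agrees_with_generic_least_squares_oracle(self, scheme21):
        rng = np.random.default_rng(4)
        spec = TensorSpec((2.1e-3, 0.8e-3, 0.3e-3), principal_direction=(0.2, -0.9, 0.4))
        sig = add_rician_noise(tensor_signal(spec, scheme21, 1000.0), 20.0, seed=9)
        t = fit_tensor(sig, scheme21)
        # independent route: generic normal equations on the same model
        g = scheme21.dw_directions
        X = scheme21.dw_bvalues[:, None] * np.column_stack(
            [g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
             2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2], 2 * g[:, 1] * g[:, 2]]
        )
        y = -np.log(sig[1:] / sig[0])
        d = np.linalg.solve(X.T @ X, X.T @ y)
        D = np.array([[d[0], d[3], d[4]], [d[3], d[1], d[5]], [d[4], d[5], d[2]]])
        np.testing.assert_allclose(t.tensor, D, atol=1e-12)

    def test_rotation_invariance_of_fa(self, scheme21):
        fas = []
        for direction in [(1, 0, 0), (0, 0, 1), (1, 1, 1), (0.3, -0.5, 0.81)]:
            spec = TensorSpec(SINGLE_FIBER, principal_direction=direction)
            lam = fit_tensor(tensor_signal(spec, scheme21, 1000.0), scheme21).eigenvalues
            fas.append(fa_from_eigenvalues(*lam))
        np.testing.assert_allclose(fas, SINGLE_FIBER_FA, atol=1e-9)

    def test_noisy_replicates_recover_lambda1_within_5_percent(
        self, scheme21, single_fiber_spec
    ):
        clean = tensor_signal(single_fiber_spec, scheme21, S0=1000.0)
        rng = np.random.default_rng(21)
        l1 = [
            fit_tensor(add_rician_noise(clean, 1000.0 / 30.0, seed=rng), scheme21).eigenvalues[0]
            for _ in range(1000)
        ]
        assert abs(np.mean(l1) - 1.7e-3) < 0.05 * 1.7e-3

    def test_degenerate_scheme_rejected(self):
        dirs = np.vstack([np.zeros(3)] + [[1.0, 0.0, 0.0]] * 6)
        bvals = np.concatenate([[0.0], np.full(6, 1000.0)])
        from gfadwi import GradientScheme

        scheme = GradientScheme(directions=dirs, bvalues=bvals)
        with pytest.raises(ValueError, match="degenerate"):
            fit_tensor(np.full(7, 500.0), scheme)


class TestMetricMap:
    def test_uniform_isotropic_phantom_has_zero_gfa(self, scheme21):
        from gfadwi import build_phantom, TensorSpec

        blocks = {
            "iso": {
                "slices": (slice(0, 6), slice(0, 6), slice(0, 2)),
                "model": TensorSpec((1e-3, 1e-3, 1e-3)),
            }
        }
        dwi, truth = build_phantom((6, 6, 2), scheme21, blocks=blocks, sigma=0.0)
        gfa = metric_map(dwi, "GFA")
        assert np.all(gfa.valid)
        np.testing.assert_allclose(gfa.data, 0.0, atol=1e-9)

    def test_single_fiber_block_fa_matches_closed_form(self, noiseless_phantom):
        dwi, truth = noiseless_phantom
        fa = metric_map(dwi, "FA", mask=truth.labels > 0)
        block = truth.labels == truth.label_table["BA4_lesioned"]
        np.testing.assert_allclose(fa.data[block], SINGLE_FIBER_FA, atol=1e-9)

    def test_crossing_block_fa_below_single_fiber_fa(self, noiseless_phantom):
        dwi, truth = noiseless_phantom
        fa = metric_map(dwi, "FA", mask=truth.labels > 0)
        single = fa.data[truth.labels == truth.label_table["BA4_lesioned"]].mean()
        crossing = fa.data[truth.labels == truth.label_table["BA6_lesioned"]].mean()
        assert crossing < single

    def test_maps_stay_in_unit_interval_on_noiseless_phantom(self, noiseless_phantom):
        dwi, truth = noiseless_phantom
        for metric in ("FA", "GFA"):
            m = metric_map(dwi, metric, mask=truth.labels > 0)
            vals = m.data[m.valid]
            assert np.all((vals >= 0.0) & (vals <= 1.0))

    def test_matches_scalar_path_voxelwise(self, scheme21, noiseless_phantom):
        dwi, truth = noiseless_phantom
        gfa = metric_map(dwi, "GFA", mask=truth.labels > 0)
        vox = tuple(np.argwhere(truth.labels > 0)[17])
        expected = gfa_from_adc_profile(adc_profile(dwi.data[vox], scheme21))
        assert gfa.data[vox] == pytest.approx(expected, abs=1e-12)

    def test_md_of_isotropic_voxel(self, scheme21):
        sig = tensor_signal(TensorSpec((1e-3, 1e-3, 1e-3)), scheme21, 1000.0)
        lam = fit_tensor(sig, scheme21).eigenvalues
        assert mean_diffusivity(*lam) == pytest.approx(1e-3, rel=1e-9)

    def test_geometry_mismatch_rejected(self, noiseless_phantom):
        dwi, _ = noiseless_phantom
        with pytest.raises(ValueError, match="mask"):
            metric_map(dwi, "FA", mask=np.ones((2, 2, 2), dtype=bool))

    def test_undefined_voxels_flagged_not_zero(self, scheme21):
        from gfadwi import build_phantom

        dwi, truth = build_phantom((8, 8, 2), scheme21, blocks={}, sigma=0.0)
        gfa = metric_map(dwi, "GFA")  # background DW signal is exactly 0
        assert not np.any(gfa.valid)
        assert np.all(np.isnan(gfa.data))
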