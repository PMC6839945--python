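import numpy as np
import pytest

from coopnet.cooperative_nmda import (
    CooperativityParams,
    GainTable,
    PatchState,
    build_distance_matrix,
    default_sigma_d,
    interneuron_current,
    patch_step,
    pyramidal_current,
)
from coopnet.synapse_kernels import nmda_gate


class TestDistanceMatrix:
    def test_diagonal_is_gaussian_mode(self):
        D = build_distance_matrix(10, 3.0)
        expected = 1.0 / np.sqrt(2 * np.pi * 9.0)
        np.testing.assert_allclose(np.diag(D), expected, rtol=1e-12)

    def test_symmetric_toeplitz(self):
        D = build_distance_matrix(20, 4.0)
        np.testing.assert_allclose(D, D.T, rtol=1e-15)
        for i in range(18):
            for j in range(18):
                assert D[i, j] == pytest.approx(D[i + 1, j + 1], rel=1e-15)

    def test_all_positive_and_noncircular(self):
        D = build_distance_matrix(30, 2.0)
        assert np.all(D > 0)
        # no wraparound: corner entry is the smallest
        assert D[0, -1] == D.min()

    def test_interior_row_sums_near_one(self):
        """Gaussian density sampled at unit spacing sums to ~1."""
        D = build_distance_matrix(250, 30.0)
        interior = D[100:150].sum(axis=1)
        np.testing.assert_allclose(interior, 1.0, rtol=0.01)

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            build_distance_matrix(10, 0.0)

    def test_default_sigma(self):
        assert default_sigma_d(250) == pytest.approx(12.5)


class TestPatchStep:
    def _setup(self, n=5):
        params = CooperativityParams(n_pyr=n)
        D = build_distance_matrix(n, params.sigma_D)
        gains = GainTable()
        return params, D, gains

    def test_leak_relaxation_closed_form(self):
        """v(t) = e_leak + (v0 - e_leak) exp(-t g_leak / C_syn); tau = 1.8 ms."""
        params, D, gains = self._setup()
        n = params.n_pyr
        v0 = -40.0
        patch = PatchState(np.full(n, v0))
        dt, T = 0.05, 10.0
        zeros = np.zeros(n)
        for k in range(int(T / dt)):
            patch = patch_step(
                patch, D, zeros, zeros, zeros, params, gains, dt
            )
        tau = params.C_syn / params.g_leak
        assert tau == pytest.approx(1.8)
        expected = params.e_leak + (v0 - params.e_leak) * np.exp(-T / tau)
        np.testing.assert_allclose(patch.v_syn, expected, rtol=1e-9)

    def test_rest_stays_at_e_leak(self):
        params, D, gains = self._setup()
        patch = PatchState.at_rest(params)
        zeros = np.zeros(params.n_pyr)
        out = patch_step(patch, D, zeros, zeros, zeros, params, gains, 0.05)
        np.testing.assert_allclose(out.v_syn, -60.6, rtol=1e-12)

    def test_drive_bounded_by_e_glu(self):
        params, D, gains = self._setup()
        n = params.n_pyr
        patch = PatchState.at_rest(params)
        big = np.full(n, 50.0)
        gate = np.ones(n)
        last = patch.v_syn.copy()
        for _ in range(5000):
            patch = patch_step(patch, D, big, big, gate, params, gains, 0.05)
            assert np.all(patch.v_syn < params.e_glu)
            assert np.all(patch.v_syn >= last - 1e-9)  # monotone approach
            last = patch.v_syn.copy()

    def test_shape_mismatch(self):
        params, D, gains = self._setup()
        with pytest.raises(ValueError, match="g_ampa"):
            patch_step(
                PatchState.at_rest(params), D, np.zeros(3),
                np.zeros(params.n_pyr), np.zeros(params.n_pyr),
                params, gains, 0.05,
            )

    def test_cooperativity_clustered_beats_spread(self):
        """Clustered co-activation yields a larger summed NMDA gate."""
        params = CooperativityParams(n_pyr=20, sigma_D=3.0)
        D = build_distance_matrix(20, 3.0)
        gains = GainTable()
        # weak drive keeps the gates off their saturation plateau
        g_clustered = np.zeros(20)
        g_clustered[5:15] = 0.02         # 10 adjacent afferents
        g_spread = np.zeros(20)
        g_spread[::2] = 0.02             # same total, evenly spaced
        out = {}
        for name, g_nmda in (("clustered", g_clustered), ("spread", g_spread)):
            patch = PatchState.at_rest(params)
            gate = nmda_gate(patch.v_syn)
            for _ in range(200):
                patch = patch_step(
                    patch, D, np.zeros(20), g_nmda, gate, params, gains, 0.05
                )
                gate = nmda_gate(patch.v_syn)
            out[name] = float(np.sum(gate * g_nmda))
        assert out["clustered"] >= out["spread"]

    def test_large_sigma_permutation_invariance(self):
        """With global cooperation, permuting inputs permutes nothing."""
        n = 16
        params = CooperativityParams(n_pyr=n, sigma_D=1e6)
        D = build_distance_matrix(n, 1e6)
        gains = GainTable()
        rng = np.random.default_rng(3)
        g = rng.uniform(0, 1, n)
        perm = rng.permutation(n)
        outs = []
        for gg in (g, g[perm]):
            patch = PatchState.at_rest(params)
            gate = nmda_gate(patch.v_syn)
            for _ in range(100):
                patch = patch_step(
                    patch, D, gg, gg, gate, params, gains, 0.05
                )
                gate = nmda_gate(patch.v_syn)
            outs.append(np.sort(patch.v_syn.round(12)))
        np.testing.assert_allclose(outs[0], outs[1], rtol=1e-9)


class TestCurrents:
    def test_zero_conductances_zero_current(self):
        params = CooperativityParams(n_pyr=4)
        gains = GainTable()
        patch = PatchState.at_rest(params)
        z = np.zeros(4)
        total, dec = interneuron_current(patch, z, z, 0.0, 0.0, -55.0, params, gains)
        assert total == 0.0
        assert dec.nmda == dec.ampa == dec.gaba == dec.ext == 0.0

    def test_nmdar_scale_zero_kills_nmda_component(self):
        params = CooperativityParams(n_pyr=4)
        gains = GainTable(nmdar_scale=0.0)
        patch = PatchState.at_rest(params)
        g = np.full(4, 2.0)
        total, dec = interneuron_current(patch, g, g, 1.0, 0.5, -55.0, params, gains)
        assert dec.nmda == 0.0
        assert dec.ampa > 0.0

    def test_zero_driving_force(self):
        params = CooperativityParams(n_pyr=4)
        gains = GainTable()
        patch = PatchState.at_rest(params)
        g = np.full(4, 2.0)
        total, dec = interneuron_current(
            patch, g, g, 1.0, 0.0, params.e_glu, params, gains
        )
        assert dec.nmda == dec.ampa == dec.ext == 0.0

    def test_decomposition_sums_to_total(self):
        params = CooperativityParams(n_pyr=6)
        gains = GainTable()
        rng = np.random.default_rng(0)
        patch = PatchState(rng.uniform(-70, -40, 6))
        g1, g2 = rng.uniform(0, 3, 6), rng.uniform(0, 3, 6)
        total, dec = interneuron_current(
            patch, g1, g2, 0.7, 1.1, -52.0, params, gains
        )
        assert total == pytest.approx(dec.total, rel=1e-12)

    def test_pyramidal_current_zero(self):
        params = CooperativityParams(n_pyr=3)
        gains = GainTable()
        I = pyramidal_current(np.zeros(3), 0.0, np.full(3, -60.0), params, gains)
        np.testing.assert_array_equal(I, 0.0)

    def test_pyramidal_gaba_zero_at_reversal(self):
        params = CooperativityParams(n_pyr=3)
        gains = GainTable(k_pyr_ext=0.0)
        v = np.full(3, params.e_GABA)
        I = pyramidal_current(np.ones(3), 5.0, v, params, gains)
        np.testing.assert_allclose(I, 0.0, atol=1e-12)

    def test_pyramidal_external_depolarizing(self):
        params = CooperativityParams(n_pyr=3)
        gains = GainTable()
        I = pyramidal_current(np.ones(3), 0.0, np.full(3, -60.0), params, gains)
        assert np.all(I > 0)

    def test_gain_table_defaults(self):
        g = GainTable()
        assert g.k_pv_ampa == 2**8
        assert g.k_pv_nmda == 2**12
        assert g.k_pv_gaba == 2**8
        assert g.k_pyr_gaba == 2**7
        assert g.k_pv_ext == 5.0 and g.k_pyr_ext == 1.0

    def test_ksyn_default(self):
        assert CooperativityParams(n_pyr=250).k_syn == pytest.approx(3.0 / 250)
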