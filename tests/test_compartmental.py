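import numpy as np
import pytest

from coopnet.compartmental import (
    CableParams,
    Morphology,
    MorphSpec,
    calibrate_rm,
    input_resistance,
    make_synthetic_morphology,
    segmentize,
    simulate,
    site_selection,
    uncaging_protocol,
    wb_rates,
    wb_steady_states,
)
from coopnet.compartmental.morphology import (
    REGION_ORIENS,
    REGION_RADIATUM,
    REGION_SOMA,
    Section,
)
from coopnet.compartmental.protocol import place_synapses


class TestMorphology:
    def test_region_diameters(self, morphology):
        o = [s.diam for s in morphology.sections if s.region == REGION_ORIENS]
        r = [s.diam for s in morphology.sections if s.region == REGION_RADIATUM]
        assert np.mean(o) < np.mean(r)

    def test_swc_round_trip(self, morphology, tmp_path):
        path = tmp_path / "cell.swc"
        morphology.to_swc(path)
        back = Morphology.from_swc(path)
        assert back.n_sections == morphology.n_sections
        for a, b in zip(morphology.sections, back.sections):
            assert a.parent == b.parent
            assert a.region == b.region
            assert a.diam == pytest.approx(b.diam, rel=1e-6)
            assert a.length == pytest.approx(b.length, rel=1e-6)

    def test_seed_variation_same_statistics(self):
        a = make_synthetic_morphology(seed=1)
        b = make_synthetic_morphology(seed=2)
        assert a.total_area() != b.total_area()
        assert a.total_area() == pytest.approx(b.total_area(), rel=0.2)

    def test_degenerate_spec_rejected(self):
        with pytest.raises(ValueError):
            MorphSpec(n_oriens_trees=0, n_radiatum_trees=0)

    def test_path_distance_accumulates(self, morphology):
        for s in morphology.sections[1:6]:
            d_prox = morphology.path_distance(s.index, 0.0)
            d_dist = morphology.path_distance(s.index, 1.0)
            assert d_dist == pytest.approx(d_prox + s.length, rel=1e-12)


class TestSegmentize:
    def test_nseg_odd(self, morphology):
        g = segmentize(morphology)
        assert np.all(g.nseg % 2 == 1)

    def test_dlambda_bound(self, morphology):
        from coopnet.compartmental.cable import ac_length_constant

        params = CableParams()
        g = segmentize(morphology, params, d_lambda=0.1, f=1000.0)
        for s in morphology.sections:
            lam = ac_length_constant(s.diam, params, 1000.0)
            seg_len = s.length / g.nseg[s.index]
            assert seg_len <= 0.1 * lam + 1e-9

    def test_nseg_monotone_in_length(self):
        params = CableParams()
        spec = MorphSpec(jitter=0.0)
        short = make_synthetic_morphology(spec, seed=0)
        sec = short.sections[1]
        doubled = Morphology(
            [
                s if s.index != 1 else Section(
                    1, s.parent, 2 * s.length, s.diam, s.region, s.x, s.y, s.z
                )
                for s in short.sections
            ]
        )
        n1 = segmentize(short, params).nseg[1]
        n2 = segmentize(doubled, params).nseg[1]
        assert n2 >= 2 * n1 - 1  # odd rounding allows one less


class TestWbChannels:
    def test_shift_is_translation(self):
        v = np.linspace(-90, 20, 50)
        a = wb_rates(v, v_shift=0.0)
        b = wb_rates(v + 12.0, v_shift=-12.0)
        for k in a:
            np.testing.assert_allclose(a[k], b[k], rtol=1e-12)

    def test_n_inf_increasing(self):
        v = np.linspace(-90, 20, 200)
        n_inf = wb_steady_states(v)["n_inf"]
        assert np.all(np.diff(n_inf) > 0)

    def test_h_inf_decreasing(self):
        v = np.linspace(-90, 20, 200)
        h_inf = wb_steady_states(v)["h_inf"]
        assert np.all(np.diff(h_inf) < 0)

    def test_rates_positive(self):
        v = np.linspace(-120, 60, 300)
        r = wb_rates(v, -12.0)
        for k, arr in r.items():
            assert np.all(arr > 0), k


class TestPassiveCable:
    def test_settles_at_e_leak(self, morphology):
        g = segmentize(morphology).passive()
        t, v = simulate(g, duration=200.0, v_init=-50.0)
        assert v[0][-1] == pytest.approx(-65.0, abs=0.01)

    def test_sealed_cable_attenuation_cosh(self):
        """Steady-state profile matches cosh((L-x)/lambda)/cosh(L/lambda)."""
        # uniform 500 µm, 1 µm cable; tiny soma of the same diameter
        sections = [
            Section(0, -1, 1.0, 1.0, REGION_SOMA, 0, 0, 1.0),
            Section(1, 0, 500.0, 1.0, REGION_ORIENS, 0, 0, 501.0),
        ]
        morph = Morphology(sections)
        params = CableParams(
            Rm_prox=10.0, Rm_dist=10.0, border=1e9,
            gNa_soma=0.0, gNa_dend_prox=0.0, gNa_dend_dist=0.0,
            gK_dend=0.0, gK_soma=0.0,
        )
        g = segmentize(morph, params, d_lambda=0.02)
        t, v = simulate(
            g, duration=2000.0, dt=0.1, i_inj=(0, 20.0),
            record=list(range(g.n_comp)),
        )
        v_ss = v[:, -1] - (-65.0)
        # lambda = sqrt(Rm * a / (2 Ra)), consistent cgs units
        lam_cm = np.sqrt(10.0e3 * (0.5e-4) / (2 * 170.0))
        lam_um = lam_cm * 1e4
        x = g.path_dist
        L = 501.0
        expected = np.cosh((L - x) / lam_um) / np.cosh(L / lam_um)
        profile = v_ss / v_ss[0]
        np.testing.assert_allclose(profile, expected, rtol=0.01)

    def test_input_resistance_isopotential_sphere(self):
        """Cylinder with area of a 20 µm sphere, Rm 10 -> ~796 MOhm."""
        morph = Morphology([Section(0, -1, 20.0, 20.0, REGION_SOMA, 0, 0, 20.0)])
        params = CableParams(Rm_prox=10.0, Rm_dist=10.0)
        rin = input_resistance(segmentize(morph, params))
        area_cm2 = np.pi * 20.0 * 20.0 * 1e-8
        expected = 10.0e3 / area_cm2 / 1e6  # MOhm
        assert rin == pytest.approx(expected, rel=1e-6)
        assert rin == pytest.approx(796.0, rel=0.01)

    def test_rin_increases_with_rm(self, morphology):
        g1 = segmentize(morphology, CableParams())
        g2 = segmentize(morphology, CableParams().scale_rm(2.0))
        assert input_resistance(g2) > input_resistance(g1)

    def test_rin_step_size_linearity(self, morphology):
        g = segmentize(morphology)
        a = input_resistance(g, i_step=-10.0)
        b = input_resistance(g, i_step=-5.0)
        assert b == pytest.approx(a, rel=0.005)


class TestCalibrateRm:
    def test_hits_target(self, morphology):
        params = calibrate_rm(segmentize(morphology), 78.0)
        rin = input_resistance(segmentize(morphology, params))
        assert rin == pytest.approx(78.0, abs=0.5)
        # 10x proximal/distal ratio preserved
        assert params.Rm_dist / params.Rm_prox == pytest.approx(10.0, rel=1e-12)

    def test_recalibration_fixed_point(self, morphology):
        p1 = calibrate_rm(segmentize(morphology), 78.0)
        p2 = calibrate_rm(segmentize(morphology, p1), 78.0)
        assert p2.Rm_prox == pytest.approx(p1.Rm_prox, rel=0.02)

    def test_larger_target_larger_multiplier(self, morphology):
        g = segmentize(morphology)
        p78 = calibrate_rm(g, 78.0)
        p120 = calibrate_rm(g, 120.0)
        assert p120.Rm_prox > p78.Rm_prox

    def test_unreachable_target(self, morphology):
        with pytest.raises(RuntimeError, match="bracket"):
            calibrate_rm(segmentize(morphology), 5000.0)


class TestActiveModel:
    def test_fast_spiking_phenotype(self, calibrated_graph):
        """Strong somatic current drives repetitive narrow spikes."""
        t, v = simulate(calibrated_graph, duration=400.0, i_inj=(0, 500.0))
        crossings = np.flatnonzero((v[0][1:] > 0) & (v[0][:-1] <= 0))
        assert len(crossings) > 20  # > 50 spikes/s
        # spike width at 0 mV well under 1 ms (fast-spiking)
        widths = []
        for c in crossings[1:10]:
            end = c + np.argmax(v[0][c:] < 0)
            widths.append((end - c) * 0.025)
        assert np.mean(widths) < 1.0

    def test_stable_rest(self, calibrated_graph):
        t, v = simulate(calibrated_graph, duration=300.0)
        assert np.all(np.abs(v[0][-1000:] - v[0][-1]) < 0.05)
        assert abs(v[0][-1] - (-65.0)) < 2.0

    def test_fine_dt_agreement(self, calibrated_graph):
        counts = []
        for dt in (0.025, 0.01):
            t, v = simulate(calibrated_graph, duration=300.0, dt=dt, i_inj=(0, 400.0))
            counts.append(int(np.sum((v[0][1:] > 0) & (v[0][:-1] <= 0))))
        assert counts[0] == pytest.approx(counts[1], abs=2)


class TestSiteSelection:
    def test_bounds_closed_interval(self, morphology):
        sites = site_selection(morphology, 40.0, 190.0)
        for sec, pos in sites:
            d = morphology.path_distance(sec, pos)
            assert 40.0 <= d <= 190.0

    def test_region_filter(self, morphology):
        for region in (REGION_ORIENS, REGION_RADIATUM):
            for sec, _ in site_selection(morphology, region=region):
                assert morphology.sections[sec].region == region

    def test_empty_range_reports_reachable(self, morphology):
        with pytest.raises(ValueError, match="reachable"):
            site_selection(morphology, 5000.0, 6000.0)


@pytest.fixture(scope="module")
def oriens_site(morphology):
    sites = site_selection(morphology, region=REGION_ORIENS)
    return min(sites, key=lambda s: abs(morphology.path_distance(*s) - 100.0))


class TestProtocol:
    def test_single_synapse_compound_equals_individual(
        self, calibrated_graph, oriens_site
    ):
        ts = uncaging_protocol(
            calibrated_graph, oriens_site, n_syn=1, g_ampa=0.3
        )
        np.testing.assert_allclose(ts.compound[0], ts.individual[0], atol=1e-12)

    def test_placement_within_spread(self, calibrated_graph, oriens_site):
        comps = place_synapses(calibrated_graph, oriens_site, 15, 30.0)
        assert len(comps) == 15
        # all placements are dendritic
        assert all(calibrated_graph.section_of[c] != 0 for c in comps)

    def test_unknown_condition(self, calibrated_graph, oriens_site):
        with pytest.raises(ValueError, match="condition"):
            uncaging_protocol(
                calibrated_graph, oriens_site, condition="bogus", g_ampa=0.3
            )

    def test_superposition_on_passive_tree(self, calibrated_graph, oriens_site):
        """Tiny conductances on the passive tree sum linearly (<1% NL)."""
        from coopnet.nonlinearity_metrics import nonlinearity_from_traceset

        passive = calibrated_graph.passive()
        ts = uncaging_protocol(
            passive, oriens_site, n_syn=5, condition="no_nmda", g_ampa=1e-4
        )
        nl = nonlinearity_from_traceset(ts, "integral", smoothing=False)
        assert abs(nl) < 1.0

    def test_rest_initialization_flat_baseline(self, calibrated_graph, oriens_site):
        ts = uncaging_protocol(calibrated_graph, oriens_site, n_syn=2, g_ampa=0.3)
        baseline = ts.individual[0][: int(ts.t0 / ts.dt)]
        assert np.abs(baseline).max() < 0.01
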