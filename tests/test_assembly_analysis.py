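import numpy as np
import pytest

from coopnet.assembly_analysis import (
    assembly_width,
    charge_per_spike,
    detect_flips,
    gamma_metrics,
    spike_ratio,
)
from coopnet.network_sim import CLASS_PV, CLASS_PYR, NetworkConfig, SimRecord
from coopnet.synthetic_data import RasterSegment, synth_raster


def _record_with(currents_value, n_pyr_spikes, duration=1000.0, record_dt=0.5):
    """Minimal single-network record with constant current traces."""
    cfg = NetworkConfig(duration=duration, record_dt=record_dt, seed=0)
    n_rec = int(duration / record_dt)
    flat = np.full((1, n_rec), float(currents_value))
    times = np.linspace(1.0, duration - 1.0, n_pyr_spikes)
    return SimRecord(
        config=cfg,
        spike_cells=np.zeros(n_pyr_spikes, dtype=np.int32),
        spike_times=times,
        spike_class=np.full(n_pyr_spikes, CLASS_PYR, dtype=np.int8),
        spike_sub=np.zeros(n_pyr_spikes, dtype=np.int8),
        t_rec=(np.arange(n_rec) + 1) * record_dt,
        v_pv=np.full((1, n_rec), -55.0),
        currents={k: flat.copy() for k in ("nmda", "ampa", "gaba", "ext")},
        I_total=4 * flat,
        drive_rates=flat.copy(),
    )


class TestChargePerSpike:
    def test_constant_current(self):
        """10 pA over 1000 ms with 100 spikes -> ~100 pA*ms per spike."""
        rec = _record_with(10.0, 100)
        got = charge_per_spike(rec, "nmda")
        assert got == pytest.approx(100.0, rel=0.01)

    def test_zero_current(self):
        rec = _record_with(0.0, 10)
        assert charge_per_spike(rec, "nmda") == 0.0

    def test_no_spikes_rejected(self):
        rec = _record_with(1.0, 0)
        with pytest.raises(ValueError, match="no pyramidal spikes"):
            charge_per_spike(rec, "nmda")

    def test_unknown_channel(self):
        rec = _record_with(1.0, 10)
        with pytest.raises(ValueError):
            charge_per_spike(rec, "gaba")

    def test_linearity_in_trace(self):
        rec = _record_with(5.0, 50)
        base = charge_per_spike(rec, "ampa")
        rec.currents["ampa"] *= 3.0
        assert charge_per_spike(rec, "ampa") == pytest.approx(3 * base, rel=1e-12)


def _dual_raster(schedule, **kw):
    return synth_raster(schedule, **kw)


class TestSpikeRatio:
    def test_equal_counts(self):
        rec = _dual_raster(
            [RasterSegment(0.0, 1000.0, 0, rate=1000.0, quiet_rate=1000.0)],
            seed=0,
        )
        assert spike_ratio(rec) == pytest.approx(1.0, abs=0.15)

    def test_pseudocount_on_silent_side(self):
        cfg = NetworkConfig(
            n_subnetworks=2, duration=1000.0,
            profile_modes=("clustered", "clustered"),
        )
        n = 100
        rec = SimRecord(
            config=cfg,
            spike_cells=np.zeros(n, dtype=np.int32),
            spike_times=np.linspace(0, 999, n),
            spike_class=np.full(n, CLASS_PYR, dtype=np.int8),
            spike_sub=np.zeros(n, dtype=np.int8),
            t_rec=np.arange(1, 3) * 0.5,
            v_pv=np.zeros((2, 2)),
            currents={k: np.zeros((2, 2)) for k in ("nmda", "ampa", "gaba", "ext")},
            I_total=np.zeros((2, 2)),
            drive_rates=np.zeros((2, 2)),
        )
        assert spike_ratio(rec) == pytest.approx(101.0)

    def test_requires_dual(self):
        rec = _record_with(1.0, 10)
        with pytest.raises(ValueError):
            spike_ratio(rec)


class TestDetectFlips:
    def test_constructed_single_flip(self):
        rec = _dual_raster(
            [RasterSegment(0.0, 1000.0, 0), RasterSegment(1000.0, 2000.0, 1)],
            seed=0,
        )
        fs = detect_flips(rec, window_ms=50.0, min_dwell=2)
        assert fs.n_flips == 1
        assert fs.flip_rate == pytest.approx(0.5)

    def test_constant_dominance_zero(self):
        rec = _dual_raster([RasterSegment(0.0, 2000.0, 1)], seed=1)
        assert detect_flips(rec).n_flips == 0

    def test_alternating_with_dwell_three(self):
        """ABAB... flicker with dwell 3 yields zero flips."""
        segs = [
            RasterSegment(k * 50.0, (k + 1) * 50.0, k % 2, rate=3000.0)
            for k in range(40)
        ]
        rec = _dual_raster(segs, seed=2)
        fs = detect_flips(rec, window_ms=50.0, min_dwell=3)
        assert fs.n_flips == 0

    def test_relabel_invariance(self):
        """Swapping subnetwork labels keeps the flip count."""
        rec = _dual_raster(
            [
                RasterSegment(0.0, 700.0, 0),
                RasterSegment(700.0, 1500.0, 1),
                RasterSegment(1500.0, 2500.0, 0),
            ],
            seed=3,
        )
        n0 = detect_flips(rec).n_flips
        swapped = SimRecord(
            config=rec.config,
            spike_cells=rec.spike_cells,
            spike_times=rec.spike_times,
            spike_class=rec.spike_class,
            spike_sub=(1 - rec.spike_sub).astype(np.int8),
            t_rec=rec.t_rec,
            v_pv=rec.v_pv,
            currents=rec.currents,
            I_total=rec.I_total,
            drive_rates=rec.drive_rates,
        )
        assert detect_flips(swapped).n_flips == n0

    def test_bad_args(self):
        rec = _dual_raster([RasterSegment(0.0, 500.0, 0)], seed=0)
        with pytest.raises(ValueError):
            detect_flips(rec, window_ms=0.0)
        with pytest.raises(ValueError):
            detect_flips(rec, min_dwell=0)


class TestGammaMetrics:
    def test_forty_hz_raster(self):
        rec = synth_raster([RasterSegment(0.0, 4000.0, 0)], gamma_f=40.0, seed=4)
        freq, _ = gamma_metrics(rec)
        assert freq == pytest.approx(40.0, abs=0.5)

    def test_locking_one_when_pv_every_cycle(self):
        rec = synth_raster([RasterSegment(0.0, 3000.0, 0)], gamma_f=50.0, seed=5)
        _, locking = gamma_metrics(rec)
        assert locking >= 0.9

    def test_silent_interneuron_zero_locking(self):
        rec = synth_raster([RasterSegment(0.0, 3000.0, 0)], gamma_f=50.0, seed=6)
        rec.spike_class = np.where(
            rec.spike_class == CLASS_PV, CLASS_PV, rec.spike_class
        )
        keep = rec.spike_class == CLASS_PYR
        rec.spike_cells = rec.spike_cells[keep]
        rec.spike_times = rec.spike_times[keep]
        rec.spike_sub = rec.spike_sub[keep]
        rec.spike_class = rec.spike_class[keep]
        _, locking = gamma_metrics(rec)
        assert locking == 0.0

    def test_short_record_rejected(self):
        rec = _record_with(1.0, 10, duration=500.0)
        with pytest.raises(ValueError, match="1 s"):
            gamma_metrics(rec)


class TestAssemblyWidth:
    def _single_sub_record(self, cells, times, duration=2000.0):
        cfg = NetworkConfig(duration=duration, seed=0)
        n = len(times)
        order = np.argsort(times)
        n_rec = int(duration / cfg.record_dt)
        z = np.zeros((1, n_rec))
        return SimRecord(
            config=cfg,
            spike_cells=np.asarray(cells, dtype=np.int32)[order],
            spike_times=np.asarray(times, dtype=float)[order],
            spike_class=np.full(n, CLASS_PYR, dtype=np.int8),
            spike_sub=np.zeros(n, dtype=np.int8),
            t_rec=(np.arange(n_rec) + 1) * cfg.record_dt,
            v_pv=z.copy(),
            currents={k: z.copy() for k in ("nmda", "ampa", "gaba", "ext")},
            I_total=z.copy(),
            drive_rates=z.copy(),
        )

    def test_single_cell_zero_width(self):
        # gamma-like bursts from one cell only
        times = np.concatenate(
            [np.full(5, 12.5 + 25.0 * k) + np.arange(5) * 0.3 for k in range(80)]
        )
        rec = self._single_sub_record(np.zeros(times.size), times)
        _, widths = assembly_width(rec)
        assert np.all(widths == 0.0)

    def test_uniform_spiking_width(self):
        """Uniform cell participation gives SD ~ sqrt((n^2 - 1)/12)."""
        rng = np.random.default_rng(0)
        times, cells = [], []
        for k in range(80):
            t = 12.5 + 25.0 * k
            c = rng.integers(0, 250, 40)
            times.extend(t + rng.uniform(-3, 3, 40))
            cells.extend(c)
        rec = self._single_sub_record(cells, times)
        _, widths = assembly_width(rec)
        expected = np.sqrt((250.0**2 - 1) / 12.0)
        assert np.mean(widths) == pytest.approx(expected, rel=0.05)
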