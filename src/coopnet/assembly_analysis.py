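"""Metrics over simulation records.

Implements the simulation readouts: NMDA/AMPA charge per principal
spike, winner spike ratio between competing subnetworks, windowed
dominance and flip-rate detection, gamma-rhythm metrics, and per-cycle
assembly width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, welch

from .network_sim import NetworkConfig, SimRecord, run_competing_networks

__all__ = [
    "FlipSeries",
    "charge_per_spike",
    "spike_ratio",
    "detect_flips",
    "flip_rate_sweep",
    "gamma_metrics",
    "assembly_width",
]

DEFAULT_FLIP_WINDOW_MS = 50.0
DEFAULT_MIN_DWELL = 2


@dataclass
class FlipSeries:
    """Windowed dominance labels and the dwell-filtered flips they imply."""

    labels: np.ndarray        # subnetwork id per window (-1 = undecided)
    flip_times: np.ndarray    # ms, start of the window establishing the flip
    flip_rate: float          # flips/s
    window_ms: float
    min_dwell: int

    @property
    def n_flips(self) -> int:
        return self.flip_times.size


def charge_per_spike(record: SimRecord, channel: str) -> float:
    """Time-integral of an interneuron current divided by pyramidal spikes.

    ``channel`` is ``"nmda"`` or ``"ampa"`` (the feedback components).
    Returns pA*ms per principal-cell spike, summed over interneurons.
    """
    if channel not in ("nmda", "ampa"):
        raise ValueError(f"channel must be 'nmda' or 'ampa', got {channel!r}")
    n_spikes = record.pyr_spike_times().size
    if n_spikes == 0:
        raise ValueError("charge per spike is undefined: no pyramidal spikes")
    I = record.currents[channel]  # (n_sub, n_rec)
    dt = record.config.record_dt
    total = float(np.sum(np.trapezoid(I, dx=dt, axis=1)))
    return total / n_spikes


def spike_ratio(record: SimRecord) -> float:
    """(count_A + 1) / (count_B + 1) over pyramidal spikes.

    The pseudocount of 1 on each side keeps the ratio finite when a
    subnetwork is silent.
    """
    if record.config.n_subnetworks != 2:
        raise ValueError("spike_ratio requires a dual-network record")
    n_a = record.pyr_spike_times(sub=0).size
    n_b = record.pyr_spike_times(sub=1).size
    return (n_a + 1.0) / (n_b + 1.0)


def _window_labels(
    record: SimRecord, window_ms: float
) -> np.ndarray:
    duration = record.config.duration
    n_win = int(duration // window_ms)
    edges = np.arange(n_win + 1) * window_ms
    counts = np.empty((2, n_win))
    for s in (0, 1):
        t = record.pyr_spike_times(sub=s)
        counts[s], _ = np.histogram(t, bins=edges)
    labels = np.full(n_win, -1, dtype=np.int64)
    prev = -1
    for w in range(n_win):
        if counts[0, w] > counts[1, w]:
            prev = 0
        elif counts[1, w] > counts[0, w]:
            prev = 1
        labels[w] = prev  # ties (incl. silence) keep the previous label
    return labels


def detect_flips(
    record: SimRecord,
    window_ms: float = DEFAULT_FLIP_WINDOW_MS,
    min_dwell: int = DEFAULT_MIN_DWELL,
) -> FlipSeries:
    """Dominance flips between subnetworks from windowed spike counts.

    Dominance per window is the subnetwork with more pyramidal spikes
    (ties keep the previous label). A change of label counts as a flip
    only if the new label persists for at least ``min_dwell`` consecutive
    windows.
    """
    if record.config.n_subnetworks != 2:
        raise ValueError("detect_flips requires a dual-network record")
    if window_ms <= 0 or min_dwell < 1:
        raise ValueError("window_ms must be > 0 and min_dwell >= 1")
    labels = _window_labels(record, window_ms)

    # run-length encode, ignoring the undecided prefix
    flips: list[float] = []
    current = -1
    w = 0
    n_win = labels.size
    while w < n_win:
        lab = labels[w]
        run = w
        while run < n_win and labels[run] == lab:
            run += 1
        run_len = run - w
        if lab >= 0 and lab != current and run_len >= min_dwell:
            if current >= 0:
                flips.append(w * window_ms)
            current = lab
        w = run
    duration_s = record.config.duration / 1000.0
    return FlipSeries(
        labels=labels,
        flip_times=np.asarray(flips),
        flip_rate=len(flips) / duration_s,
        window_ms=window_ms,
        min_dwell=min_dwell,
    )


def flip_rate_sweep(
    base_config: NetworkConfig,
    nmdar_scales,
    ampar_scales,
    n_seeds: int = 3,
    window_ms: float = DEFAULT_FLIP_WINDOW_MS,
    min_dwell: int = DEFAULT_MIN_DWELL,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean flip rate over a (nmdar_scale x ampar_scale) grid.

    Runs ``run_competing_networks`` per grid cell per seed. Returns
    (mean_rates, sd_rates), each of shape (len(nmdar), len(ampar)).
    """
    nmdar_scales = np.asarray(nmdar_scales, dtype=float)
    ampar_scales = np.asarray(ampar_scales, dtype=float)
    if np.any(nmdar_scales <= 0) or np.any(nmdar_scales > 2) or np.any(
        ampar_scales <= 0
    ) or np.any(ampar_scales > 2):
        raise ValueError("scales must lie in (0, 2]")
    if n_seeds < 3:
        raise ValueError("n_seeds must be >= 3")
    mean = np.empty((nmdar_scales.size, ampar_scales.size))
    sd = np.empty_like(mean)
    for i, ns in enumerate(nmdar_scales):
        for j, asc in enumerate(ampar_scales):
            rates = []
            for k in range(n_seeds):
                cfg = base_config.with_overrides(
                    seed=base_config.seed + k,
                    gains=base_config.gains.with_overrides(
                        nmdar_scale=float(ns), ampar_scale=float(asc)
                    ),
                )
                try:
                    rec = run_competing_networks(cfg)
                except RuntimeError as exc:
                    raise RuntimeError(
                        f"simulation failed at grid cell (nmdar={ns}, "
                        f"ampar={asc}), seed {cfg.seed}"
                    ) from exc
                rates.append(detect_flips(rec, window_ms, min_dwell).flip_rate)
            mean[i, j] = np.mean(rates)
            sd[i, j] = np.std(rates)
    return mean, sd


def _population_rate(record: SimRecord, bin_ms: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    duration = record.config.duration
    edges = np.arange(0.0, duration + bin_ms, bin_ms)
    counts, _ = np.histogram(record.pyr_spike_times(), bins=edges)
    return edges[:-1], counts.astype(float)


def gamma_metrics(
    record: SimRecord,
    band: tuple[float, float] = (10.0, 200.0),
    bin_ms: float = 1.0,
) -> tuple[float | None, float]:
    """Population rhythm frequency and interneuron cycle-locking fraction.

    Frequency is the dominant peak of the mean-subtracted population-rate
    periodogram within ``band``; ``None`` if no peak rises above the
    spectral noise floor (median power). Locking is the fraction of
    population cycles containing at least one interneuron spike.
    """
    if record.config.duration < 1000.0:
        raise ValueError("gamma metrics need at least 1 s of data")
    t, rate = _population_rate(record, bin_ms)
    if rate.sum() == 0:
        return None, 0.0
    fs = 1000.0 / bin_ms
    x = rate - rate.mean()
    nperseg = min(1024, x.size)
    f, p = welch(x, fs=fs, nperseg=nperseg)
    # light smoothing favours the broad population-rhythm bump over
    # narrow noise lines
    p = np.convolve(p, np.ones(3) / 3.0, mode="same")
    in_band = (f >= band[0]) & (f <= band[1])
    if not np.any(in_band) or np.all(p[in_band] == 0):
        return None, 0.0
    peak_idx = np.argmax(p[in_band])
    peak_power = p[in_band][peak_idx]
    noise_floor = float(np.median(p[in_band]))
    if noise_floor > 0 and peak_power < 2.0 * noise_floor:
        freq = None
    else:
        freq = float(f[in_band][peak_idx])

    # cycles: peaks of the smoothed population rate
    if freq is None:
        return None, 0.0
    period_bins = max(1, int(round(1000.0 / freq / bin_ms)))
    kernel = np.ones(max(1, period_bins // 4))
    smooth = np.convolve(rate, kernel / kernel.size, mode="same")
    peaks, _ = find_peaks(smooth, distance=max(1, int(0.7 * period_bins)))
    if peaks.size < 2:
        return freq, 0.0
    # cycle boundaries at midpoints between consecutive peaks
    bounds = np.concatenate(
        ([0.0], (t[peaks[:-1]] + t[peaks[1:]]) / 2.0, [record.config.duration])
    )
    pv_times = np.concatenate(
        [record.pv_spike_times(s) for s in range(record.config.n_subnetworks)]
    )
    occupied, _ = np.histogram(pv_times, bins=bounds)
    locking = float(np.mean(occupied > 0))
    return freq, locking


def assembly_width(
    record: SimRecord,
    bin_ms: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cycle dispersion of the active-cell index distribution.

    Returns (cycle_start_times, widths) where each width is the
    spike-count-weighted standard deviation of spiking cell indices
    within one population cycle; cycles with no pyramidal spikes are
    skipped.
    """
    if record.config.n_subnetworks != 1:
        raise ValueError("assembly_width expects a single-network record")
    freq, _ = gamma_metrics(record, bin_ms=bin_ms)
    if freq is None:
        raise ValueError("no population rhythm detected")
    t, rate = _population_rate(record, bin_ms)
    period_bins = max(1, int(round(1000.0 / freq / bin_ms)))
    kernel = np.ones(max(1, period_bins // 4))
    smooth = np.convolve(rate, kernel / kernel.size, mode="same")
    peaks, _ = find_peaks(smooth, distance=max(1, int(0.7 * period_bins)))
    bounds = np.concatenate(
        ([0.0], (t[peaks[:-1]] + t[peaks[1:]]) / 2.0, [record.config.duration])
        if peaks.size >= 2
        else ([0.0], [record.config.duration])
    )
    times = record.pyr_spike_times()
    cells = record.pyr_spike_cells()
    starts, widths = [], []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        sel = (times >= lo) & (times < hi)
        if not np.any(sel):
            continue
        idx = cells[sel].astype(float)
        widths.append(float(np.std(idx)))
        starts.append(float(lo))
    return np.asarray(starts), np.asarray(widths)
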