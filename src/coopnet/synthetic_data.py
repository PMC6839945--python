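"""Ground-truth-known fixture generators.

Every generator is deterministic given its seed and returns the exact
ground-truth quantities alongside the data, so tests never re-derive
them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .external_drive import OUParams, ou_path
from .network_sim import CLASS_PV, CLASS_PYR, NetworkConfig, SimRecord
from .nonlinearity_metrics import TraceSet
from .synapse_kernels import BiExpParams, biexp_impulse_response

__all__ = [
    "synth_uepsp_set",
    "synth_raster",
    "synth_ou_stream",
]


def synth_uepsp_set(
    n_sites: int,
    kinetics: BiExpParams = BiExpParams(1.0, 12.0),
    amplitudes: np.ndarray | float = 0.5,
    gain_profile: np.ndarray | float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    dt: float = 0.05,
    t0: float = 20.0,
    duration: float = 120.0,
    inter_site_shift: float = 1.0,
) -> tuple[TraceSet, float]:
    """Noisy uncaging-style trace set with known nonlinearity.

    Individual traces are bi-exponential EPSP kernels scaled to the given
    peak amplitudes (mV). Compound trace i is ``gain_profile[i] x`` the
    arithmetic sum of traces 1..i with the inter-site shift, plus noise.
    Returns (traceset, ground_truth_percent) where the ground truth is
    ``100 * mean(gain_profile[1:] - 1)`` — exact when noise_sd = 0.

    Constant-ratio profiles (e.g. all 1.24) therefore produce exactly
    24.0% through the full pipeline.
    """
    if n_sites < 2:
        raise ValueError("n_sites must be >= 2")
    rng = np.random.default_rng(seed)
    amplitudes = np.broadcast_to(np.asarray(amplitudes, dtype=float), (n_sites,))
    gains = np.broadcast_to(np.asarray(gain_profile, dtype=float), (n_sites,))
    n_samples = int(round(duration / dt))
    t = np.arange(n_samples) * dt

    kernel = biexp_impulse_response(kinetics, np.clip(t - t0, 0.0, None))
    kernel[t < t0] = 0.0
    kernel = kernel / kernel.max()

    individual = amplitudes[:, None] * kernel[None, :]
    shift_samples = int(round(inter_site_shift / dt))
    compound = np.zeros_like(individual)
    acc = np.zeros(n_samples)
    for k in range(n_sites):
        shifted = np.zeros(n_samples)
        off = k * shift_samples
        if off < n_samples:
            shifted[off:] = individual[k, : n_samples - off]
        acc = acc + shifted
        compound[k] = gains[k] * acc
    if noise_sd > 0:
        individual = individual + rng.normal(0.0, noise_sd, individual.shape)
        compound = compound + rng.normal(0.0, noise_sd, compound.shape)
    ts = TraceSet(
        dt=dt, individual=individual, compound=compound,
        t0=t0, inter_site_shift=inter_site_shift,
    )
    truth = float(100.0 * np.mean(gains[1:] - 1.0))
    return ts, truth


@dataclass(frozen=True)
class RasterSegment:
    """One epoch of a dominance schedule: [t_start, t_end) ms."""

    t_start: float
    t_end: float
    dominant: int            # subnetwork index carrying the bursts
    rate: float = 2000.0     # population spikes/s in the dominant subnetwork
    quiet_rate: float = 0.0  # population spikes/s in the other subnetwork


def synth_raster(
    schedule: list[RasterSegment],
    gamma_f: float = 40.0,
    n_pyr: int = 250,
    center: int = 125,
    width: float = 10.0,
    seed: int = 0,
) -> SimRecord:
    """SimRecord-shaped spike data with a known dominance schedule.

    Pyramidal spikes arrive in gamma-locked bursts (rectangular windows of
    a quarter period around each cycle peak) with cell indices drawn from
    a Gaussian around ``center``; one interneuron spike accompanies each
    burst of the dominant subnetwork. Dominance and flip times are known
    by construction.
    """
    if not schedule:
        raise ValueError("schedule must not be empty")
    schedule = sorted(schedule, key=lambda s: s.t_start)
    for a, b in zip(schedule[:-1], schedule[1:]):
        if b.t_start < a.t_end:
            raise ValueError(
                f"overlapping schedule segments at {b.t_start} ms"
            )
    rng = np.random.default_rng(seed)
    duration = schedule[-1].t_end
    period = 1000.0 / gamma_f
    cells, times, classes, subs = [], [], [], []
    for seg in schedule:
        n_cycles = int((seg.t_end - seg.t_start) / period)
        for c in range(n_cycles):
            t_peak = seg.t_start + (c + 0.5) * period
            for sub, rate in ((seg.dominant, seg.rate),
                              (1 - seg.dominant, seg.quiet_rate)):
                n = rng.poisson(rate * period / 1000.0)
                if n == 0:
                    continue
                burst = t_peak + rng.uniform(-period / 8, period / 8, n)
                idx = np.clip(
                    np.round(rng.normal(center, width, n)), 0, n_pyr - 1
                ).astype(int)
                cells.extend(sub * n_pyr + idx)
                times.extend(burst)
                classes.extend([CLASS_PYR] * n)
                subs.extend([sub] * n)
            # interneuron fires once per cycle of the dominant subnetwork
            cells.append(2 * n_pyr + seg.dominant)
            times.append(t_peak)
            classes.append(CLASS_PV)
            subs.append(seg.dominant)

    order = np.argsort(times)
    config = NetworkConfig(
        n_pyr=n_pyr, n_subnetworks=2, duration=duration, seed=seed,
        profile_modes=("clustered", "clustered"),
    )
    n_rec = int(duration / config.record_dt)
    empty = np.zeros((2, n_rec))
    return SimRecord(
        config=config,
        spike_cells=np.asarray(cells, dtype=np.int32)[order],
        spike_times=np.asarray(times, dtype=float)[order],
        spike_class=np.asarray(classes, dtype=np.int8)[order],
        spike_sub=np.asarray(subs, dtype=np.int8)[order],
        t_rec=(np.arange(n_rec) + 1) * config.record_dt,
        v_pv=empty.copy(),
        currents={k: empty.copy() for k in ("nmda", "ampa", "gaba", "ext")},
        I_total=empty.copy(),
        drive_rates=empty.copy(),
    )


def synth_ou_stream(
    params: OUParams,
    T: float,
    dt: float,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """OU rate path plus its exact generation moments.

    Returns (path, moments) with moments holding the stationary mean, SD
    and correlation time used to generate the path.
    """
    path = ou_path(params, dt, T, np.random.default_rng(seed))
    moments = {
        "mean": params.mu,
        "sd": params.stationary_cv * params.mu,
        "tau": params.tau,
    }
    return path, moments
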