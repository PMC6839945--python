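"""Full network assembly and integration.

A network is ``n_pyr`` pyramidal cells reciprocally connected to a single
fast-spiking interneuron; the competing configuration is two such
subnetworks whose interneurons inhibit both pyramidal populations and
both interneurons (autapses included). Every pyramidal spike injects one
impulse into its AMPA and NMDA feedback kernels onto its own
interneuron; GABA is global across subnetworks with a configurable
cross-weight.

Step order per dt: external impulses and kernel decay -> conductances ->
lagged NMDA gates -> patch voltages -> applied currents -> Izhikevich
updates and resets.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np

from . import _core
from .cooperative_nmda import CooperativityParams, GainTable, build_distance_matrix
from .external_drive import (
    OUParams,
    ou_path,
    poisson_spikes,
    receptive_field_gains,
    theta_modulate,
)
from .point_neuron import IzhikevichParams, fs_pv_params, pyramidal_params
from .synapse_kernels import (
    AMPA_ONTO_PV,
    AMPA_ONTO_PYR,
    GABA_ONTO_PV,
    GABA_ONTO_PYR,
    NMDA_ONTO_PV,
)

__all__ = [
    "NetworkConfig",
    "SimRecord",
    "run_single_network",
    "run_competing_networks",
    "calibrate_operating_point",
    "DEFAULT_DRIVE_SCALE",
]

logger = logging.getLogger(__name__)

#: drive-intensity multiplier found by :func:`calibrate_operating_point`
#: on the default single-network configuration (sparse gamma regime).
DEFAULT_DRIVE_SCALE = 3.0

CLASS_PYR = 0
CLASS_PV = 1


@dataclass(frozen=True)
class NetworkConfig:
    """Everything needed to reproduce one simulation."""

    n_pyr: int = 250
    n_subnetworks: int = 1
    dt: float = 0.05              # ms
    duration: float = 2000.0      # ms
    seed: int = 0
    drive_scale: float = DEFAULT_DRIVE_SCALE
    ou: OUParams = field(default_factory=OUParams)
    #: receptive-field mode per subnetwork ("clustered" | "dispersed")
    profile_modes: tuple[str, ...] = ("clustered",)
    #: receptive-field hump center/width; None -> n_pyr/2 and n_pyr/10
    #: (cell 125 and 25 cells at the published population size)
    profile_center: int | None = None
    profile_width: float | None = None
    theta_f: float = 8.0          # Hz
    theta_depth: float = 0.0      # 0 disables theta modulation
    gains: GainTable = field(default_factory=GainTable)
    coop: CooperativityParams | None = None
    cross_gaba_weight: float = 2.0
    #: give every subnetwork the same drive realization (symmetry checks)
    symmetrize_drive: bool = False
    record_dt: float = 0.5        # ms, trace decimation
    record_patch: bool = False
    record_patch_dt: float = 1.0  # ms

    def __post_init__(self) -> None:
        if self.n_pyr < 2:
            raise ValueError("n_pyr must be >= 2")
        if self.n_subnetworks not in (1, 2):
            raise ValueError("n_subnetworks must be 1 or 2")
        if not self.duration >= self.dt > 0:
            raise ValueError("need duration >= dt > 0")
        if len(self.profile_modes) != self.n_subnetworks:
            raise ValueError("profile_modes must have one entry per subnetwork")
        if self.coop is None:
            object.__setattr__(self, "coop", CooperativityParams(n_pyr=self.n_pyr))
        elif self.coop.n_pyr != self.n_pyr:
            raise ValueError("coop.n_pyr must equal n_pyr")
        if self.profile_center is None:
            object.__setattr__(self, "profile_center", self.n_pyr // 2)
        if self.profile_width is None:
            object.__setattr__(self, "profile_width", self.n_pyr / 10.0)

    def with_overrides(self, **kwargs) -> "NetworkConfig":
        return replace(self, **kwargs)

    def digest(self) -> str:
        """Short hash of the full configuration, for logging."""
        return hashlib.sha256(repr(self).encode()).hexdigest()[:12]


@dataclass
class SimRecord:
    """Everything recorded from one simulation.

    Spikes are never decimated; voltage/current traces are sampled every
    ``config.record_dt`` ms at times ``t_rec``. ``currents`` maps channel
    name (nmda, ampa, gaba, ext) to an (n_subnetworks, n_rec) array of
    interneuron currents (pA).
    """

    config: NetworkConfig
    spike_cells: np.ndarray      # global cell index
    spike_times: np.ndarray      # ms
    spike_class: np.ndarray      # CLASS_PYR | CLASS_PV
    spike_sub: np.ndarray        # subnetwork index
    t_rec: np.ndarray
    v_pv: np.ndarray             # (n_sub, n_rec) mV
    currents: dict[str, np.ndarray]
    I_total: np.ndarray          # (n_sub, n_rec) pA
    drive_rates: np.ndarray      # (n_sub, n_rec) spikes/s (OU path, decimated)
    patch_v: np.ndarray | None = None   # (n_patch_rec, n_sub*n_pyr) mV
    t_patch: np.ndarray | None = None

    # -- convenience selectors ---------------------------------------
    def pyr_spike_times(self, sub: int | None = None) -> np.ndarray:
        m = self.spike_class == CLASS_PYR
        if sub is not None:
            m &= self.spike_sub == sub
        return self.spike_times[m]

    def pyr_spike_cells(self, sub: int | None = None) -> np.ndarray:
        m = self.spike_class == CLASS_PYR
        if sub is not None:
            m &= self.spike_sub == sub
        return self.spike_cells[m] - (
            self.spike_sub[m].astype(np.int64) * self.config.n_pyr
        )

    def pv_spike_times(self, sub: int = 0) -> np.ndarray:
        m = (self.spike_class == CLASS_PV) & (self.spike_sub == sub)
        return self.spike_times[m]

    def spikes_to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "cell": self.spike_cells,
                "time_ms": self.spike_times,
                "cell_class": self.spike_class,
                "subnetwork": self.spike_sub,
            }
        )

    def save(self, path) -> None:
        """Write to an HDF5 container (spikes, currents, traces, config)."""
        import h5py
        import yaml

        from .config import config_to_dict

        with h5py.File(path, "w") as f:
            f.create_dataset("spikes/cell", data=self.spike_cells)
            f.create_dataset("spikes/time", data=self.spike_times)
            f.create_dataset("spikes/class", data=self.spike_class)
            f.create_dataset("spikes/subnetwork", data=self.spike_sub)
            f.create_dataset("t_rec", data=self.t_rec)
            f.create_dataset("v_pv", data=self.v_pv)
            for name, arr in self.currents.items():
                f.create_dataset(f"currents/{name}", data=arr)
            f.create_dataset("I_total", data=self.I_total)
            f.create_dataset("drive_rates", data=self.drive_rates)
            if self.patch_v is not None:
                f.create_dataset("patch_v", data=self.patch_v)
                f.create_dataset("t_patch", data=self.t_patch)
            f.attrs["config"] = yaml.safe_dump(config_to_dict(self.config))

    @classmethod
    def load(cls, path) -> "SimRecord":
        import h5py
        import yaml

        from .config import config_from_dict

        with h5py.File(path, "r") as f:
            cfg = config_from_dict(yaml.safe_load(f.attrs["config"]))
            return cls(
                config=cfg,
                spike_cells=f["spikes/cell"][:],
                spike_times=f["spikes/time"][:],
                spike_class=f["spikes/class"][:],
                spike_sub=f["spikes/subnetwork"][:],
                t_rec=f["t_rec"][:],
                v_pv=f["v_pv"][:],
                currents={k: f[f"currents/{k}"][:] for k in f["currents"]},
                I_total=f["I_total"][:],
                drive_rates=f["drive_rates"][:],
                patch_v=f["patch_v"][:] if "patch_v" in f else None,
                t_patch=f["t_patch"][:] if "t_patch" in f else None,
            )


def _izh_vector(p: IzhikevichParams) -> np.ndarray:
    return np.array(
        [p.Cm, p.k_low, p.k_high, p.vr, p.vt, p.vpeak, p.a, p.b, p.c, p.d]
    )


def _generate_drive(
    config: NetworkConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell external spike counts and the per-subnetwork OU rate paths.

    Seed streams: the master seed spawns three independent child streams
    per subnetwork (OU path, Poisson draws, dispersed permutation), in
    that order, so subnetworks and conditions never share randomness.
    """
    n_steps = int(round(config.duration / config.dt))
    n_sub, n_pyr = config.n_subnetworks, config.n_pyr
    children = np.random.SeedSequence(config.seed).spawn(3 * n_sub)
    counts = np.empty((n_sub * n_pyr, n_steps), dtype=np.int16)
    ou_paths = np.empty((n_sub, n_steps))
    for s in range(n_sub):
        s_eff = 0 if config.symmetrize_drive else s
        ou_rng, pois_rng, perm_rng = (
            np.random.default_rng(children[3 * s_eff + k]) for k in range(3)
        )
        rate = ou_path(config.ou, config.dt, config.duration, ou_rng)
        if config.theta_depth > 0:
            rate = theta_modulate(rate, config.theta_f, config.theta_depth, config.dt)
        ou_paths[s] = rate
        profile = receptive_field_gains(
            n_pyr,
            config.profile_center,
            config.profile_width,
            config.profile_modes[s],
            perm_rng,
        )
        scale = config.drive_scale
        # chunked Poisson draws to bound peak memory
        block = 20000
        for lo in range(0, n_steps, block):
            hi = min(lo + block, n_steps)
            rates = profile.gains[:, None] * rate[None, lo:hi] * scale
            counts[s * n_pyr : (s + 1) * n_pyr, lo:hi] = poisson_spikes(
                rates, config.dt, pois_rng
            ).astype(np.int16)
    return counts, ou_paths


def _run(config: NetworkConfig) -> SimRecord:
    t_wall = time.perf_counter()
    n_steps = int(round(config.duration / config.dt))
    n_sub, n_pyr = config.n_subnetworks, config.n_pyr
    counts, ou_paths = _generate_drive(config)
    D = build_distance_matrix(n_pyr, config.coop.sigma_D)
    rec_stride = max(1, int(round(config.record_dt / config.dt)))
    patch_stride = (
        max(1, int(round(config.record_patch_dt / config.dt)))
        if config.record_patch
        else 0
    )
    # generous bound: 600 spikes/s per cell
    max_spikes = int((n_sub * (n_pyr + 1)) * max(config.duration, 1000.0) * 0.6)
    g = config.gains

    out = _core.simulate_network(
        n_sub,
        n_pyr,
        n_steps,
        config.dt,
        counts,
        D,
        _izh_vector(pyramidal_params()),
        _izh_vector(fs_pv_params()),
        np.array([AMPA_ONTO_PYR.tau1, AMPA_ONTO_PYR.tau2]),
        np.array([AMPA_ONTO_PV.tau1, AMPA_ONTO_PV.tau2]),
        np.array([NMDA_ONTO_PV.tau1, NMDA_ONTO_PV.tau2]),
        np.array([GABA_ONTO_PYR.tau1, GABA_ONTO_PYR.tau2]),
        np.array([GABA_ONTO_PV.tau1, GABA_ONTO_PV.tau2]),
        g.k_pv_ampa * g.ampar_scale,
        g.k_pv_nmda * g.nmdar_scale,
        g.k_pv_gaba,
        g.k_pv_ext,
        g.k_pyr_gaba,
        g.k_pyr_ext,
        config.coop.k_syn,
        config.coop.C_syn,
        config.coop.g_leak,
        config.coop.e_leak,
        config.coop.e_glu,
        config.coop.e_GABA,
        config.coop.gate_at_sender,
        config.cross_gaba_weight,
        rec_stride,
        patch_stride,
        max_spikes,
    )
    (spike_cell, spike_time, v_pv_rec, I_rec, I_tot_rec, patch_rec, err_step) = out
    if err_step >= 0:
        raise RuntimeError(
            f"non-finite membrane state at t = {err_step * config.dt:.3f} ms "
            f"(config {config.digest()})"
        )

    is_pv = spike_cell >= n_sub * n_pyr
    spike_class = np.where(is_pv, CLASS_PV, CLASS_PYR).astype(np.int8)
    spike_sub = np.where(
        is_pv, spike_cell - n_sub * n_pyr, spike_cell // n_pyr
    ).astype(np.int8)
    n_rec = n_steps // rec_stride
    t_rec = (np.arange(n_rec) + 1) * rec_stride * config.dt
    drive_rates = ou_paths[:, rec_stride - 1 :: rec_stride][:, :n_rec]

    record = SimRecord(
        config=config,
        spike_cells=spike_cell,
        spike_times=spike_time,
        spike_class=spike_class,
        spike_sub=spike_sub,
        t_rec=t_rec,
        v_pv=v_pv_rec,
        currents={
            "nmda": I_rec[:, 0], "ampa": I_rec[:, 1],
            "gaba": I_rec[:, 2], "ext": I_rec[:, 3],
        },
        I_total=I_tot_rec,
        drive_rates=drive_rates,
        patch_v=patch_rec if config.record_patch else None,
        t_patch=(
            (np.arange(patch_rec.shape[0]) + 1) * patch_stride * config.dt
            if config.record_patch
            else None
        ),
    )
    logger.info(
        "simulated %s ms (%d subnetwork(s), seed %d, config %s) in %.2f s: "
        "%d spikes",
        config.duration, n_sub, config.seed, config.digest(),
        time.perf_counter() - t_wall, spike_cell.size,
    )
    return record


def run_single_network(config: NetworkConfig) -> SimRecord:
    """Simulate one pyramidal population with its interneuron."""
    if config.n_subnetworks != 1:
        raise ValueError("run_single_network requires n_subnetworks == 1")
    return _run(config)


def run_competing_networks(config: NetworkConfig) -> SimRecord:
    """Simulate two mutually inhibiting subnetworks with independent drive."""
    if config.n_subnetworks != 2:
        raise ValueError("run_competing_networks requires n_subnetworks == 2")
    return _run(config)


def calibrate_operating_point(
    config: NetworkConfig,
    target_rate: float = 8.0,
    rate_band: tuple[float, float] = (1.0, 20.0),
    freq_band: tuple[float, float] = (30.0, 100.0),
    min_locking: float = 0.8,
    bracket: tuple[float, float] = (0.05, 50.0),
    tol: float = 0.05,
    max_iter: int = 30,
) -> tuple[float, dict]:
    """Bisection over the drive multiplier to reach the sparse-gamma regime.

    Searches ``drive_scale`` until the mean pyramidal rate is within
    ``tol`` (relative) of ``target_rate``, then verifies the population
    rhythm frequency, rate band and interneuron cycle-locking. Returns the
    multiplier and the achieved metrics.
    """
    from .assembly_analysis import gamma_metrics

    def metrics_at(scale: float) -> dict:
        rec = _run(config.with_overrides(drive_scale=scale, n_subnetworks=1,
                                         profile_modes=("clustered",)))
        n_spk = rec.pyr_spike_times().size
        rate = n_spk / config.n_pyr / (config.duration / 1000.0)
        freq, locking = gamma_metrics(rec)
        return {"rate": rate, "freq": freq, "locking": locking, "scale": scale}

    lo, hi = bracket
    m_lo, m_hi = metrics_at(lo), metrics_at(hi)
    if m_lo["rate"] > target_rate or m_hi["rate"] < target_rate:
        raise RuntimeError(
            "drive bracket does not straddle the target rate: "
            f"rate({lo})={m_lo['rate']:.2f}, rate({hi})={m_hi['rate']:.2f}"
        )
    m_mid = m_hi
    for _ in range(max_iter):
        mid = np.sqrt(lo * hi)  # geometric bisection: rate spans decades
        m_mid = metrics_at(mid)
        if abs(m_mid["rate"] - target_rate) <= tol * target_rate:
            break
        if m_mid["rate"] < target_rate:
            lo = mid
        else:
            hi = mid
    ok = (
        rate_band[0] <= m_mid["rate"] <= rate_band[1]
        and m_mid["freq"] is not None
        and freq_band[0] <= m_mid["freq"] <= freq_band[1]
        and m_mid["locking"] >= min_locking
    )
    if not ok:
        raise RuntimeError(f"no operating point found; last metrics: {m_mid}")
    return m_mid["scale"], m_mid
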