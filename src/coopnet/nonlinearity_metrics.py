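"""Dendritic-integration nonlinearity quantification.

Given a set of individual site responses and measured compound responses
to cumulative activation of sites 1..n, the percent nonlinearity is

    %NL = 100 * [ sum_{i=2..n} (M_i / A_i - 1) ] / (n - 1)

where M_i is the measured amplitude (or time-integral) of the compound
response to i sites and A_i that of the arithmetically summed waveform
(individual traces shifted by the inter-site interval and added).

Peaks are taken on raw traces; time-integrals are taken after optional
Savitzky-Golay smoothing, mirroring the analysis convention.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

__all__ = [
    "TraceSet",
    "arithmetic_sum",
    "peak_amplitude",
    "time_integral",
    "percent_nonlinearity",
    "nonlinearity_from_traceset",
]

#: Savitzky-Golay defaults: ~1 ms window on a 20 kHz-equivalent grid.
SAVGOL_WINDOW_MS = 1.05
SAVGOL_ORDER = 3
DEFAULT_BASELINE_MS = 10.0
DEFAULT_INTEGRAL_WINDOW_MS = 50.0


@dataclass
class TraceSet:
    """Individual and compound somatic responses from an uncaging protocol.

    Attributes
    ----------
    dt : float
        Sampling interval (ms).
    individual : ndarray, shape (n_sites, n_samples)
        Response of each site activated alone, aligned to onset at ``t0``.
    compound : ndarray, shape (n_sites, n_samples)
        Measured response to cumulative activation of sites 1..i
        (row i-1), first stimulus at ``t0``, successive sites separated
        by ``inter_site_shift``.
    t0 : float
        Time of the first stimulus within each trace (ms).
    inter_site_shift : float
        Interval between successive site activations (ms).
    """

    dt: float
    individual: np.ndarray
    compound: np.ndarray
    t0: float
    inter_site_shift: float = 1.0

    def __post_init__(self) -> None:
        self.individual = np.atleast_2d(np.asarray(self.individual, dtype=float))
        self.compound = np.atleast_2d(np.asarray(self.compound, dtype=float))
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.individual.shape != self.compound.shape:
            raise ValueError("individual and compound must have the same shape")
        if self.inter_site_shift < 0:
            raise ValueError("inter_site_shift must be non-negative")

    @property
    def n_sites(self) -> int:
        return self.individual.shape[0]

    @property
    def n_samples(self) -> int:
        return self.individual.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt

    def onset_of_site(self, k: int) -> float:
        """Stimulus time of site k (0-based) within the compound protocol."""
        return self.t0 + k * self.inter_site_shift

    # ---- plain-text round trip -------------------------------------
    def to_csv(self, path_or_buf) -> None:
        """Write as CSV: metadata header lines then one column per trace."""
        cols = {f"ind_{k}": self.individual[k] for k in range(self.n_sites)}
        cols.update({f"cmp_{k}": self.compound[k] for k in range(self.n_sites)})
        df = pd.DataFrame(cols)
        header = (
            f"# dt_ms={self.dt!r} t0_ms={self.t0!r} "
            f"shift_ms={self.inter_site_shift!r}\n"
        )
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(header)
            df.to_csv(path_or_buf, index=False)
        else:
            with open(path_or_buf, "w") as fh:
                fh.write(header)
                df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path_or_buf) -> "TraceSet":
        if hasattr(path_or_buf, "read"):
            text = path_or_buf.read()
        else:
            with open(path_or_buf) as fh:
                text = fh.read()
        header, _, body = text.partition("\n")
        meta = dict(
            kv.split("=") for kv in header.lstrip("# ").split() if "=" in kv
        )
        df = pd.read_csv(io.StringIO(body))
        n_sites = sum(c.startswith("ind_") for c in df.columns)
        ind = np.stack([df[f"ind_{k}"].to_numpy() for k in range(n_sites)])
        cmp_ = np.stack([df[f"cmp_{k}"].to_numpy() for k in range(n_sites)])
        return cls(
            dt=float(meta["dt_ms"]),
            individual=ind,
            compound=cmp_,
            t0=float(meta["t0_ms"]),
            inter_site_shift=float(meta["shift_ms"]),
        )


def _shift_samples(shift_ms: float, dt: float) -> int:
    n = shift_ms / dt
    if abs(n - round(n)) > 1e-9:
        raise ValueError(
            f"inter-site shift {shift_ms} ms is not an integer multiple of "
            f"the sampling interval {dt} ms; resample the traces first"
        )
    return int(round(n))


def arithmetic_sum(
    traceset: TraceSet,
    inter_site_shift: float | None = None,
) -> np.ndarray:
    """Arithmetic compound traces for cumulative combinations 1..n.

    Row i-1 is the sum of individual traces 1..i, trace k shifted right by
    (k-1) x shift. The shift must be an integer multiple of ``dt``.
    """
    shift = (
        traceset.inter_site_shift if inter_site_shift is None else inter_site_shift
    )
    if shift < 0:
        raise ValueError("shift must be non-negative")
    m = _shift_samples(shift, traceset.dt)
    n_sites, n_samples = traceset.individual.shape
    out = np.zeros((n_sites, n_samples))
    acc = np.zeros(n_samples)
    for k in range(n_sites):
        shifted = np.zeros(n_samples)
        off = k * m
        if off < n_samples:
            shifted[off:] = traceset.individual[k, : n_samples - off]
        acc = acc + shifted
        out[k] = acc
    return out


def _baseline(trace: np.ndarray, dt: float, onset: float, baseline_ms: float) -> float:
    i_on = int(round(onset / dt))
    i_lo = max(0, i_on - int(round(baseline_ms / dt)))
    if i_on <= i_lo:
        raise ValueError("empty baseline window before onset")
    return float(np.mean(trace[i_lo:i_on]))


def peak_amplitude(
    trace: np.ndarray,
    dt: float,
    onset: float,
    baseline_ms: float = DEFAULT_BASELINE_MS,
) -> float:
    """Baseline-subtracted maximum of the post-onset trace (mV)."""
    trace = np.asarray(trace, dtype=float)
    b = _baseline(trace, dt, onset, baseline_ms)
    i_on = int(round(onset / dt))
    return float(np.max(trace[i_on:]) - b)


def _savgol(trace: np.ndarray, dt: float) -> np.ndarray:
    win = int(round(SAVGOL_WINDOW_MS / dt))
    win = max(win | 1, SAVGOL_ORDER + 2 | 1)  # odd, > polyorder
    if win >= trace.size:
        return trace
    return savgol_filter(trace, win, SAVGOL_ORDER)


def time_integral(
    trace: np.ndarray,
    dt: float,
    onset: float,
    window: float = DEFAULT_INTEGRAL_WINDOW_MS,
    smoothing: bool = True,
    baseline_ms: float = DEFAULT_BASELINE_MS,
) -> float:
    """Baseline-subtracted trapezoidal integral over [onset, onset+window].

    With ``smoothing`` on, a Savitzky-Golay filter is applied first.
    Returns mV*ms.
    """
    trace = np.asarray(trace, dtype=float)
    i_on = int(round(onset / dt))
    i_hi = i_on + int(round(window / dt))
    if i_hi >= trace.size:
        raise ValueError(
            f"integration window [{onset}, {onset + window}] ms exceeds trace "
            f"length {trace.size * dt} ms"
        )
    if smoothing:
        trace = _savgol(trace, dt)
    b = _baseline(trace, dt, onset, baseline_ms)
    return float(np.trapezoid(trace[i_on : i_hi + 1] - b, dx=dt))


def percent_nonlinearity(measured: np.ndarray, arithmetic: np.ndarray) -> float:
    """Percent nonlinearity over combinations 2..n.

    ``measured`` and ``arithmetic`` hold M_2..M_n and A_2..A_n (either
    amplitudes or integrals). All A_i must be positive.
    """
    M = np.asarray(measured, dtype=float)
    A = np.asarray(arithmetic, dtype=float)
    if M.shape != A.shape or M.ndim != 1 or M.size < 1:
        raise ValueError("measured and arithmetic must be equal-length 1-D arrays")
    if np.any(A <= 0):
        raise ValueError("arithmetic values must all be positive")
    return float(np.mean(M / A - 1.0) * 100.0)


def nonlinearity_from_traceset(
    traceset: TraceSet,
    measure: str = "integral",
    window: float = DEFAULT_INTEGRAL_WINDOW_MS,
    baseline_ms: float = DEFAULT_BASELINE_MS,
    smoothing: bool = True,
) -> float:
    """End-to-end percent nonlinearity of a TraceSet.

    ``measure`` is ``"integral"`` (Savitzky-Golay smoothed by default) or
    ``"amplitude"`` (always raw). The onset for every combination is the
    time of the first stimulus.
    """
    if traceset.n_sites < 2:
        raise ValueError("nonlinearity requires at least 2 sites")
    A_traces = arithmetic_sum(traceset)
    onset = traceset.t0
    M, A = [], []
    for i in range(1, traceset.n_sites):  # combinations 2..n
        if measure == "amplitude":
            M.append(peak_amplitude(traceset.compound[i], traceset.dt, onset, baseline_ms))
            A.append(peak_amplitude(A_traces[i], traceset.dt, onset, baseline_ms))
        elif measure == "integral":
            M.append(
                time_integral(
                    traceset.compound[i], traceset.dt, onset, window, smoothing, baseline_ms
                )
            )
            A.append(
                time_integral(
                    A_traces[i], traceset.dt, onset, window, smoothing, baseline_ms
                )
            )
        else:
            raise ValueError(f"unknown measure {measure!r}")
    return percent_nonlinearity(np.array(M), np.array(A))
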