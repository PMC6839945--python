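"""Wang-Buzsaki Na+/K+ channel kinetics with a voltage shift.

Standard fast-spiking kinetics: Na activation m is instantaneous
(m = m_inf), Na inactivation h and K activation n are first-order gated
with a temperature factor phi = 5. All rate functions see the shifted
voltage ``v + v_shift``: a negative shift feeds the channels a
hyperpolarized copy of the membrane potential, moving the effective
spike threshold to more depolarized values (the stock kinetics fire too
readily for a PV+ cell).
"""

from __future__ import annotations

import numpy as np

__all__ = ["wb_rates", "wb_steady_states", "PHI"]

PHI = 5.0


def _vtrap(x: np.ndarray, y: float) -> np.ndarray:
    """x / (1 - exp(-x/y)) with the singularity at x = 0 removed."""
    x = np.asarray(x, dtype=float)
    out = np.where(
        np.abs(x / y) < 1e-6, y * (1.0 + x / (2.0 * y)), x / (1.0 - np.exp(-x / y))
    )
    return out


def wb_rates(v: np.ndarray | float, v_shift: float = 0.0) -> dict[str, np.ndarray]:
    """Forward/backward rates (1/ms) for m, h and n at voltage ``v`` (mV).

    The temperature factor is applied to the gated variables (h, n) but
    not to the instantaneous m.
    """
    u = np.asarray(v, dtype=float) + v_shift
    alpha_m = 0.1 * _vtrap(u + 35.0, 10.0)
    beta_m = 4.0 * np.exp(-(u + 60.0) / 18.0)
    alpha_h = PHI * 0.07 * np.exp(-(u + 58.0) / 20.0)
    beta_h = PHI * 1.0 / (np.exp(-0.1 * (u + 28.0)) + 1.0)
    alpha_n = PHI * 0.01 * _vtrap(u + 34.0, 10.0)
    beta_n = PHI * 0.125 * np.exp(-(u + 44.0) / 80.0)
    return {
        "alpha_m": alpha_m, "beta_m": beta_m,
        "alpha_h": alpha_h, "beta_h": beta_h,
        "alpha_n": alpha_n, "beta_n": beta_n,
    }


def wb_steady_states(
    v: np.ndarray | float, v_shift: float = 0.0
) -> dict[str, np.ndarray]:
    """Steady-state activations m_inf, h_inf, n_inf at voltage ``v``."""
    r = wb_rates(v, v_shift)
    return {
        "m_inf": r["alpha_m"] / (r["alpha_m"] + r["beta_m"]),
        "h_inf": r["alpha_h"] / (r["alpha_h"] + r["beta_h"]),
        "n_inf": r["alpha_n"] / (r["alpha_n"] + r["beta_n"]),
    }
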