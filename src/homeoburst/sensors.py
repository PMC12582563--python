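"""Calcium sensors, target mismatch filtering, match score and activity gate.

Three filters of intracellular calcium summarize the neuron's activity:

* ``F`` (fast) responds to the brief, large calcium transients of individual
  spikes, ``S`` (slow) to the slow-wave envelope of a burst, and ``D`` (DC) to
  the mean calcium load. Each sensor is built like a gated conductance: an
  activation gate ``M`` (and for F and S an inactivation gate ``H``) relaxes
  toward a logistic function of calcium on its own timescale, and the sensor
  output is ``G · M² · H`` (``G · M²`` for D, which does not inactivate).

* The mismatch between each sensor and its target is low-pass filtered over a
  2-s window into ``E_F``, ``E_S``, ``E_D``; the match score combines the
  tolerance-normalized mismatches with an L⁸ norm, which makes the score track
  the worst-offending sensor.

* A steep gate returns 1 when the score is below the acceptance threshold ρ
  and 0 above it; the activity sensor α is a 2-s average of the gate's
  complement, so α → 0 means the calcium targets are satisfied. α multiplies
  the regulation drives, idling the mechanism once targets are met.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Sensor kinetic constants: output gain G, logistic midpoints (µM) of the
#: calcium dependence of activation (z_m) and inactivation (z_h), and gate
#: time constants (ms). D has no inactivation gate.
SENSOR_KINETICS = {
    "F": {"g": 10.0, "z_m": 14.2, "z_h": 9.8, "tau_m": 0.5, "tau_h": 15.0},
    "S": {"g": 3.0, "z_m": 40.0, "z_h": 15.0, "tau_m": 50.0, "tau_h": 15.0},
    "D": {"g": 0.207, "z_m": 8.0, "z_h": None, "tau_m": 500.0, "tau_h": None},
}


@dataclass
class SensorConfig:
    """Targets, tolerances and gate constants for the calcium-sensor feedback."""

    target_f: float = 0.25
    target_s: float = 0.03
    target_d: float = 0.02
    delta_f: float = 0.25
    delta_s: float = 0.02
    delta_d: float = 0.015  # raised to 0.035 under the elevated-K perturbation
    tau_error_ms: float = 2000.0
    rho: float = 0.3
    delta_alpha: float = 0.01
    norm_order: int = 8
    tau_alpha_ms: float = 2000.0

    def __post_init__(self):
        if min(self.delta_f, self.delta_s, self.delta_d) <= 0:
            raise ValueError("sensor tolerances must be positive")
        if self.norm_order < 2 or self.norm_order % 2:
            raise ValueError("norm order must be an even integer >= 2")


@dataclass
class SensorState:
    """Gates, outputs, filtered mismatches and the activity sensor."""

    m_f: float = 1.0
    h_f: float = 0.0
    m_s: float = 1.0
    h_s: float = 0.0
    m_d: float = 1.0
    e_f: float = 1.0
    e_s: float = 1.0
    e_d: float = 1.0
    alpha: float = 1.0

    def outputs(self):
        """Instantaneous sensor outputs (F, S, D)."""
        kf, ks, kd = SENSOR_KINETICS["F"], SENSOR_KINETICS["S"], SENSOR_KINETICS["D"]
        return (
            kf["g"] * self.m_f**2 * self.h_f,
            ks["g"] * self.m_s**2 * self.h_s,
            kd["g"] * self.m_d**2,
        )


def _sig(x):
    return 1.0 / (1.0 + np.exp(x))


def sensor_gate_steady_states(ca):
    """Steady-state M and H gate values at calcium ``ca`` (µM).

    Returns ``{"F": (m, h), "S": (m, h), "D": (m, None)}``. Activation gates
    open with rising calcium, inactivation gates close.
    """
    out = {}
    for name, k in SENSOR_KINETICS.items():
        m = _sig(k["z_m"] - ca)
        h = _sig(ca - k["z_h"]) if k["z_h"] is not None else None
        out[name] = (m, h)
    return out


def sensor_rhs(state: SensorState, ca: float):
    """Derivatives of the five sensor gates at calcium ``ca``.

    Returns ``(dm_f, dh_f, dm_s, dh_s, dm_d)``.
    """
    ss = sensor_gate_steady_states(ca)
    kf, ks, kd = SENSOR_KINETICS["F"], SENSOR_KINETICS["S"], SENSOR_KINETICS["D"]
    return (
        (ss["F"][0] - state.m_f) / kf["tau_m"],
        (ss["F"][1] - state.h_f) / kf["tau_h"],
        (ss["S"][0] - state.m_s) / ks["tau_m"],
        (ss["S"][1] - state.h_s) / ks["tau_h"],
        (ss["D"][0] - state.m_d) / kd["tau_m"],
    )


def error_rhs(e, sensor_output, target, tau_error_ms=2000.0):
    """First-order low-pass of the sensor-target mismatch.

    dE/dt = ((sensor − target) − E) / τ; E tracks a 2-s moving average of the
    mismatch and settles at the mismatch's mean for stationary input.
    """
    if tau_error_ms <= 0:
        raise ValueError("tau_error_ms must be positive")
    return ((sensor_output - target) - e) / tau_error_ms


def match_score(e_f, e_s, e_d, cfg: SensorConfig):
    """L^p norm (default p=8) of the tolerance-normalized filtered mismatches."""
    p = cfg.norm_order
    r = (
        np.abs(e_f / cfg.delta_f) ** p
        + np.abs(e_s / cfg.delta_s) ** p
        + np.abs(e_d / cfg.delta_d) ** p
    )
    return r ** (1.0 / p)


def threshold_gate(score, rho=0.3, delta_alpha=0.01):
    """Steep decreasing sigmoid: ≈1 below ρ, ≈0 above, 1/2 at ρ."""
    return _sig((np.asarray(score, dtype=float) - rho) / delta_alpha)


def alpha_rhs(alpha, gate_value, tau_alpha_ms=2000.0):
    """Activity sensor: α relaxes toward (1 − gate) over a 2-s window.

    The gate is 1 when the match score is below threshold, so satisfied
    targets drive α to 0.
    """
    return ((1.0 - gate_value) - alpha) / tau_alpha_ms
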