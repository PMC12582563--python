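"""Simulation engine: starting-parameter sampling, integration, convergence
detection, freeze verification and the elevated-potassium perturbation.

The engine couples the membrane (13 ODEs), the calcium sensors (9 ODEs) and
the regulation laws (18 ODEs) into one 40-dimensional system, integrated with
an adaptive Runge–Kutta 5(4) pair and sampled on a fixed 0.5-ms grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from . import _kernel as K
from .channels import (
    CALCIUM_DYNAMICS,
    CHANNELS,
    GAS_CONSTANT,
    FARADAY,
    INACTIVATING,
    MembraneParams,
    MembraneState,
)
from .regulation import COEFFS, RegulationCoeffs, RegulationConfig
from .sensors import SENSOR_KINETICS, SensorConfig, SensorState


@dataclass
class SimulationConfig:
    """Integration and convergence settings."""

    rtol: float = 1e-4
    atol: float = 1e-6
    save_dt_ms: float = 0.5
    snapshot_dt_ms: float = 10_000.0
    max_steps: int = int(1e10)
    alpha_threshold: float = 0.02
    alpha_smooth_s: float = 8.0
    sustain_min: float = 100.0  # assembly criterion; 5.0 for perturbation recovery
    freeze_verify_s: float = 9000.0


#: Reduced-duration profile for desk-scale experiments: faster conductance
#: regulation and a shorter sustain requirement. Paper-mode constants stay the
#: defaults of RegulationConfig / SimulationConfig.
SCALED_DOWN = {
    "tau_g_s": 60.0,
    "sustain_min": 10.0,
    "duration_min": 45.0,
}


@dataclass
class Trajectory:
    """Fixed-grid output of one integration."""

    t_ms: np.ndarray
    v: np.ndarray
    ca: np.ndarray
    alpha: np.ndarray
    snapshots_t_ms: np.ndarray
    snapshots: np.ndarray  # (n, 40) full state at coarse cadence
    final_state: np.ndarray  # (40,)
    full: Optional[np.ndarray] = None  # (n, 40) when save_full was requested
    seed: Optional[int] = None

    @property
    def duration_ms(self) -> float:
        return float(self.t_ms[-1] - self.t_ms[0])


@dataclass
class AssemblyResult:
    status: str  # assembled | not-converged | irregular
    final_state: np.ndarray
    convergence_min: Optional[float]
    trajectory: Trajectory


def pack_state(mem: MembraneState, sens: SensorState, params: MembraneParams) -> np.ndarray:
    y = np.empty(K.N_STATE)
    y[K.IDX_V] = mem.v
    y[K.IDX_M : K.IDX_M + 7] = mem.m
    y[K.IDX_H : K.IDX_H + 4] = mem.h
    y[K.IDX_CA] = mem.ca
    y[K.IDX_SENS : K.IDX_SENS + 5] = (sens.m_f, sens.h_f, sens.m_s, sens.h_s, sens.m_d)
    y[K.IDX_E : K.IDX_E + 3] = (sens.e_f, sens.e_s, sens.e_d)
    y[K.IDX_ALPHA] = sens.alpha
    y[K.IDX_GBAR : K.IDX_GBAR + 7] = params.gbar
    y[K.IDX_SM : K.IDX_SM + 7] = params.shift_m
    y[K.IDX_SH : K.IDX_SH + 4] = params.shift_h
    return y


def unpack_state(y: np.ndarray, params: MembraneParams):
    """Split a packed state vector into (MembraneState, SensorState, MembraneParams)."""
    mem = MembraneState(
        v=float(y[K.IDX_V]),
        m=y[K.IDX_M : K.IDX_M + 7].copy(),
        h=y[K.IDX_H : K.IDX_H + 4].copy(),
        ca=float(y[K.IDX_CA]),
    )
    sens = SensorState(
        m_f=float(y[K.IDX_SENS]),
        h_f=float(y[K.IDX_SENS + 1]),
        m_s=float(y[K.IDX_SENS + 2]),
        h_s=float(y[K.IDX_SENS + 3]),
        m_d=float(y[K.IDX_SENS + 4]),
        e_f=float(y[K.IDX_E]),
        e_s=float(y[K.IDX_E + 1]),
        e_d=float(y[K.IDX_E + 2]),
        alpha=float(y[K.IDX_ALPHA]),
    )
    new_params = replace(
        params,
        gbar=y[K.IDX_GBAR : K.IDX_GBAR + 7].copy(),
        shift_m=y[K.IDX_SM : K.IDX_SM + 7].copy(),
        shift_h=y[K.IDX_SH : K.IDX_SH + 4].copy(),
    )
    return mem, sens, new_params


def pack_params(
    mp: MembraneParams,
    sc: SensorConfig,
    rc: RegulationConfig,
    coeffs: RegulationCoeffs = COEFFS,
) -> np.ndarray:
    p = np.zeros(K.N_PARAMS)
    p[K.P_C] = mp.capacitance_nF
    p[K.P_GLEAK] = mp.g_leak
    p[K.P_ENA] = mp.e_na
    p[K.P_EH] = mp.e_h
    p[K.P_EK] = mp.e_k
    p[K.P_EL] = mp.e_leak
    p[K.P_CAOUT] = mp.ca_out_mM
    p[K.P_RT2F] = 1000.0 * GAS_CONSTANT * (mp.temperature_C + 273.15) / (2.0 * FARADAY)
    p[K.P_FCA] = CALCIUM_DYNAMICS["f"]
    p[K.P_TAUCA] = CALCIUM_DYNAMICS["tau_ca"]
    p[K.P_CAREST] = CALCIUM_DYNAMICS["ca_rest"]
    kf, ks, kd = SENSOR_KINETICS["F"], SENSOR_KINETICS["S"], SENSOR_KINETICS["D"]
    p[K.P_GF], p[K.P_GS], p[K.P_GD] = kf["g"], ks["g"], kd["g"]
    p[K.P_ZMF], p[K.P_ZHF] = kf["z_m"], kf["z_h"]
    p[K.P_ZMS], p[K.P_ZHS] = ks["z_m"], ks["z_h"]
    p[K.P_ZMD] = kd["z_m"]
    p[K.P_TMF], p[K.P_THF] = kf["tau_m"], kf["tau_h"]
    p[K.P_TMS], p[K.P_THS] = ks["tau_m"], ks["tau_h"]
    p[K.P_TMD] = kd["tau_m"]
    p[K.P_TARGF], p[K.P_TARGS], p[K.P_TARGD] = sc.target_f, sc.target_s, sc.target_d
    p[K.P_DF], p[K.P_DS], p[K.P_DD] = sc.delta_f, sc.delta_s, sc.delta_d
    p[K.P_TAUERR] = sc.tau_error_ms
    p[K.P_RHO] = sc.rho
    p[K.P_DALPHA] = sc.delta_alpha
    p[K.P_NORM] = float(sc.norm_order)
    p[K.P_TAUALPHA] = sc.tau_alpha_ms
    p[K.P_ACTIVE_G] = 0.0 if rc.g_frozen else 1.0
    p[K.P_ACTIVE_H] = 0.0 if rc.half_frozen else 1.0
    p[K.P_TAUG] = 1.0 if rc.g_frozen else rc.tau_g_s * 1000.0
    p[K.P_TAUHALF] = 1.0 if rc.half_frozen else rc.tau_half_s * 1000.0
    p[K.P_GAMMA] = rc.gamma / 1000.0  # stated per second; engine runs per ms
    p[K.P_GAMMAHAT] = rc.gamma_hat  # stated per ms (keeps shift bounds subtle)
    p[K.P_COEF : K.P_COEF + 21] = coeffs.conductance.ravel()
    p[K.P_COEF + 21 : K.P_COEF + 42] = coeffs.activation.ravel()
    p[K.P_COEF + 42 : K.P_COEF + 54] = coeffs.inactivation.ravel()
    return p


_TAU_FORM_CODE = {"sigmoid": 0, "biexp": 1, "product": 2}
_REV_CODE = {30.0: 0, -20.0: 1, -80.0: 2}


def pack_kinetics(channels=CHANNELS):
    """Channel kinetic constants as flat arrays for the compiled RHS."""
    q = np.array([c.q for c in channels], dtype=np.float64)
    mvh = np.array([c.activation.vhalf for c in channels])
    mk = np.array([c.activation.k for c in channels])
    kca_half = np.array(
        [c.activation.ca_half if c.activation.ca_half else 0.0 for c in channels]
    )
    hvh = np.array([channels[i].inactivation.vhalf for i in INACTIVATING])
    hk = np.array([channels[i].inactivation.k for i in INACTIVATING])
    tmf = np.array([_TAU_FORM_CODE[c.activation.tau_form] for c in channels], dtype=np.int64)
    tmc = np.zeros((7, 6))
    for i, c in enumerate(channels):
        tmc[i, : len(c.activation.tau_coeffs)] = c.activation.tau_coeffs
    thf = np.array(
        [_TAU_FORM_CODE[channels[i].inactivation.tau_form] for i in INACTIVATING],
        dtype=np.int64,
    )
    thc = np.zeros((4, 6))
    for j, i in enumerate(INACTIVATING):
        thc[j, : len(channels[i].inactivation.tau_coeffs)] = channels[i].inactivation.tau_coeffs
    revcode = np.array(
        [3 if c.ca_reversal else _REV_CODE[float(c.reversal)] for c in channels],
        dtype=np.int64,
    )
    return (q, mvh, mk, kca_half, hvh, hk, tmf, tmc, thf, thc, revcode)


def full_rhs(y: np.ndarray, p: np.ndarray, kin=None) -> np.ndarray:
    """Derivative of the packed 40-component state (compiled path)."""
    if kin is None:
        kin = pack_kinetics()
    dy = np.empty(K.N_STATE)
    K.rhs(y, dy, p, *kin)
    return dy


def sample_starting_parameters(rng: np.random.Generator, params_template=None):
    """Draw a random starting condition.

    Conductances uniform on 0.3–0.9 nS (in µS), half-(in)activation shifts
    uniform on ±0.5 mV, V = −50 mV, gates uniform on 0.2–0.3, Ca = 0.4 µM;
    sensor errors and α start at 1, sensor gates at M = 1, H = 0.
    """
    gbar = rng.uniform(0.3e-3, 0.9e-3, size=7)  # nS -> µS
    shift_m = rng.uniform(-0.5, 0.5, size=7)
    shift_h = rng.uniform(-0.5, 0.5, size=4)
    mem = MembraneState(
        v=-50.0,
        m=rng.uniform(0.2, 0.3, size=7),
        h=rng.uniform(0.2, 0.3, size=4),
        ca=0.4,
    )
    base = params_template if params_template is not None else MembraneParams(
        gbar=gbar, shift_m=shift_m, shift_h=shift_h
    )
    params = replace(base, gbar=gbar, shift_m=shift_m, shift_h=shift_h)
    return mem, SensorState(), params


def run_simulation(
    y0: np.ndarray,
    params: MembraneParams,
    sensor_cfg: SensorConfig,
    reg_cfg: RegulationConfig,
    duration_ms: float,
    sim_cfg: SimulationConfig = None,
    *,
    coeffs: RegulationCoeffs = COEFFS,
    save_full: bool = False,
    t0_ms: float = 0.0,
) -> Trajectory:
    """Integrate the coupled system for ``duration_ms`` and sample every 0.5 ms."""
    sim_cfg = sim_cfg or SimulationConfig()
    if not np.all(np.isfinite(y0)):
        raise ValueError("non-finite initial state")
    p = pack_params(params, sensor_cfg, reg_cfg, coeffs)
    kin = pack_kinetics()
    saved, snaps, yf, status, t_reached, _ = K.integrate(
        np.asarray(y0, dtype=float),
        p,
        *kin,
        t0_ms,
        t0_ms + duration_ms,
        sim_cfg.save_dt_ms,
        sim_cfg.rtol,
        sim_cfg.atol,
        sim_cfg.max_steps,
        save_full,
        sim_cfg.snapshot_dt_ms,
    )
    if status != K.STATUS_OK:
        reason = "step-size underflow" if status == K.STATUS_UNDERFLOW else "max steps exceeded"
        raise RuntimeError(f"solver failure ({reason}) at t = {t_reached:.3f} ms")
    t = t0_ms + sim_cfg.save_dt_ms * np.arange(saved.shape[0])
    ts = t0_ms + sim_cfg.snapshot_dt_ms * np.arange(snaps.shape[0])
    if save_full:
        return Trajectory(t, saved[:, K.IDX_V], saved[:, K.IDX_CA], saved[:, K.IDX_ALPHA],
                          ts, snaps, yf, full=saved)
    return Trajectory(t, saved[:, 0], saved[:, 1], saved[:, 2], ts, snaps, yf)


def smoothed_alpha(alpha: np.ndarray, save_dt_ms: float, window_s: float = 8.0) -> np.ndarray:
    """Trailing running mean of α over the previous ``window_s`` seconds.

    For samples earlier than one full window the mean is taken over what
    exists so far.
    """
    n = alpha.size
    w = int(round(window_s * 1000.0 / save_dt_ms))
    if w < 1 or n == 0:
        raise ValueError("trace shorter than the smoothing window")
    c = np.concatenate(([0.0], np.cumsum(alpha)))
    out = np.empty(n)
    for_head = min(w, n)
    idx = np.arange(n)
    lo = np.maximum(idx - w + 1, 0)
    out = (c[idx + 1] - c[lo]) / (idx + 1 - lo)
    return out


def detect_convergence(
    alpha: np.ndarray,
    save_dt_ms: float = 0.5,
    threshold: float = 0.02,
    window_s: float = 8.0,
    sustain_min: float = 100.0,
):
    """Find the last downward crossing of the smoothed α below ``threshold``.

    Converged iff the smoothed trace stays below threshold from that crossing
    through the end, for at least ``sustain_min`` minutes. Returns
    ``(converged, crossing_time_min)``.
    """
    sm = smoothed_alpha(np.asarray(alpha, dtype=float), save_dt_ms, window_s)
    below = sm < threshold
    if not below[-1]:
        return False, None
    # last index where the trace was at/above threshold
    above_idx = np.nonzero(~below)[0]
    start = (above_idx[-1] + 1) if above_idx.size else 0
    sustained_ms = (below.size - 1 - start) * save_dt_ms
    if sustained_ms >= sustain_min * 60_000.0:
        return True, start * save_dt_ms / 60_000.0
    return False, None


def assemble(
    seed: int,
    duration_min: float,
    params_template: MembraneParams = None,
    sensor_cfg: SensorConfig = None,
    reg_cfg: RegulationConfig = None,
    sim_cfg: SimulationConfig = None,
) -> AssemblyResult:
    """Run the full assembly protocol from a seeded random starting condition."""
    sensor_cfg = sensor_cfg or SensorConfig()
    reg_cfg = reg_cfg or RegulationConfig()
    sim_cfg = sim_cfg or SimulationConfig()
    rng = np.random.default_rng(seed)
    mem, sens, params = sample_starting_parameters(rng, params_template)
    y0 = pack_state(mem, sens, params)
    traj = run_simulation(y0, params, sensor_cfg, reg_cfg, duration_min * 60_000.0, sim_cfg)
    traj.seed = seed
    conv, t_conv = detect_convergence(
        traj.alpha, sim_cfg.save_dt_ms, sim_cfg.alpha_threshold,
        sim_cfg.alpha_smooth_s, sim_cfg.sustain_min,
    )
    status = "assembled" if conv else "not-converged"
    return AssemblyResult(status, traj.final_state, t_conv, traj)


def verify_frozen(
    final_state: np.ndarray,
    params: MembraneParams,
    sensor_cfg: SensorConfig,
    sim_cfg: SimulationConfig = None,
    duration_s: float = 9000.0,
) -> bool:
    """Freeze both mechanisms and check smoothed α < threshold throughout."""
    sim_cfg = sim_cfg or SimulationConfig()
    frozen = RegulationConfig(tau_g_s=math.inf, tau_half_s=math.inf)
    traj = run_simulation(final_state, params, sensor_cfg, frozen, duration_s * 1000.0, sim_cfg)
    reg_block = slice(K.IDX_GBAR, K.N_STATE)
    if not np.array_equal(traj.snapshots[0, reg_block], traj.snapshots[-1, reg_block]):
        raise AssertionError("frozen mechanisms must leave regulated parameters bit-identical")
    sm = smoothed_alpha(traj.alpha, sim_cfg.save_dt_ms, sim_cfg.alpha_smooth_s)
    return bool(np.all(sm < sim_cfg.alpha_threshold))


def perturbed_leak_reversal(e_leak0: float, e_k0: float, e_na: float, e_k_new: float) -> float:
    """Leak reversal after a potassium-reversal change.

    The baseline leak is decomposed into K and Na components: solve
    E_L0 = f·E_K0 + (1−f)·E_Na for the potassium fraction f, then recompute
    the weighted average with the new potassium reversal.
    """
    if not (e_k0 < e_leak0 < e_na):
        raise ValueError("baseline leak reversal must lie between E_K and E_Na")
    f = (e_na - e_leak0) / (e_na - e_k0)
    return f * e_k_new + (1.0 - f) * e_na


#: Potassium reversal (mV) corresponding to the modeled 2.5-fold rise in
#: extracellular potassium.
E_K_ELEVATED = -55.0


def apply_potassium_perturbation(
    params: MembraneParams, sensor_cfg: SensorConfig, e_k_new: float = E_K_ELEVATED
):
    """Elevated-extracellular-potassium protocol.

    Sets E_K to −55 mV (2.5-fold K increase), moves the leak reversal by its
    potassium fraction, and widens the DC sensor tolerance Δ_D to 0.035.
    Everything else is untouched. Returns new (params, sensor_cfg).
    """
    new_el = perturbed_leak_reversal(params.e_leak, params.e_k, params.e_na, e_k_new)
    new_params = replace(params, e_k=e_k_new, e_leak=new_el)
    new_sc = replace(sensor_cfg, delta_d=0.035)
    return new_params, new_sc
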