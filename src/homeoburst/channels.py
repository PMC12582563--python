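"""Single-compartment seven-current neuron: channels, gating and membrane dynamics.

The neuron carries a fast sodium current (Na), two calcium currents (CaT, CaS),
a hyperpolarization-activated inward current (H), three potassium currents
(Kd, KCa, A) and an ohmic leak. Gating follows Hodgkin–Huxley kinetics with
logistic steady-state curves and voltage-dependent time constants; the KCa
activation additionally saturates with intracellular calcium. Every channel's
voltage dependence can be translated by a per-channel half-(in)activation
shift: the steady-state half voltage moves by the shift and the time-constant
curve moves with it, so the gate's response speed is preserved wherever the
curve is centred.

Units: mV, ms, µS, nA, nF, µM (so that dV/dt = -I/C is in mV/ms).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Optional

import numpy as np
import yaml

CHANNEL_NAMES = ("Na", "CaT", "CaS", "H", "Kd", "KCa", "A")
#: indices (into CHANNEL_NAMES) of the channels that inactivate
INACTIVATING = (0, 1, 2, 6)

GAS_CONSTANT = 8.314462618  # J / (mol K)
FARADAY = 96485.33212  # C / mol

_TAU_FORMS = ("sigmoid", "biexp", "product")


@dataclass(frozen=True)
class GateCurve:
    """One gating variable: logistic steady state plus a tau curve."""

    vhalf: float  # mV, baseline half-(in)activation
    k: float  # mV, logistic slope factor (sign sets orientation)
    tau_form: str
    tau_coeffs: tuple
    ca_half: Optional[float] = None  # µM; only the KCa activation sets this

    def steady_state(self, v: float, shift: float = 0.0, ca: Optional[float] = None):
        """Steady-state gate value at voltage ``v`` with the curve translated by ``shift``."""
        x = 1.0 / (1.0 + np.exp((v - (self.vhalf + shift)) / self.k))
        if self.ca_half is not None:
            if ca is None:
                raise ValueError("calcium-dependent activation requires Ca_in")
            x = x * (ca / (ca + self.ca_half))
        return x

    def time_constant(self, v: float, shift: float = 0.0):
        """Voltage-dependent time constant (ms), translated with the curve."""
        u = v - shift
        c = self.tau_coeffs
        if self.tau_form == "sigmoid":
            return c[0] - c[1] / (1.0 + np.exp((u - c[2]) / c[3]))
        if self.tau_form == "biexp":
            return c[0] + c[1] / (np.exp((u - c[2]) / c[3]) + np.exp((u - c[4]) / c[5]))
        if self.tau_form == "product":
            return (c[0] / (1.0 + np.exp((u - c[2]) / c[3]))) * (
                c[1] + 1.0 / (1.0 + np.exp((u - c[4]) / c[5]))
            )
        raise ValueError(f"unknown tau form {self.tau_form!r}")


@dataclass(frozen=True)
class ChannelDef:
    """Static description of one intrinsic current."""

    name: str
    q: int  # activation gate exponent
    reversal: object  # fixed mV, or the string "nernst-calcium"
    activation: GateCurve
    inactivation: Optional[GateCurve] = None

    @property
    def has_inactivation(self) -> bool:
        return self.inactivation is not None

    @property
    def ca_reversal(self) -> bool:
        return self.reversal == "nernst-calcium"


def _load_yaml(name: str) -> dict:
    with resources.files("homeoburst.data").joinpath(name).open() as fh:
        return yaml.safe_load(fh)


def _gate_from_dict(d: dict) -> GateCurve:
    tau = d["tau"]
    if tau["form"] not in _TAU_FORMS:
        raise ValueError(f"unknown tau form {tau['form']!r}")
    return GateCurve(
        vhalf=float(d["vhalf"]),
        k=float(d["k"]),
        tau_form=tau["form"],
        tau_coeffs=tuple(float(c) for c in tau["coeffs"]),
        ca_half=float(d["ca_half"]) if "ca_half" in d else None,
    )


def load_channel_table(path=None):
    """Load the channel definitions (package default table unless ``path`` given).

    Returns ``(channels, calcium_dynamics, leak_conductance)`` where ``channels``
    is a tuple of seven :class:`ChannelDef` in the model's canonical order.
    """
    raw = _load_yaml("channels.yaml") if path is None else yaml.safe_load(open(path))
    chans = []
    for rec in raw["channels"]:
        act = _gate_from_dict(rec["activation"])
        inact = _gate_from_dict(rec["inactivation"]) if "inactivation" in rec else None
        rev = rec["reversal"]
        if rev != "nernst-calcium":
            rev = float(rev)
        chans.append(ChannelDef(rec["name"], int(rec["q"]), rev, act, inact))
    names = tuple(c.name for c in chans)
    if names != CHANNEL_NAMES:
        raise ValueError(f"channel table must list {CHANNEL_NAMES}, got {names}")
    for i, c in enumerate(chans):
        if c.has_inactivation != (i in INACTIVATING):
            raise ValueError(f"inactivation mismatch for {c.name}")
    ca = raw["calcium_dynamics"]
    cadyn = {
        "tau_ca": float(ca["tau_ca_ms"]),
        "f": float(ca["f_uM_per_nA"]),
        "ca_rest": float(ca["ca_rest_uM"]),
    }
    return tuple(chans), cadyn, float(raw["leak_conductance_uS"])


CHANNELS, CALCIUM_DYNAMICS, LEAK_CONDUCTANCE = load_channel_table()
CHANNEL_INDEX = {c.name: i for i, c in enumerate(CHANNELS)}


@dataclass
class MembraneParams:
    """Reversal potentials, regulated parameters and cell constants.

    ``gbar`` excludes the leak, whose conductance is fixed. E_Ca is never
    stored; it is recomputed from intracellular calcium via the Nernst
    equation at every evaluation.
    """

    gbar: np.ndarray  # µS, 7 channels
    shift_m: np.ndarray  # mV, 7 activation shifts
    shift_h: np.ndarray  # mV, 4 inactivation shifts (Na, CaT, CaS, A)
    e_na: float = 30.0
    e_h: float = -20.0
    e_k: float = -80.0
    e_leak: float = -50.0
    g_leak: float = LEAK_CONDUCTANCE
    ca_out_mM: float = 3.0
    temperature_C: float = 10.0
    capacitance_nF: float = 1.0

    def __post_init__(self):
        self.gbar = np.asarray(self.gbar, dtype=float)
        self.shift_m = np.asarray(self.shift_m, dtype=float)
        self.shift_h = np.asarray(self.shift_h, dtype=float)
        if self.gbar.shape != (7,) or self.shift_m.shape != (7,) or self.shift_h.shape != (4,):
            raise ValueError("expected 7 conductances, 7 activation shifts, 4 inactivation shifts")
        if np.any(self.gbar < 0):
            raise ValueError("maximal conductances must be nonnegative")

    def reversal(self, i: int, ca_in: float) -> float:
        ch = CHANNELS[i]
        if ch.ca_reversal:
            return nernst_calcium(ca_in, self.ca_out_mM, self.temperature_C)
        return {30.0: self.e_na, -20.0: self.e_h, -80.0: self.e_k}.get(
            float(ch.reversal), float(ch.reversal)
        )


@dataclass
class MembraneState:
    """Instantaneous electrical state."""

    v: float  # mV
    m: np.ndarray  # 7 activation gates
    h: np.ndarray  # 4 inactivation gates (Na, CaT, CaS, A)
    ca: float  # µM intracellular calcium

    def __post_init__(self):
        self.m = np.asarray(self.m, dtype=float)
        self.h = np.asarray(self.h, dtype=float)
        if self.m.shape != (7,) or self.h.shape != (4,):
            raise ValueError("expected 7 activation and 4 inactivation gates")
        if self.ca <= 0:
            raise ValueError("intracellular calcium must be positive")


def gate_steady_state(v, channel: ChannelDef, shift: float = 0.0, ca_in=None, *, kind="m"):
    """Activation (``kind='m'``) or inactivation (``kind='h'``) steady state.

    The half voltage is translated by ``shift``. ``ca_in`` is required only for
    the calcium-dependent KCa activation.
    """
    if kind == "m":
        return channel.activation.steady_state(v, shift, ca_in)
    if kind == "h":
        if channel.inactivation is None:
            raise ValueError(f"channel {channel.name} has no inactivation gate")
        return channel.inactivation.steady_state(v, shift)
    raise ValueError("kind must be 'm' or 'h'")


def gate_time_constant(v, channel: ChannelDef, shift: float = 0.0, *, kind="m"):
    """Gate time constant (ms); the tau curve shifts with the half-(in)activation."""
    curve = channel.activation if kind == "m" else channel.inactivation
    if curve is None:
        raise ValueError(f"channel {channel.name} has no inactivation gate")
    return curve.time_constant(v, shift)


def nernst_calcium(ca_in_uM, ca_out_mM=3.0, temperature_C=10.0):
    """Calcium reversal potential (mV) for a divalent ion.

    (RT/2F) ln([Ca]_out/[Ca]_in); concentrations converted to a common scale.
    """
    ca_in = np.asarray(ca_in_uM, dtype=float)
    if np.any(ca_in <= 0) or ca_out_mM <= 0:
        raise ValueError("concentrations must be positive")
    rt_2f = GAS_CONSTANT * (temperature_C + 273.15) / (2.0 * FARADAY)  # volts
    return 1000.0 * rt_2f * np.log(ca_out_mM * 1000.0 / ca_in)


def ionic_current(i: int, state: MembraneState, params: MembraneParams) -> float:
    """Current through channel ``i`` in nA (positive = outward)."""
    ch = CHANNELS[i]
    m = state.m[i]
    h = state.h[INACTIVATING.index(i)] if ch.has_inactivation else 1.0
    e_rev = params.reversal(i, state.ca)
    return params.gbar[i] * m**ch.q * h * (state.v - e_rev)


def leak_current(state: MembraneState, params: MembraneParams) -> float:
    return params.g_leak * (state.v - params.e_leak)


def membrane_rhs(state: MembraneState, params: MembraneParams):
    """Time derivatives of the membrane state (reference implementation).

    Returns ``(dv, dm, dh, dca)``. The compiled full-system right-hand side in
    :mod:`homeoburst._kernel` must agree with this composition of the
    single-channel operations; tests assert that.
    """
    if not np.all(np.isfinite([state.v, state.ca])) or not (
        np.all(np.isfinite(state.m)) and np.all(np.isfinite(state.h))
    ):
        raise ValueError("non-finite membrane state")
    currents = [ionic_current(i, state, params) for i in range(7)]
    i_total = sum(currents) + leak_current(state, params)
    dv = -i_total / params.capacitance_nF

    dm = np.empty(7)
    for i, ch in enumerate(CHANNELS):
        minf = gate_steady_state(state.v, ch, params.shift_m[i], state.ca)
        taum = gate_time_constant(state.v, ch, params.shift_m[i])
        dm[i] = (minf - state.m[i]) / taum
    dh = np.empty(4)
    for j, i in enumerate(INACTIVATING):
        ch = CHANNELS[i]
        hinf = gate_steady_state(state.v, ch, params.shift_h[j], kind="h")
        tauh = gate_time_constant(state.v, ch, params.shift_h[j], kind="h")
        dh[j] = (hinf - state.h[j]) / tauh

    cad = CALCIUM_DYNAMICS
    i_ca = currents[CHANNEL_INDEX["CaT"]] + currents[CHANNEL_INDEX["CaS"]]
    dca = (-cad["f"] * i_ca - state.ca + cad["ca_rest"]) / cad["tau_ca"]
    return dv, dm, dh, dca
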