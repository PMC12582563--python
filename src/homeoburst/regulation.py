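"""Activity-dependent update laws for conductances and half-(in)activation shifts.

Two regulation mechanisms run on independently controlled timescales:

* Maximal conductances evolve on τ_g (default 600 s). The drive converts
  filtered calcium-sensor mismatches into conductance changes through a
  per-channel coefficient triple (A, B, C); it is multiplied by the
  conductance itself (so conductances stay nonnegative and change
  exponentially) and by the activity sensor α (so regulation idles once
  targets are met). A cubic damping term −γ·g̅³ prevents unbounded growth.

* Half-(in)activation shifts evolve on τ_half (default 6 s) under the same
  structure, with coefficient triples derived from the conductance ones:
  activation-shift triples are their negatives, inactivation-shift triples
  are equal (with explicit table overrides). The cubic term −γ̂·V³ bounds the
  translations.

Either timescale may be frozen (τ = ∞), which makes the corresponding
derivatives exactly zero.

The sign convention: mismatches enter as (target − sensor), so when every
sensor exceeds its target, an inward current like Na loses conductance and
becomes harder to activate (its activation curve shifts depolarized), while
an outward current like A gains conductance and becomes easier to activate —
both excitability-reducing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
import numpy as np
import yaml

from .channels import CHANNEL_NAMES, INACTIVATING

INACT_NAMES = tuple(CHANNEL_NAMES[i] for i in INACTIVATING)


@dataclass
class RegulationConfig:
    """Timescales and cubic constants for the two regulation mechanisms.

    τ_g and τ_half are in seconds (``math.inf`` freezes a mechanism
    exactly); γ is in 1/(µS²·s) and γ̂ in 1/(mV²·ms). The activity sensor α
    multiplies the entire law — sensor drive and cubic damping alike — so a
    model that satisfies its targets (α → 0) stops adjusting altogether, and
    the cubic terms cap runaway growth only while regulation is active. The
    conductance cap sits at g* = sqrt(drive/(τ_g·γ)) ≈ 65 µS for a
    unit-coefficient drive at default settings — the scale of stomatogastric
    maximal conductances — while the shift bound
    V* = (drive/(τ_half·γ̂))^{1/3} stays under ~2 mV, keeping
    voltage-dependence changes subtle. When τ_g is reduced for desk-scale
    runs, γ should be raised by the same factor to preserve the cap (see the
    engine's scaled-down profile).
    """

    tau_g_s: float = 600.0
    tau_half_s: float = 6.0
    gamma: float = 1e-7
    gamma_hat: float = 1e-5

    def __post_init__(self):
        if self.tau_g_s <= 0 or self.tau_half_s <= 0:
            raise ValueError("timescales must be positive (inf allowed)")
        if self.gamma < 0 or self.gamma_hat < 0:
            raise ValueError("cubic constants must be nonnegative")

    @property
    def g_frozen(self) -> bool:
        return math.isinf(self.tau_g_s)

    @property
    def half_frozen(self) -> bool:
        return math.isinf(self.tau_half_s)


@dataclass(frozen=True)
class RegulationCoeffs:
    """Coefficient triples per channel (rows ordered as CHANNEL_NAMES)."""

    conductance: np.ndarray  # (7, 3)
    activation: np.ndarray  # (7, 3)
    inactivation: np.ndarray  # (4, 3), rows ordered as INACT_NAMES
    overrides: tuple = ()


def derive_shift_coefficients(conductance: np.ndarray):
    """Generate shift coefficient triples from the conductance triples.

    Activation triples are the negated conductance triples; inactivation
    triples (inactivating channels only) equal the conductance triples. Used
    to cross-validate the shipped table, whose explicit rows win.
    """
    conductance = np.asarray(conductance, dtype=float)
    if conductance.shape != (7, 3):
        raise ValueError("expected a (7, 3) conductance coefficient array")
    activation = -conductance
    inactivation = conductance[list(INACTIVATING)].copy()
    return activation, inactivation


def load_coefficients(path=None, *, log=None) -> RegulationCoeffs:
    """Load the coefficient table; report rows deviating from the sign-flip rule."""
    if path is None:
        with resources.files("homeoburst.data").joinpath("regulation_coeffs.yaml").open() as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = yaml.safe_load(open(path))

    cond = np.array([raw["conductance"][n] for n in CHANNEL_NAMES], dtype=float)
    act = np.array([raw["activation"][n] for n in CHANNEL_NAMES], dtype=float)
    inact = np.array([raw["inactivation"][n] for n in INACT_NAMES], dtype=float)

    exp_act, exp_inact = derive_shift_coefficients(cond)
    overrides = []
    for i, n in enumerate(CHANNEL_NAMES):
        if not np.array_equal(act[i], exp_act[i]):
            overrides.append(f"activation/{n}: {act[i].tolist()} (rule: {exp_act[i].tolist()})")
    for j, n in enumerate(INACT_NAMES):
        if not np.array_equal(inact[j], exp_inact[j]):
            overrides.append(f"inactivation/{n}: {inact[j].tolist()} (rule: {exp_inact[j].tolist()})")
    if log is not None:
        for o in overrides:
            log(f"coefficient override: {o}")
    return RegulationCoeffs(cond, act, inact, tuple(overrides))


COEFFS = load_coefficients()


def _drive(coeff_row, e_f, e_s, e_d, deltas):
    """Sensor drive: coefficients contract against the tolerance-normalized
    (target − sensor) mismatches, the same normalized errors the match score
    uses, so every sensor speaks with a comparable voice."""
    return (coeff_row[0] * (-e_f / deltas[0])
            + coeff_row[1] * (-e_s / deltas[1])
            + coeff_row[2] * (-e_d / deltas[2]))


DEFAULT_DELTAS = (0.25, 0.02, 0.015)


def conductance_rhs(gbar, e_f, e_s, e_d, alpha, coeffs: RegulationCoeffs,
                    cfg: RegulationConfig, deltas=None):
    """dg̅/dt (µS/ms) for all seven regulated conductances.

    Exactly zero when the mechanism is frozen (τ_g = ∞).
    """
    gbar = np.asarray(gbar, dtype=float)
    deltas = DEFAULT_DELTAS if deltas is None else deltas
    if cfg.g_frozen:
        return np.zeros_like(gbar)
    drive = np.array([_drive(coeffs.conductance[i], e_f, e_s, e_d, deltas)
                      for i in range(7)])
    tau_ms = cfg.tau_g_s * 1000.0
    return alpha * (gbar * drive / tau_ms - cfg.gamma / 1000.0 * gbar**3)


def activation_shift_rhs(shift_m, e_f, e_s, e_d, alpha, coeffs: RegulationCoeffs,
                         cfg: RegulationConfig, deltas=None):
    """dV_s^m/dt (mV/ms) for the seven activation-curve shifts."""
    shift_m = np.asarray(shift_m, dtype=float)
    deltas = DEFAULT_DELTAS if deltas is None else deltas
    if cfg.half_frozen:
        return np.zeros_like(shift_m)
    drive = np.array([_drive(coeffs.activation[i], e_f, e_s, e_d, deltas)
                      for i in range(7)])
    tau_ms = cfg.tau_half_s * 1000.0
    return alpha * (drive / tau_ms - cfg.gamma_hat * shift_m**3)


def inactivation_shift_rhs(shift_h, e_f, e_s, e_d, alpha, coeffs: RegulationCoeffs,
                           cfg: RegulationConfig, deltas=None):
    """dV_s^h/dt (mV/ms) for the four inactivation-curve shifts."""
    shift_h = np.asarray(shift_h, dtype=float)
    deltas = DEFAULT_DELTAS if deltas is None else deltas
    if cfg.half_frozen:
        return np.zeros_like(shift_h)
    drive = np.array([_drive(coeffs.inactivation[j], e_f, e_s, e_d, deltas)
                      for j in range(4)])
    tau_ms = cfg.tau_half_s * 1000.0
    return alpha * (drive / tau_ms - cfg.gamma_hat * shift_h**3)
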