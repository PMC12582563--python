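"""Waveform measurement: peak/trough detection, the six burst features,
regularity classification, current-contribution shares, and a synthetic
fixture generator with known ground truth.

The measurement procedure mirrors standard bursting-neuron analysis: local
maxima with topographic prominence ≥ 2 mV are spikes; troughs are peaks of
the negated trace; cycle boundaries are the deep troughs found by stepping an
integer-mV threshold up from −85 mV until some troughs fall below it; the six
features (period, burst duration, interburst interval, spike height, maximum
hyperpolarization, slow-wave amplitude) are computed per cycle and averaged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
from scipy.signal import find_peaks as _scipy_find_peaks

DEFAULT_PROMINENCE_MV = 2.0
DEFAULT_WINDOW_S = 90.0
HYPERPOL_SCAN_START_MV = -85.0


@dataclass
class BurstSummary:
    """Per-trace activity features (ms / mV) with per-cycle detail."""

    period: float
    burst_duration: float
    interburst_interval: float
    spike_height: float
    max_hyperpolarization: float
    slow_wave_amplitude: float
    spikes_per_cycle: List[int]
    per_cycle: dict  # feature name -> per-cycle array
    regular: bool
    rsd: dict  # feature name -> relative standard deviation (fraction)
    measurable: bool = True

    FEATURES = (
        "period",
        "burst_duration",
        "interburst_interval",
        "spike_height",
        "max_hyperpolarization",
        "slow_wave_amplitude",
    )


def find_peaks(trace: np.ndarray, min_prominence: float = DEFAULT_PROMINENCE_MV) -> np.ndarray:
    """Indices of local maxima with topographic prominence ≥ ``min_prominence``.

    Prominence is measured against the higher of the two deepest valleys
    separating the peak from nearer higher terrain, with the trace ends
    treated as open boundaries. Troughs of a trace are
    ``find_peaks(-trace)``.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 1 or trace.size < 3:
        raise ValueError("need a 1-D trace with at least 3 samples")
    idx, _ = _scipy_find_peaks(trace, prominence=min_prominence)
    return idx


def last_window(trace: np.ndarray, dt_ms: float, window_s: float = DEFAULT_WINDOW_S) -> np.ndarray:
    """The final ``window_s`` seconds of a uniformly sampled trace."""
    n = int(round(window_s * 1000.0 / dt_ms))
    if trace.size < n:
        raise ValueError(f"trace shorter than the {window_s:.0f}-s window")
    return np.asarray(trace, dtype=float)[-n:]


def max_hyperpolarization_threshold(trough_values: np.ndarray,
                                    start_mV: float = HYPERPOL_SCAN_START_MV):
    """Integer-mV stepping rule that separates cycle-boundary troughs.

    Starting at −85 mV and stepping by +1 mV, find the first threshold with
    troughs strictly below it. Returns ``(threshold, mask_of_selected)``.
    """
    trough_values = np.asarray(trough_values, dtype=float)
    if trough_values.size == 0:
        raise ValueError("no troughs")
    thr = start_mV
    while not np.any(trough_values < thr):
        thr += 1.0
    return thr, trough_values < thr


def measure_activity(trace: np.ndarray, dt_ms: float = 0.5,
                     window_s: float = DEFAULT_WINDOW_S,
                     min_prominence: float = DEFAULT_PROMINENCE_MV) -> BurstSummary:
    """Measure the six activity features on the last ``window_s`` of ``trace``.

    Cycle boundaries are maximum-hyperpolarization troughs; all features are
    computed per cycle then averaged. Returns a summary flagged unmeasurable
    when fewer than two cycle boundaries exist.
    """
    v = last_window(trace, dt_ms, window_s)
    peaks = find_peaks(v, min_prominence)
    troughs = find_peaks(-v, min_prominence)

    def unmeasurable():
        nanz = {f: np.array([]) for f in BurstSummary.FEATURES}
        return BurstSummary(*(np.nan,) * 6, [], nanz, False, {}, measurable=False)

    if troughs.size == 0 or peaks.size == 0:
        return unmeasurable()

    thr, sel = max_hyperpolarization_threshold(v[troughs])
    bounds = troughs[sel]
    if bounds.size < 3:  # need at least two complete cycles
        return unmeasurable()

    periods, burst_dur, ibi, spike_h, maxhyp, slow_wave, nspikes = ([] for _ in range(7))
    for a, b in zip(bounds[:-1], bounds[1:]):
        period = (b - a) * dt_ms
        cyc_peaks = peaks[(peaks > a) & (peaks < b)]
        cyc_troughs = troughs[(troughs > a) & (troughs < b)]
        spike_troughs = cyc_troughs[~(v[cyc_troughs] < thr)]
        if cyc_peaks.size == 0:
            continue
        hyp = 0.5 * (v[a] + v[b])  # the cycle's bounding troughs
        sw = (v[spike_troughs].mean() - hyp) if spike_troughs.size else 0.0
        sh = v[cyc_peaks].mean() - hyp - sw
        bd = (cyc_peaks[-1] - cyc_peaks[0]) * dt_ms
        periods.append(period)
        burst_dur.append(bd)
        ibi.append(period - bd)
        spike_h.append(sh)
        maxhyp.append(hyp)
        slow_wave.append(sw)
        nspikes.append(int(cyc_peaks.size))

    if len(periods) == 0:
        return unmeasurable()

    per_cycle = {
        "period": np.array(periods),
        "burst_duration": np.array(burst_dur),
        "interburst_interval": np.array(ibi),
        "spike_height": np.array(spike_h),
        "max_hyperpolarization": np.array(maxhyp),
        "slow_wave_amplitude": np.array(slow_wave),
    }
    means = {f: float(per_cycle[f].mean()) for f in BurstSummary.FEATURES}
    rsd = {}
    for f, vals in per_cycle.items():
        mu = np.abs(vals.mean())
        rsd[f] = float(vals.std(ddof=0) / mu) if mu > 0 else 0.0

    # boundary-trough voltages (both ends of every cycle) for the 3-mV rule
    boundary_volts = v[bounds]
    summary = BurstSummary(
        period=means["period"],
        burst_duration=means["burst_duration"],
        interburst_interval=means["interburst_interval"],
        spike_height=means["spike_height"],
        max_hyperpolarization=means["max_hyperpolarization"],
        slow_wave_amplitude=means["slow_wave_amplitude"],
        spikes_per_cycle=nspikes,
        per_cycle=per_cycle,
        regular=False,
        rsd=rsd,
    )
    summary.regular = classify_regular_burster(summary, boundary_volts)
    return summary


def classify_regular_burster(summary: BurstSummary,
                             boundary_trough_volts: Optional[np.ndarray] = None) -> bool:
    """Regular bursting requires, over all measured cycles:

    1. more than one spike per cycle,
    2. all cycle maximum-hyperpolarization voltages within 3 mV of one another,
    3. spikes per cycle varying by no more than 1.
    """
    if not summary.measurable or len(summary.spikes_per_cycle) == 0:
        return False
    ns = np.asarray(summary.spikes_per_cycle)
    if not np.all(ns > 1):
        return False
    hyp = (np.asarray(boundary_trough_volts)
           if boundary_trough_volts is not None
           else summary.per_cycle["max_hyperpolarization"])
    if hyp.max() - hyp.min() > 3.0:
        return False
    return int(ns.max() - ns.min()) <= 1


def current_contributions(currents: np.ndarray):
    """Percentage shares of inward and outward current, per sample.

    ``currents`` is (n_samples, n_currents), positive = outward. Returns
    ``(outward_pct, inward_pct, total_outward, total_inward, undefined)``
    where the pct arrays give each current's share of its polarity's total
    (rows summing to 100 where defined) and ``undefined`` flags all-zero
    frames.
    """
    c = np.asarray(currents, dtype=float)
    out = np.where(c > 0, c, 0.0)
    inw = np.where(c < 0, -c, 0.0)
    tot_out = out.sum(axis=1)
    tot_in = inw.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out_pct = 100.0 * out / tot_out[:, None]
        in_pct = 100.0 * inw / tot_in[:, None]
    undefined = (tot_out == 0) & (tot_in == 0)
    return out_pct, in_pct, tot_out, -tot_in, undefined


def generate_fixture(
    period_ms: float = 416.0,
    spikes_per_cycle: int = 4,
    spike_height: float = 40.0,
    slow_wave: float = 12.0,
    floor: float = -62.0,
    jitter: float = 0.0,
    n_cycles: int = 20,
    dt_ms: float = 0.5,
    burst_fraction: float = 0.45,
    seed: int = 0,
):
    """Deterministic synthetic bursting waveform with known features.

    Each cycle is a raised-cosine slow wave of amplitude ``slow_wave`` on a
    ``floor`` baseline, carrying ``spikes_per_cycle`` triangular spikes whose
    peaks sit ``spike_height`` above the slow-wave plateau. ``jitter`` (ms,
    standard deviation) perturbs cycle onsets. Returns ``(trace, truth)``
    where ``truth`` is a dict of the ground-truth feature values.
    """
    if min(period_ms, spike_height, n_cycles) <= 0 or slow_wave < 0:
        raise ValueError("fixture geometry must be positive")
    burst_ms = burst_fraction * period_ms
    spike_half_ms = 4.0
    if spikes_per_cycle < 1:
        raise ValueError("need at least one spike per cycle")
    if spikes_per_cycle > 1:
        gap = burst_ms / (spikes_per_cycle - 1)
        if gap <= 2 * spike_half_ms:
            raise ValueError("spikes do not fit in the burst")
    rng = np.random.default_rng(seed)

    n = int(round(n_cycles * period_ms / dt_ms)) + 1
    t = np.arange(n) * dt_ms
    v = np.full(n, floor)

    spike_offsets = (
        np.linspace(0.0, burst_ms, spikes_per_cycle)
        if spikes_per_cycle > 1
        else np.array([burst_ms / 2.0])
    )
    plateau_start = 0.12 * period_ms  # burst sits on the slow-wave plateau
    for c in range(n_cycles):
        onset = c * period_ms + (rng.normal(0.0, jitter) if jitter > 0 else 0.0)
        # trapezoidal slow wave: cosine ramps flanking a flat plateau that
        # carries the spikes, so inter-spike troughs sit exactly at
        # floor + slow_wave
        rise_lo = onset + 0.04 * period_ms
        plat_lo = onset + plateau_start - 2 * spike_half_ms
        plat_hi = onset + plateau_start + burst_ms + 2 * spike_half_ms
        fall_hi = onset + 0.88 * period_ms
        m = (t >= rise_lo) & (t < plat_lo)
        v[m] = np.maximum(
            v[m],
            floor + slow_wave * 0.5 * (1 - np.cos(np.pi * (t[m] - rise_lo) / (plat_lo - rise_lo))),
        )
        m = (t >= plat_lo) & (t <= plat_hi)
        v[m] = np.maximum(v[m], floor + slow_wave)
        m = (t > plat_hi) & (t <= fall_hi)
        v[m] = np.maximum(
            v[m],
            floor + slow_wave * 0.5 * (1 + np.cos(np.pi * (t[m] - plat_hi) / (fall_hi - plat_hi))),
        )
        for off in spike_offsets:
            # snap the apex onto the sample grid so the measured peak height
            # equals the nominal one
            center = round((onset + plateau_start + off) / dt_ms) * dt_ms
            mm = np.abs(t - center) <= spike_half_ms
            tri = (1.0 - np.abs(t[mm] - center) / spike_half_ms)
            v[mm] = np.maximum(v[mm], (floor + slow_wave) + spike_height * tri)

    truth = {
        "period": period_ms,
        "burst_duration": burst_ms if spikes_per_cycle > 1 else 0.0,
        "interburst_interval": period_ms - (burst_ms if spikes_per_cycle > 1 else 0.0),
        "spike_height": spike_height,
        "max_hyperpolarization": floor,
        "slow_wave_amplitude": slow_wave,
        "spikes_per_cycle": spikes_per_cycle,
    }
    return v, truth
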