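"""Population assembly, filtering, reference selection, and the
perturbation-recovery experiment.

The pipeline mirrors how a degenerate population of bursters is built and
probed: many seeded assemblies are run; regular bursters are filtered by
slow-wave amplitude and burst period; a reference model is chosen as the one
whose period is most similar to its four nearest neighbours in the sorted
period list; a group is sampled from the reference's neighbourhood; and each
group member is challenged with the elevated-potassium perturbation under
several half-(in)activation timescales.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence

import numpy as np

from . import engine as eng
from .burst_metrics import BurstSummary, measure_activity
from .channels import MembraneParams
from .regulation import RegulationConfig
from .sensors import SensorConfig


@dataclass
class PopulationRecord:
    seed: int
    status: str
    convergence_min: Optional[float]
    summary: Optional[BurstSummary]
    final_state: Optional[np.ndarray]
    slow_wave_pass: Optional[bool] = None
    period_window_pass: Optional[bool] = None
    in_group: bool = False

    @property
    def is_regular(self) -> bool:
        return (
            self.status == "assembled"
            and self.summary is not None
            and self.summary.measurable
            and self.summary.regular
        )


def assemble_population(
    seeds: Sequence[int],
    duration_min: float,
    sensor_cfg: SensorConfig = None,
    reg_cfg: RegulationConfig = None,
    sim_cfg: eng.SimulationConfig = None,
    params_template: MembraneParams = None,
) -> List[PopulationRecord]:
    """Run one assembly per seed and measure the outcome.

    Failures (solver errors, non-convergence, irregular activity) are
    recorded, never raised.
    """
    records = []
    for seed in seeds:
        try:
            res = eng.assemble(seed, duration_min, params_template, sensor_cfg, reg_cfg, sim_cfg)
            summary = measure_activity(res.trajectory.v, (sim_cfg or eng.SimulationConfig()).save_dt_ms)
            status = res.status
            if status == "assembled" and not (summary.measurable and summary.regular):
                status = "irregular"
            records.append(
                PopulationRecord(seed, status, res.convergence_min, summary, res.final_state)
            )
        except (RuntimeError, ValueError) as exc:
            records.append(PopulationRecord(seed, f"failed: {exc}", None, None, None))
    return records


def success_fraction(records: Sequence[PopulationRecord]) -> float:
    if not records:
        return float("nan")
    return sum(r.is_regular for r in records) / len(records)


def filter_and_window(
    records: Sequence[PopulationRecord],
    slow_wave_max: float = 25.0,
    period_window=(380.0, 500.0),
) -> List[PopulationRecord]:
    """Keep regular bursters with slow wave below ``slow_wave_max`` (mV) whose
    mean period lies inside ``period_window`` (ms)."""
    if not records:
        raise ValueError("empty record list")
    out = []
    for r in records:
        if not r.is_regular:
            continue
        r = replace(r)
        r.slow_wave_pass = r.summary.slow_wave_amplitude < slow_wave_max
        r.period_window_pass = period_window[0] <= r.summary.period <= period_window[1]
        if r.slow_wave_pass and r.period_window_pass:
            out.append(r)
    return out


def pick_reference(periods: Sequence[float]) -> int:
    """Index (into the period-sorted order) of the record whose five-record
    neighbourhood (two neighbours each side) has the smallest period range.

    Only positions with two neighbours on each side are eligible; ties go to
    the smallest period. ``periods`` need not be pre-sorted; the returned
    index refers to the sorted order.
    """
    periods = np.asarray(periods, dtype=float)
    n = periods.size
    if n < 5:
        raise ValueError("need at least 5 records to pick a reference")
    order = np.sort(periods)
    best_i, best_range = None, np.inf
    for i in range(2, n - 2):
        rng = order[i + 2] - order[i - 2]
        if rng < best_range - 1e-12:
            best_i, best_range = i, rng
    return best_i


def sample_group(
    records: Sequence[PopulationRecord],
    rng: np.random.Generator,
    expansion: float = 0.20,
    k: int = 20,
    include_reference: bool = True,
):
    """Select the reference and sample the comparison group.

    Records are sorted by period; the reference's five-record period range is
    symmetrically expanded about the reference period by ``expansion``; ``k``
    records (the reference plus ``k``−1 sampled without replacement when
    ``include_reference``) are drawn from those inside the expanded range.
    Returns ``(reference_record, group_records)``.
    """
    recs = sorted(records, key=lambda r: r.summary.period)
    periods = np.array([r.summary.period for r in recs])
    ref_i = pick_reference(periods)
    ref = recs[ref_i]
    p_ref = periods[ref_i]
    lo, hi = periods[ref_i - 2], periods[ref_i + 2]
    half = max(p_ref - lo, hi - p_ref) * (1.0 + expansion)
    n_draw = k - 1 if include_reference else k
    if n_draw > len(recs) - 1:
        raise ValueError(f"only {len(recs)} records for a group of {k}")
    # when the expanded neighbourhood is too sparse, widen it symmetrically to
    # the n-th nearest period so a full group can always be formed
    dist = np.sort(np.abs(periods - p_ref))
    needed = dist[min(int(1.5 * n_draw), len(dist) - 1)]
    half = max(half, needed)
    eligible = [r for r in recs if abs(r.summary.period - p_ref) <= half and r is not ref]
    chosen = list(rng.choice(len(eligible), size=n_draw, replace=False))
    group = ([ref] if include_reference else []) + [eligible[i] for i in sorted(chosen)]
    for r in group:
        r.in_group = True
    return ref, group


@dataclass
class RecoveryCell:
    seed: int
    tau_half_s: float
    recovered: Optional[bool]
    recovery_min: Optional[float]
    summary: Optional[BurstSummary]
    error: Optional[str] = None


def recovery_experiment(
    group: Sequence[PopulationRecord],
    base_params: MembraneParams,
    sensor_cfg: SensorConfig,
    tau_half_conditions: Sequence[float] = (6.0, 600.0, math.inf),
    tau_g_s: float = 600.0,
    duration_min: float = 60.0,
    sim_cfg: eng.SimulationConfig = None,
    gamma: float = 1e-7,
) -> List[RecoveryCell]:
    """Perturb each assembled model and test recovery per τ_half condition.

    Each cell applies the elevated-potassium perturbation to the member's
    assembled state, simulates with regulation active (conductances on
    ``tau_g_s``; shifts on the cell's τ_half), and classifies recovery by the
    smoothed-α criterion with the 5-minute sustain rule. Solver failures are
    recorded per cell without aborting the table.
    """
    sim_cfg = sim_cfg or eng.SimulationConfig(sustain_min=5.0)
    pert_params, pert_sensors = eng.apply_potassium_perturbation(base_params, sensor_cfg)
    cells = []
    for rec in group:
        for tau_half in tau_half_conditions:
            try:
                reg = RegulationConfig(tau_g_s=tau_g_s, tau_half_s=tau_half, gamma=gamma)
                traj = eng.run_simulation(
                    rec.final_state, pert_params, pert_sensors, reg,
                    duration_min * 60_000.0, sim_cfg,
                )
                ok, t_min = eng.detect_convergence(
                    traj.alpha, sim_cfg.save_dt_ms, sim_cfg.alpha_threshold,
                    sim_cfg.alpha_smooth_s, sustain_min=sim_cfg.sustain_min,
                )
                summary = None
                if ok and traj.duration_ms >= 90_000.0:
                    summary = measure_activity(traj.v, sim_cfg.save_dt_ms)
                cells.append(RecoveryCell(rec.seed, tau_half, ok, t_min, summary))
            except (RuntimeError, ValueError) as exc:
                cells.append(RecoveryCell(rec.seed, tau_half, None, None, None, str(exc)))
    return cells


def recovery_counts(cells: Sequence[RecoveryCell]) -> Dict[float, int]:
    """Number of recovered models per τ_half condition."""
    out: Dict[float, int] = {}
    for c in cells:
        out.setdefault(c.tau_half_s, 0)
        if c.recovered:
            out[c.tau_half_s] += 1
    return out
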