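# homeoburst

Homeostatic self-assembly and recovery of a bursting neuron under
dual-timescale regulation of channel density and channel voltage dependence.

Neurons hold stable activity patterns for years while their ion channels
turn over in days. `homeoburst` implements a computational account of how:
a single-compartment, seven-current stomatogastric-style model neuron whose
maximal conductances g̅ᵢ *and* half-(in)activation voltages are adjusted by
feedback from three intracellular-calcium sensors, each mechanism on its own
timescale (τ_g for channel number, default 600 s; τ_half for voltage
dependence, default 6 s — fast like phosphorylation, or slow like subunit
synthesis, or frozen entirely with τ = ∞). The package is for computational
neuroscientists who want to simulate activity-dependent homeostasis: it
bundles the 40-ODE model, the elevated-extracellular-potassium perturbation
protocol, the burst-feature measurement stack, and a population-selection
pipeline, behind both a Python API and a CLI.

## The model in brief

Membrane: C dV/dt = −Σᵢ g̅ᵢ mᵢ^{qᵢ} hᵢ (V−Eᵢ) − g_L(V−E_L), with the classic
seven-current kinetic set (Na, CaT, CaS, H, Kd, KCa, A; exponents
3,3,3,1,4,4,3), Nernstian calcium reversal at 10 °C, and a fast calcium pool
τ_Ca d[Ca]/dt = −f·(I_CaT+I_CaS) − [Ca] + Ca₀.

Control: three calcium sensors F/S/D (spike transients, burst plateau, duty
cycle) are filtered against targets (F̄, S̄, D̄) = (0.25, 0.03, 0.02); the
tolerance-normalized errors ε_X combine into an L⁸ match score whose
threshold gate (ρ = 0.3) drives the activity sensor α ∈ [0,1] (0 = targets
met). Regulation, entirely gated by α:

    dg̅ᵢ/dt = α [ g̅ᵢ (Aᵢ ε_F + Bᵢ ε_S + Cᵢ ε_D)/τ_g − γ g̅ᵢ³ ]
    dVₛ/dt  = α [ (Âᵢ ε_F + B̂ᵢ ε_S + Ĉᵢ ε_D)/τ_half − γ̂ Vₛ³ ]

Activation-shift coefficients are the negatives of the conductance ones;
inactivation shifts reuse them (sodium's inactivation is unregulated). From
sub-nanosiemens random starting conductances the feedback grows a full
bursting repertoire; see `docs/methods.md` for every equation, constant and
calibration decision.

## Worked example

Assemble a burster from seeded random starting parameters under the
desk-scale profile (τ_g = 60 s with the cap-preserving γ = 10⁻⁶), then
measure it:

```python
import math
from homeoburst import engine as eng
from homeoburst.regulation import RegulationConfig
from homeoburst.sensors import SensorConfig
from homeoburst.burst_metrics import measure_activity

res = eng.assemble(seed=1, duration_min=300.0,
                   sensor_cfg=SensorConfig(),
                   reg_cfg=RegulationConfig(tau_g_s=60.0, gamma=1e-6),
                   sim_cfg=eng.SimulationConfig(sustain_min=10.0))
summary = measure_activity(res.trajectory.v)
print(res.status, summary.regular)
print(f"period {summary.period:.0f} ms, "
      f"{max(summary.spikes_per_cycle)} spikes/burst, "
      f"max hyperpolarization {summary.max_hyperpolarization:.1f} mV")
```

prints (seed 1, this package's defaults):

```
assembled True
period 646 ms, 8 spikes/burst, max hyperpolarization -54.8 mV
```

meaning the mechanism grew, from ~0.5 nS random seeds, a regular burster
satisfying the calcium targets (trailing 8-s mean of α below 0.02, held),
with the stated cycle period, spike count and interburst floor. The same
workflows are scriptable from the shell:

```
homeoburst assemble --seed 1 --duration-min 300 --out runs/seed1
homeoburst measure --trace runs/seed1/trajectory.csv
homeoburst perturb --model runs/seed1/trajectory.csv --tau-half 6 --out runs/seed1-pert
```

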