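# Seven-current stomatogastric neuron channel kinetics (the classic
# lobster STG model family).
#
# Units: voltages mV, time constants ms, calcium µM, conductance µS.
#
# Steady-state curves are logistic: x_inf(V) = 1 / (1 + exp((V - vhalf) / k)).
# k < 0 gives an activation curve increasing with V; k > 0 a curve decreasing
# with V (inactivation, and the hyperpolarization-activated H current).
# KCa additionally multiplies its activation by Ca / (Ca + ca_half).
#
# Time-constant curves come in three parametric families:
#   form sigmoid:    tau(V) = c0 - c1 / (1 + exp((V - c2) / c3))
#   form biexp:      tau(V) = c0 + c1 / (exp((V - c2) / c3) + exp((V - c4) / c5))
#   form product:    tau(V) = (c0 / (1 + exp((V - c2) / c3))) * (c1 + 1 / (1 + exp((V - c4) / c5)))
#
# A regulated half-(in)activation shift s translates the whole voltage
# dependence: steady states are evaluated with vhalf + s, taus at V - s.

leak_conductance_uS: 0.01

channels:
  - name: Na
    q: 3
    reversal: 30.0
    activation:
      vhalf: -25.5
      k: -5.29
      tau: {form: sigmoid, coeffs: [2.64, 2.52, -120.0, -25.0]}
    inactivation:
      vhalf: -48.9
      k: 5.18
      tau: {form: product, coeffs: [1.34, 1.5, -62.9, -10.0, -34.9, 3.6]}

  - name: CaT
    q: 3
    reversal: nernst-calcium
    activation:
      vhalf: -27.1
      k: -7.2
      tau: {form: sigmoid, coeffs: [43.4, 42.6, -68.1, -20.5]}
    inactivation:
      vhalf: -32.1
      k: 5.5
      tau: {form: sigmoid, coeffs: [210.0, 179.6, -55.0, -16.9]}

  - name: CaS
    q: 3
    reversal: nernst-calcium
    activation:
      vhalf: -33.0
      k: -8.1
      tau: {form: biexp, coeffs: [2.8, 14.0, -27.0, 10.0, -70.0, -13.0]}
    inactivation:
      vhalf: -60.0
      k: 6.2
      tau: {form: biexp, coeffs: [120.0, 300.0, -55.0, 9.0, -65.0, -16.0]}

  - name: H
    q: 1
    reversal: -20.0
    activation:
      vhalf: -75.0
      k: 5.5
      tau: {form: biexp, coeffs: [0.0, 2.0, -169.7, -11.6, 26.7, 14.3]}

  - name: Kd
    q: 4
    reversal: -80.0
    activation:
      vhalf: -12.3
      k: -11.8
      tau: {form: sigmoid, coeffs: [14.4, 12.8, -28.3, -19.2]}

  - name: KCa
    q: 4
    reversal: -80.0
    activation:
      vhalf: -28.3
      k: -12.6
      ca_half: 3.0
      tau: {form: sigmoid, coeffs: [180.6, 150.2, -46.0, -22.7]}

  - name: A
    q: 3
    reversal: -80.0
    activation:
      vhalf: -27.2
      k: -8.7
      tau: {form: sigmoid, coeffs: [23.2, 20.8, -32.9, -15.2]}
    inactivation:
      vhalf: -56.9
      k: 4.9
      tau: {form: sigmoid, coeffs: [77.2, 58.4, -38.9, -26.5]}

calcium_dynamics:
  # tau_ca * d[Ca]/dt = -f * (I_CaT + I_CaS) - [Ca] + ca_rest
  tau_ca_ms: 20.0
  f_uM_per_nA: 14.96
  ca_rest_uM: 0.05
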