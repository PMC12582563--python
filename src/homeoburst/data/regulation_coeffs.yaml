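# Sensor-to-parameter regulation coefficients, per channel.
#
# conductance: [A, B, C] weights on the tolerance-normalized (target - sensor)
#   mismatches of the fast (F), slow-wave (S) and DC (D) calcium sensors in
#   the maximal-conductance update law.
#
#   The base prescription makes above-target activity lower inward and raise
#   outward conductances (Na loses channels when spike-driven calcium is too
#   high; the A current gains them when slow-wave or mean calcium is too
#   high). Three rows deviate from that pure sign logic, pragmatically, so
#   that the mechanism converges from silent, blocked and tonic states alike:
#   - Kd rides the F mismatch with Na's sign, so the spike-generating and
#     spike-repolarizing conductances grow and shrink together and spikes
#     stay healthy throughout assembly;
#   - KCa grows on a slow-wave deficit (organizing spikes into bursts is what
#     creates slow-wave calcium) while still growing on a DC surplus, which
#     lets it break depolarization block;
#   - H shrinks when the slow wave overshoots, damping over-strong bursting
#     without ever accumulating enough conductance to clamp the membrane.
#
# activation: weights for the activation-curve shift law; the rule is the
#   negatives of the conductance weights.
# inactivation: weights for the inactivation-curve shift law (inactivating
#   channels only); the rule is the conductance weights themselves. Na is an
#   explicit exception with an all-zero row.
#
# Rows that deviate from the shift sign-flip rule are listed under
# `overrides` and are reported by the loader.

conductance:
  Na:  [1, 0, 0]
  CaT: [0, 1, 0]
  CaS: [0, 0, 1]
  H:   [0, -1, 0]
  Kd:  [1, 0, 0]
  KCa: [0, 1, -1]
  A:   [0, -1, -1]

activation:
  Na:  [-1, 0, 0]
  CaT: [0, -1, 0]
  CaS: [0, 0, -1]
  H:   [0, 1, 0]
  Kd:  [-1, 0, 0]
  KCa: [0, -1, 1]
  A:   [0, 1, 1]

inactivation:
  Na:  [0, 0, 0]
  CaT: [0, 1, 0]
  CaS: [0, 0, 1]
  A:   [0, -1, -1]

overrides:
  - "inactivation/Na: zeroed (sodium inactivation is not activity-regulated)"
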