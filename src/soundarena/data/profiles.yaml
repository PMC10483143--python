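# Agent parameter profiles for simulated cohorts.
#
# The "ko" profile emulates the auditory-avoidance phenotype class: silence-
# seeking that switches on ~15 min into the exposure phase and is strong
# enough to lift silent-quadrant occupancy into the mid-40s percent range
# over the whole exposure phase.  The "wt" profile has no sound response.
wt:
  mean_speed_cm_s: 8.0
  speed_shape: 2.0
  turn_sd_rad: 0.25
  avoidance_strength: 0.0
  onset_latency_s: 0.0
ko:
  mean_speed_cm_s: 8.0
  speed_shape: 2.0
  turn_sd_rad: 0.25
  avoidance_strength: 0.6
  onset_latency_s: 900.0
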