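# Reference run: hypothetical solid co-formulant, use-rate maximization
# against a target RCR of 0.9, no PPE.  Expected maximized rates:
# 1.16 kg/ha (tractor group) and 0.768 kg/ha (hand-held group).
substance:
  name: reference co-formulant
  physical_state: solid
  vapour_pressure: 0.001        # Pa
  dnel_worker_dermal: 3.0       # mg/kg bw/day
  dnel_worker_inhalation: 11.0  # mg/m^3
  dnel_general_dermal: 1.5      # mg/kg bw/day
  dnel_general_inhalation: 2.6  # mg/m^3
target_rcr: 0.9
ges: [ges1]
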