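{
  "description": "Per-sensor incremental current draw (mA) when active, reconstructed from the published per-cluster current-reduction accounting; env-temp/humidity symmetry assumed. i_total_mA is the implied full-system draw.",
  "currents_mA": {
    "body_temp": 0.312,
    "env_temp": 0.263,
    "humidity": 0.263,
    "wrist_accel": 0.312,
    "ankle_accel": 2.70,
    "eda": 0.312,
    "hr": 2.673
  },
  "i_total_mA": 9.9455
}
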