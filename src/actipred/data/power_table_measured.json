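{
  "description": "Per-sensor incremental current draw (mA) from bench measurements of the prototype wrist/chest platform (full-function minus sensor-disabled states). Ankle accelerometer uses the chest-accelerometer increment; skin temperature and EDA use the wrist-accelerometer increment. i_total_mA = wrist + chest full-function draw.",
  "currents_mA": {
    "body_temp": 0.32,
    "env_temp": 0.27,
    "humidity": 0.27,
    "wrist_accel": 0.32,
    "ankle_accel": 2.70,
    "eda": 0.32,
    "hr": 2.67
  },
  "i_total_mA": 10.02
}
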