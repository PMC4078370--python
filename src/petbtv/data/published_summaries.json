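{
  "analysis_set_size": 9,
  "table1_mean_cc": {
    "GTV": 41.3,
    "Pre40%": 19.9,
    "Pre50%": 12.1,
    "Post90%": 0.1,
    "Post80%": 0.7,
    "Post70%": 2.9,
    "Post60%": 7.7
  },
  "gtv_range_cc": [22.3, 80.2],
  "table2_mean_pct": {
    "Pre40|Post90": 83.3,
    "Pre40|Post80": 84.0,
    "Pre40|Post70": 83.7,
    "Pre40|Post60": 77.9,
    "Pre50|Post90": 77.8,
    "Pre50|Post80": 69.9,
    "Pre50|Post70": 74.5,
    "Pre50|Post60": 64.8
  },
  "patients_without_full_post90_containment": 2
}
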