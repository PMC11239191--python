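{
  "aux_forces": [],
  "calc": {
    "D_um2_s": 7.1,
    "injection_range_nm": [
      1700.0,
      1700.0
    ],
    "voltages_mV": [
      -2.0,
      -1.0,
      -0.5,
      0.0,
      0.5,
      1.0,
      2.0
    ]
  },
  "entropy": {
    "b_nm": 0.6,
    "delta_nm": 0.001,
    "lt_nm": 0.0,
    "nu": 0.59,
    "tethered": false,
    "use_entropy": true
  },
  "eof": {
    "b_eof": 0.0,
    "m_eof": 9.35
  },
  "pore": {
    "Lp_nm": 2.355
  },
  "schema_version": 1,
  "sequence": {
    "direction": "N_to_C",
    "laa_nm": 34.0,
    "text": "AEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEEX"
  },
  "thermal": {
    "thermal_voltage_mV": 25.693
  }
}
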