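[
  {"kind": "COS_OGSE", "frequency_hz": 25.0, "n_cycles": 1, "delta_ms": 40.0, "Delta_ms": 40.0, "b_s_mm2": 0.0, "group": "25HZ", "effective_diffusion_time_ms": 7.3},
  {"kind": "COS_OGSE", "frequency_hz": 25.0, "n_cycles": 1, "delta_ms": 40.0, "Delta_ms": 40.0, "b_s_mm2": 350.0, "group": "25HZ", "effective_diffusion_time_ms": 7.3},
  {"kind": "COS_OGSE", "frequency_hz": 25.0, "n_cycles": 1, "delta_ms": 40.0, "Delta_ms": 40.0, "b_s_mm2": 710.0, "group": "25HZ", "effective_diffusion_time_ms": 7.3},
  {"kind": "COS_OGSE", "frequency_hz": 40.0, "n_cycles": 2, "delta_ms": 50.0, "Delta_ms": 50.0, "b_s_mm2": 0.0, "group": "40HZ", "effective_diffusion_time_ms": 4.7},
  {"kind": "COS_OGSE", "frequency_hz": 40.0, "n_cycles": 2, "delta_ms": 50.0, "Delta_ms": 50.0, "b_s_mm2": 150.0, "group": "40HZ", "effective_diffusion_time_ms": 4.7},
  {"kind": "COS_OGSE", "frequency_hz": 40.0, "n_cycles": 2, "delta_ms": 50.0, "Delta_ms": 50.0, "b_s_mm2": 315.0, "group": "40HZ", "effective_diffusion_time_ms": 4.7},
  {"kind": "PGSE", "frequency_hz": 0.0, "n_cycles": 0, "delta_ms": 54.3, "Delta_ms": 59.3, "b_s_mm2": 0.0, "group": "PGSE", "effective_diffusion_time_ms": 41.1},
  {"kind": "PGSE", "frequency_hz": 0.0, "n_cycles": 0, "delta_ms": 54.3, "Delta_ms": 59.3, "b_s_mm2": 350.0, "group": "PGSE", "effective_diffusion_time_ms": 41.1},
  {"kind": "PGSE", "frequency_hz": 0.0, "n_cycles": 0, "delta_ms": 54.3, "Delta_ms": 59.3, "b_s_mm2": 710.0, "group": "PGSE", "effective_diffusion_time_ms": 41.1}
]
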