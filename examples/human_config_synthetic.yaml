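# Synthetic example configuration for `clozapk translate` / `clozapk occupancy`.
# The human plasma constants and receptor dissociation constants are invented
# stand-ins: replace them with literature values for real use.
human:
  cl_clo_plasma: 0.7     # L/min, total apparent clearance CL/F
  v_clo_plasma: 500.0    # L
  ka_clo: 0.012          # 1/min
  cl_met_plasma: 0.5     # L/min
  v_met_plasma: 400.0    # L
  fm: 0.5                # fraction of clozapine clearance forming norclozapine
  fu: 0.03               # clozapine plasma unbound fraction
  doses_mg: [200, 300, 400]
receptors:
  receptors:
    - {name: D2,     compound: clozapine,    kd_nm: 120.0, reference: synthetic-example}
    - {name: 5HT2A,  compound: clozapine,    kd_nm: 8.0,   reference: synthetic-example}
    - {name: M1,     compound: clozapine,    kd_nm: 6.0,   reference: synthetic-example}
    - {name: alpha1, compound: clozapine,    kd_nm: 4.0,   reference: synthetic-example}
    - {name: alpha2, compound: clozapine,    kd_nm: 90.0,  reference: synthetic-example}
    - {name: H1,     compound: clozapine,    kd_nm: 2.0,   reference: synthetic-example}
    - {name: D2,     compound: norclozapine, kd_nm: 180.0, reference: synthetic-example}
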