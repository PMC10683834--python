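# Slow-dissociating competitive inhibitor assayed by substrate-initiated
# reactions after full enzyme-inhibitor preincubation.
case_id: slow
params:
  k1: 1.0e+8      # E+S association, 1/M/s
  k_1: 1.0        # ES dissociation, 1/s
  k2: 1000.0      # catalysis, 1/s
  koff: 1.0e-5    # E.I dissociation, 1/s (sweep 1e-5 - 1e3)
  Kd_I: 1.0e-6    # koff/kon, M
  E0: 1.0e-10     # M
grids:
  S: {lo: 1.0e-6, hi: 2.0e-4, n: 8, log: true}
  I: {lo: 5.0e-7, hi: 5.0e-5, n: 8, log: true, prepend_zero: true}
protocol:
  detection_time: 60.0
  initiation: preincubate
  velocity_mode: chord
  max_consumption: 0.02
sweep:
  variable: koff
  values: [1.0e-5, 1.0e-4, 1.0e-3, 1.0e-2, 1.0e-1, 1.0, 1.0e+1, 1.0e+2, 1.0e+3]
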