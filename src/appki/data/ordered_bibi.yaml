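# Compulsory-order ternary-complex (bi-bi) mechanism, dead-end inhibitor
# competitive with the leading substrate A, assayed against substrate B.
case_id: ordered_bibi
params:
  k1: 1.0e+8      # E+A association, 1/M/s
  k_1: 2500.0     # EA dissociation, 1/s  (Ks = 25 uM)
  k2: 1.0e+8      # EA+B association, 1/M/s
  k_2: 400.0      # EAB dissociation, 1/s (KmB = 5 uM)
  kcat: 100.0     # EAB -> E+P+Q, 1/s    (KmA = kcat/k1 = 1 uM)
  Ki: 1.0e-8      # E.I dissociation constant, M
  kon_I: 1.0e+8   # E+I association, 1/M/s
  E0: 1.0e-9      # M
  A_fixed: 2.5e-5 # default fixed [A], M
grids:
  B: {lo: 2.5e-6, hi: 2.0e-4, n: 8, log: true}
  I: {lo: 1.0e-10, hi: 1.0e-8, n: 8, log: true, prepend_zero: true}
protocol:
  detection_time: 60.0
  initiation: co_start
  velocity_mode: instantaneous
  max_consumption: 0.02
sweep:
  variable: A_fixed
  values: [1.0e-7, 3.7e-7, 1.4e-6, 5.2e-6, 1.93e-5, 7.2e-5, 2.68e-4, 1.0e-3]
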