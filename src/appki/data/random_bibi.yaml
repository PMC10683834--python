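# Random-order ternary-complex mechanism: the ordered case mirrored over both
# binding orders, dead-end inhibitor binding every A-site-free enzyme form.
case_id: random_bibi
params:
  k1: 1.0e+8      # A association (E+A and EB+A), 1/M/s
  k_1: 2500.0     # A dissociation, 1/s (Ks = 25 uM on both pathways)
  k2: 1.0e+8      # B association (E+B and EA+B), 1/M/s
  k_2: 400.0      # B dissociation, 1/s
  kcat: 100.0     # EAB -> E+P+Q, 1/s
  Ki: 1.0e-8      # inhibitor dissociation constant, M (binds E and EB)
  kon_I: 1.0e+8   # 1/M/s
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
  values: [1.0e-6, 1.0e-5, 1.0e-4]
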