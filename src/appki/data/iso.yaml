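# Iso-mechanism enzyme: turnover splits into a chemical segment (ES -> F + P)
# and a free-enzyme isomerisation (F <-> E).  The dead-end inhibitor binds the
# free enzyme pool (both isomers E and F) with the same Kd; see package notes
# for why binding both isomers is required to reproduce the Fiso relation.
case_id: iso
params:
  k1: 1.0e+8      # E+S association, 1/M/s
  k_1: 100.0      # ES dissociation, 1/s
  k2: 200.0       # chemical step ES -> F+P, 1/s (Fiso table)
  k_2: 200.0      # reverse chemical step F+P -> ES, 1/M/s (negligible at [P]~0)
  k4: 200.0       # forward isomerisation F -> E, 1/s (Fiso table)
  k_4: 200.0      # reverse isomerisation E -> F, 1/s (Fiso table)
  Kd: 1.0e-8      # inhibitor dissociation constant, M
  kon_I: 1.0e+8   # 1/M/s
  E0: 1.0e-10     # M
  fiso_label: 0.5
grids:
  S: {lo: 2.0e-6, hi: 1.0e-4, n: 8, log: true}
  I: {lo: 1.0e-9, hi: 1.0e-7, n: 8, log: true, prepend_zero: true}
protocol:
  detection_time: 60.0
  initiation: co_start
  velocity_mode: instantaneous
  max_consumption: 0.02
sweep:
  variable: fiso_label
  values: [0.0, 0.1, 0.2, 0.5, 0.7, 1.0]
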