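# Exo-site enzyme: substrate binds a remote recognition surface first
# (encounter complex SE), then isomerises into the catalytically competent
# complex ES.  The active-site inhibitor binds E and SE but not ES.
case_id: exosite
params:
  k1: 1.0e+8      # E+S association (exo-site), 1/M/s
  k_1: 1.0        # SE dissociation, 1/s
  k2: 50.0        # SE -> ES isomerisation, 1/s (sweep 1e6 -> 50)
  k_2: 1.0        # ES -> SE, 1/s
  k3: 1.0e+6      # catalysis ES -> E+P, 1/s (sweep 50 -> 1e6, mirrored: k3 = 5e7/k2)
  Kd: 1.0e-8      # inhibitor dissociation constant (E and SE), M
  kon_I: 1.0e+8   # 1/M/s
  E0: 1.0e-10     # M
grids:
  S: {lo: 2.0e-7, hi: 1.0e-4, n: 8, log: true}
  I: {lo: 1.0e-9, hi: 1.0e-7, n: 8, log: true, prepend_zero: true}
protocol:
  detection_time: 60.0
  initiation: co_start
  velocity_mode: instantaneous
  max_consumption: 0.02
sweep:
  variable: k2
  values: [1.0e+6, 2.3e+5, 5.4e+4, 1.25e+4, 2.9e+3, 6.7e+2, 1.55e+2, 50.0]
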