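# Formal two-site mixed-inhibition mechanism (I binds E with Kd=Kic and the
# ES complex with Kd=Kiu, both dead-end).  Ground-truth generator used to
# calibrate the Dixon / Cornish-Bowden estimators.
case_id: two_site_reference
params:
  k1: 1.0e+8      # E+S association, 1/M/s
  Km: 1.0e-5      # M; k_1 = Km*k1 - kcat
  kcat: 100.0     # 1/s
  Kic: 5.0e-6     # E.I dissociation constant, M
  Kiu: 2.0e-5     # ES.I dissociation constant, M; null = competitive topology
  kon_I: 1.0e+8   # 1/M/s
  E0: 1.0e-12     # M
grids:
  S: {lo: 2.0e-6, hi: 5.0e-5, n: 6, log: true}
  # [I] grid is derived from (Kic, Kiu): 0 plus n_I log points from
  # 0.3*min to 3*max of the bounded constants.
  n_I: 6
protocol:
  detection_time: 60.0
  initiation: co_start
  velocity_mode: instantaneous
  max_consumption: 0.02
sweep:
  variable: Kic
  values: [1.0e-6, 5.0e-6, 2.0e-5, 1.0e-4]
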