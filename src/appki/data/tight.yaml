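# Single-substrate Michaelis-Menten enzyme with a potent competitive
# inhibitor whose depletion by binding breaks the free==total assumption.
case_id: tight
params:
  k1: 2.0e+7        # E+S association, 1/M/s
  k_1: 50.0         # ES dissociation, 1/s
  k2: 50.0          # catalysis, 1/s
  Ki: null          # E.I dissociation constant, M; null = i_over_e*E0/10
                    # so that [I]/Ki = 10 across the potency sweep (0.01-10 nM)
  kon_I: 1.0e+10    # E+I association, 1/M/s (fast enough to equilibrate by 60 s)
  E0: 1.0e-9        # M
  i_over_e: 0.1     # inhibitor-to-enzyme ratio of the central [I]
grids:
  S: {lo: 1.0e-5, hi: 4.0e-4, n: 8, log: true}
  # [I] points as multiples of the central concentration i_over_e*E0,
  # bracketing it two-fold each way; 0 is always prepended.
  I_bracket: [0.5, 0.707, 1.0, 1.414, 2.0]
protocol:
  detection_time: 60.0
  initiation: co_start
  velocity_mode: instantaneous
  max_consumption: null
sweep:
  variable: i_over_e
  values: [10.0, 3.0, 1.0, 0.3, 0.1, 0.03, 0.01, 0.003]
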