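# Cooperator-stable restricted sampling design (derived, synthetic stand-in).
#
# The eight quantities the sensitivity analysis perturbs are drawn from the
# inner quartile range of the fully stable subset of a 3,000-draw
# biofilm-cooperator survey (root seed 7, t_end 20,000, n_stable = 354),
# produced by scripts/calibrate_ranges.py; drawn log-uniform except mu
# (uniform), mirroring the full survey.  Every other quantity is fixed at
# the reference stable-median value.  Cooperator-only draws from this design
# verify as 100% fully stable, so no further narrowing was applied.  The
# initial cheater concentration is fixed at 0 here; the invasion experiment
# overrides it with log-uniform [0.01, 2).
condition: cooperator_stable
ks_coupled_to_S0: true
specs:
  K_S:     {family: loguniform, lo: 0.004187, hi: 0.066683}
  mu:      {family: uniform,    lo: 38.218489, hi: 82.839281}
  S0:      {family: loguniform, lo: 0.205685, hi: 1.095053}
  alpha:   {family: loguniform, lo: 0.026530, hi: 0.394690}
  beta_X:  {family: loguniform, lo: 0.002809, hi: 0.048494}
  delta:   {family: loguniform, lo: 0.031866, hi: 0.355904}
  gamma:   {family: loguniform, lo: 0.191544, hi: 1.059806}
  X1_init: {family: loguniform, lo: 0.052691, hi: 0.770646}
  D:       {family: fixed, value: 0.41712}
  Q:       {family: fixed, value: 0.47026}
  eta:     {family: fixed, value: 0.80704}
  E2_max:  {family: fixed, value: 0.19065}
  X2_max:  {family: fixed, value: 0.23565}
  beta_E:  {family: fixed, value: 0.02042}
  S_init:  {family: fixed, value: 0.14862}
  E1_init: {family: fixed, value: 0.13806}
  E2_init: {family: fixed, value: 0.0}
  X2_init: {family: fixed, value: 0.0}
  X3_init: {family: fixed, value: 0.0}
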