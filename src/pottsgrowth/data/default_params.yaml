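# Default simulation parameters, resolved to lattice units
# (areas in lattice sites, times in Monte Carlo steps, lambda = 1).
# Derived from the AS/tau0/lambda-scaled defaults with AS = 1377 sites,
# tau0 = 225 MCS, with the calibrated temperature and crowding groups
# kBT/(lambda*AS^2) = 2e-5, k*AS^2 = 400; see
# pottsgrowth.params.calibrated_params and docs/methods.md.
kBT: 37.92258
Jcc: 5.978424818138721
Jcm: 10.015139011582814
lam: 1.0
G: 7.0992
k: 0.00021095611110847416
tau0_mean: 225.0
tau0_sd: 5.625
As_mean: 1377.0
As_sd: 34.4
papo_max: 0.0015
rho_half: 0.0010904139433551199
alpha: 1332.936
box_area: 2203200.0
seed: 0
t_max: 9000
apoptosis_enabled: true
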