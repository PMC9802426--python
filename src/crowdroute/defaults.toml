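seed = 0

[geometry]
lambda_g = 1.35
l_a = 1.0
a_ref = 15.0

[diagram]
v0 = 1.012
kappa = 0.017
sigma_eps = 0.15

[perception]
mu = 1.15
sigma = 0.2
beta = 0.33
data_fit_mu = 0.77
data_fit_sigma = 0.3
data_fit_beta = 0.68

[sweep]
n_min = 1
n_max = 30
m = 10000

[dataset]
n_frames = 50000
count_low = 1
count_high = 25
measurement_noise_sd = 0.05
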