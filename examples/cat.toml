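# Cat-like tapered cochlea (the package defaults, written out explicitly).
output_dir = "cochlearhorn-out"

[geometry]
species = "cat"
A_Hz = 456.0
gamma = 0.8
L_mm = 25.0
k0_Pa_per_m = 4.0e9
S0_mm2 = 1.0
b0_mm = 0.1
b1_mm = 0.3
rho_kg_m3 = 1000.0
s_transition_center = 0.6
s_transition_width = 0.1

[micromechanics]
mode = "active"
delta = 0.4
delta_act = -0.55
beta_act = 0.75
w_act = 0.15
beta_r = 1.07

[solver]
n_points = 4096
tol = 1e-6
max_iter = 100

[experiment]
n_sites = 20
cf_min_kHz = 0.2
cf_max_kHz = 10.0
n_ears = 128
roughness_amplitude = 0.01
seed = 0
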