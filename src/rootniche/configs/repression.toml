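# Repression-of-a-mobile-activator model: BRAVO represses the production of
# its own diffusible activator Z; no BRAVO-WOX5 sequestration.

[model]
variant = "repression"
production_mode = "hill"
wox5_self_repression = false
basal_vi_production = false
genotype = "wt"

[params]
alpha = 0.5
k_B = 0.2
n = 2.0
beta = 1.0
k_Z = 1.0
c = 1.0         # repression strength of BRAVO on Z
gamma = 1.0
d_B = 0.1
d_W = 0.1
d_Z = 0.05
D_W = 2.0
D_Z = 12.0
L_QC = 15.0

[solver]
method = "euler"
dt = 0.01
t_final = 1000.0

[grid]
x_min = -400.0
x_max = 400.0
dx = 1.0

[scan]
axis1 = ["beta", 0.1, 10.0]
axis2 = ["c", 0.03, 30.0]
n_points = 15
dt = 0.05
t_final = 300.0
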