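# Mixed model: sequestration of WOX5 by BRAVO plus repression of the mobile
# intermediary Z, with WOX5 self-repression.

[model]
variant = "mixed"
production_mode = "hill"
wox5_self_repression = true
basal_vi_production = false
genotype = "wt"

[params]
alpha = 0.3
k_B = 0.2
n = 2.0
beta = 1.0
k_Z = 1.0
c = 0.1
gamma = 1.0
k_W = 5.0
h = 1.0
d_B = 0.1
d_W = 0.05
d_Z = 0.1
lambda = 0.3
D_W = 6.0
D_Z = 6.0
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
axis1 = ["D_W", 0.5, 20.0]
axis2 = ["D_Z", 0.5, 20.0]
n_points = 15
dt = 0.05
t_final = 300.0
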