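# Immobilization-by-sequestration model, linear activation.
# Default 1D parameter set: all four compatibility observables fall inside
# their experimental ranges, and the boundary-value and Euler routes agree
# to well under 1% on the coarse grid.

[model]
variant = "sequestration"
production_mode = "linear"
wox5_self_repression = false
basal_vi_production = false
genotype = "wt"

[params]
alpha_L = 0.2   # BRAVO production per unit WOX5 (1/time)
gamma = 1.0     # WOX5 production in the QC (conc/time)
d_B = 0.1       # BRAVO degradation (1/time)
d_W = 0.1       # WOX5 degradation (1/time)
lambda = 0.1    # BRAVO-WOX5 sequestration (1/(conc*time))
D_W = 10.0      # WOX5 diffusion (length^2/time)
L_QC = 15.0     # QC length (a.u.)

[solver]
method = "euler"
dt = 0.01
t_final = 1000.0

[grid]
x_min = -400.0
x_max = 400.0
dx = 1.0

[scan]
axis1 = ["lambda", 0.01, 1.0]
axis2 = ["D_W", 2.0, 20.0]
n_points = 15
dt = 0.05
t_final = 300.0
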