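# Mixed model on a 2D pixel-grid root layout with GFP reporters.
# Diffusion coefficients are per species and per compartment (cytoplasm vs
# cell wall, in px^2/time); BRAVO cannot cross walls.  The intermediary Z is
# long-lived and wall-permeable, which carries the activation shootward;
# sequestration plus repression confine it in the wild type.

[model]
variant = "mixed"
production_mode = "hill"
wox5_self_repression = true
basal_vi_production = true
genotype = "wt"

[params]
alpha = 1.0
k_B = 0.1
n = 2.0
beta = 1.0
k_Z = 1.0
c = 1.0
gamma = 1.0
k_W = 5.0
h = 1.0
alpha_0 = 0.02
d_B = 0.1
d_W = 0.1
d_Z = 0.01
lambda = 1.0
L_QC = 15.0

[sim2d]
template = "wildtype"   # wildtype | mutant | small
dt = 0.1
t_end = 3000.0
D_B_cyt = 0.3
D_B_wall = 0.0
D_W_cyt = 1.0
D_W_wall = 0.02
D_Z_cyt = 1.0
D_Z_wall = 0.8
D_GFP_cyt = 0.5
D_GFP_wall = 0.03
d_GFP = 0.1
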