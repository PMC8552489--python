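# Desk-scale variant of the two-region chemotaxis experiment:
# 200-monomer NP, 30 x 30 nm surface, denser kernel schedule.
mode = "mcg"
seed = 1

[np]
n_monomers = 200

[surface]
kind = "two_region"
lx = 30.0
ly = 30.0
rho_high = 0.4
ratio = 0.015625
receptor_model = "monobead_frozen"
lz = 12.0

[assembly]
z_offset = 0.6
xy = [7.5, 15.0]

[integrator]
dt = 0.02
temperature = 300.0
gamma = 1.0

[metad]
cv = "com_xy"
height = 20.0
widths = [1.0, 1.0]
stride = 250
log_stride = 50
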