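# Full-size minimalistic model: 1925-monomer NP on a two-region surface
# with a 64-fold receptor-density contrast, biased by MetaD on the COM (x, y).
mode = "mcg"
seed = 1

[np]
n_monomers = 1925
n_guests = 12

[surface]
kind = "two_region"
lx = 40.0
ly = 40.0
rho_high = 1.0
ratio = 0.015625
receptor_model = "monobead_frozen"
lz = 20.0

[assembly]
z_offset = 0.8
xy = [10.0, 20.0]

[integrator]
dt = 0.02
temperature = 300.0
gamma = 1.0

[metad]
cv = "com_xy"
height = 20.0
widths = [1.0, 1.0]
stride = 5000
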