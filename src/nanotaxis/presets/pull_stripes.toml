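# Full-scale rolling/exfoliation layout: 44-oligomer NP pulled by a constant
# COM force along a 120 x 30 nm gradient surface (0 / 0.12 / 0.52 / 1.12
# receptors/nm^2 stripes), with the COM z-wall at 5 nm.
mode = "fcg"
seed = 1

[np]
n_oligomers = 44
n_guests = 10
n_charged_heads = 3

[surface]
kind = "stripes"
stripe_densities = [0.0, 0.12, 0.52, 1.12]
stripe_lx = 30.0
ly = 30.0
receptor_model = "tribead_tethered"
head_charge = 1.0
lz = 15.0

[assembly]
z_offset = 0.8
neutralize = true
xy = [8.0, 15.0]

[integrator]
dt = 0.02
temperature = 300.0
gamma = 1.0

[external]
group = "np"
vector = [100.0, 0.0, 0.0]

[restraint]
z0 = 5.0
kappa = 150.0
exp = 2
group = "np"
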