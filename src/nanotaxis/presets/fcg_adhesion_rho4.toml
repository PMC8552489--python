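# Static adhesion of the trivalent 44-oligomer assembly on the densest
# uniform surface (1 charged group / nm^2, 20 x 20 nm).
mode = "fcg"
seed = 1

[np]
n_oligomers = 44
n_guests = 10
n_charged_heads = 3

[surface]
kind = "uniform"
lx = 20.0
ly = 20.0
rho = 1.0
receptor_model = "tribead_tethered"
head_charge = 1.0
lz = 15.0

[assembly]
z_offset = 0.8
neutralize = true

[integrator]
dt = 0.02
temperature = 300.0
gamma = 1.0
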