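# Multiple-walker MetaD of the oligomer assembly on a gradient surface,
# desk-scale analogue of the 36-walker shared-bias exploration.
mode = "fcg"
seed = 1

[np]
n_oligomers = 12
n_guests = 0
n_charged_heads = 1

[surface]
kind = "stripes"
stripe_densities = [0.0, 0.12, 0.52, 1.12]
stripe_lx = 8.0
ly = 10.0
receptor_model = "tribead_tethered"
head_charge = 1.0
lz = 12.0

[assembly]
z_offset = 0.8
neutralize = true
xy = [4.0, 5.0]

[integrator]
dt = 0.02
temperature = 300.0
gamma = 1.0

[metad]
cv = "com_xy"
height = 1.2
widths = [0.1, 0.1]
stride = 500
log_stride = 50
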