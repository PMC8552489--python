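# 1D double-well toy used to validate the infrequent-MetaD kinetics
# pipeline against brute-force mean first-passage times.
mode = "toy1d"
seed = 1

[toy]
barrier = 10.0
a = 0.5
mass = 72.0
gamma = 1.0

[integrator]
dt = 0.02
temperature = 300.0
gamma = 1.0

[metad]
cv = "com_xy"
height = 0.5
widths = [0.15]
stride = 1000
bias_factor = 10.0
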