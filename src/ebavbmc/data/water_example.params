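# Example Vashishta-form water parameter set (eV, Angstrom, elementary charges).
# Tuned so that an isolated monomer relaxes to O-H = 0.960 A and
# H-O-H = 104.4 deg (E_monomer = -3.157 eV) and the water dimer is
# bound by ~0.25 eV. This is an illustrative parameterization for
# exercising the sampler end-to-end, NOT an optimized literature set;
# load your own file for production work.
H_OO = 300.0
H_OH = 0.295717
H_HH = 0.2
eta_OO = 9.0
eta_OH = 7.0
eta_HH = 9.0
Z_O = -0.659
Z_H = 0.3295
D_OO = 0.1
D_OH = 0.05
D_HH = 0.0
W_OO = 1.0
W_OH = 0.0
W_HH = 0.0
r1s = 4.43
r4s = 2.5
rc = 6.0
B_HOH = 30.0
xi = 1.0
r0 = 1.6
cos_theta0 = -0.099568
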