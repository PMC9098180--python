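# coarse-grained duplex model parameters
k_bond = 50
r0_ps = 3.988
r0_sb = 4
r0_sp3 = 3.988
k_angle = 20
theta0_psp = 0
theta0_sps = 0
k_base_angle = 3
theta0_psb = 0
k_dihedral = 8
phi0_psps = 10
phi0_spsp = 10
d_at = 3.5
d_gc = 5
morse_a = 1.8
pair_r0 = 3.4641
pair_cutoff = 5.5
d_stack = 1.6
stack_a = 1.6
stack_r0 = 3.6177
d_basephos = 1.2
basephos_a = 2.2
basephos_r0 = 3.4
ev_epsilon = 20
ev_sigma = 2.5
rise = 3.4
twist_deg = 36
r_base = 2
r_sugar = 6
r_phos = 8.8
attach_deg = 60
p_offset_deg = 18
p_offset_z = 1.7
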