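# Default half thick-filament model: the full-filament-overlap parameter set.
# Flat key-value config; every field of the geometry types is exposed.
head_seed: 0
head_n_spheres: 68
head_radius: 0.72
regular_eps_head1: 2.0
regular_eps_head2: 26.0
regular_r_h: 9.8
regular_length: 215.0
perturbed_eps_head1: -13.0
perturbed_eps_head2: 15.0
perturbed_r_h: 12.7
perturbed_length: 516.0
phi1: 3.0
phi2: 50.0
phi3: 123.0
axial_sep1: 10.84
axial_sep2: 14.94
axial_sep3: 17.24
backbone_radius: 7.0
cprotein_enabled: true
cprotein_repeat: 45.33
cprotein_n_domains: 11
cprotein_bead_diameter: 4.0
cprotein_n_anchored: 3
cprotein_bend_after: 5
cprotein_bend_angle: 90.0
cprotein_anchor_radius: 7.0
cprotein_sigma_proj: 1.0
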