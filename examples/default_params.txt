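# reedcarbon model parameters
pac_init = 103.0
pbc_init = 1650.0
carrya_max = 2450.0
depth_opt = 0.8
waterdepth_max = 1.8
k_co2 = 300.0
k_rad = 6.0
theta_photo = 1.09
theta_respb = 1.09
theta_respa = 1.07
theta_transfer = 1.07
theta_react = 1.07
theta_mortal_a = 1.05
theta_mortal_b = 1.05
theta_decay = 1.05
t_ref = 20.0
transratio = 0.2
reratio = 0.005
mrespiratio_pa = 0.005
mrespiratio_pb = 0.005
mortalrate_pa = 0.001
decayrate_pa = 0.005
mortalrate_pb = 0.001
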