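n_pairs: 2
nodes_per_arm: 48
k_spring: 100.0
k_bend: 25.0
k_pair: 20.0
k_confine: 100.0
k_tether: 100.0
friction: 1.0
kBT: 1.0
dt: 0.002
nucleus_radius: 24.0
rabl_patch_radius: 5.0
capture_radius: 1.0
p_unpair: 0.8
rest_length: 1.0
n_steps: 50000
record_every: 500
burn_in_steps: 5000
seed: 7
length_unit_um: 0.2
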