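# Two-prophage induction profile: expected virion read shares 97% and 0.8%
# with ~2.2% host background. induction_weight is an event (burst) rate;
# reads are sampled proportionally to molecule length, so weights are set
# to percent/(length - read_len + 1) to realise the read shares.
seed = 1

[simulate]
n_molecules = 100000
host_read_share = 0.022
host_fragment_len = 5000

[simulate.host]
id = "host"
length_bp = 3000000
gc_fraction = 0.665

[[simulate.prophages]]
id = "mge2"
length_bp = 40000
attb_pos = 1000000
packaging_mode = "excised_circle"
induction_weight = 2.4310167664970805

[[simulate.prophages]]
id = "mge8"
length_bp = 35000
attb_pos = 2000000
packaging_mode = "excised_circle"
induction_weight = 0.02292197931291367

[reads]
read_len = 100
n_reads = 100000
error_rate = 0.001
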