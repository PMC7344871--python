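# Five-prophage induction profile spanning four orders of magnitude:
# expected virion read shares 52 / 6.6 / 0.1 / 35.5 / 0.026 % with ~2% host
# background. Weights are percent/(length - read_len + 1) (see
# induction_two_phage.toml).
seed = 1

[simulate]
n_molecules = 300000
host_read_share = 0.02
host_fragment_len = 5000

[simulate.host]
id = "host"
length_bp = 6000000
gc_fraction = 0.665

[[simulate.prophages]]
id = "mge3"
length_bp = 40000
attb_pos = 800000
packaging_mode = "excised_circle"
induction_weight = 1.3032254830705996

[[simulate.prophages]]
id = "mge4"
length_bp = 62000
attb_pos = 1800000
packaging_mode = "excised_circle"
induction_weight = 0.10662186394403968

[[simulate.prophages]]
id = "mge5"
length_bp = 35000
attb_pos = 2800000
packaging_mode = "excised_circle"
induction_weight = 0.0028652474141142087

[[simulate.prophages]]
id = "mge8"
length_bp = 46000
attb_pos = 3800000
packaging_mode = "excised_circle"
induction_weight = 0.7734036295505544

[[simulate.prophages]]
id = "mge13"
length_bp = 10000
attb_pos = 4800000
packaging_mode = "excised_circle"
induction_weight = 0.002625997374002626

[reads]
read_len = 100
n_reads = 300000
error_rate = 0.001
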