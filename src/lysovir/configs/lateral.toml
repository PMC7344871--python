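# Lateral-transduction scenario: one 46-kb pac-type prophage packaging in
# situ off its left (attL) flank from a pac site 16 kb inside the prophage,
# up to 4 headfuls with geometric continuation 0.5, ~2% host-read background.
seed = 1

[simulate]
n_molecules = 30000
host_read_share = 0.02
host_fragment_len = 5000

[simulate.host]
id = "host"
length_bp = 450000
gc_fraction = 0.665

[[simulate.prophages]]
id = "mge8"
length_bp = 46000
attb_pos = 250000
orientation = "-"
pac_offset_bp = 16000
packaging_mode = "headful_in_situ"
induction_weight = 1.0
in_situ_prob = 0.5
max_headfuls = 4
continuation_prob = 0.5

[reads]
read_len = 100
n_reads = 200000
error_rate = 0.001

[staircase]
target_prophage = "mge8"
flank_bp = 195000
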