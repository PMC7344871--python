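# Null scenario: the same prophage packages only from the excised circle
# (no in-situ headfuls), so no staircase exists and detection must be
# negative.
seed = 1

[simulate]
n_molecules = 4000
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
packaging_mode = "excised_circle"
induction_weight = 1.0
in_situ_prob = 0.0
max_headfuls = 1
continuation_prob = 0.0

[reads]
read_len = 100
n_reads = 20000
error_rate = 0.001

[staircase]
target_prophage = "mge8"
flank_bp = 195000
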