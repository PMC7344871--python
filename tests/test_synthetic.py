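"""Simulator unit and property tests: host generation, lysogen assembly,
virion packaging geometry, and read sampling."""
import io

import numpy as np
import pytest

from lysovir import _seq, synthetic
from lysovir.synthetic import (
    HEADFUL_IN_SITU,
    ProphageSpec,
    build_lysogen,
    generate_host,
    molecules_to_reads,
    simulate_virions,
)


class TestGenerateHost:
    def test_length_and_alphabet(self):
        g = generate_host(100_000, 0.665, seed=1)
        assert len(g) == 100_000
        assert set(g.sequence) <= set("ACGT")

    def test_gc_content_close_to_requested(self):
        g = generate_host(100_000, 0.665, seed=1)
        assert abs(_seq.gc_fraction(g.sequence) - 0.665) < 0.01

    def test_default_gc_is_high_gc_pseudomonad(self):
        import inspect

        sig = inspect.signature(generate_host)
        assert sig.parameters["gc_fraction"].default == 0.665

    def test_seeded_reproducibility(self):
        assert generate_host(5000, 0.5, seed=7).sequence == generate_host(5000, 0.5, seed=7).sequence
        assert generate_host(5000, 0.5, seed=7).sequence != generate_host(5000, 0.5, seed=8).sequence

    @pytest.mark.parametrize("bad", [0, -10])
    def test_nonpositive_length_rejected(self, bad):
        with pytest.raises(ValueError):
            generate_host(bad, 0.5, seed=1)


class TestBuildLysogen:
    def test_empty_spec_list_is_identity(self, small_host):
        lys = build_lysogen(small_host, [], seed=1)
        assert lys.genome.sequence == small_host.sequence
        assert lys.placements == []

    def test_insertion_arithmetic(self, small_host):
        spec = ProphageSpec(id="p", length_bp=46_000, attb_pos=50_000)
        lys = build_lysogen(small_host, [spec], seed=1)
        assert len(lys.genome) == 146_000
        (pid, attl, attr), = lys.placements
        assert attr - attl == 46_000

    def test_att_core_duplicated_at_both_junctions(self, small_lysogen):
        core = small_lysogen.att_site_seq
        assert core == "ATCACCATGCAGTT"
        (_, attl, attr), = small_lysogen.placements
        seq = small_lysogen.genome.sequence
        assert seq[attl : attl + len(core)] == core
        assert seq[attr : attr + len(core)] == core

    def test_multiple_prophages_sorted_and_shifted(self, small_host):
        specs = [
            ProphageSpec(id="b", length_bp=12_000, attb_pos=70_000),
            ProphageSpec(id="a", length_bp=10_000, attb_pos=20_000),
        ]
        lys = build_lysogen(small_host, specs, seed=1)
        assert [p[0] for p in lys.placements] == ["a", "b"]
        assert lys.placements[0][1] == 20_000
        assert lys.placements[1][1] == 70_000 + 10_000  # shifted by prophage a
        assert len(lys.genome) == 100_000 + 22_000

    def test_overlapping_insertions_rejected(self, small_host):
        specs = [
            ProphageSpec(id="a", length_bp=10_000, attb_pos=20_000),
            ProphageSpec(id="b", length_bp=10_000, attb_pos=20_005),
        ]
        with pytest.raises(ValueError, match="overlap"):
            build_lysogen(small_host, specs, seed=1)


class TestProphageSpecValidation:
    def test_pac_offset_must_be_inside(self):
        with pytest.raises(ValueError):
            ProphageSpec(id="p", length_bp=10_000, attb_pos=0, pac_offset_bp=10_000)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            ProphageSpec(id="p", length_bp=10_000, attb_pos=0, induction_weight=-1)


class TestSimulateVirions:
    def test_no_in_situ_means_no_chromosomal_bases(self, small_host):
        spec = ProphageSpec(
            id="p", length_bp=46_000, attb_pos=50_000,
            packaging_mode=HEADFUL_IN_SITU, in_situ_prob=0.0,
        )
        lys = build_lysogen(small_host, [spec], seed=1)
        attl, attr = lys.placement("p")
        mols = simulate_virions(lys, [spec], 500, host_contamination_frac=0.0, seed=2)
        for m in mols:
            for s, e in m.intervals:
                assert attl <= s and e <= attr

    def test_headful_one_contains_thirty_kb_of_chromosome(self, small_lysogen, lt_spec):
        """pac 16 kb inside a 46-kb prophage -> headful 1 carries exactly
        30 kb of chromosome adjacent to attL."""
        mols = simulate_virions(small_lysogen, [lt_spec], 2000, 0.0, seed=3)
        attl, _ = small_lysogen.placement("p1")
        h1 = [m for m in mols if m.headful_index == 1 and not m.truncated]
        assert h1
        for m in h1:
            (s, e), = m.intervals
            assert e - s == 46_000
            chromosomal = attl - s
            assert chromosomal == 30_000
            assert s == attl - 30_000  # immediately adjacent to attL

    def test_headful_conservation(self, small_lysogen, lt_spec):
        mols = simulate_virions(small_lysogen, [lt_spec], 1000, 0.0, seed=4)
        for m in mols:
            if m.kind == "headful" and not m.truncated:
                assert m.span == lt_spec.length_bp

    def test_geometric_continuation_rate(self, small_host):
        """Fraction of in-situ series reaching headful 2 matches the
        geometric continuation probability."""
        spec = ProphageSpec(
            id="p", length_bp=10_000, attb_pos=80_000, orientation="-",
            pac_offset_bp=4000, packaging_mode=HEADFUL_IN_SITU,
            in_situ_prob=1.0, max_headfuls=4, continuation_prob=0.5,
        )
        lys = build_lysogen(small_host, [spec], seed=1)
        mols = simulate_virions(lys, [spec], 10_000, 0.0, seed=5)
        n_series = len({m.series_index for m in mols})
        n_multi = len({m.series_index for m in mols if m.headful_index == 2})
        assert n_series == 10_000
        assert abs(n_multi / n_series - 0.5) < 0.02

    def test_orientation_plus_packages_right_of_attr(self, small_host):
        spec = ProphageSpec(
            id="p", length_bp=20_000, attb_pos=30_000, orientation="+",
            pac_offset_bp=5000, packaging_mode=HEADFUL_IN_SITU,
            in_situ_prob=1.0, max_headfuls=1,
        )
        lys = build_lysogen(small_host, [spec], seed=1)
        attl, attr = lys.placement("p")
        mols = simulate_virions(lys, [spec], 50, 0.0, seed=6)
        for m in mols:
            (s, e), = m.intervals
            assert s == attr - 5000
            assert e == attr + 15_000

    def test_truncation_flagged_on_linear_reference(self, small_host):
        spec = ProphageSpec(
            id="p", length_bp=46_000, attb_pos=20_000, orientation="-",
            pac_offset_bp=16_000, packaging_mode=HEADFUL_IN_SITU,
            in_situ_prob=1.0, max_headfuls=1,
        )
        lys = build_lysogen(small_host, [spec], seed=1)
        mols = simulate_virions(lys, [spec], 20, 0.0, seed=7)
        # headful 1 would reach attL-30000 = -10000 on a linear reference
        assert all(m.truncated for m in mols)
        assert all(m.intervals[0][0] == 0 for m in mols)

    def test_circular_reference_wraps(self):
        host = synthetic.generate_host(60_000, 0.5, seed=1, circular=True)
        spec = ProphageSpec(
            id="p", length_bp=20_000, attb_pos=10_000, orientation="-",
            pac_offset_bp=5000, packaging_mode=HEADFUL_IN_SITU,
            in_situ_prob=1.0, max_headfuls=1,
        )
        lys = build_lysogen(host, [spec], seed=1)
        mols = simulate_virions(lys, [spec], 20, 0.0, seed=8)
        for m in mols:
            assert not m.truncated
            assert m.span == 20_000
            assert len(m.intervals) == 2  # wraps the origin

    def test_all_zero_weights_rejected(self, small_lysogen):
        spec = ProphageSpec(id="p1", length_bp=46_000, attb_pos=50_000, induction_weight=0.0)
        with pytest.raises(ValueError, match="weights"):
            simulate_virions(small_lysogen, [spec], 10, 0.0, seed=1)


class TestMoleculesToReads:
    def test_zero_reads_gives_empty_outputs(self, small_lysogen, lt_spec, tmp_path):
        mols = simulate_virions(small_lysogen, [lt_spec], 10, 0.0, seed=1)
        rs = molecules_to_reads(mols, small_lysogen, 100, 0, seed=1)
        assert len(rs) == 0
        rs.to_fastq(tmp_path / "empty.fastq")
        assert (tmp_path / "empty.fastq").read_text() == ""
        assert len(rs.truth) == 0

    def test_error_free_reads_are_exact_substrings(self, small_lysogen, lt_spec):
        mols = simulate_virions(small_lysogen, [lt_spec], 200, 0.02, seed=2)
        rs = molecules_to_reads(mols, small_lysogen, 100, 500, error_rate=0.0, seed=3)
        genome = small_lysogen.genome.sequence
        for name, seq, (_, row) in zip(rs.names, rs.sequences(), rs.truth.iterrows()):
            if row.lysogen_start >= 0:
                window = genome[row.lysogen_start : row.lysogen_start + 100]
                expected = window if row.strand == "+" else _seq.revcomp(window)
                assert seq == expected

    def test_multinomial_read_fractions_match_weights(self, small_host):
        """Two equal-length prophages weighted 97:0.8 yield per-source read
        counts within 3 multinomial s.d. of expectation."""
        specs = [
            ProphageSpec(id="a", length_bp=20_000, attb_pos=20_000, induction_weight=0.97),
            ProphageSpec(id="b", length_bp=20_000, attb_pos=60_000, induction_weight=0.008),
        ]
        lys = build_lysogen(small_host, specs, seed=1)
        mols = simulate_virions(lys, specs, 100_000, 0.0, seed=2)
        n = 100_000
        rs = molecules_to_reads(mols, lys, 100, n, seed=3)
        counts = rs.truth.source.value_counts()
        exp = synthetic.expected_read_fractions(specs, 0.0, 5000, 100)
        for src in ("a", "b"):
            p = exp[src]
            sd = (n * p * (1 - p)) ** 0.5
            assert abs(counts.get(src, 0) - n * p) < 3 * sd

    def test_truth_row_count_equals_read_count(self, small_lysogen, lt_spec):
        mols = simulate_virions(small_lysogen, [lt_spec], 100, 0.0, seed=1)
        rs = molecules_to_reads(mols, small_lysogen, 100, 777, seed=2)
        assert len(rs.truth) == len(rs) == 777

    def test_byte_identical_under_fixed_seed(self, small_lysogen, lt_spec, tmp_path):
        mols = simulate_virions(small_lysogen, [lt_spec], 100, 0.02, seed=9)
        outs = []
        for run in ("x", "y"):
            rs = molecules_to_reads(mols, small_lysogen, 100, 300, 0.01, seed=42)
            fq = tmp_path / f"{run}.fastq"
            tt = tmp_path / f"{run}.tsv"
            rs.to_fastq(fq)
            rs.write_truth(tt)
            outs.append((fq.read_bytes(), tt.read_bytes()))
        assert outs[0] == outs[1]

    def test_short_molecules_skipped(self, small_lysogen, lt_spec):
        mols = simulate_virions(small_lysogen, [lt_spec], 50, 0.5,
                                host_fragment_len=50, seed=1)
        rs = molecules_to_reads(mols, small_lysogen, 100, 200, seed=2)
        assert set(rs.truth.source) == {"p1"}  # 50-bp host fragments skipped

    def test_fastq_round_trip(self, small_lysogen, lt_spec, tmp_path):
        mols = simulate_virions(small_lysogen, [lt_spec], 50, 0.0, seed=1)
        rs = molecules_to_reads(mols, small_lysogen, 80, 40, seed=2)
        rs.to_fastq(tmp_path / "r.fastq")
        back = synthetic.ReadSet.from_fastq(tmp_path / "r.fastq")
        assert back.sequences() == rs.sequences()
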