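"""Exact seed-and-extend read mapping and per-base coverage.

The mapper is deliberately simple and fully deterministic: reads are mapped
by exact k-mer seeds (disjoint seed offsets, pigeonhole-complete for up to
``max_mismatch`` substitutions when ``read_len >= (max_mismatch+1)*k``)
followed by full-length verification counting substitutions. Among equally
good placements the lowest coordinate wins, and '+' beats '-' at the same
coordinate, so runs need no random state.

Externally produced alignments can substitute: a minimal single-segment SAM
dialect is written, and coverage can be built from any SAM file or bedGraph.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import _seq
from .synthetic import GenomeRecord, ReadSet


@dataclass
class Alignment:
    read_id: str
    ref_id: str
    start: int
    strand: str
    matched: bool
    n_mismatches: int = 0
    read_len: int = 0
    has_n: bool = False


@dataclass
class CoverageTrack:
    """Per-base read depth over one named reference."""

    ref_id: str
    depth: np.ndarray

    def __len__(self) -> int:
        return len(self.depth)

    def write_bedgraph(self, path: str | Path) -> None:
        """Write 0-based half-open bedGraph with equal-value runs merged
        (zero runs included, so the track round-trips exactly)."""
        d = self.depth
        change = np.flatnonzero(np.diff(d)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [len(d)]])
        with open(path, "w") as fh:
            for s, e in zip(starts, ends):
                fh.write(f"{self.ref_id}\t{s}\t{e}\t{int(d[s])}\n")

    @classmethod
    def read_bedgraph(cls, path: str | Path, ref_length: int | None = None) -> "CoverageTrack":
        chroms, starts, ends, vals = [], [], [], []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("track", "#", "browser")):
                    continue
                c, s, e, v = line.split("\t")
                chroms.append(c)
                starts.append(int(s))
                ends.append(int(e))
                vals.append(int(float(v)))
        if not chroms:
            raise ValueError("empty bedGraph")
        if len(set(chroms)) != 1:
            raise ValueError("bedGraph must describe a single reference")
        n = ref_length if ref_length is not None else max(ends)
        depth = np.zeros(n, dtype=np.int64)
        for s, e, v in zip(starts, ends, vals):
            depth[s:e] = v
        return cls(ref_id=chroms[0], depth=depth)


class KmerIndex:
    """Sorted-array k-mer index over the forward strand of a reference."""

    def __init__(self, reference: GenomeRecord, k: int = 21):
        if k < 1 or k > 31:
            raise ValueError("k must be in [1, 31]")
        self.reference = reference
        self.k = k
        codes = _seq.encode(reference.sequence)
        self.n = len(codes)
        if reference.circular:
            # extend so windows crossing the origin exist in the index
            self.codes = np.concatenate([codes, codes[: self.n - 1]])
        else:
            self.codes = codes
        self.kmers, self.valid_starts = self._kmerize(self.codes, k)
        order = np.argsort(self.kmers, kind="stable")
        self.sorted_kmers = self.kmers[order]
        self.sorted_pos = self.valid_starts[order]

    @staticmethod
    def _kmerize(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
        n = len(codes)
        if n < k:
            return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64)
        km = np.zeros(n - k + 1, dtype=np.int64)
        bad = np.zeros(n - k + 1, dtype=bool)
        for j in range(k):
            col = codes[j : j + n - k + 1]
            km = km * 4 + np.where(col < 4, col, 0)
            bad |= col >= 4
        starts = np.arange(n - k + 1, dtype=np.int64)
        return km[~bad], starts[~bad]

    def candidates(self, kmer: int) -> np.ndarray:
        lo = np.searchsorted(self.sorted_kmers, kmer, side="left")
        hi = np.searchsorted(self.sorted_kmers, kmer, side="right")
        return self.sorted_pos[lo:hi]


def _seed_offsets(read_len: int, k: int, max_mismatch: int) -> list[int]:
    n_seeds = min(max_mismatch + 1, read_len // k)
    return [i * k for i in range(max(n_seeds, 1))]


def map_reads(
    reads: ReadSet,
    reference: GenomeRecord,
    k: int = 21,
    max_mismatch: int = 2,
    index: KmerIndex | None = None,
) -> list[Alignment]:
    """Map every read; unmapped reads appear with matched=False.

    Reads containing N are reported unmapped with ``has_n`` set.
    """
    if reads.read_len < k:
        raise ValueError("k must not exceed the read length")
    idx = index if index is not None else KmerIndex(reference, k)
    n_ref = idx.n
    ext = idx.codes  # extended for circular references
    rl = reads.read_len
    offsets = _seed_offsets(rl, k, max_mismatch)
    n_reads = len(reads.names)
    circular = reference.circular

    fwd = reads.seq_matrix
    rev = _seq._COMP[fwd][:, ::-1]
    has_n = np.any(fwd >= 4, axis=1) if n_reads else np.zeros(0, dtype=bool)

    # batch seed-kmer lookup: for each strand and seed offset, one
    # searchsorted over all reads at once
    lookups: list[tuple[int, int, np.ndarray, np.ndarray]] = []
    for strand_rank, mat in enumerate((fwd, rev)):
        safe = np.where(mat < 4, mat, 0).astype(np.int64)
        for off in offsets:
            kmers = np.zeros(n_reads, dtype=np.int64)
            for j in range(k):
                kmers = kmers * 4 + safe[:, off + j]
            lo = np.searchsorted(idx.sorted_kmers, kmers, side="left")
            hi = np.searchsorted(idx.sorted_kmers, kmers, side="right")
            lookups.append((strand_rank, off, lo, hi))

    sorted_pos = idx.sorted_pos
    out: list[Alignment] = []
    for r in range(n_reads):
        name = reads.names[r]
        if has_n[r]:
            out.append(Alignment(name, reference.id, -1, "+", False, read_len=rl, has_n=True))
            continue
        best: tuple[int, int, int] | None = None  # (mm, start, strand_rank)
        queries = (fwd[r], rev[r])
        seen: tuple[set[int], set[int]] = (set(), set())
        for strand_rank, off, lo, hi in lookups:
            if lo[r] == hi[r]:
                continue
            query = queries[strand_rank]
            for pos in sorted_pos[lo[r] : hi[r]]:
                start = int(pos) - off
                if start < 0:
                    if circular:
                        start += n_ref
                    else:
                        continue
                if not circular and start + rl > n_ref:
                    continue
                if circular and start >= n_ref:
                    start -= n_ref
                if start in seen[strand_rank]:
                    continue
                seen[strand_rank].add(start)
                window = ext[start : start + rl]
                if len(window) < rl:  # circular tail
                    window = np.concatenate([window, ext[: rl - len(window)]])
                mm = int(np.count_nonzero(window != query))
                if mm <= max_mismatch:
                    cand = (mm, start, strand_rank)
                    if best is None or cand < best:
                        best = cand
        if best is None:
            out.append(Alignment(name, reference.id, -1, "+", False, read_len=rl))
        else:
            mm, start, strand_rank = best
            out.append(
                Alignment(name, reference.id, start, "+-"[strand_rank], True, mm, rl)
            )
    return out


def mapping_stats(alignments: list[Alignment]) -> dict[str, int]:
    mapped = sum(a.matched for a in alignments)
    with_n = sum(a.has_n for a in alignments)
    return {
        "total": len(alignments),
        "mapped": mapped,
        "unmapped": len(alignments) - mapped,
        "with_n": with_n,
    }


def coverage_from_alignments(
    alignments: list[Alignment], reference: GenomeRecord
) -> CoverageTrack:
    """Per-base depth from mapped alignments (wrapping on circular refs)."""
    n = len(reference)
    diff = np.zeros(n + 1, dtype=np.int64)
    for a in alignments:
        if not a.matched:
            continue
        if a.ref_id != reference.id:
            raise ValueError(f"alignment on {a.ref_id!r}, expected {reference.id!r}")
        end = a.start + a.read_len
        if end <= n:
            diff[a.start] += 1
            diff[end] -= 1
        elif reference.circular:
            diff[a.start] += 1
            diff[n] -= 1
            diff[0] += 1
            diff[end - n] -= 1
        else:
            raise ValueError(
                f"alignment of {a.read_id!r} extends past the end of linear reference"
            )
    return CoverageTrack(ref_id=reference.id, depth=np.cumsum(diff[:-1]))


def write_sam(
    alignments: list[Alignment],
    reads: ReadSet,
    reference: GenomeRecord,
    path: str | Path,
) -> None:
    """Minimal single-segment SAM: mapped reads only, MAPQ 255, full-length
    match CIGAR. Sufficient for pileup by samtools/pysam."""
    name_to_row = {name: i for i, name in enumerate(reads.names)}
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        fh.write(f"@SQ\tSN:{reference.id}\tLN:{len(reference)}\n")
        for a in alignments:
            if not a.matched:
                continue
            row = reads.seq_matrix[name_to_row[a.read_id]]
            if a.strand == "-":
                row = _seq.revcomp_codes(row)
            seq = _seq.decode(row)
            flag = 16 if a.strand == "-" else 0
            fh.write(
                f"{a.read_id}\t{flag}\t{a.ref_id}\t{a.start + 1}\t255\t"
                f"{a.read_len}M\t*\t0\t0\t{seq}\t{'I' * a.read_len}\n"
            )


def coverage_from_sam(path: str | Path, ref_id: str | None = None) -> CoverageTrack:
    """Build a coverage track from any SAM/BAM file (external alignments)."""
    import pysam

    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        if ref_id is None:
            if fh.header.nreferences != 1:
                raise ValueError("ref_id required for multi-reference SAM")
            ref_id = fh.header.references[0]
        n = fh.header.get_reference_length(ref_id)
        diff = np.zeros(n + 1, dtype=np.int64)
        for rec in fh:
            if rec.is_unmapped or rec.reference_name != ref_id:
                continue
            diff[rec.reference_start] += 1
            diff[rec.reference_end] -= 1
    return CoverageTrack(ref_id=ref_id, depth=np.cumsum(diff[:-1]))
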