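"""Synthetic polylysogen and virion-DNA simulator.

This module generates the full ground-truth chain needed to exercise the
analysis stages: a random host chromosome, a lysogen carrying one or more
integrated prophages with a duplicated att core at attL/attR, packaged virion
DNA molecules (excised-circle packaging, and in-situ processive headful
packaging that runs off a pac site into the flanking chromosome), uniform
host-DNA contamination, and finally uniformly sampled sequencing reads with a
truth table.

Coordinates are 0-based, half-open throughout.

The headful model: a pac-type prophage of length L integrated at attB may
package *in situ*, before excision. Packaging initiates at the pac site,
located ``pac_offset_bp`` inside the prophage measured from the
chromosome-proximal prophage end on the side packaging exits, and proceeds in
headfuls of exactly L bases. Headful 1 therefore contains
``L - pac_offset_bp`` bases of flanking chromosome; each further headful is
pure chromosome. The series continues past headful k with probability
``continuation_prob`` per step (geometric decay), up to ``max_headfuls``.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _seq

logger = logging.getLogger(__name__)

DEFAULT_ATT_SITE = "ATCACCATGCAGTT"
DEFAULT_GC = 0.665

EXCISED_CIRCLE = "excised_circle"
HEADFUL_IN_SITU = "headful_in_situ"


@dataclass
class GenomeRecord:
    """A named DNA sequence over {A,C,G,T}."""

    id: str
    sequence: str
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("genome sequence must be non-empty")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ProphageSpec:
    """Geometry and packaging behaviour of one integrated prophage.

    ``attb_pos`` is the 0-based insertion coordinate in the ancestral,
    prophage-free host. ``orientation`` gives the side packaging exits into
    the chromosome: '-' means off the attL (left) end, '+' off the attR
    (right) end. ``pac_offset_bp`` is measured inward from that
    chromosome-proximal end.
    """

    id: str
    length_bp: int
    attb_pos: int
    orientation: str = "-"
    pac_offset_bp: int = 0
    packaging_mode: str = EXCISED_CIRCLE
    induction_weight: float = 1.0
    in_situ_prob: float = 0.0
    max_headfuls: int = 1
    continuation_prob: float = 0.0
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"{self.id}: length_bp must be > 0")
        if not 0 <= self.pac_offset_bp < self.length_bp:
            raise ValueError(f"{self.id}: pac_offset_bp must lie inside the prophage")
        if self.orientation not in ("+", "-"):
            raise ValueError(f"{self.id}: orientation must be '+' or '-'")
        if self.packaging_mode not in (EXCISED_CIRCLE, HEADFUL_IN_SITU):
            raise ValueError(f"{self.id}: unknown packaging_mode {self.packaging_mode!r}")
        if self.induction_weight < 0:
            raise ValueError(f"{self.id}: induction_weight must be >= 0")
        if not 0.0 <= self.in_situ_prob <= 1.0:
            raise ValueError(f"{self.id}: in_situ_prob must be in [0,1]")
        if self.max_headfuls < 1:
            raise ValueError(f"{self.id}: max_headfuls must be >= 1")
        if not 0.0 <= self.continuation_prob <= 1.0:
            raise ValueError(f"{self.id}: continuation_prob must be in [0,1]")
        if self.sequence is not None and len(self.sequence) != self.length_bp:
            raise ValueError(f"{self.id}: supplied sequence length != length_bp")


@dataclass
class LysogenGenome:
    """A host chromosome with integrated prophages.

    ``placements`` are (prophage_id, attl_pos, attr_pos) triples in lysogen
    coordinates, 0-based half-open, sorted by position. The att core sequence
    is present at both attL and attR of every placement (duplicated core).
    ``excised_host`` is the prophage-free ancestral chromosome (with the att
    core planted once at each attB).
    """

    genome: GenomeRecord
    placements: list[tuple[str, int, int]]
    att_site_seq: str
    excised_host: GenomeRecord
    prophage_sequences: dict[str, str] = field(default_factory=dict)

    def placement(self, prophage_id: str) -> tuple[int, int]:
        for pid, attl, attr in self.placements:
            if pid == prophage_id:
                return attl, attr
        raise KeyError(f"prophage {prophage_id!r} not placed in lysogen")


@dataclass
class PackagedMolecule:
    """One packaged DNA molecule, as intervals on the lysogen.

    ``kind`` is 'circle' (excised-circle packaging), 'headful' (one headful
    of an in-situ series) or 'host' (contaminating chromosome fragment).
    A headful molecule spans exactly the prophage length unless it ran off a
    linear reference end, in which case ``truncated`` is set.
    """

    source: str
    intervals: list[tuple[int, int]]
    kind: str
    headful_index: int | None = None
    series_index: int | None = None
    truncated: bool = False

    @property
    def span(self) -> int:
        return sum(e - s for s, e in self.intervals)


@dataclass
class ReadSet:
    """Simulated reads plus their ground truth.

    Sequences are kept as a (n_reads, read_len) uint8 code matrix for speed;
    ``to_fastq`` renders standard FASTQ with constant quality 'I'.
    """

    names: list[str]
    seq_matrix: np.ndarray
    truth: pd.DataFrame
    read_len: int

    def __len__(self) -> int:
        return len(self.names)

    def sequences(self) -> list[str]:
        return [_seq.decode(row) for row in self.seq_matrix]

    def to_fastq(self, path: str | Path) -> None:
        qual = "I" * self.read_len
        with open(path, "w") as fh:
            for name, row in zip(self.names, self.seq_matrix):
                fh.write(f"@{name}\n{_seq.decode(row)}\n+\n{qual}\n")

    def write_truth(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# coordinates are 0-based, half-open\n")
            self.truth.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_fastq(cls, path: str | Path) -> "ReadSet":
        from Bio import SeqIO

        names: list[str] = []
        rows: list[np.ndarray] = []
        for rec in SeqIO.parse(str(path), "fastq"):
            names.append(rec.id)
            rows.append(_seq.encode(str(rec.seq)))
        if rows and any(len(r) != len(rows[0]) for r in rows):
            raise ValueError("read length must be uniform per run")
        read_len = len(rows[0]) if rows else 0
        mat = np.vstack(rows) if rows else np.zeros((0, 0), dtype=np.uint8)
        truth = pd.DataFrame({"read_id": names})
        return cls(names=names, seq_matrix=mat, truth=truth, read_len=read_len)


def generate_host(
    length_bp: int,
    gc_fraction: float = DEFAULT_GC,
    seed: int = 0,
    *,
    id: str = "host",
    circular: bool = False,
) -> GenomeRecord:
    """Generate a random host chromosome with i.i.d. bases at the given GC."""
    if length_bp <= 0:
        raise ValueError("length_bp must be > 0")
    if not 0.0 < gc_fraction < 1.0:
        raise ValueError("gc_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    return GenomeRecord(id=id, sequence=_seq.random_sequence(length_bp, gc_fraction, rng), circular=circular)


def build_lysogen(
    host: GenomeRecord,
    specs: list[ProphageSpec],
    att_site_seq: str = DEFAULT_ATT_SITE,
    seed: int = 0,
) -> LysogenGenome:
    """Integrate prophages into a host chromosome at their attB positions.

    The att core is planted into the host at each attB (replacing host bases,
    host length unchanged) and each prophage sequence begins with the same
    core, so that after insertion the core appears at both attL and attR and
    excision regenerates a single attB copy exactly.
    """
    core = att_site_seq
    clen = len(core)
    positions = sorted((s.attb_pos, s.id) for s in specs)
    for (p1, id1), (p2, id2) in zip(positions, positions[1:]):
        if p2 - p1 < clen:
            raise ValueError(f"overlapping insertions: {id1} at {p1} and {id2} at {p2}")
    for s in specs:
        if not 0 <= s.attb_pos <= len(host) - clen:
            raise ValueError(f"{s.id}: attb_pos {s.attb_pos} outside host")

    rng = np.random.default_rng(seed)
    host_gc = _seq.gc_fraction(host.sequence) if specs else DEFAULT_GC

    # plant att cores into the ancestral host
    host_seq = list(host.sequence)
    for s in specs:
        host_seq[s.attb_pos : s.attb_pos + clen] = core
    excised = GenomeRecord(id=host.id, sequence="".join(host_seq), circular=host.circular)

    pro_seqs: dict[str, str] = {}
    for s in sorted(specs, key=lambda s: s.attb_pos):
        if s.sequence is not None:
            seq = s.sequence
        else:
            seq = core + _seq.random_sequence(s.length_bp - clen, host_gc, rng)
        if not seq.startswith(core):
            seq = core + seq[clen:]
        pro_seqs[s.id] = seq

    parts: list[str] = []
    placements: list[tuple[str, int, int]] = []
    cursor = 0
    offset = 0
    for s in sorted(specs, key=lambda s: s.attb_pos):
        parts.append(excised.sequence[cursor : s.attb_pos])
        attl = s.attb_pos + offset
        parts.append(pro_seqs[s.id])
        placements.append((s.id, attl, attl + s.length_bp))
        offset += s.length_bp
        cursor = s.attb_pos
    parts.append(excised.sequence[cursor:])
    lysogen_seq = "".join(parts)

    genome = GenomeRecord(id=f"{host.id}|lysogen", sequence=lysogen_seq, circular=host.circular)
    assert len(genome) == len(host) + sum(s.length_bp for s in specs)
    return LysogenGenome(
        genome=genome,
        placements=placements,
        att_site_seq=core,
        excised_host=excised,
        prophage_sequences=pro_seqs,
    )


def _headful_intervals(start: int, end: int, n: int, circular: bool) -> tuple[list[tuple[int, int]], bool]:
    """Clip/wrap one headful window [start, end) against a reference of length n."""
    if 0 <= start and end <= n:
        return [(start, end)], False
    if circular:
        s, e = start % n, end % n if end % n != 0 else n
        if start < 0:
            return [(start % n, n), (0, end)], False
        # end > n
        return [(s, n), (0, end - n)], False
    # linear: truncate
    return [(max(start, 0), min(end, n))], True


def simulate_virions(
    lysogen: LysogenGenome,
    specs: list[ProphageSpec],
    n_molecules: int,
    host_contamination_frac: float = 0.02,
    host_fragment_len: int = 5000,
    seed: int = 0,
) -> list[PackagedMolecule]:
    """Simulate packaging events and return the resulting DNA molecules.

    ``n_molecules`` counts packaging *events*; an in-situ event yields one
    molecule per headful, so the returned list may be longer.
    """
    if n_molecules <= 0:
        raise ValueError("n_molecules must be > 0")
    weights = np.array([s.induction_weight for s in specs], dtype=float)
    if specs and not np.any(weights > 0):
        raise ValueError("induction weights must not all be zero")
    if not specs and host_contamination_frac <= 0:
        raise ValueError("no prophages and no host contamination: nothing to package")

    rng = np.random.default_rng(seed)
    n = len(lysogen.genome)
    circular = lysogen.genome.circular
    is_host = rng.random(n_molecules) < host_contamination_frac
    n_phage = int(np.count_nonzero(~is_host))
    if specs:
        p = weights / weights.sum()
        src_idx = rng.choice(len(specs), size=n_phage, p=p)
    else:
        src_idx = np.zeros(0, dtype=int)

    molecules: list[PackagedMolecule] = []
    series_counter = 0
    phage_cursor = 0
    for ev in range(n_molecules):
        if is_host[ev]:
            frag = min(host_fragment_len, n)
            if circular:
                start = int(rng.integers(0, n))
                ivs, trunc = _headful_intervals(start, start + frag, n, True)
            else:
                start = int(rng.integers(0, n - frag + 1))
                ivs, trunc = [(start, start + frag)], False
            molecules.append(PackagedMolecule(source="host", intervals=ivs, kind="host"))
            continue
        s = specs[src_idx[phage_cursor]]
        phage_cursor += 1
        attl, attr = lysogen.placement(s.id)
        in_situ = s.packaging_mode == HEADFUL_IN_SITU and rng.random() < s.in_situ_prob
        if not in_situ:
            molecules.append(
                PackagedMolecule(source=s.id, intervals=[(attl, attr)], kind="circle")
            )
            continue
        series_counter += 1
        L = s.length_bp
        if s.orientation == "-":
            pac = attl + s.pac_offset_bp
        else:
            pac = attr - s.pac_offset_bp
        k = 1
        while k < s.max_headfuls and rng.random() < s.continuation_prob:
            k += 1
        for h in range(1, k + 1):
            if s.orientation == "-":
                start, end = pac - h * L, pac - (h - 1) * L
            else:
                start, end = pac + (h - 1) * L, pac + h * L
            ivs, trunc = _headful_intervals(start, end, n, circular)
            molecules.append(
                PackagedMolecule(
                    source=s.id,
                    intervals=ivs,
                    kind="headful",
                    headful_index=h,
                    series_index=series_counter,
                    truncated=trunc,
                )
            )
            if trunc:
                logger.warning(
                    "%s in-situ series %d truncated at linear reference end (headful %d)",
                    s.id,
                    series_counter,
                    h,
                )
                break
    return molecules


def molecules_to_reads(
    molecules: list[PackagedMolecule],
    lysogen: LysogenGenome,
    read_len: int,
    n_reads: int,
    error_rate: float = 0.0,
    seed: int = 0,
) -> ReadSet:
    """Sample reads uniformly over the packaged molecules.

    A molecule is chosen proportionally to its number of valid start
    positions (span − read_len + 1), then a start offset and strand are drawn
    uniformly. Substitution errors are i.i.d. per base at ``error_rate``.
    Molecules shorter than ``read_len`` are skipped with a warning.
    """
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must be in [0, 1)")
    truth_cols = [
        "read_id",
        "source",
        "kind",
        "headful_index",
        "molecule_index",
        "strand",
        "mol_offset",
        "lysogen_start",
    ]
    if n_reads == 0:
        empty = pd.DataFrame(columns=truth_cols)
        return ReadSet(names=[], seq_matrix=np.zeros((0, read_len), dtype=np.uint8), truth=empty, read_len=read_len)

    spans = np.array([m.span for m in molecules], dtype=np.int64)
    valid = spans >= read_len
    n_skipped = int(np.count_nonzero(~valid))
    if n_skipped:
        logger.warning("%d molecules shorter than read_len=%d skipped", n_skipped, read_len)
    if not np.any(valid):
        raise ValueError("no molecule is long enough for the requested read length")

    starts_per_mol = np.where(valid, spans - read_len + 1, 0).astype(float)
    p = starts_per_mol / starts_per_mol.sum()
    rng = np.random.default_rng(seed)
    mol_idx = rng.choice(len(molecules), size=n_reads, p=p)
    offsets = (rng.random(n_reads) * (starts_per_mol[mol_idx])).astype(np.int64)
    strands = np.where(rng.random(n_reads) < 0.5, "+", "-")

    lys_codes = _seq.encode(lysogen.genome.sequence)
    seq_matrix = np.empty((n_reads, read_len), dtype=np.uint8)
    lys_start = np.full(n_reads, -1, dtype=np.int64)

    order = np.argsort(mol_idx, kind="stable")
    i = 0
    while i < len(order):
        j = i
        mi = mol_idx[order[i]]
        while j < len(order) and mol_idx[order[j]] == mi:
            j += 1
        mol = molecules[mi]
        mol_codes = np.concatenate([lys_codes[s:e] for s, e in mol.intervals])
        # interval boundaries in molecule coordinates, for lysogen_start lookup
        bounds = np.cumsum([0] + [e - s for s, e in mol.intervals])
        for idx in order[i:j]:
            off = offsets[idx]
            window = mol_codes[off : off + read_len]
            if strands[idx] == "-":
                window = _seq.revcomp_codes(window)
            seq_matrix[idx] = window
            # read fully inside one interval -> unambiguous lysogen coordinate
            iv = int(np.searchsorted(bounds, off, side="right") - 1)
            if off + read_len <= bounds[iv + 1]:
                lys_start[idx] = mol.intervals[iv][0] + (off - bounds[iv])
        i = j

    if error_rate > 0:
        err_mask = rng.random((n_reads, read_len)) < error_rate
        shifts = rng.integers(1, 4, size=int(err_mask.sum()), dtype=np.uint8)
        seq_matrix[err_mask] = (seq_matrix[err_mask] + shifts) % 4

    names = []
    for r in range(n_reads):
        m = molecules[mol_idx[r]]
        hf = m.headful_index if m.headful_index is not None else 0
        names.append(f"r{r}|src={m.source}|kind={m.kind}|hf={hf}|mol={mol_idx[r]}|pos={lys_start[r]}")

    truth = pd.DataFrame(
        {
            "read_id": names,
            "source": [molecules[i].source for i in mol_idx],
            "kind": [molecules[i].kind for i in mol_idx],
            "headful_index": [molecules[i].headful_index for i in mol_idx],
            "molecule_index": mol_idx,
            "strand": strands,
            "mol_offset": offsets,
            "lysogen_start": lys_start,
        }
    )
    return ReadSet(names=names, seq_matrix=seq_matrix, truth=truth, read_len=read_len)


def expected_read_fractions(
    specs: list[ProphageSpec],
    host_contamination_frac: float,
    host_fragment_len: int,
    read_len: int,
) -> dict[str, float]:
    """Expected per-source read fractions under the length-weighted sampling
    used by :func:`molecules_to_reads` (ignoring end truncation).

    An in-situ series contributes one genome-length molecule per headful;
    the expected number of headfuls is the capped geometric mean.
    """
    weights = np.array([s.induction_weight for s in specs], dtype=float)
    p_spec = weights / weights.sum() if specs else weights
    mass: dict[str, float] = {}
    for s, ps in zip(specs, p_spec):
        e_headfuls = sum(s.continuation_prob**j for j in range(s.max_headfuls))
        e_mols = 1.0 if s.packaging_mode == EXCISED_CIRCLE else (
            (1 - s.in_situ_prob) + s.in_situ_prob * e_headfuls
        )
        mass[s.id] = (1 - host_contamination_frac) * ps * e_mols * (s.length_bp - read_len + 1)
    mass["host"] = host_contamination_frac * (host_fragment_len - read_len + 1)
    total = sum(mass.values())
    return {k: v / total for k, v in mass.items()}


def host_fraction_for_read_share(
    specs: list[ProphageSpec],
    target_read_share: float,
    host_fragment_len: int,
    read_len: int,
) -> float:
    """Molecule-level host-contamination probability that yields the given
    expected host READ share (host fragments are shorter than phage
    molecules, so the two fractions differ)."""
    f = expected_read_fractions(specs, 0.5, host_fragment_len, read_len)
    # with prob 0.5 the per-event masses are directly comparable
    host_mass = f["host"]
    phage_mass = sum(v for k, v in f.items() if k != "host")
    r = target_read_share
    # solve f*h / (f*h + (1-f)*p) = r  with h, p the per-event masses
    h, p = host_mass, phage_mass
    return (r * p) / (h * (1 - r) + r * p)


def write_fasta(record: GenomeRecord, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        fh.write(f">{record.id}\n")
        s = record.sequence
        for i in range(0, len(s), width):
            fh.write(s[i : i + width] + "\n")


def write_placements_bed(lysogen: LysogenGenome, path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid, attl, attr in lysogen.placements:
            fh.write(f"{lysogen.genome.id}\t{attl}\t{attr}\t{pid}\n")


def write_truth_json(
    specs: list[ProphageSpec],
    lysogen: LysogenGenome,
    params: dict,
    path: str | Path,
) -> None:
    payload = {
        "coordinates": "0-based, half-open",
        "att_site_seq": lysogen.att_site_seq,
        "lysogen_length": len(lysogen.genome),
        "placements": [
            {"prophage_id": pid, "attl": attl, "attr": attr}
            for pid, attl, attr in lysogen.placements
        ],
        "prophages": [
            {
                "id": s.id,
                "length_bp": s.length_bp,
                "attb_pos": s.attb_pos,
                "orientation": s.orientation,
                "pac_offset_bp": s.pac_offset_bp,
                "packaging_mode": s.packaging_mode,
                "induction_weight": s.induction_weight,
                "in_situ_prob": s.in_situ_prob,
                "max_headfuls": s.max_headfuls,
                "continuation_prob": s.continuation_prob,
                "first_headful_chromosomal_bp": s.length_bp - s.pac_offset_bp,
            }
            for s in specs
        ],
        "params": params,
    }
    Path(path).write_text(json.dumps(payload, indent=2))
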