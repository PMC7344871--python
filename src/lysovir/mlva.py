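"""In-silico MLVA (multiple-locus VNTR analysis) typing.

Alleles are extracted by locating a locus's two flanking sequences in the
genome (an in-silico stand-in for PCR primers: each flank must occur exactly
once on one strand), sizing the virtual amplicon, and converting the size to
a repeat count. An IS element of ~1 kb or more inside a VNTR enlarges the
amplicon far beyond any plausible repeat number and is called as a null
allele (``NULL_IS``); a locus whose flanks cannot be located uniquely is
``MISSING``. Profiles are compared with the categorical coefficient (share
of compared loci that differ; missing loci excluded), clustered by UPGMA
with a deterministic lexicographic tie-break, and partitioned at a distance
cutoff — the conventional cluster rule being "12 of 14 alleles shared",
i.e. a cutoff of 2/14.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _seq
from .synthetic import GenomeRecord

NULL_IS = "NULL_IS"
MISSING = "MISSING"

DEFAULT_CLUSTER_DISTANCE = 2.0 / 14.0


@dataclass
class VNTRLocus:
    """One VNTR locus: two anchoring flanks and the repeat geometry.

    ``offset_bp`` counts the non-repeat bases inside the amplicon (both
    flanks plus any unique spacer); ``max_alleles`` bounds the plausible
    repeat number used for IS null-allele calling.
    """

    id: str
    left_flank: str
    right_flank: str
    repeat_unit_bp: int
    offset_bp: int = 0
    max_alleles: int = 30

    def __post_init__(self) -> None:
        if not self.left_flank or not self.right_flank:
            raise ValueError(f"{self.id}: flanks must be non-empty")
        if self.repeat_unit_bp <= 0:
            raise ValueError(f"{self.id}: repeat_unit_bp must be > 0")
        if self.offset_bp < 0:
            raise ValueError(f"{self.id}: offset_bp must be >= 0")


@dataclass
class MLVAProfile:
    strain_id: str
    alleles: list[int | str]
    half_unit_flags: list[bool] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.alleles)


@dataclass
class Dendrogram:
    """UPGMA tree as a merge list.

    ``merges`` holds (cluster_a, cluster_b, height, size) with leaf clusters
    0..n−1 and internal clusters numbered onward, scipy-linkage style;
    heights are ultrametric node heights (half the cophenetic distance).
    """

    labels: list[str]
    merges: list[tuple[int, int, float, int]]

    def to_newick(self) -> str:
        n = len(self.labels)
        height: dict[int, float] = {i: 0.0 for i in range(n)}
        node: dict[int, str] = {i: self.labels[i] for i in range(n)}
        nxt = n
        for a, b, h, _size in self.merges:
            la = h - height[a]
            lb = h - height[b]
            node[nxt] = f"({node[a]}:{la:.6g},{node[b]}:{lb:.6g})"
            height[nxt] = h
            nxt += 1
        root = nxt - 1 if self.merges else 0
        return node[root] + ";"

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")

    def cut(self, max_height: float) -> list[set[str]]:
        n = len(self.labels)
        members: dict[int, set[int]] = {i: {i} for i in range(n)}
        nxt = n
        for a, b, h, _size in self.merges:
            if h <= max_height + 1e-12:
                members[nxt] = members.pop(a) | members.pop(b)
            else:
                members[nxt] = set()  # placeholder so ids stay aligned
                # keep a and b as final clusters
            nxt += 1
        out = [frozenset(m) for m in members.values() if m]
        return [set(self.labels[i] for i in m) for m in out]


def read_panel_tsv(path: str | Path) -> list[VNTRLocus]:
    df = pd.read_csv(path, sep="\t", comment="#")
    loci = []
    for _, row in df.iterrows():
        loci.append(
            VNTRLocus(
                id=str(row["id"]),
                left_flank=str(row["left_flank"]),
                right_flank=str(row["right_flank"]),
                repeat_unit_bp=int(row["repeat_unit_bp"]),
                offset_bp=int(row.get("offset_bp", 0)),
                max_alleles=int(row.get("max_alleles", 30)),
            )
        )
    return loci


def write_panel_tsv(loci: list[VNTRLocus], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "id": l.id,
                "left_flank": l.left_flank,
                "right_flank": l.right_flank,
                "repeat_unit_bp": l.repeat_unit_bp,
                "offset_bp": l.offset_bp,
                "max_alleles": l.max_alleles,
            }
            for l in loci
        ]
    ).to_csv(path, sep="\t", index=False)


def _find_unique(haystack: str, needle: str) -> int | None:
    """Start of the unique occurrence of needle, or None."""
    first = haystack.find(needle)
    if first == -1:
        return None
    if haystack.find(needle, first + 1) != -1:
        return None
    return first


def extract_allele(
    genome: GenomeRecord, locus: VNTRLocus
) -> tuple[int | str, bool]:
    """Extract one allele; returns (allele, half_unit_flag).

    The amplicon runs from the start of the left flank to the end of the
    right flank on whichever strand carries the unique flank pair. The
    allele is the rounded repeat count; an amplicon exceeding the largest
    plausible allele size (an inserted IS element) is a null allele.
    """
    for seq in (genome.sequence, _seq.revcomp(genome.sequence)):
        left = _find_unique(seq, locus.left_flank)
        if left is None:
            continue
        right = _find_unique(seq, locus.right_flank)
        if right is None:
            continue
        amp_end = right + len(locus.right_flank)
        if amp_end <= left:
            continue
        amplicon_len = amp_end - left
        # an IS inside the repeat tract inflates the amplicon beyond any
        # plausible repeat count -> null allele (gel-visible "large amplicon")
        largest_plausible = locus.offset_bp + locus.max_alleles * locus.repeat_unit_bp
        if amplicon_len > largest_plausible:
            return NULL_IS, False
        units = (amplicon_len - locus.offset_bp) / locus.repeat_unit_bp
        allele = int(round(units))
        if allele < 0:
            return MISSING, False
        half_unit = abs(units - allele) > 0.25
        return allele, half_unit
    return MISSING, False


def profile_genome(
    genome: GenomeRecord, loci: list[VNTRLocus], strain_id: str | None = None
) -> MLVAProfile:
    alleles: list[int | str] = []
    flags: list[bool] = []
    for locus in loci:
        a, f = extract_allele(genome, locus)
        alleles.append(a)
        flags.append(f)
    return MLVAProfile(
        strain_id=strain_id or genome.id, alleles=alleles, half_unit_flags=flags
    )


def categorical_distance(p: MLVAProfile, q: MLVAProfile) -> float:
    """Share of compared loci with unequal values; loci where either profile
    is MISSING are excluded; NULL_IS is an ordinary category."""
    if len(p) != len(q):
        raise ValueError("profiles have different panel sizes")
    compared = 0
    diff = 0
    for a, b in zip(p.alleles, q.alleles):
        if a == MISSING or b == MISSING:
            continue
        compared += 1
        if a != b:
            diff += 1
    if compared == 0:
        raise ValueError(
            f"no comparable loci between {p.strain_id} and {q.strain_id}"
        )
    return diff / compared


def distance_matrix(profiles: list[MLVAProfile]) -> pd.DataFrame:
    ids = [p.strain_id for p in profiles]
    n = len(profiles)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = categorical_distance(profiles[i], profiles[j])
    return pd.DataFrame(d, index=ids, columns=ids)


def upgma(dm: pd.DataFrame | np.ndarray, labels: list[str] | None = None) -> Dendrogram:
    """Average-linkage agglomeration with a deterministic tie-break.

    Among equally close pairs, the pair whose (sorted) smallest member
    labels are lexicographically first is merged. Merge height is half the
    average inter-cluster distance, so two strains at distance d merge at
    height d/2 and heights are ultrametric.
    """
    if isinstance(dm, pd.DataFrame):
        labels = list(dm.index)
        mat = dm.to_numpy(dtype=float)
    else:
        mat = np.asarray(dm, dtype=float)
        if labels is None:
            labels = [f"s{i}" for i in range(len(mat))]
    n = len(mat)
    if mat.shape != (n, n) or not np.allclose(mat, mat.T) or not np.allclose(np.diag(mat), 0):
        raise ValueError("distance matrix must be square, symmetric, zero-diagonal")

    # active clusters: id -> (min leaf label, size)
    active: dict[int, tuple[str, int]] = {i: (labels[i], 1) for i in range(n)}
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(mat[i, j])

    merges: list[tuple[int, int, float, int]] = []
    nxt = n
    while len(active) > 1:
        best_key = None
        best = None
        for (i, j), d in dist.items():
            li, lj = active[i][0], active[j][0]
            tag = tuple(sorted((li, lj)))
            key = (d, tag)
            if best is None or key < best:
                best = key
                best_key = (i, j)
        i, j = best_key
        d = dist.pop((i, j))
        (li, si), (lj, sj) = active[i], active[j]
        # order children deterministically by min leaf label
        a, b = (i, j) if li <= lj else (j, i)
        merges.append((a, b, d / 2.0, si + sj))
        # Lance-Williams average-linkage update
        new_d: dict[tuple[int, int], float] = {}
        for k in active:
            if k in (i, j):
                continue
            dik = dist.pop((min(i, k), max(i, k)))
            djk = dist.pop((min(j, k), max(j, k)))
            new_d[(k, nxt)] = (si * dik + sj * djk) / (si + sj)
        del active[i], active[j]
        active[nxt] = (min(li, lj), si + sj)
        for (k, m), v in new_d.items():
            dist[(min(k, m), max(k, m))] = v
        nxt += 1
    return Dendrogram(labels=labels, merges=merges)


def cluster_at(dendrogram: Dendrogram, max_distance: float = DEFAULT_CLUSTER_DISTANCE) -> list[set[str]]:
    """Partition strains at a cophenetic-distance cutoff (inclusive)."""
    return dendrogram.cut(max_distance / 2.0)


def write_profiles_tsv(profiles: list[MLVAProfile], path: str | Path) -> None:
    rows = []
    for p in profiles:
        row: dict = {"strain_id": p.strain_id}
        for i, a in enumerate(p.alleles, start=1):
            row[f"locus_{i}"] = a
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def synthesize_panel_genome(
    loci: list[VNTRLocus],
    alleles: list[int],
    seed: int = 0,
    spacer_len: int = 400,
    strain_id: str = "synthetic",
    is_inserts: dict[str, int] | None = None,
) -> GenomeRecord:
    """Construct a synthetic genome carrying the panel loci with known
    repeat counts (and optional IS insertions of given sizes inside loci),
    so extraction can be round-trip tested."""
    rng = np.random.default_rng(seed)
    is_inserts = is_inserts or {}
    parts = [_seq.random_sequence(spacer_len, 0.5, rng)]
    for locus, count in zip(loci, alleles):
        unit_seed = abs(hash(locus.id)) % (2**31)
        unit = _seq.random_sequence(locus.repeat_unit_bp, 0.5, np.random.default_rng(unit_seed))
        body = unit * count
        if locus.id in is_inserts:
            ins = _seq.random_sequence(is_inserts[locus.id], 0.5, rng)
            mid = len(body) // 2
            body = body[:mid] + ins + body[mid:]
        parts.append(locus.left_flank + body + locus.right_flank)
        parts.append(_seq.random_sequence(spacer_len, 0.5, rng))
    return GenomeRecord(id=strain_id, sequence="".join(parts))
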