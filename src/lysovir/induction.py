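"""Per-prophage virion read fractions and activation calls.

After mapping induced-virion reads onto the lysogen genome, each mapped read
is assigned to the prophage interval containing its alignment midpoint
(midpoint assignment avoids double counting at the att junctions), or to
"host" otherwise. Fractions over mapped reads sum to one across
{prophages} ∪ {host}; fractions over all reads (counting unmapped) are
reported alongside. Background depth is the median depth over host positions
at least ``background_margin_bp`` away from any prophage interval — a robust
estimate that ignores the lateral-transduction shoulder — and a prophage is
called activated when its mean depth exceeds ``fold_threshold`` times that
background.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .mapping import Alignment, CoverageTrack, coverage_from_alignments
from .synthetic import GenomeRecord

logger = logging.getLogger(__name__)

DEFAULT_FOLD_THRESHOLD = 5.0
DEFAULT_BACKGROUND_MARGIN_BP = 10_000


@dataclass
class ProphageInterval:
    id: str
    ref_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.id}: end must exceed start")


@dataclass
class InductionProfile:
    """Read counts, fractions and depths per source.

    ``fractions`` are over mapped reads (they sum to 1 over prophages+host);
    ``fractions_of_total`` use all reads, mapped or not, as denominator.
    """

    counts: dict[str, int]
    fractions: dict[str, float]
    fractions_of_total: dict[str, float]
    mean_depth: dict[str, float]
    background_depth: float
    n_mapped: int
    n_unmapped: int
    assignment: str = "midpoint"
    activated: dict[str, bool] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "assignment": self.assignment,
            "n_mapped": self.n_mapped,
            "n_unmapped": self.n_unmapped,
            "background_depth": self.background_depth,
            "counts": self.counts,
            "fractions_of_mapped": self.fractions,
            "fractions_of_total": self.fractions_of_total,
            "mean_depth": self.mean_depth,
            "activated": self.activated,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for src in self.counts:
            rows.append(
                {
                    "source": src,
                    "reads": self.counts[src],
                    "fraction_of_mapped": self.fractions[src],
                    "fraction_of_total": self.fractions_of_total[src],
                    "mean_depth": self.mean_depth.get(src, float("nan")),
                    "activated": self.activated.get(src, ""),
                }
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def intervals_from_bed(path: str | Path) -> list[ProphageInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else f"{chrom}:{start}-{end}"
            out.append(ProphageInterval(id=name, ref_id=chrom, start=start, end=end))
    return out


def quantify_induction(
    alignments: list[Alignment],
    intervals: list[ProphageInterval],
    reference: GenomeRecord,
    n_unmapped_extra: int = 0,
    background_margin_bp: int = DEFAULT_BACKGROUND_MARGIN_BP,
    coverage: CoverageTrack | None = None,
) -> InductionProfile:
    """Assign mapped reads to prophages by alignment midpoint and compute
    the per-source read fractions and depths."""
    ivs = sorted(intervals, key=lambda iv: iv.start)
    for a, b in zip(ivs, ivs[1:]):
        if b.start < a.end:
            raise ValueError(f"overlapping prophage intervals {a.id} and {b.id}")

    mapped = [a for a in alignments if a.matched]
    unmapped = len(alignments) - len(mapped) + n_unmapped_extra
    if not mapped:
        raise ValueError("no mapped reads: induction profile undefined")

    starts = np.array([iv.start for iv in ivs], dtype=np.int64)
    ends = np.array([iv.end for iv in ivs], dtype=np.int64)
    mid = np.array([a.start + a.read_len // 2 for a in mapped], dtype=np.int64)
    # interval containing each midpoint, or -1
    pos = np.searchsorted(starts, mid, side="right") - 1
    inside = (pos >= 0) & (mid < ends[np.clip(pos, 0, len(ivs) - 1)]) if ivs else np.zeros(len(mid), dtype=bool)

    counts: dict[str, int] = {iv.id: 0 for iv in ivs}
    for i, iv_idx in enumerate(pos):
        if inside[i]:
            counts[ivs[iv_idx].id] += 1
    counts["host"] = len(mapped) - int(np.count_nonzero(inside))

    cov = coverage if coverage is not None else coverage_from_alignments(mapped, reference)
    depth = cov.depth

    host_mask = np.ones(len(reference), dtype=bool)
    for iv in ivs:
        lo = max(iv.start - background_margin_bp, 0)
        hi = min(iv.end + background_margin_bp, len(reference))
        host_mask[lo:hi] = False
    background = float(np.median(depth[host_mask])) if host_mask.any() else 0.0

    mean_depth = {iv.id: float(depth[iv.start : iv.end].mean()) for iv in ivs}
    mean_depth["host"] = float(depth[host_mask].mean()) if host_mask.any() else 0.0

    total = len(mapped) + unmapped
    fractions = {k: v / len(mapped) for k, v in counts.items()}
    fractions_of_total = {k: v / total for k, v in counts.items()}
    return InductionProfile(
        counts=counts,
        fractions=fractions,
        fractions_of_total=fractions_of_total,
        mean_depth=mean_depth,
        background_depth=background,
        n_mapped=len(mapped),
        n_unmapped=unmapped,
    )


def call_activated(
    profile: InductionProfile,
    intervals: list[ProphageInterval],
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
) -> dict[str, bool]:
    """A prophage is activated iff its mean depth exceeds
    ``fold_threshold`` × background. Zero background with nonzero prophage
    depth counts as activated (logged)."""
    calls: dict[str, bool] = {}
    for iv in intervals:
        d = profile.mean_depth[iv.id]
        if profile.background_depth == 0:
            calls[iv.id] = d > 0
            if d > 0:
                logger.info("%s: zero background, activated by convention", iv.id)
        else:
            calls[iv.id] = d > fold_threshold * profile.background_depth
    profile.activated = calls
    return calls
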