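"""Lateral-transduction detection from the staircase coverage signature.

A pac-type prophage that packages in situ exports consecutive headfuls of
chromosomal DNA off one side of its insertion site. Mapped onto the
prophage-free reference, the virion reads form a staircase next to attB: a
first step of width ``genome_length − pac_offset`` followed by steps of one
phage-genome length each, with geometrically decreasing depth. This module
segments the flanking coverage into such steps, derives the headful period,
the pac offset (period − first-step width) and the per-step decay, and scans
for the packaging-initiation motif near the inferred pac position.

Segmentation is greedy binary segmentation of log2(depth+1) — the log
stabilises the Poisson-like depth variance — with a minimum segment length
and an SSE-reduction stopping rule (a split is accepted while it removes
more than ``penalty_frac`` of the total initial SSE).
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _seq
from .mapping import CoverageTrack
from .synthetic import GenomeRecord, LysogenGenome

logger = logging.getLogger(__name__)

DEFAULT_PAC_MOTIF = "GCTAAA"


@dataclass
class StaircaseParams:
    """Tunables of the staircase fit (all config-exposed)."""

    min_segment_bp: int = 5000
    penalty_frac: float = 0.02
    background: float | None = None  # estimated from outside the flanks if None
    background_factor: float = 1.5


@dataclass
class StaircaseFit:
    attb_pos: int
    side: str  # left / right / none
    breakpoints: list[int]  # ref coords, ordered from attB outward
    steps: list[tuple[int, float]]  # (width_bp, mean_depth), from attB outward
    n_steps: int
    first_step_bp: int
    period_bp: float
    decay_ratios: list[float]
    pac_offset_bp: float
    asymmetry: float
    opposite_mass_fraction: float
    background: float
    r_squared: float
    score: float

    def to_dict(self) -> dict:
        return {
            "attb_pos": self.attb_pos,
            "side": self.side,
            "breakpoints": self.breakpoints,
            "steps": [{"width_bp": w, "mean_depth": h} for w, h in self.steps],
            "n_steps": self.n_steps,
            "first_step_bp": self.first_step_bp,
            "period_bp": self.period_bp,
            "decay_ratios": self.decay_ratios,
            "pac_offset_bp": self.pac_offset_bp,
            "asymmetry": self.asymmetry,
            "opposite_mass_fraction": self.opposite_mass_fraction,
            "background": self.background,
            "r_squared": self.r_squared,
            "score": self.score,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def steps_to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("step\twidth_bp\tmean_depth\n")
            for i, (w, h) in enumerate(self.steps, start=1):
                fh.write(f"{i}\t{w}\t{h}\n")


@dataclass
class MotifHit:
    position: int
    strand: str
    motif: str


def excise_reference(
    lysogen: LysogenGenome, prophage_id: str
) -> tuple[GenomeRecord, int]:
    """Remove one prophage from the lysogen, fusing attL/attR back to attB.

    Returns the prophage-free reference and the attB coordinate on it.
    """
    attl, attr = lysogen.placement(prophage_id)  # KeyError for unknown ids
    seq = lysogen.genome.sequence
    excised_seq = seq[:attl] + seq[attr:]
    attb = attl
    # other placements shift if they sit right of the excised one
    record = GenomeRecord(
        id=f"{lysogen.genome.id}|excised:{prophage_id}",
        sequence=excised_seq,
        circular=lysogen.genome.circular,
    )
    return record, attb


def insert_prophage(
    reference: GenomeRecord, attb_pos: int, prophage_seq: str
) -> GenomeRecord:
    """Inverse of :func:`excise_reference` (round-trip checkable)."""
    seq = reference.sequence
    return GenomeRecord(
        id=reference.id,
        sequence=seq[:attb_pos] + prophage_seq + seq[attb_pos:],
        circular=reference.circular,
    )


def _binned_median(depth: np.ndarray, bin_bp: int = 1000) -> float:
    """Median of bin-mean depths: robust to localized peaks like a per-base
    median, but still meaningful when most single positions are zero (sparse
    low-depth background)."""
    if depth.size == 0:
        return 0.0
    nb = depth.size // bin_bp
    if nb < 2:
        return float(depth.mean())
    return float(np.median(depth[: nb * bin_bp].reshape(nb, bin_bp).mean(axis=1)))


def _sse_from_cumsums(c1: np.ndarray, c2: np.ndarray, a: int, b: int) -> float:
    n = b - a
    s1 = c1[b] - c1[a]
    s2 = c2[b] - c2[a]
    return float(s2 - s1 * s1 / n)


def _best_split(c1: np.ndarray, c2: np.ndarray, a: int, b: int, min_seg: int):
    """Best single split of y[a:b]; returns (gain, split) or (0, None)."""
    if b - a < 2 * min_seg:
        return 0.0, None
    t = np.arange(a + min_seg, b - min_seg + 1)
    nl = t - a
    nr = b - t
    sl = c1[t] - c1[a]
    sr = c1[b] - c1[t]
    sse_l = (c2[t] - c2[a]) - sl * sl / nl
    sse_r = (c2[b] - c2[t]) - sr * sr / nr
    total = _sse_from_cumsums(c1, c2, a, b)
    gains = total - (sse_l + sse_r)
    i = int(np.argmax(gains))
    return float(gains[i]), int(t[i])


def binary_segmentation(
    y: np.ndarray, min_segment: int, penalty_frac: float
) -> list[int]:
    """Greedy binary segmentation; returns sorted interior breakpoints.

    Splits are accepted while the SSE reduction exceeds
    ``penalty_frac`` × SSE of the unsegmented series.
    """
    y = np.asarray(y, dtype=np.float64)
    n = len(y)
    c1 = np.concatenate([[0.0], np.cumsum(y)])
    c2 = np.concatenate([[0.0], np.cumsum(y * y)])
    total_sse = _sse_from_cumsums(c1, c2, 0, n)
    if total_sse <= 0:
        return []
    threshold = penalty_frac * total_sse

    segments = [(0, n)]
    best_splits = {(0, n): _best_split(c1, c2, 0, n, min_segment)}
    breakpoints: list[int] = []
    while True:
        best_seg, best_gain, best_t = None, threshold, None
        for seg in segments:
            gain, t = best_splits[seg]
            if t is not None and gain > best_gain:
                best_seg, best_gain, best_t = seg, gain, t
        if best_seg is None:
            break
        a, b = best_seg
        segments.remove(best_seg)
        for sub in ((a, best_t), (best_t, b)):
            segments.append(sub)
            best_splits[sub] = _best_split(c1, c2, sub[0], sub[1], min_segment)
        breakpoints.append(best_t)
    return sorted(breakpoints)


def fit_staircase(
    coverage: CoverageTrack,
    attb_pos: int,
    flank_bp: int,
    params: StaircaseParams | None = None,
) -> StaircaseFit:
    """Fit the headful staircase in the flank with the larger read mass.

    The flank is oriented away from attB (index 0 adjacent to attB), the
    log-depth is segmented into piecewise-constant steps, and the step list
    is trimmed to the maximal prefix that is strictly decreasing and above
    ``background × background_factor``. An empty prefix yields side='none'
    (no lateral transduction detected), not an exception.
    """
    params = params or StaircaseParams()
    depth = np.asarray(coverage.depth, dtype=np.float64)
    n = len(depth)
    if not 0 <= attb_pos <= n:
        raise ValueError("attb_pos outside the coverage track")
    left_avail = min(flank_bp, attb_pos)
    right_avail = min(flank_bp, n - attb_pos)
    # side choice compares read mass over equal-width windows
    cmp_bp = min(left_avail, right_avail)
    if cmp_bp <= 0:
        raise ValueError("no flank available around attb_pos")

    mass_l = float(depth[attb_pos - cmp_bp : attb_pos].sum())
    mass_r = float(depth[attb_pos : attb_pos + cmp_bp].sum())
    if mass_l >= mass_r:
        side = "left"
        flank = depth[attb_pos - left_avail : attb_pos][::-1]
        larger, smaller = mass_l, mass_r
    else:
        side = "right"
        flank = depth[attb_pos : attb_pos + right_avail]
        larger, smaller = mass_r, mass_l
    asymmetry = larger / smaller if smaller > 0 else float("inf")
    total_mass = mass_l + mass_r
    opposite_frac = smaller / total_mass if total_mass > 0 else 0.5

    if params.background is not None:
        background = params.background
    else:
        # conservative default: the larger of the binned-median depth
        # outside the flanks and on the opposite flank (which carries only
        # dispersed background once the staircase side is chosen)
        outside = np.concatenate(
            [depth[: max(attb_pos - left_avail, 0)], depth[attb_pos + right_avail :]]
        )
        if side == "left":
            opposite = depth[attb_pos : attb_pos + cmp_bp]
        else:
            opposite = depth[attb_pos - cmp_bp : attb_pos]
        background = max(_binned_median(outside), _binned_median(opposite))

    def _null(side_val: str = "none") -> StaircaseFit:
        return StaircaseFit(
            attb_pos=attb_pos,
            side=side_val,
            breakpoints=[],
            steps=[],
            n_steps=0,
            first_step_bp=0,
            period_bp=float("nan"),
            decay_ratios=[],
            pac_offset_bp=float("nan"),
            asymmetry=asymmetry,
            opposite_mass_fraction=opposite_frac,
            background=background,
            r_squared=0.0,
            score=0.0,
        )

    if total_mass == 0:
        return _null()

    y = np.log2(flank + 1.0)
    bps = binary_segmentation(y, params.min_segment_bp, params.penalty_frac)
    edges = [0] + bps + [len(flank)]
    seg_means = [float(flank[a:b].mean()) for a, b in zip(edges, edges[1:])]
    seg_widths = [b - a for a, b in zip(edges, edges[1:])]

    # maximal prefix: strictly decreasing and above background
    floor = background * params.background_factor
    steps: list[tuple[int, float]] = []
    prev = float("inf")
    for w, h in zip(seg_widths, seg_means):
        if h <= floor or h >= prev:
            break
        steps.append((w, h))
        prev = h
    if not steps:
        return _null()

    n_steps = len(steps)
    first_step_bp = steps[0][0]
    widths = [w for w, _ in steps]
    heights = [h for _, h in steps]
    period = float(np.median(widths[1:])) if n_steps >= 2 else float("nan")
    pac_offset = period - first_step_bp if n_steps >= 2 else float("nan")
    decay = [heights[i + 1] / heights[i] for i in range(n_steps - 1)]

    # goodness of the piecewise-constant fit over the staircase region (log space)
    region_len = sum(widths)
    yr = y[:region_len]
    fitted = np.concatenate(
        [np.full(w, np.log2(h + 1.0)) for w, h in steps]
    )
    sst = float(np.sum((yr - yr.mean()) ** 2))
    sse = float(np.sum((yr - fitted) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    r2 = max(r2, 0.0)
    asym_term = 1.0 if asymmetry == float("inf") else asymmetry / (1.0 + asymmetry)
    score = r2 * asym_term

    sign = -1 if side == "left" else 1
    ref_bps = [attb_pos]
    acc = 0
    for w in widths:
        acc += w
        ref_bps.append(attb_pos + sign * acc)

    return StaircaseFit(
        attb_pos=attb_pos,
        side=side,
        breakpoints=ref_bps,
        steps=steps,
        n_steps=n_steps,
        first_step_bp=first_step_bp,
        period_bp=period,
        decay_ratios=decay,
        pac_offset_bp=pac_offset,
        asymmetry=asymmetry,
        opposite_mass_fraction=opposite_frac,
        background=background,
        r_squared=r2,
        score=score,
    )


def scan_pac_motif(
    sequence: str,
    center: int,
    window_bp: int,
    motif: str = DEFAULT_PAC_MOTIF,
) -> list[MotifHit]:
    """All exact occurrences of the motif on both strands within
    [center − window_bp, center + window_bp), sorted by distance to center."""
    if not motif:
        raise ValueError("motif must be non-empty")
    if any(b not in "ACGT" for b in motif):
        raise ValueError("motif must be over {A,C,G,T}")
    lo = max(center - window_bp, 0)
    hi = min(center + window_bp, len(sequence))
    region = sequence[lo:hi]
    hits: list[MotifHit] = []
    for strand, m in (("+", motif), ("-", _seq.revcomp(motif))):
        start = region.find(m)
        while start != -1:
            hits.append(MotifHit(position=lo + start, strand=strand, motif=motif))
            start = region.find(m, start + 1)
    hits.sort(key=lambda h: (abs(h.position - center), h.position, h.strand))
    return hits


def detect_lateral_transduction(
    fit: StaircaseFit,
    min_steps: int = 2,
    min_asymmetry: float = 3.0,
) -> tuple[bool, dict]:
    """Call lateral transduction on a staircase fit.

    Positive iff at least ``min_steps`` decreasing steps were found and the
    flank read-mass asymmetry reaches ``min_asymmetry``.
    """
    positive = (
        fit.side != "none"
        and fit.n_steps >= min_steps
        and fit.asymmetry >= min_asymmetry
    )
    report = {
        "lateral_transduction_detected": positive,
        "min_steps": min_steps,
        "min_asymmetry": min_asymmetry,
        "fit": fit.to_dict(),
    }
    return positive, report


def plot_staircase(
    coverage: CoverageTrack,
    fit: StaircaseFit,
    path: str | Path,
    flank_bp: int | None = None,
) -> None:
    """Coverage around attB with the fitted step boundaries overlaid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    flank = flank_bp or (max(abs(b - fit.attb_pos) for b in fit.breakpoints) + 20_000 if fit.breakpoints else 50_000)
    lo = max(fit.attb_pos - flank, 0)
    hi = min(fit.attb_pos + flank, len(coverage.depth))
    x = np.arange(lo, hi)
    fig, ax = plt.subplots(figsize=(10, 4))
    ax.fill_between(x, coverage.depth[lo:hi], step="mid", color="#4878a8", linewidth=0)
    ax.axvline(fit.attb_pos, color="k", linestyle="--", label="attB")
    for b in fit.breakpoints[1:]:
        ax.axvline(b, color="crimson", linestyle=":")
    ax.set_xlabel("position (bp)")
    ax.set_ylabel("depth")
    ax.set_title(
        f"side={fit.side}, n_steps={fit.n_steps}, first={fit.first_step_bp} bp, "
        f"period={fit.period_bp:.0f} bp, pac offset={fit.pac_offset_bp:.0f} bp"
    )
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
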