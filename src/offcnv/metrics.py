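"""Profile-quality and cross-platform comparison statistics.

Covers the evaluation toolbox: a diff-based robust noise estimate (MAD of
lag-1 differences, scaled to a per-bin standard deviation), signal-to-noise
ratios of segmented regions, array-probe pseudo-counts on the bin grid,
length-weighted concordance between segmentations, and a random-placement
simulation for interval-overlap enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from offcnv.coverage import BinGrid
from offcnv.genome_io import GenomeLayout, IntervalSet
from offcnv.segment import Segment, SegmentSet


def mad_diff(values: Sequence[float]) -> float:
    """Robust per-bin noise estimate from lag-1 differences.

    MAD of the consecutive differences of the non-missing values (in
    genomic order), scaled by 1.4826 for normal consistency and divided by
    sqrt(2) because differencing doubles the variance.  Invariant to
    additive shifts and to any piecewise-constant signal with few jumps.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 3:
        raise ValueError("need at least 3 non-missing values")
    d = np.diff(v)
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2))


def signal_to_noise(
    segments: SegmentSet,
    mad: float,
    chrom: str,
    start: int,
    end: int,
) -> float:
    """|segmentation value| / MAD for the segment overlapping a region most.

    The signal is the mean log2 of the segment with the largest bp overlap
    with [start, end) on ``chrom``.
    """
    if mad <= 0:
        raise ValueError("MAD must be > 0")
    best: Segment | None = None
    best_ov = 0
    for seg in segments.for_chrom(chrom):
        ov = min(seg.end, end) - max(seg.start, start)
        if ov > best_ov:
            best, best_ov = seg, ov
    if best is None:
        raise ValueError(f"no segment overlaps {chrom}:{start}-{end}")
    return abs(best.mean) / mad


@dataclass(frozen=True)
class ProbeSet:
    """Array probes: per-chromosome positions (bp) and log2-scale intensities."""

    positions: dict[str, np.ndarray]
    intensities: dict[str, np.ndarray]

    @staticmethod
    def from_frame(df: pd.DataFrame) -> "ProbeSet":
        pos, inten = {}, {}
        for chrom, grp in df.groupby("chrom", sort=False):
            order = np.argsort(grp["position"].to_numpy(), kind="stable")
            pos[str(chrom)] = grp["position"].to_numpy()[order].astype(np.int64)
            inten[str(chrom)] = grp["intensity"].to_numpy()[order].astype(float)
        return ProbeSet(pos, inten)

    def is_empty(self) -> bool:
        return not any(len(p) for p in self.positions.values())


def array_pseudocounts(probes: ProbeSet, bins: BinGrid, mode: str = "nearest") -> np.ndarray:
    """Per-bin surrogate intensities from array probes.

    ``nearest``: intensity of the probe closest to the bin centre (ties to
    the lower coordinate).  ``mean``: average intensity of probes inside
    the bin, NaN when the bin holds none.
    """
    if probes.is_empty():
        raise ValueError("empty probe set")
    if mode not in ("nearest", "mean"):
        raise ValueError(f"unknown mode {mode!r}")
    out = np.full(len(bins), np.nan)
    for chrom, lo, hi in bins.chrom_slices():
        pos = probes.positions.get(chrom)
        if pos is None or not len(pos):
            continue
        inten = probes.intensities[chrom]
        if mode == "nearest":
            centers = (bins.start[lo:hi] + bins.end[lo:hi]) / 2.0
            right = np.searchsorted(pos, centers)
            for k, (c, r) in enumerate(zip(centers, right)):
                cands = [i for i in (r - 1, r) if 0 <= i < len(pos)]
                # ties: lower coordinate wins (left candidate evaluated first)
                best = min(cands, key=lambda i: (abs(pos[i] - c), pos[i]))
                out[lo + k] = inten[best]
        else:
            first = np.searchsorted(pos, bins.start[lo:hi], side="left")
            last = np.searchsorted(pos, bins.end[lo:hi], side="left")
            for k, (a, b) in enumerate(zip(first, last)):
                if b > a:
                    out[lo + k] = inten[a:b].mean()
    return out


@dataclass(frozen=True)
class ConcordanceResult:
    weighted_euclidean: float
    weighted_pearson: float
    total_weight: int  # bp


def segment_concordance(a: SegmentSet, b: SegmentSet) -> ConcordanceResult:
    """Length-weighted agreement between two segmentations.

    Intersect the two segment sets; for each overlap region r of length
    w_r with means a_r and b_r, compute the weighted Euclidean distance
    sqrt(sum w_r (a_r - b_r)^2 / sum w_r) and the w_r-weighted Pearson
    correlation of the mean pairs.
    """
    regions: list[tuple[int, float, float]] = []
    b_by_chrom: dict[str, list[Segment]] = {}
    for seg in b:
        b_by_chrom.setdefault(seg.chrom, []).append(seg)
    for sa in a:
        for sb in b_by_chrom.get(sa.chrom, []):
            w = min(sa.end, sb.end) - max(sa.start, sb.start)
            if w > 0:
                regions.append((w, sa.mean, sb.mean))
    if not regions:
        raise ValueError("segment sets share no overlapping regions")
    w = np.array([r[0] for r in regions], dtype=float)
    va = np.array([r[1] for r in regions])
    vb = np.array([r[2] for r in regions])
    wsum = w.sum()
    euclid = float(np.sqrt(np.sum(w * (va - vb) ** 2) / wsum))
    ma, mb = np.sum(w * va) / wsum, np.sum(w * vb) / wsum
    cov = np.sum(w * (va - ma) * (vb - mb))
    sa_ = np.sqrt(np.sum(w * (va - ma) ** 2))
    sb_ = np.sqrt(np.sum(w * (vb - mb) ** 2))
    pearson = float(cov / (sa_ * sb_)) if sa_ > 0 and sb_ > 0 else 1.0
    return ConcordanceResult(euclid, pearson, int(wsum))


def random_placement_overlap(
    query: IntervalSet,
    annotation: IntervalSet,
    layout: GenomeLayout,
    n_sim: int = 10_000,
    seed: int = 0,
):
    """Overlap-enrichment test by random re-placement of the query intervals.

    Observed statistic: fraction of query intervals overlapping the
    annotation by >= 1 bp.  Each simulation re-places the same interval
    lengths uniformly at random, choosing a chromosome with probability
    proportional to its placeable length, and records the same fraction.
    Empirical p uses the +1 correction: (1 + #{sims >= observed}) / (1 + n).
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    lengths = []
    n_query = 0
    observed_hits = 0
    for chrom in query.chroms():
        for s, e in query.intervals(chrom):
            lengths.append(int(e - s))
            n_query += 1
            if annotation.overlaps(chrom, int(s), int(e)):
                observed_hits += 1
    if n_query == 0:
        raise ValueError("query set is empty")
    observed = observed_hits / n_query

    chrom_names = list(layout.names)
    chrom_lens = np.array([layout.length(c) for c in chrom_names], dtype=np.int64)
    rng = np.random.default_rng(seed)
    sims = np.empty(n_sim)
    lengths_arr = np.asarray(lengths, dtype=np.int64)
    for s in range(n_sim):
        hits = 0
        for L in lengths_arr:
            placeable = chrom_lens - L + 1
            ok = placeable > 0
            if not ok.any():
                raise ValueError(f"interval of length {L} longer than every chromosome")
            p = np.where(ok, placeable, 0).astype(float)
            ci = rng.choice(len(chrom_names), p=p / p.sum())
            start = int(rng.integers(0, placeable[ci]))
            if annotation.overlaps(chrom_names[ci], start, start + int(L)):
                hits += 1
        sims[s] = hits / n_query
    p_emp = (1 + int(np.sum(sims >= observed))) / (1 + n_sim)
    return observed, sims, p_emp
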