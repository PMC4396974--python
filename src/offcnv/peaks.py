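"""Single-sample enrichment-peak calling and peak removal.

Capture baits (and co-captured homologous sequence) produce narrow read
pile-ups that would dominate binned off-target coverage.  Peaks are called
with a local-Poisson model in the ChIP-seq tradition: each read is extended
to the expected fragment length from its 5' end, and a base is enriched if
its extended coverage exceeds a Poisson tail threshold under the maximum of
the genome-wide rate and local rates estimated in windows around the base.
A precomputed peak BED can be supplied instead of the internal caller.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from offcnv.genome_io import AlignedRead, GenomeLayout, IntervalSet


@dataclass(frozen=True)
class PeakCallerConfig:
    """Parameters of the local-Poisson enrichment caller.

    fragment_extension
        Length d to which each read is extended from its 5' end (bp).
    pvalue_cutoff
        Poisson tail probability below which a base is enrichment-candidate.
    local_lambda_windows
        Window sizes (bp) for local background rates; the local rate is the
        maximum of the genome-wide rate and each windowed rate.
    merge_gap
        Candidate bases closer than this are merged into one peak.
    min_peak_width
        Peaks narrower than this are dropped.
    """

    fragment_extension: int = 200
    pvalue_cutoff: float = 1e-5
    local_lambda_windows: tuple[int, ...] = (5000, 10000)
    merge_gap: int = 100
    min_peak_width: int = 50

    def __post_init__(self) -> None:
        if self.fragment_extension <= 0:
            raise ValueError("fragment_extension must be > 0")
        if not 0 < self.pvalue_cutoff < 1:
            raise ValueError("pvalue_cutoff must be in (0, 1)")
        if tuple(sorted(self.local_lambda_windows)) != tuple(self.local_lambda_windows):
            raise ValueError("local_lambda_windows must be sorted ascending")


class PeakSet(IntervalSet):
    """An IntervalSet carrying per-peak summit position and -log10 p score."""

    def __init__(self):
        super().__init__()
        self._summits: dict[str, np.ndarray] = {}
        self._scores: dict[str, np.ndarray] = {}

    def _add_chrom(self, chrom: str, intervals: np.ndarray, summits: np.ndarray, scores: np.ndarray) -> None:
        self._by_chrom[chrom] = np.asarray(intervals, dtype=np.int64).reshape(-1, 2)
        self._summits[chrom] = np.asarray(summits, dtype=np.int64)
        self._scores[chrom] = np.asarray(scores, dtype=float)

    def summits(self, chrom: str) -> np.ndarray:
        return self._summits.get(chrom, np.empty(0, dtype=np.int64))

    def scores(self, chrom: str) -> np.ndarray:
        return self._scores.get(chrom, np.empty(0))

    def write_bed(self, path) -> None:
        """BED6: name=peak_<k>, score column carries -log10 p (capped 10000)."""
        with open(path, "w") as fh:
            k = 0
            for chrom in self.chroms():
                for (s, e), score in zip(self.intervals(chrom), self.scores(chrom)):
                    k += 1
                    fh.write(f"{chrom}\t{s}\t{e}\tpeak_{k}\t{min(score, 10000.0):.2f}\t.\n")


def _extended_coverage(starts: np.ndarray, strands: np.ndarray, d: int, chrom_len: int) -> np.ndarray:
    """Base-level coverage of reads extended to d bp from their 5' end."""
    cov = np.zeros(chrom_len + 1, dtype=np.int32)
    fwd = starts[~strands]
    rev = starts[strands]  # for reverse reads `starts` holds the 5' end (alignment end)
    if len(fwd):
        lo = np.clip(fwd, 0, chrom_len)
        hi = np.clip(fwd + d, 0, chrom_len)
        np.add.at(cov, lo, 1)
        np.add.at(cov, hi, -1)
    if len(rev):
        lo = np.clip(rev - d, 0, chrom_len)
        hi = np.clip(rev, 0, chrom_len)
        np.add.at(cov, lo, 1)
        np.add.at(cov, hi, -1)
    return np.cumsum(cov[:-1]).astype(np.int32)


def _windowed_rate(cov: np.ndarray, w: int) -> np.ndarray:
    """Mean coverage in a w-bp window centred on each base (edges truncated)."""
    n = len(cov)
    cs = np.concatenate([[0], np.cumsum(cov, dtype=np.float64)])
    half = w // 2
    lo = np.clip(np.arange(n) - half, 0, n)
    hi = np.clip(np.arange(n) + (w - half), 0, n)
    return (cs[hi] - cs[lo]) / np.maximum(hi - lo, 1)


def call_enriched_peaks(
    reads: Sequence[AlignedRead],
    layout: GenomeLayout,
    cfg: PeakCallerConfig = PeakCallerConfig(),
) -> PeakSet:
    """Call read-enrichment peaks with the local-Poisson model.

    Deterministic for fixed input.  The genome-wide rate excludes
    mitochondrial chromosomes.
    """
    if not reads:
        raise ValueError("no reads for peak calling")
    d = cfg.fragment_extension
    genome_len = sum(l for c, l in layout.chromosomes if not layout.is_mitochondrial(c))
    # genome rate: expected extended-read coverage per base
    n_nonmito = sum(1 for r in reads if not layout.is_mitochondrial(r.chrom))
    lambda_genome = n_nonmito * d / genome_len

    by_chrom: dict[str, list[AlignedRead]] = {}
    for r in reads:
        by_chrom.setdefault(r.chrom, []).append(r)

    out = PeakSet()
    for chrom in layout.names:
        if chrom not in by_chrom or layout.is_mitochondrial(chrom):
            continue
        chrom_len = layout.length(chrom)
        rs = by_chrom[chrom]
        # Without strand information on AlignedRead, treat all reads as
        # forward; peak boundaries shift by at most d, immaterial for masking.
        starts = np.fromiter((r.start for r in rs), dtype=np.int64, count=len(rs))
        strands = np.zeros(len(rs), dtype=bool)
        cov = _extended_coverage(starts, strands, d, chrom_len)

        lam = np.full(chrom_len, lambda_genome)
        for w in cfg.local_lambda_windows:
            np.maximum(lam, _windowed_rate(cov, w), out=lam)

        # quick pre-screen: a base can only be significant where cov > lam
        cand_mask = cov > lam
        if cand_mask.any():
            idx = np.flatnonzero(cand_mask)
            pv = stats.poisson.sf(cov[idx] - 1, lam[idx])  # P(X >= k)
            sig = pv < cfg.pvalue_cutoff
            idx = idx[sig]
            pv = pv[sig]
        else:
            idx = np.empty(0, dtype=np.int64)
            pv = np.empty(0)
        if not len(idx):
            continue

        # merge candidate bases within merge_gap
        breaks = np.flatnonzero(np.diff(idx) > cfg.merge_gap)
        group_starts = np.concatenate([[0], breaks + 1])
        group_ends = np.concatenate([breaks, [len(idx) - 1]])
        ivs, summits, scores = [], [], []
        for gs, ge in zip(group_starts, group_ends):
            s, e = int(idx[gs]), int(idx[ge]) + 1
            if e - s < cfg.min_peak_width:
                continue
            block = slice(gs, ge + 1)
            summit = int(idx[block][np.argmax(cov[idx[block]])])
            with np.errstate(divide="ignore"):
                score = float(-np.log10(max(pv[block].min(), 1e-300)))
            ivs.append((s, e))
            summits.append(summit)
            scores.append(score)
        if ivs:
            out._add_chrom(chrom, np.asarray(ivs), np.asarray(summits), np.asarray(scores))
    return out


def remove_reads_in_peaks(reads: Sequence[AlignedRead], peaks: IntervalSet) -> list[AlignedRead]:
    """Discard reads whose alignment overlaps any peak by >= 1 bp.

    Applied identically to sample and reference.  Empty peak set is the
    identity.
    """
    if peaks.is_empty():
        return list(reads)
    return [r for r in reads if not peaks.overlaps(r.chrom, r.start, r.end)]


def peak_bp_per_bin(peaks: IntervalSet, bins) -> np.ndarray:
    """Cumulative masked bp x_i: intersection of peaks with each bin.

    0 <= x_i <= bin length; sums over bins to the total merged peak bp
    (peaks clipped to chromosome ends by the bin grid extent).
    """
    x = np.zeros(len(bins), dtype=np.int64)
    for chrom, lo, hi in bins.chrom_slices():
        ivs = peaks.intervals(chrom)
        if not len(ivs):
            continue
        starts = bins.start[lo:hi]
        ends = bins.end[lo:hi]
        # clip peaks to the binned extent of the chromosome
        cend = int(ends[-1])
        ivs = np.clip(ivs, 0, cend)
        ivs = ivs[ivs[:, 0] < ivs[:, 1]]
        for s, e in ivs:
            first = int(np.searchsorted(ends, s, side="right"))
            last = int(np.searchsorted(starts, e, side="left"))
            for i in range(first, last):
                x[lo + i] += min(e, ends[i]) - max(s, starts[i])
    return x
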