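"""Genome-wide bin grid, binned depth of coverage, and peak compensation.

Depth of coverage (DOC) is the number of reads whose leftmost aligned base
falls in a bin — the standard read-count statistic for copy-number work.
When enrichment peaks are masked out of a bin, the remaining territory is
smaller, so the count is rescaled by bin_length / (bin_length - masked_bp)
("compensated DOC").  Per-base pileup is used only by the on-target
comparator, which averages coverage per base over each capture region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from offcnv.genome_io import AlignedRead, GenomeLayout, IntervalSet

DEFAULT_BIN_SIZE = 20_000


@dataclass(frozen=True)
class BinGrid:
    """Consecutive fixed-width bins tiling each chromosome.

    All bins have width ``bin_size`` except possibly the terminal bin of
    each chromosome, which keeps its true (shorter) length.
    """

    layout: GenomeLayout
    bin_size: int
    chrom: np.ndarray  # per-bin chromosome name
    start: np.ndarray
    end: np.ndarray

    def __len__(self) -> int:
        return len(self.start)

    @property
    def length(self) -> np.ndarray:
        """Actual bin lengths L_b."""
        return self.end - self.start

    def chrom_slices(self) -> Iterator[tuple[str, int, int]]:
        """Yield (chrom, first_bin_index, stop_bin_index) per chromosome."""
        lo = 0
        for name, _ in self.layout.chromosomes:
            hi = lo
            while hi < len(self) and self.chrom[hi] == name:
                hi += 1
            if hi > lo:
                yield name, lo, hi
            lo = hi

    def index_of(self, chrom: str, pos: int) -> int:
        for name, lo, hi in self.chrom_slices():
            if name == chrom:
                return lo + min(pos // self.bin_size, hi - lo - 1)
        raise KeyError(chrom)

    def autosomal_mask(self) -> np.ndarray:
        return np.fromiter(
            (self.layout.is_autosome(c) for c in self.chrom), dtype=bool, count=len(self)
        )


def make_bins(layout: GenomeLayout, bin_size: int = DEFAULT_BIN_SIZE) -> BinGrid:
    """Tile every non-mitochondrial chromosome with consecutive bins."""
    if bin_size <= 0:
        raise ValueError("bin size must be > 0")
    chroms, starts, ends = [], [], []
    for name, length in layout.chromosomes:
        if layout.is_mitochondrial(name):
            continue
        edges = np.arange(0, length, bin_size, dtype=np.int64)
        chroms.extend([name] * len(edges))
        starts.append(edges)
        ends.append(np.minimum(edges + bin_size, length))
    return BinGrid(
        layout=layout,
        bin_size=int(bin_size),
        chrom=np.asarray(chroms, dtype=object),
        start=np.concatenate(starts) if starts else np.empty(0, dtype=np.int64),
        end=np.concatenate(ends) if ends else np.empty(0, dtype=np.int64),
    )


def depth_of_coverage(reads: Sequence[AlignedRead], bins: BinGrid) -> np.ndarray:
    """Read-start counts per bin; conserves the total read count."""
    doc = np.zeros(len(bins), dtype=np.int64)
    offsets = {chrom: (lo, hi) for chrom, lo, hi in bins.chrom_slices()}
    for r in reads:
        if r.chrom not in offsets:
            continue
        lo, hi = offsets[r.chrom]
        doc[lo + min(r.start // bins.bin_size, hi - lo - 1)] += 1
    return doc


def compensate_doc(
    raw_doc: np.ndarray,
    x: np.ndarray,
    bin_length: np.ndarray,
    min_effective_fraction: float = 0.1,
) -> np.ndarray:
    """Rescale counts for peak-masked territory: raw * L_b / (L_b - x).

    Bins whose effective (unmasked) fraction falls below
    ``min_effective_fraction`` become NaN: the compensation factor would
    explode and the count carries almost no information.
    """
    raw_doc = np.asarray(raw_doc, dtype=float)
    x = np.asarray(x, dtype=float)
    bin_length = np.asarray(bin_length, dtype=float)
    if np.any(x > bin_length):
        raise ValueError("masked bp exceeds bin length; peak accounting bug upstream")
    effective = bin_length - x
    ok = effective / bin_length >= min_effective_fraction
    out = np.full(len(raw_doc), np.nan)
    out[ok] = raw_doc[ok] * bin_length[ok] / effective[ok]
    return out


@dataclass
class CoverageProfile:
    """Per-bin coverage values through the normalisation pipeline.

    Missing values are NaN.  ``usable`` marks bins that pass the filters
    and participate in normalisation and segmentation.
    """

    bins: BinGrid
    raw_doc: np.ndarray
    x: np.ndarray
    comp_doc: np.ndarray | None = None
    gc: np.ndarray | None = None
    mappability: np.ndarray | None = None
    corrected: np.ndarray | None = None
    log2: np.ndarray | None = None
    usable: np.ndarray | None = None

    def _col(self, name: str) -> np.ndarray:
        v = getattr(self, name)
        if v is None:
            return np.full(len(self.bins), np.nan)
        return v

    def to_frame(self) -> pd.DataFrame:
        usable = self.usable if self.usable is not None else np.ones(len(self.bins), dtype=bool)
        return pd.DataFrame(
            {
                "chrom": self.bins.chrom,
                "start": self.bins.start,
                "end": self.bins.end,
                "raw_doc": self.raw_doc,
                "masked_bp": self.x,
                "comp_doc": self._col("comp_doc"),
                "gc": self._col("gc"),
                "mappability": self._col("mappability"),
                "corrected": self._col("corrected"),
                "log2": self._col("log2"),
                "usable": usable,
            }
        )


def ontarget_mean_doc(
    reads: Sequence[AlignedRead],
    capture_regions: IntervalSet,
    layout: GenomeLayout,
) -> pd.DataFrame:
    """Mean per-base coverage over each capture region (the exon comparator).

    Uses filtered but *not* peak-removed reads: the comparator disregards
    background reads and applies no peak removal or compensation.  Returns
    a DataFrame (chrom, start, end, mean_doc) in layout order; downstream
    normalisation and segmentation are shared with the off-target pipeline.
    """
    if capture_regions.is_empty():
        raise ValueError("capture region set is empty")
    by_chrom: dict[str, list[AlignedRead]] = {}
    for r in reads:
        by_chrom.setdefault(r.chrom, []).append(r)
    rows = []
    for chrom in layout.names:
        ivs = capture_regions.intervals(chrom)
        if not len(ivs):
            continue
        chrom_len = layout.length(chrom)
        cov = np.zeros(chrom_len + 1, dtype=np.int32)
        for r in by_chrom.get(chrom, []):
            cov[min(r.start, chrom_len)] += 1
            cov[min(r.end, chrom_len)] -= 1
        cov = np.cumsum(cov[:-1])
        cs = np.concatenate([[0], np.cumsum(cov, dtype=np.float64)])
        for s, e in ivs:
            rows.append((chrom, int(s), int(e), (cs[e] - cs[s]) / (e - s)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "mean_doc"])
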