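"""Alignment, genome, and region-file I/O with the workflow's read filters.

All internal coordinates are 0-based half-open.  SAM/BAM positions are
converted on ingest (pysam already reports 0-based ``reference_start``);
BED is consumed natively.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from pyfaidx import Fasta

DEFAULT_MITOCHONDRIAL_NAMES = frozenset({"chrM", "MT", "chrMT", "M"})
DEFAULT_SEX_NAMES = frozenset({"chrX", "chrY", "X", "Y"})


class MissingIndexError(FileNotFoundError):
    """A coordinate-sorted BAM was supplied without its index."""


class UnknownChromosomeError(ValueError):
    """A chromosome in the input cannot be resolved against the genome layout."""


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths; the shared coordinate universe.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length)`` pairs; names unique, lengths positive.
    mitochondrial_names
        Names treated as mitochondrial (excluded from coverage analysis).
    sex_names
        Names treated as sex chromosomes (excluded from the normalisation
        median so X/Y copy state does not shift the autosomal baseline).
    """

    chromosomes: tuple[tuple[str, int], ...]
    mitochondrial_names: frozenset[str] = DEFAULT_MITOCHONDRIAL_NAMES
    sex_names: frozenset[str] = DEFAULT_SEX_NAMES

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(names) != len(set(names)):
            raise ValueError("chromosome names must be unique")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        object.__setattr__(self, "chromosomes", tuple((str(n), int(l)) for n, l in self.chromosomes))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.chromosomes)

    @property
    def lengths(self) -> Mapping[str, int]:
        return dict(self.chromosomes)

    def length(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise UnknownChromosomeError(f"chromosome {chrom!r} not in genome layout") from None

    def is_mitochondrial(self, chrom: str) -> bool:
        return chrom in self.mitochondrial_names

    def is_autosome(self, chrom: str) -> bool:
        return chrom not in self.mitochondrial_names and chrom not in self.sex_names

    def autosome_names(self) -> tuple[str, ...]:
        return tuple(n for n in self.names if self.is_autosome(n))

    def resolve(self, chrom: str) -> str | None:
        """Map a chromosome name onto the layout, tolerating a 'chr' prefix mismatch.

        Returns the layout name, or None if the name is absent even after
        adding/stripping the prefix.
        """
        if chrom in self.lengths:
            return chrom
        alt = chrom[3:] if chrom.startswith("chr") else "chr" + chrom
        if alt in self.lengths:
            return alt
        return None

    @classmethod
    def from_chrom_sizes(cls, path: str | os.PathLike, **kw) -> "GenomeLayout":
        """Load from a two-column chrom<TAB>size table."""
        tbl = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1], names=["chrom", "size"])
        return cls(tuple(zip(tbl["chrom"].astype(str), tbl["size"].astype(int))), **kw)

    @classmethod
    def from_fasta(cls, path: str | os.PathLike, **kw) -> "GenomeLayout":
        """Load from an (indexed) FASTA; builds the .fai on first use."""
        fa = Fasta(str(path))
        return cls(tuple((name, len(fa[name])) for name in fa.keys()), **kw)

    @classmethod
    def from_alignment(cls, path: str | os.PathLike, **kw) -> "GenomeLayout":
        with pysam.AlignmentFile(str(path), require_index=False) as af:
            return cls(tuple(zip(af.references, af.lengths)), **kw)


@dataclass(frozen=True)
class AlignedRead:
    """A mapped sequencing read in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    mapq: int
    proper_pair: bool
    duplicate: bool = False
    unmapped: bool = False

    def __post_init__(self) -> None:
        if not self.unmapped and self.start >= self.end:
            raise ValueError(f"mapped read must have start < end, got [{self.start}, {self.end})")
        if not 0 <= self.mapq <= 255:
            raise ValueError(f"mapq {self.mapq} outside [0, 255]")


@dataclass(frozen=True)
class ReadFilterConfig:
    """Read filters applied before any coverage computation.

    Defaults follow the workflow: retain proper pairs with mapping quality
    at least 37, drop duplicates and mitochondrial reads.
    """

    min_mapq: int = 37
    require_proper_pair: bool = True
    drop_duplicates: bool = True
    drop_mitochondrial: bool = True

    def __post_init__(self) -> None:
        if self.min_mapq < 0:
            raise ValueError("min_mapq must be >= 0")


class IntervalSet:
    """Sorted, merged, per-chromosome genomic intervals (0-based half-open).

    Container for capture regions, enrichment peaks, and blacklists.
    Intervals are normalised on construction: sorted by start and merged
    where overlapping or book-ended.  Optional per-interval scores are
    dropped by merging; use :class:`~offcnv.peaks.PeakSet` to keep scores.
    """

    def __init__(self, intervals: Mapping[str, Sequence[tuple[int, int]]] | None = None):
        self._by_chrom: dict[str, np.ndarray] = {}
        if intervals:
            for chrom, ivs in intervals.items():
                arr = np.asarray(sorted((int(s), int(e)) for s, e in ivs), dtype=np.int64)
                self._by_chrom[chrom] = _merge(arr)

    @staticmethod
    def from_dataframe(df: pd.DataFrame) -> "IntervalSet":
        out = IntervalSet()
        for chrom, grp in df.groupby("chrom", sort=False):
            arr = np.asarray(sorted(zip(grp["start"].astype(int), grp["end"].astype(int))), dtype=np.int64)
            out._by_chrom[str(chrom)] = _merge(arr)
        return out

    @staticmethod
    def read_bed(path: str | os.PathLike) -> "IntervalSet":
        """Read BED3+ (extra columns ignored; '#' and 'track' lines skipped)."""
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                rows.append((f[0], int(f[1]), int(f[2])))
        if not rows:
            return IntervalSet()
        return IntervalSet.from_dataframe(pd.DataFrame(rows, columns=["chrom", "start", "end"]))

    def write_bed(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            for chrom in self.chroms():
                for s, e in self.intervals(chrom):
                    fh.write(f"{chrom}\t{s}\t{e}\n")

    def chroms(self) -> list[str]:
        return [c for c in self._by_chrom if len(self._by_chrom[c])]

    def intervals(self, chrom: str) -> np.ndarray:
        """(n, 2) array of merged intervals on one chromosome (possibly empty)."""
        return self._by_chrom.get(chrom, np.empty((0, 2), dtype=np.int64))

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_chrom.values())

    def total_bp(self) -> int:
        return int(sum((v[:, 1] - v[:, 0]).sum() for v in self._by_chrom.values()))

    def is_empty(self) -> bool:
        return len(self) == 0

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True iff [start, end) overlaps any interval by >= 1 bp."""
        ivs = self.intervals(chrom)
        if not len(ivs):
            return False
        i = int(np.searchsorted(ivs[:, 0], end, side="left"))
        return i > 0 and ivs[i - 1, 1] > start

    def overlap_bp(self, chrom: str, start: int, end: int) -> int:
        """Total intersection bp between [start, end) and the set."""
        ivs = self.intervals(chrom)
        if not len(ivs):
            return 0
        s = np.maximum(ivs[:, 0], start)
        e = np.minimum(ivs[:, 1], end)
        return int(np.maximum(e - s, 0).sum())

    def clipped_to(self, layout: GenomeLayout) -> "IntervalSet":
        out = IntervalSet()
        for chrom in self.chroms():
            res = layout.resolve(chrom)
            if res is None:
                continue
            n = layout.length(res)
            ivs = np.clip(self.intervals(chrom), 0, n)
            ivs = ivs[ivs[:, 0] < ivs[:, 1]]
            if len(ivs):
                out._by_chrom[res] = _merge(ivs)
        return out

    def union(self, other: "IntervalSet") -> "IntervalSet":
        out = IntervalSet()
        for chrom in set(self.chroms()) | set(other.chroms()):
            both = np.vstack([self.intervals(chrom), other.intervals(chrom)])
            out._by_chrom[chrom] = _merge(both[np.lexsort((both[:, 1], both[:, 0]))])
        return out


def _merge(arr: np.ndarray) -> np.ndarray:
    """Merge sorted intervals that overlap or touch."""
    if len(arr) <= 1:
        return arr
    merged = [list(arr[0])]
    for s, e in arr[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged, dtype=np.int64)


def _open_alignment(path: str | os.PathLike) -> pysam.AlignmentFile:
    path = str(path)
    af = pysam.AlignmentFile(path, require_index=False)
    if af.is_bam or af.is_cram:
        if not af.has_index():
            af.close()
            raise MissingIndexError(
                f"{path} has no index (.bai/.csi); run 'samtools index' on the coordinate-sorted file"
            )
    return af


def _iter_primary(af: pysam.AlignmentFile) -> Iterator[pysam.AlignedSegment]:
    for rec in af:
        if rec.is_secondary or rec.is_supplementary:
            continue
        yield rec


def _check_chrom(chrom: str, layout: GenomeLayout) -> str:
    res = layout.resolve(chrom)
    if res is None:
        raise UnknownChromosomeError(
            f"chromosome {chrom!r} present in alignment file but absent from the genome layout"
        )
    return res


def load_filtered_reads(
    alignment_path: str | os.PathLike,
    layout: GenomeLayout,
    cfg: ReadFilterConfig = ReadFilterConfig(),
) -> list[AlignedRead]:
    """Load mapped reads passing the workflow filters, in coordinate order.

    Retains primary, mapped, proper-pair (if required), non-duplicate (if
    required) reads with ``mapq >= min_mapq`` on non-mitochondrial
    chromosomes.  Secondary/supplementary alignments are never counted.
    """
    out: list[AlignedRead] = []
    with _open_alignment(alignment_path) as af:
        for rec in _iter_primary(af):
            if rec.is_unmapped:
                continue
            chrom = _check_chrom(rec.reference_name, layout)
            if cfg.drop_mitochondrial and layout.is_mitochondrial(chrom):
                continue
            if rec.mapping_quality < cfg.min_mapq:
                continue
            if cfg.require_proper_pair and not rec.is_proper_pair:
                continue
            if cfg.drop_duplicates and rec.is_duplicate:
                continue
            out.append(
                AlignedRead(
                    chrom=chrom,
                    start=rec.reference_start,
                    end=rec.reference_end if rec.reference_end is not None else rec.reference_start + 1,
                    mapq=rec.mapping_quality,
                    proper_pair=rec.is_proper_pair,
                    duplicate=rec.is_duplicate,
                )
            )
    return out


def classify_reads(
    alignment_path: str | os.PathLike,
    peaks: IntervalSet,
    layout: GenomeLayout,
    cfg: ReadFilterConfig = ReadFilterConfig(),
) -> dict[str, int]:
    """Classify primary records into mutually exclusive QC categories.

    Categories, assigned in order: ``low_quality`` (unmapped, duplicate,
    mapq below threshold, or not properly paired), ``mitochondrial``,
    ``in_peaks`` (alignment overlaps an enrichment peak by >= 1 bp), and
    ``remaining`` (the reads usable for copy-number calling).  Counts sum
    to the number of primary records in the file.
    """
    counts = {"low_quality": 0, "mitochondrial": 0, "in_peaks": 0, "remaining": 0}
    with _open_alignment(alignment_path) as af:
        for rec in _iter_primary(af):
            if (
                rec.is_unmapped
                or rec.is_duplicate
                or rec.mapping_quality < cfg.min_mapq
                or (cfg.require_proper_pair and not rec.is_proper_pair)
            ):
                counts["low_quality"] += 1
                continue
            chrom = _check_chrom(rec.reference_name, layout)
            if layout.is_mitochondrial(chrom):
                counts["mitochondrial"] += 1
                continue
            end = rec.reference_end if rec.reference_end is not None else rec.reference_start + 1
            if peaks.overlaps(chrom, rec.reference_start, end):
                counts["in_peaks"] += 1
                continue
            counts["remaining"] += 1
    return counts


def write_bin_table(profile, path: str | os.PathLike) -> None:
    """Write the per-bin log table (tab-separated)."""
    profile.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="NA")


def write_seg(segments, path: str | os.PathLike, sample: str = "sample") -> None:
    """Write segments in the IGV SEG dialect (1-based inclusive start)."""
    with open(path, "w") as fh:
        fh.write("ID\tchrom\tloc.start\tloc.end\tnum.mark\tseg.mean\n")
        for seg in segments:
            fh.write(f"{sample}\t{seg.chrom}\t{seg.start + 1}\t{seg.end}\t{seg.n_bins}\t{seg.mean:.6f}\n")
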