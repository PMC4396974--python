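"""End-to-end workflow: filter -> peaks -> bin -> compensate -> correct ->
log2 -> (reference subtraction) -> segment, in relative or absolute mode.

Relative mode (a matched reference alignment is given) subtracts the
reference's normalised log2 from the sample's, cancelling shared capture
artefacts.  Absolute mode normalises the sample against its own autosomal
median; peaks are then called in the sample itself.  The exon-based
"on-target" comparator shares the normalisation and segmentation stages
but uses mean per-base coverage over capture regions, with no peak removal
or compensation.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from offcnv import genome_io
from offcnv.coverage import (
    BinGrid,
    CoverageProfile,
    compensate_doc,
    depth_of_coverage,
    make_bins,
    ontarget_mean_doc,
)
from offcnv.genome_io import GenomeLayout, IntervalSet, ReadFilterConfig
from offcnv.metrics import mad_diff
from offcnv.normalize import (
    BinFilterConfig,
    LoessConfig,
    apply_bin_filters,
    correct_profile,
    gc_fraction_per_bin,
    mappability_per_bin,
    median_normalize_log2,
    read_bedgraph,
    relative_log2,
)
from offcnv.peaks import PeakCallerConfig, call_enriched_peaks, peak_bp_per_bin, remove_reads_in_peaks
from offcnv.segment import SegmentSet, SegmentationConfig, cbs_segment


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Mode is derived: relative iff ``reference_path`` is given.
    """

    sample_path: str
    reference_path: str | None = None
    bin_size: int = 20_000
    genome_fasta: str | None = None
    chrom_sizes: str | None = None
    mappability_path: str | None = None
    blacklist_path: str | None = None
    peaks_bed: str | None = None
    capture_bed: str | None = None
    method: str = "offtarget"  # or "ontarget"
    peak_removal: bool = True
    union_peaks: bool = False  # union of sample+reference peak sets
    output_dir: str | None = None
    sample_name: str = "sample"
    seed: int = 0
    read_filter: ReadFilterConfig = field(default_factory=ReadFilterConfig)
    peak_caller: PeakCallerConfig = field(default_factory=PeakCallerConfig)
    loess: LoessConfig = field(default_factory=LoessConfig)
    bin_filter: BinFilterConfig = field(default_factory=BinFilterConfig)
    segmentation: SegmentationConfig | None = None
    segment: bool = True

    @property
    def relative(self) -> bool:
        return self.reference_path is not None

    def resolved_segmentation(self) -> SegmentationConfig:
        return self.segmentation or SegmentationConfig(seed=self.seed)


@dataclass
class PipelineResult:
    layout: GenomeLayout
    bins: BinGrid
    profile: CoverageProfile
    reference_profile: CoverageProfile | None
    final_log2: np.ndarray
    usable: np.ndarray
    peaks: IntervalSet
    segments: SegmentSet | None
    qc: dict


def _load_layout(cfg: RunConfig) -> GenomeLayout:
    if cfg.genome_fasta:
        return GenomeLayout.from_fasta(cfg.genome_fasta)
    if cfg.chrom_sizes:
        return GenomeLayout.from_chrom_sizes(cfg.chrom_sizes)
    return GenomeLayout.from_alignment(cfg.sample_path)


def _normalized_log2(
    profile: CoverageProfile, blacklist: IntervalSet | None, cfg: RunConfig
) -> np.ndarray:
    """Loess corrections, filters, median normalisation for one profile."""
    if profile.gc is not None or profile.mappability is not None:
        profile.corrected = correct_profile(profile, cfg.loess)
    else:
        profile.corrected = np.asarray(profile.comp_doc, dtype=float)
    apply_bin_filters(profile, blacklist, cfg.bin_filter)
    profile.log2 = median_normalize_log2(profile.corrected, profile.usable, profile.bins)
    return profile.log2


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute the full workflow; identical config and inputs give identical outputs."""
    stage = "setup"
    written: list[Path] = []
    try:
        layout = _load_layout(cfg)
        bins = make_bins(layout, cfg.bin_size)

        stage = "read filtering"
        sample_reads = genome_io.load_filtered_reads(cfg.sample_path, layout, cfg.read_filter)
        ref_reads = (
            genome_io.load_filtered_reads(cfg.reference_path, layout, cfg.read_filter)
            if cfg.relative
            else None
        )

        stage = "peak calling"
        if cfg.peaks_bed:
            peaks: IntervalSet = IntervalSet.read_bed(cfg.peaks_bed).clipped_to(layout)
        elif not cfg.peak_removal:
            peaks = IntervalSet()
        elif cfg.relative:
            peaks = call_enriched_peaks(ref_reads, layout, cfg.peak_caller)
            if cfg.union_peaks:
                peaks = peaks.union(call_enriched_peaks(sample_reads, layout, cfg.peak_caller))
        else:
            peaks = call_enriched_peaks(sample_reads, layout, cfg.peak_caller)

        if cfg.method == "ontarget":
            return _run_ontarget(cfg, layout, sample_reads, ref_reads, peaks)
        if cfg.method != "offtarget":
            raise ValueError(f"unknown method {cfg.method!r}")

        stage = "peak removal"
        if cfg.peak_removal:
            sample_kept = remove_reads_in_peaks(sample_reads, peaks)
            ref_kept = remove_reads_in_peaks(ref_reads, peaks) if ref_reads is not None else None
        else:
            sample_kept, ref_kept = sample_reads, ref_reads

        stage = "binned coverage"
        x = peak_bp_per_bin(peaks, bins) if cfg.peak_removal else np.zeros(len(bins), dtype=np.int64)

        def build_profile(reads) -> CoverageProfile:
            doc = depth_of_coverage(reads, bins)
            prof = CoverageProfile(bins=bins, raw_doc=doc, x=x)
            prof.comp_doc = compensate_doc(doc, x, bins.length)
            return prof

        profile = build_profile(sample_kept)
        ref_profile = build_profile(ref_kept) if ref_kept is not None else None

        stage = "bin annotation"
        gc = gc_fraction_per_bin(cfg.genome_fasta, bins) if cfg.genome_fasta else None
        mapp = (
            mappability_per_bin(read_bedgraph(cfg.mappability_path), bins)
            if cfg.mappability_path
            else None
        )
        for prof in filter(None, [profile, ref_profile]):
            prof.gc = gc
            prof.mappability = mapp

        stage = "normalization"
        blacklist = (
            IntervalSet.read_bed(cfg.blacklist_path).clipped_to(layout) if cfg.blacklist_path else None
        )
        sample_log2 = _normalized_log2(profile, blacklist, cfg)
        if ref_profile is not None:
            ref_log2 = _normalized_log2(ref_profile, blacklist, cfg)
            final = relative_log2(sample_log2, ref_log2)
            usable = profile.usable & ref_profile.usable
        else:
            final = sample_log2
            usable = profile.usable

        stage = "segmentation"
        segments = (
            cbs_segment(final, usable, bins, cfg.resolved_segmentation()) if cfg.segment else None
        )

        stage = "reporting"
        sel = usable & np.isfinite(final)
        qc = {
            "mode": "relative" if cfg.relative else "absolute",
            "n_reads_sample": len(sample_reads),
            "n_reads_sample_after_peak_removal": len(sample_kept),
            "n_peaks": len(peaks),
            "peak_bp": peaks.total_bp(),
            "n_bins": len(bins),
            "n_usable_bins": int(sel.sum()),
            "mad_diff": mad_diff(final[sel]) if sel.sum() >= 3 else None,
            "n_segments": len(segments) if segments is not None else None,
        }
        result = PipelineResult(layout, bins, profile, ref_profile, final, usable, peaks, segments, qc)
        if cfg.output_dir:
            written = _write_outputs(cfg, result, final)
        return result
    except PipelineError:
        raise
    except Exception as err:
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError(f"pipeline failed at stage '{stage}': {err}") from err


def _run_ontarget(cfg, layout, sample_reads, ref_reads, peaks) -> PipelineResult:
    """The exon-DOC comparator: per-capture-region mean coverage, no peak
    removal or compensation, shared normalisation and segmentation."""
    if not cfg.capture_bed:
        raise ValueError("method 'ontarget' requires capture regions (--capture-bed)")
    regions = IntervalSet.read_bed(cfg.capture_bed).clipped_to(layout)
    tbl = ontarget_mean_doc(sample_reads, regions, layout)
    grid = BinGrid(
        layout=layout,
        bin_size=cfg.bin_size,
        chrom=tbl["chrom"].to_numpy(dtype=object),
        start=tbl["start"].to_numpy(),
        end=tbl["end"].to_numpy(),
    )
    prof = CoverageProfile(bins=grid, raw_doc=tbl["mean_doc"].to_numpy(), x=np.zeros(len(grid), dtype=np.int64))
    prof.comp_doc = tbl["mean_doc"].to_numpy(dtype=float)
    blacklist = IntervalSet.read_bed(cfg.blacklist_path).clipped_to(layout) if cfg.blacklist_path else None
    apply_bin_filters(prof, blacklist, cfg.bin_filter)
    prof.corrected = np.asarray(prof.comp_doc, dtype=float)
    prof.log2 = median_normalize_log2(prof.corrected, prof.usable, grid)
    final = prof.log2
    usable = prof.usable
    ref_prof = None
    if ref_reads is not None:
        rtbl = ontarget_mean_doc(ref_reads, regions, layout)
        ref_prof = CoverageProfile(
            bins=grid, raw_doc=rtbl["mean_doc"].to_numpy(), x=np.zeros(len(grid), dtype=np.int64)
        )
        ref_prof.comp_doc = rtbl["mean_doc"].to_numpy(dtype=float)
        apply_bin_filters(ref_prof, blacklist, cfg.bin_filter)
        ref_prof.corrected = np.asarray(ref_prof.comp_doc, dtype=float)
        ref_prof.log2 = median_normalize_log2(ref_prof.corrected, ref_prof.usable, grid)
        final = relative_log2(prof.log2, ref_prof.log2)
        usable = prof.usable & ref_prof.usable
    segments = cbs_segment(final, usable, grid, cfg.resolved_segmentation()) if cfg.segment else None
    sel = usable & np.isfinite(final)
    qc = {
        "mode": ("relative" if ref_reads is not None else "absolute") + "-ontarget",
        "n_regions": len(grid),
        "n_usable_bins": int(sel.sum()),
        "mad_diff": mad_diff(final[sel]) if sel.sum() >= 3 else None,
        "n_segments": len(segments) if segments is not None else None,
    }
    return PipelineResult(layout, grid, prof, ref_prof, final, usable, peaks, segments, qc)


def _config_digest(cfg: RunConfig) -> str:
    blob = json.dumps(
        {k: v for k, v in asdict(cfg).items() if not isinstance(v, (ReadFilterConfig,))},
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _write_outputs(cfg: RunConfig, result: PipelineResult, final: np.ndarray) -> list[Path]:
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    prof = result.profile
    tbl = prof.to_frame()
    tbl["final_log2"] = final
    bin_path = outdir / f"{cfg.sample_name}.bins.tsv"
    tbl.to_csv(bin_path, sep="\t", index=False, float_format="%.6g", na_rep="NA")
    written.append(bin_path)

    peaks_path = outdir / f"{cfg.sample_name}.peaks.bed"
    result.peaks.write_bed(peaks_path)
    written.append(peaks_path)

    if result.segments is not None:
        seg_path = outdir / f"{cfg.sample_name}.segments.seg"
        genome_io.write_seg(result.segments, seg_path, sample=cfg.sample_name)
        written.append(seg_path)

    qc_path = outdir / f"{cfg.sample_name}.qc.json"
    qc_path.write_text(json.dumps(result.qc, indent=2) + "\n")
    written.append(qc_path)

    log_path = outdir / f"{cfg.sample_name}.run.log"
    from offcnv import __version__

    lines = [f"offcnv {__version__}", f"config_digest {_config_digest(cfg)}"]
    for k, v in asdict(cfg).items():
        lines.append(f"{k} = {v}")
    log_path.write_text("\n".join(lines) + "\n")
    written.append(log_path)
    return written


def plot_profile(result: PipelineResult, path: str | os.PathLike, title: str = "") -> None:
    """One basic genome-wide profile plot: per-bin log2 with segment means."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    bins = result.bins
    offsets = {}
    acc = 0
    for name, length in result.layout.chromosomes:
        offsets[name] = acc
        acc += length
    xs = np.array([offsets[c] for c in bins.chrom]) + (bins.start + bins.end) / 2
    fig, ax = plt.subplots(figsize=(12, 4))
    sel = result.usable & np.isfinite(result.final_log2)
    ax.plot(xs[sel], result.final_log2[sel], ".", ms=2, color="0.4")
    if result.segments is not None:
        for seg in result.segments:
            o = offsets[seg.chrom]
            ax.plot([o + seg.start, o + seg.end], [seg.mean, seg.mean], "r-", lw=2)
    for name in offsets:
        ax.axvline(offsets[name], color="0.8", lw=0.5)
    ax.set_ylabel("log2 ratio")
    ax.set_xlabel("genome position")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
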