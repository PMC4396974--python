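"""Bin annotation (GC, mappability), loess corrections, filters, log2 ratios.

Read counts from capture protocols carry systematic trends in GC content
and alignability.  Each trend is removed by a multiplicative loess
correction: a local-polynomial curve m(c) is fitted to the counts against
the covariate, and each bin is rescaled by median(values)/m(c_i), which
flattens the trend while preserving the profile median.  Corrections are
applied covariate by covariate (GC first, then mappability).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
import numpy as np
import pandas as pd
from pyfaidx import Fasta

from offcnv.coverage import BinGrid, CoverageProfile
from offcnv.genome_io import IntervalSet, UnknownChromosomeError


@dataclass(frozen=True)
class BinFilterConfig:
    """Usability filters applied before normalisation.

    A bin is excluded if its mappability is below ``min_mappability``, if
    its blacklist overlap fraction exceeds ``blacklist_overlap_max``
    (default: any overlap excludes), or if it has zero/missing compensated
    count (``require_nonzero_doc``).
    """

    min_mappability: float = 0.2
    blacklist_overlap_max: float = 0.0
    require_nonzero_doc: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.min_mappability <= 1 or not 0 <= self.blacklist_overlap_max <= 1:
            raise ValueError("thresholds must lie in [0, 1]")


@dataclass(frozen=True)
class LoessConfig:
    """Local-polynomial correction parameters.

    ``robust_iterations`` bisquare-reweights the fit so copy-number
    aberrations are treated as outliers of the covariate trend rather than
    absorbed into it (the symmetric-family loess of common read-depth
    pipelines); 0 disables.  ``trim_quantiles`` drops bins with extreme
    residuals from a first-pass fit before refitting.
    """

    span: float = 0.75
    degree: int = 2
    covariate_order: tuple[str, ...] = ("gc", "mappability")
    robust_iterations: int = 3
    trim_quantiles: tuple[float, float] = (0.1, 0.9)

    def __post_init__(self) -> None:
        if not 0 < self.span <= 1:
            raise ValueError("span must be in (0, 1]")
        if self.degree not in (1, 2):
            raise ValueError("degree must be 1 or 2")
        if self.robust_iterations < 0:
            raise ValueError("robust_iterations must be >= 0")
        lo, hi = self.trim_quantiles
        if not 0 <= lo < hi <= 1:
            raise ValueError("trim_quantiles must satisfy 0 <= lo < hi <= 1")


def gc_fraction_per_bin(genome_fasta: str | os.PathLike, bins: BinGrid, min_defined_fraction: float = 0.1) -> np.ndarray:
    """(G+C)/(A+C+G+T) per bin, case-insensitive; NaN when the bin is
    mostly undefined (non-ACGT bases > 1 - min_defined_fraction)."""
    fa = Fasta(str(genome_fasta))
    gc = np.full(len(bins), np.nan)
    for chrom, lo, hi in bins.chrom_slices():
        if chrom not in fa:
            raise UnknownChromosomeError(f"chromosome {chrom!r} absent from FASTA")
        seq = np.frombuffer(str(fa[chrom][:]).upper().encode(), dtype="S1")
        for i in range(lo, hi):
            sub = seq[bins.start[i] : bins.end[i]]
            n_gc = int(np.sum(sub == b"G") + np.sum(sub == b"C"))
            n_at = int(np.sum(sub == b"A") + np.sum(sub == b"T"))
            n = n_gc + n_at
            if n >= min_defined_fraction * (bins.end[i] - bins.start[i]):
                gc[i] = n_gc / n
    return gc


def read_bedgraph(path: str | os.PathLike) -> pd.DataFrame:
    """Read a bedGraph track (chrom, start, end, value)."""
    return pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float},
    )


def mappability_per_bin(track: pd.DataFrame, bins: BinGrid) -> np.ndarray:
    """Length-weighted mean mappability over each bin; uncovered bases
    count as 0.  `track` is a bedGraph-style frame with values in [0, 1]."""
    if len(track) and (track["value"].min() < 0 or track["value"].max() > 1):
        raise ValueError("mappability values must lie in [0, 1]")
    out = np.zeros(len(bins))
    grouped = {c: g for c, g in track.groupby("chrom", sort=False)}
    for chrom, lo, hi in bins.chrom_slices():
        g = grouped.get(chrom)
        if g is None:
            continue
        ts = g["start"].to_numpy()
        te = g["end"].to_numpy()
        tv = g["value"].to_numpy()
        starts = bins.start[lo:hi]
        ends = bins.end[lo:hi]
        for j, (s, e, v) in enumerate(zip(ts, te, tv)):
            first = int(np.searchsorted(ends, s, side="right"))
            last = int(np.searchsorted(starts, e, side="left"))
            for i in range(first, last):
                ov = min(e, ends[i]) - max(s, starts[i])
                if ov > 0:
                    out[lo + i] += v * ov
    out /= bins.length
    return out


def _local_poly_eval(
    xs: np.ndarray,
    ys: np.ndarray,
    rw: np.ndarray,
    x_eval: np.ndarray,
    k: int,
    degree: int,
) -> np.ndarray:
    """Evaluate a tricube-weighted local polynomial of sorted data at x_eval."""
    n = len(xs)
    out = np.empty(len(x_eval))
    for i, x0 in enumerate(x_eval):
        pos = int(np.searchsorted(xs, x0))
        lo = max(0, pos - k)
        hi = min(n, pos + k)
        window = np.abs(xs[lo:hi] - x0)
        take = min(k, hi - lo)
        idx = np.argpartition(window, take - 1)[:take] + lo
        xi, yi, rwi = xs[idx], ys[idx], rw[idx]
        h = np.abs(xi - x0).max()
        if h == 0:
            out[i] = np.average(yi, weights=rwi) if rwi.sum() > 0 else yi.mean()
            continue
        w = (1 - np.clip(np.abs(xi - x0) / h, 0, 1) ** 3) ** 3 * rwi
        if w.sum() <= 0 or np.count_nonzero(w) <= degree:
            out[i] = yi.mean()
            continue
        X = np.vander(xi - x0, degree + 1, increasing=True)
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], yi * sw, rcond=None)
        out[i] = beta[0]
    return out


def _loess_fit(
    x: np.ndarray,
    y: np.ndarray,
    x_eval: np.ndarray,
    span: float,
    degree: int,
    robust_iterations: int = 3,
) -> np.ndarray:
    """Tricube-weighted local polynomial regression evaluated at x_eval.

    With ``robust_iterations`` > 0, the fit is re-run with Tukey-bisquare
    robustness weights on the residuals, so isolated level shifts (copy
    number changes) do not bend the covariate trend.
    """
    n = len(x)
    k = min(max(int(np.ceil(span * n)), degree + 2), n)
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    rw = np.ones(n)
    for _ in range(robust_iterations):
        fitted_s = _local_poly_eval(xs, ys, rw, xs, k, degree)
        resid = ys - fitted_s
        s = np.median(np.abs(resid))
        if s <= 0:
            break
        rw = np.clip(1 - (resid / (6 * s)) ** 2, 0, None) ** 2
    return _local_poly_eval(xs, ys, rw, np.asarray(x_eval, dtype=float), k, degree)


def loess_correct(
    values: np.ndarray,
    covariate: np.ndarray,
    cfg: LoessConfig = LoessConfig(),
    min_pairs: int = 30,
) -> np.ndarray:
    """Flatten a covariate trend: corrected_i = values_i * median(values) / m(c_i).

    Two-pass fit: a first robust loess captures the trend, then bins whose
    residuals fall outside the central ``trim_quantiles`` band are dropped
    and the curve refitted.  Copy-number-aberrant bins are level shifts the
    smooth trend cannot explain, so they land in the residual tails and do
    not bend the technical curve, while a genuine strong covariate trend
    (small residuals everywhere) survives trimming intact.  The final
    curve is evaluated at every bin with a finite covariate and positive
    value; bins with missing covariate stay missing.
    """
    values = np.asarray(values, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    ok = np.isfinite(values) & np.isfinite(covariate) & (values > 0)
    if ok.sum() < min_pairs:
        raise ValueError(
            f"only {int(ok.sum())} usable (value, covariate) pairs (< {min_pairs}); "
            "increase the bin size or skip this correction"
        )
    first = _loess_fit(
        covariate[ok], values[ok], covariate[ok], cfg.span, cfg.degree, cfg.robust_iterations
    )
    resid = values[ok] - first
    q_lo, q_hi = np.quantile(resid, cfg.trim_quantiles)
    keep = (resid >= q_lo) & (resid <= q_hi)
    if keep.sum() < min_pairs:
        keep[:] = True
    fit_idx = np.flatnonzero(ok)[keep]
    fitted = _loess_fit(
        covariate[fit_idx], values[fit_idx], covariate[ok], cfg.span, cfg.degree, cfg.robust_iterations
    )
    med = float(np.median(values[ok]))
    out = np.full(len(values), np.nan)
    # guard: non-positive fitted values cannot serve as a divisor
    good = fitted > 0
    idx = np.flatnonzero(ok)[good]
    out[idx] = values[ok][good] * med / fitted[good]
    return out


def correct_profile(profile: CoverageProfile, cfg: LoessConfig = LoessConfig()) -> np.ndarray:
    """Apply the loess corrections in covariate order to comp_doc."""
    values = np.asarray(profile.comp_doc, dtype=float)
    for name in cfg.covariate_order:
        cov = getattr(profile, name)
        if cov is None:
            continue
        values = loess_correct(values, cov, cfg)
    return values


def apply_bin_filters(
    profile: CoverageProfile,
    blacklist: IntervalSet | None = None,
    cfg: BinFilterConfig = BinFilterConfig(),
) -> np.ndarray:
    """Set the per-bin usability flags (returned and stored on the profile)."""
    bins = profile.bins
    usable = np.ones(len(bins), dtype=bool)
    if profile.mappability is not None:
        usable &= np.nan_to_num(profile.mappability, nan=-1.0) >= cfg.min_mappability
    if blacklist is not None and not blacklist.is_empty():
        frac = np.zeros(len(bins))
        for chrom, lo, hi in bins.chrom_slices():
            for i in range(lo, hi):
                frac[i] = blacklist.overlap_bp(chrom, int(bins.start[i]), int(bins.end[i]))
        frac /= bins.length
        usable &= frac <= cfg.blacklist_overlap_max
    if cfg.require_nonzero_doc and profile.comp_doc is not None:
        cd = np.asarray(profile.comp_doc, dtype=float)
        usable &= np.isfinite(cd) & (cd > 0)
    profile.usable = usable
    return usable


def median_normalize_log2(
    values: np.ndarray,
    usable: np.ndarray,
    bins: BinGrid,
) -> np.ndarray:
    """log2(values / m) with m the median over usable *autosomal* bins.

    Sex chromosomes are reported but excluded from the median so their copy
    state does not shift the genome baseline; missing values propagate.
    """
    values = np.asarray(values, dtype=float)
    sel = usable & bins.autosomal_mask() & np.isfinite(values) & (values > 0)
    if not sel.any():
        raise ValueError("no usable autosomal bins with positive values")
    m = float(np.median(values[sel]))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(np.isfinite(values) & (values > 0), np.log2(values / m), np.nan)
    return out


def relative_log2(sample_log2: np.ndarray, reference_log2: np.ndarray) -> np.ndarray:
    """Per-bin sample minus reference log2 (the relative profile)."""
    sample_log2 = np.asarray(sample_log2, dtype=float)
    reference_log2 = np.asarray(reference_log2, dtype=float)
    if sample_log2.shape != reference_log2.shape:
        raise ValueError("sample and reference are on different bin grids")
    return sample_log2 - reference_log2
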