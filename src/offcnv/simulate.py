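"""Synthetic targeted-capture sequencing with known copy-number truth.

Emulates the data regime the off-target method is built for: a small
multi-chromosome genome with a programmed GC gradient, capture baits tiled
at regular spacing with heterogeneous (log-normal) per-bait efficiency,
on-target read pairs piled on the baits, and off-target background pairs
placed uniformly per base pair at a rate proportional to local copy
number.  Reads are emitted as already-aligned proper-pair records (sorted,
indexed BAM); a configured fraction carries low mapping quality and is
removed by the read filters.

Everything is deterministic per seed: the master seed is split into
independent streams for the genome sequence, the bait efficiencies, and
each sample's reads, so a tumor and its matched reference share baits and
genome but draw independent reads.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pysam

from offcnv.coverage import BinGrid
from offcnv.genome_io import GenomeLayout


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the simulated capture experiment.

    Per-bait capture efficiency has a bait-intrinsic log-normal component
    (``bait_efficiency_sd``, shared by every sample of the "capture set")
    and an independent per-sample log-normal jitter
    (``bait_efficiency_sample_sd``): capture efficiency reproduces between
    libraries, but not perfectly, which is why exon-count ratios stay noisy
    even against a matched reference.

    Rates are per copy at diploid baseline: ``theta_on`` is the expected
    read-pair count per bait per copy, ``theta_off`` the expected off-target
    pair count per bp per copy.  Defaults emulate a deeply sequenced exome
    run: roughly 240 off-target read starts per 20 kb bin at diploid copy
    number and an off-target read fraction near one third of retained
    reads, inside the 40-60% capture-efficiency range typical of target
    enrichment.
    """

    chrom_lengths: tuple[int, ...] = (10_000_000, 10_000_000)
    bait_spacing: int = 10_000
    bait_width: int = 120
    bait_efficiency_sd: float = 0.5
    bait_efficiency_sample_sd: float = 0.3
    theta_on: float = 30.0
    theta_off: float = 3.0e-3
    read_length: int = 100
    fragment_length: int = 300
    low_mapq_fraction: float = 0.05
    gc_start: float = 0.3
    gc_end: float = 0.6
    gc_wave_amplitude: float = 0.04
    gc_wave_period: int = 1_000_000
    gc_bias_exponent: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be > 0")
        if self.theta_on < 0 or self.theta_off < 0:
            raise ValueError("rates must be >= 0")
        if self.fragment_length < self.read_length:
            raise ValueError("fragment_length must be >= read_length")

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(f"chr{i + 1}" for i in range(len(self.chrom_lengths)))

    def layout(self) -> GenomeLayout:
        return GenomeLayout(tuple(zip(self.chrom_names, self.chrom_lengths)))

    def _streams(self, n_samples: int = 4) -> list[np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(2 + n_samples)
        return [np.random.default_rng(c) for c in children]


@dataclass(frozen=True)
class SimTruth:
    """Ground truth: copy-number regions tiling each chromosome (baseline 2)."""

    regions: tuple[tuple[str, int, int, int], ...]  # (chrom, start, end, CN)

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[tuple[int, int, int]]] = {}
        for chrom, s, e, cn in self.regions:
            if cn < 0:
                raise ValueError("copy number must be >= 0")
            by_chrom.setdefault(chrom, []).append((s, e, cn))
        for chrom, regs in by_chrom.items():
            regs.sort()
            if regs[0][0] != 0:
                raise ValueError(f"{chrom}: truth regions must start at 0")
            for (s1, e1, _), (s2, _, _) in zip(regs[:-1], regs[1:]):
                if e1 != s2:
                    raise ValueError(f"{chrom}: truth regions must tile without gaps")

    def validate_against(self, layout: GenomeLayout) -> None:
        ends = {}
        for chrom, s, e, cn in self.regions:
            if layout.resolve(chrom) is None:
                raise ValueError(f"truth chromosome {chrom!r} absent from genome")
            ends[chrom] = max(ends.get(chrom, 0), e)
        for chrom, end in ends.items():
            if end != layout.length(chrom):
                raise ValueError(f"{chrom}: truth regions end at {end}, chromosome is {layout.length(chrom)}")

    def copy_number_at(self, chrom: str, pos: int) -> int:
        for c, s, e, cn in self.regions:
            if c == chrom and s <= pos < e:
                return cn
        raise KeyError(f"{chrom}:{pos} not covered by truth")

    def breakpoints(self, chrom: str) -> list[int]:
        """Internal change positions (bp) on one chromosome."""
        regs = sorted((s, e, cn) for c, s, e, cn in self.regions if c == chrom)
        return [s for (s, _, _) in regs[1:]]

    def write_bed(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            for chrom, s, e, cn in self.regions:
                fh.write(f"{chrom}\t{s}\t{e}\t{cn}\n")


def default_truth(cfg: SimConfig) -> SimTruth:
    """One CN=4 gain on chr1 and one CN=1 loss on chr2, diploid elsewhere.

    Aberration boundaries sit at fixed fractions of the chromosome so the
    same truth shape works at any simulated genome size.
    """
    regions = []
    for k, (name, length) in enumerate(zip(cfg.chrom_names, cfg.chrom_lengths)):
        if k == 0:
            a, b = int(0.3 * length), int(0.5 * length)
            regions += [(name, 0, a, 2), (name, a, b, 4), (name, b, length, 2)]
        elif k == 1:
            a, b = int(0.4 * length), int(0.6 * length)
            regions += [(name, 0, a, 2), (name, a, b, 1), (name, b, length, 2)]
        else:
            regions.append((name, 0, length, 2))
    return SimTruth(tuple(regions))


def flat_truth(cfg: SimConfig, cn: int = 2) -> SimTruth:
    return SimTruth(tuple((n, 0, l, cn) for n, l in zip(cfg.chrom_names, cfg.chrom_lengths)))


def simulate_genome(cfg: SimConfig, out_fasta: str | os.PathLike) -> GenomeLayout:
    """Write a random genome FASTA with a programmed GC landscape.

    The per-base probability of G/C is a linear drift from ``gc_start`` at
    the chromosome start to ``gc_end`` at its end, plus a megabase-scale
    sinusoidal component (``gc_wave_amplitude`` / ``gc_wave_period``) that
    mimics isochore structure.  The drift keeps the per-bin GC trend
    monotone along each chromosome, while the wave makes any given GC value
    recur at several genomic positions — as it does in real genomes — so a
    contiguous copy-number aberration never owns an entire GC stratum.
    Byte-identical per seed.
    """
    rng = cfg._streams()[0]
    bases = np.frombuffer(b"ACGT", dtype="S1")
    with open(out_fasta, "w") as fh:
        for name, length in zip(cfg.chrom_names, cfg.chrom_lengths):
            pos = np.arange(length)
            p_gc = np.linspace(cfg.gc_start, cfg.gc_end, length)
            if cfg.gc_wave_amplitude > 0:
                p_gc = p_gc + cfg.gc_wave_amplitude * np.sin(2 * np.pi * pos / cfg.gc_wave_period)
            p_gc = np.clip(p_gc, 0.05, 0.95)
            is_gc = rng.random(length) < p_gc
            half = rng.random(length) < 0.5
            codes = np.where(is_gc, np.where(half, 1, 2), np.where(half, 0, 3))
            seq = bases[codes].tobytes().decode()
            fh.write(f">{name}\n")
            for i in range(0, length, 60):
                fh.write(seq[i : i + 60] + "\n")
    # drop any stale index so downstream readers see the fresh sequence
    fai = str(out_fasta) + ".fai"
    if os.path.exists(fai):
        os.unlink(fai)
    return cfg.layout()


def bait_positions(cfg: SimConfig) -> dict[str, np.ndarray]:
    """Bait start positions per chromosome (width ``bait_width``)."""
    out = {}
    for name, length in zip(cfg.chrom_names, cfg.chrom_lengths):
        starts = np.arange(cfg.bait_spacing // 2, length - cfg.bait_width, cfg.bait_spacing, dtype=np.int64)
        out[name] = starts
    return out


def bait_efficiencies(cfg: SimConfig) -> dict[str, np.ndarray]:
    """Per-bait capture efficiencies, log-normal with sd parameter (median 1)."""
    rng = cfg._streams()[1]
    return {
        chrom: rng.lognormal(mean=0.0, sigma=cfg.bait_efficiency_sd, size=len(starts))
        for chrom, starts in bait_positions(cfg).items()
    }


def _gc_windows(fasta_path: str | os.PathLike, chrom: str, length: int, w: int = 10_000) -> np.ndarray:
    from pyfaidx import Fasta

    seq = np.frombuffer(str(Fasta(str(fasta_path))[chrom][:]).upper().encode(), dtype="S1")
    edges = np.arange(0, length, w)
    gc = np.empty(len(edges))
    for i, s in enumerate(edges):
        sub = seq[s : s + w]
        gc[i] = np.mean((sub == b"G") | (sub == b"C"))
    return gc


def simulate_capture_experiment(
    fasta_path: str | os.PathLike,
    truth: SimTruth,
    cfg: SimConfig,
    out_bam: str | os.PathLike,
    sample_index: int = 0,
) -> str:
    """Simulate one capture-sequencing sample into a sorted, indexed BAM.

    Per bait b with efficiency e_b at copy number c: read-pair count
    ~ Poisson(theta_on * e_b * c/2), fragments placed around the bait.
    Off-target pairs are placed uniformly at per-bp rate theta_off * c/2,
    optionally modulated by exp(gc_bias_exponent * (gc - 0.5)) of the local
    10 kb window.  Proper-pair flags set; mapq 60 except a configured
    fraction at mapq 20.  ``sample_index`` selects an independent read
    stream (0 = sample, 1 = matched reference, ...).
    """
    layout = cfg.layout()
    truth.validate_against(layout)
    rng = cfg._streams(4 + sample_index)[2 + sample_index]
    baits = bait_positions(cfg)
    effs = bait_efficiencies(cfg)
    rl, fl = cfg.read_length, cfg.fragment_length

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": l} for n, l in layout.chromosomes],
    }
    with pysam.AlignmentFile(str(out_bam), "wb", header=header) as bam:
        for tid, (chrom, length) in enumerate(layout.chromosomes):
            frag_starts: list[np.ndarray] = []
            origin: list[np.ndarray] = []  # True = on-target
            # on-target pairs
            starts = baits[chrom]
            centers = starts + cfg.bait_width // 2
            cn = np.array([truth.copy_number_at(chrom, int(c)) for c in centers])
            sample_jitter = (
                rng.lognormal(0.0, cfg.bait_efficiency_sample_sd, len(starts))
                if cfg.bait_efficiency_sample_sd > 0
                else 1.0
            )
            lam = cfg.theta_on * effs[chrom] * sample_jitter * cn / 2.0
            n_pairs = rng.poisson(lam)
            for c, k in zip(centers, n_pairs):
                if k:
                    frag_starts.append(rng.integers(c - fl, c + 1, size=k))
                    origin.append(np.ones(k, bool))
            # off-target pairs, chunked at 10 kb for CN and GC lookup
            w = 10_000
            gc = (
                _gc_windows(fasta_path, chrom, length, w)
                if cfg.gc_bias_exponent != 0.0
                else None
            )
            edges = np.arange(0, length, w)
            for i, s in enumerate(edges):
                e = min(s + w, length)
                c = truth.copy_number_at(chrom, int(s))
                rate = cfg.theta_off * (e - s) * c / 2.0
                if gc is not None:
                    rate *= float(np.exp(cfg.gc_bias_exponent * (gc[i] - 0.5)))
                k = rng.poisson(rate)
                if k:
                    frag_starts.append(rng.integers(s, e, size=k))
                    origin.append(np.zeros(k, bool))
            if not frag_starts:
                continue
            fs = np.concatenate(frag_starts)
            ontag = np.concatenate(origin)
            fs = np.clip(fs, 0, length - fl)
            low = rng.random(len(fs)) < cfg.low_mapq_fraction
            mapq = np.where(low, 20, 60).astype(np.int64)
            # two records per pair, coordinate sorted
            pos = np.concatenate([fs, fs + fl - rl])
            is_r2 = np.concatenate([np.zeros(len(fs), bool), np.ones(len(fs), bool)])
            q = np.concatenate([mapq, mapq])
            mate = np.concatenate([fs + fl - rl, fs])
            pair_id = np.concatenate([np.arange(len(fs)), np.arange(len(fs))])
            tag = np.concatenate([ontag, ontag])
            order = np.argsort(pos, kind="stable")
            for j in order:
                rec = pysam.AlignedSegment()
                kind = "on" if tag[j] else "off"
                rec.query_name = f"sim{sample_index}_{kind}_{chrom}_{pair_id[j]}"
                rec.flag = 147 if is_r2[j] else 99  # paired, proper, mate-reverse/reverse
                rec.reference_id = tid
                rec.reference_start = int(pos[j])
                rec.mapping_quality = int(q[j])
                rec.cigarstring = f"{rl}M"
                rec.next_reference_id = tid
                rec.next_reference_start = int(mate[j])
                rec.template_length = int(fl) if not is_r2[j] else -int(fl)
                bam.write(rec)
    pysam.index(str(out_bam))
    return str(out_bam)


def expected_log2_truth(truth: SimTruth, bins: BinGrid) -> np.ndarray:
    """Length-weighted mean of log2(CN/2) over each bin."""
    out = np.zeros(len(bins))
    for chrom, lo, hi in bins.chrom_slices():
        regs = sorted((s, e, cn) for c, s, e, cn in truth.regions if c == chrom)
        for i in range(lo, hi):
            bs, be = int(bins.start[i]), int(bins.end[i])
            acc = 0.0
            for s, e, cn in regs:
                ov = min(e, be) - max(s, bs)
                if ov > 0:
                    with np.errstate(divide="ignore"):
                        acc += ov * np.log2(cn / 2.0)
            out[i] = acc / (be - bs)
    return out
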