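"""Shared fixtures: hand-built alignment files and seeded simulations."""

from __future__ import annotations

import pysam
import pytest
from hypothesis import settings

from offcnv.genome_io import GenomeLayout
from offcnv.pipeline import RunConfig, run_pipeline
from offcnv.simulate import (
    SimConfig,
    default_truth,
    flat_truth,
    simulate_capture_experiment,
    simulate_genome,
)

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def write_bam(path, layout: GenomeLayout, records, index: bool = True) -> str:
    """Write aligned records given as dicts; coordinate order is the caller's job.

    Record keys: chrom, start (0-based), length (default 100), mapq (default 60),
    proper_pair (default True), duplicate, unmapped, secondary.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": l} for n, l in layout.chromosomes],
    }
    tids = {n: i for i, (n, _) in enumerate(layout.chromosomes)}
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for i, r in enumerate(records):
            rec = pysam.AlignedSegment()
            rec.query_name = r.get("name", f"r{i}")
            flag = 0x1
            if r.get("proper_pair", True):
                flag |= 0x2
            if r.get("unmapped", False):
                flag |= 0x4
            if r.get("duplicate", False):
                flag |= 0x400
            if r.get("secondary", False):
                flag |= 0x100
            rec.flag = flag
            if not r.get("unmapped", False):
                rec.reference_id = tids[r["chrom"]]
                rec.reference_start = r["start"]
                rec.cigarstring = f"{r.get('length', 100)}M"
            rec.mapping_quality = r.get("mapq", 60)
            bam.write(rec)
    if index:
        pysam.index(str(path))
    return str(path)


@pytest.fixture(scope="session")
def toy_layout() -> GenomeLayout:
    return GenomeLayout((("chr1", 1_000_000), ("chr2", 500_000), ("chrM", 16_000)))


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A 2 x 3 Mb capture simulation with matched reference and a CN=2 replicate."""
    d = tmp_path_factory.mktemp("small_sim")
    cfg = SimConfig(chrom_lengths=(3_000_000, 3_000_000), seed=101)
    layout = simulate_genome(cfg, d / "genome.fa")
    truth = default_truth(cfg)
    simulate_capture_experiment(d / "genome.fa", truth, cfg, d / "tumor.bam", sample_index=0)
    simulate_capture_experiment(d / "genome.fa", flat_truth(cfg), cfg, d / "normal.bam", sample_index=1)
    return {"dir": d, "cfg": cfg, "layout": layout, "truth": truth,
            "fasta": str(d / "genome.fa"), "tumor": str(d / "tumor.bam"), "normal": str(d / "normal.bam")}


@pytest.fixture(scope="session")
def default_sim(tmp_path_factory):
    """The default study conditions: two 10 Mb chromosomes, CN=4 gain and CN=1 loss."""
    d = tmp_path_factory.mktemp("default_sim")
    cfg = SimConfig(seed=2024)
    layout = simulate_genome(cfg, d / "genome.fa")
    truth = default_truth(cfg)
    simulate_capture_experiment(d / "genome.fa", truth, cfg, d / "tumor.bam", sample_index=0)
    simulate_capture_experiment(d / "genome.fa", flat_truth(cfg), cfg, d / "normal.bam", sample_index=1)
    simulate_capture_experiment(d / "genome.fa", flat_truth(cfg), cfg, d / "diploid.bam", sample_index=2)
    return {"dir": d, "cfg": cfg, "layout": layout, "truth": truth,
            "fasta": str(d / "genome.fa"), "tumor": str(d / "tumor.bam"),
            "normal": str(d / "normal.bam"), "diploid": str(d / "diploid.bam")}


@pytest.fixture(scope="session")
def default_relative_run(default_sim):
    """Relative-mode pipeline result on the default simulation (segmented)."""
    return run_pipeline(
        RunConfig(
            sample_path=default_sim["tumor"],
            reference_path=default_sim["normal"],
            genome_fasta=default_sim["fasta"],
            seed=1,
        )
    )
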