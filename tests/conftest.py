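"""Shared fixtures: small simulated studies reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from h1splice import annotation, pipeline
from h1splice import synthetic_data as sd

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_study() -> sd.SimStudy:
    """Compact study with every library generated (RNA, ChIP, methylation)."""
    return sd.simulate_study(sd.SimConfig(n_genes=60), seed=7)


@pytest.fixture(scope="session")
def small_track(small_study):
    return pipeline.chip_occupancy_track(
        small_study.chip_reads["h1"],
        small_study.chip_reads["input"],
        small_study.genome_sizes,
        read_len=small_study.config.chip_read_len,
        frag_len=small_study.config.chip_frag_len,
    )


@pytest.fixture(scope="session")
def recovery_study():
    """Study sized for class recovery (~300 internal exons) with its
    occupancy track and classification, shared across tests."""
    cfg = sd.SimConfig(n_genes=88)
    ss = np.random.SeedSequence(11).generate_state(2) % (2**31)
    genome, models, truth = sd.simulate_genome_and_annotation(cfg, int(ss[0]))
    sizes = {c: len(s) for c, s in genome.items()}
    chip = sd.simulate_chip_libraries(truth, cfg, sizes, seed=int(ss[1]))
    track = pipeline.chip_occupancy_track(
        chip["h1"], chip["input"], sizes, cfg.chip_read_len, cfg.chip_frag_len
    )
    exons = annotation.build_internal_exon_table(models)
    classification = pipeline.classify_exons(track, exons, seed=0)
    return {
        "config": cfg,
        "genome": genome,
        "models": models,
        "truth": truth,
        "exons": exons,
        "track": track,
        "classification": classification,
    }


@pytest.fixture(scope="session")
def geometry_study():
    """Larger chromatin-only study for the length-vs-distance geometry check."""
    cfg = sd.SimConfig(n_genes=260)
    ss = np.random.SeedSequence(0).generate_state(2) % (2**31)
    genome, models, truth = sd.simulate_genome_and_annotation(cfg, int(ss[0]))
    sizes = {c: len(s) for c, s in genome.items()}
    chip = sd.simulate_chip_libraries(truth, cfg, sizes, seed=int(ss[1]))
    track = pipeline.chip_occupancy_track(
        chip["h1"], chip["input"], sizes, cfg.chip_read_len, cfg.chip_frag_len
    )
    exons = annotation.build_internal_exon_table(models)
    return {"truth": truth, "track": track, "exons": exons}


TINY_GTF = """\
chr1\ttest\texon\t101\t200\t.\t+\t.\tgene_id "gA"; transcript_id "tA";
chr1\ttest\texon\t301\t400\t.\t+\t.\tgene_id "gA"; transcript_id "tA";
chr1\ttest\texon\t501\t600\t.\t+\t.\tgene_id "gA"; transcript_id "tA";
chrM\ttest\texon\t11\t60\t.\t+\t.\tgene_id "gM"; transcript_id "tM";
chr1\ttest\tCDS\t701\t800\t.\t+\t.\tgene_id "gB"; transcript_id "tB";
"""


@pytest.fixture()
def tiny_gtf(tmp_path):
    path = tmp_path / "tiny.gtf"
    path.write_text(TINY_GTF)
    return path
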