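"""Shared fixtures: small synthetic studies generated at test time."""

import numpy as np
import pandas as pd
import pytest

from chexseq import genemodel, pipeline, priming, synthdata


@pytest.fixture(scope="session")
def default_config():
    return synthdata.SyntheticConfig(seed=7)


@pytest.fixture(scope="session")
def small_study(default_config):
    """Genome + planted truth for the default study conditions."""
    genome, _ = synthdata.generate_genome(default_config)
    truth = synthdata.plant_ssdna(default_config, genome)
    return default_config, genome, truth


@pytest.fixture(scope="session")
def pipeline_result(default_config):
    """One full synthetic pipeline run, reused by read-only tests."""
    return pipeline.run_synthetic_pipeline(default_config)


@pytest.fixture(scope="session")
def toy_model():
    """Hand-built two-gene model with known arithmetic."""
    rows = []
    for gene_id, chrom, start, end, strand, exons, cds in [
        ("GPLUS", "chr1", 10_000, 20_000, "+",
         [(10_000, 12_000), (14_000, 16_000), (18_000, 20_000)],
         [(10_500, 12_000), (14_000, 16_000), (18_000, 19_500)]),
        ("GMINUS", "chr1", 30_000, 40_000, "-",
         [(30_000, 33_000), (36_000, 40_000)],
         [(30_500, 33_000), (36_000, 39_500)]),
    ]:
        tx = gene_id + ".1"
        rows.append((chrom, "gene", start, end, strand, gene_id, tx))
        rows += [(chrom, "exon", s, e, strand, gene_id, tx) for s, e in exons]
        rows += [(chrom, "CDS", s, e, strand, gene_id, tx) for s, e in cds]
    frame = pd.DataFrame(
        rows, columns=["chrom", "feature", "start", "end", "strand", "gene_id", "transcript_id"]
    )
    return genemodel.build_genic_regions(frame, chrom_lengths={"chr1": 100_000})


def make_site(chrom, pos, strand="+", quality="A1", sample="S1", read_id=None,
              score=50.0, mapped_length=50):
    return priming.PrimingSite(
        chrom=chrom, pos=pos, strand=strand, quality=quality, sample_id=sample,
        read_id=read_id or f"r{pos}_{strand}", score=score, mapped_length=mapped_length,
    )


@pytest.fixture
def site_factory():
    return make_site


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
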