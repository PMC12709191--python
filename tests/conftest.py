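import numpy as np
import pytest

from gcrmap.genome_model import repair_region_span
from gcrmap.splitread import align_reads, detect_split_reads
from gcrmap.classify import classify_reads
from gcrmap.synthetic_pool import (
    ToyGenomeConfig,
    build_toy_genome,
    sample_pool_events,
    simulate_pool,
)

DEFAULT_MIXTURE = {
    "telomere_addition": 0.5,
    "deletion": 0.2,
    "translocation_A": 0.1,
    "translocation_B": 0.1,
    "translocation_C": 0.1,
}


@pytest.fixture(scope="session")
def toy():
    """(config, genome, annotations, region) for the default toy genome."""
    cfg = ToyGenomeConfig(seed=1)
    genome, annotations = build_toy_genome(cfg)
    region = repair_region_span(annotations, cfg.repair_chrom)
    return cfg, genome, annotations, region


@pytest.fixture(scope="session")
def analyzed_pool(toy):
    """One fully simulated and analyzed pool (seed 1, error 0.001)."""
    cfg, genome, annotations, region = toy
    truth = sample_pool_events(DEFAULT_MIXTURE, 30, genome, annotations, 1, cfg)
    clones, reads = simulate_pool(
        genome, annotations, truth, depth=30, error_rate=0.001, seed=1
    )
    anchored = align_reads(reads, genome, region)
    split = detect_split_reads(anchored, region)
    read_events = classify_reads(split, annotations, region, genome)
    return {
        "truth": truth,
        "clones": clones,
        "reads": reads,
        "anchored": anchored,
        "split": split,
        "read_events": read_events,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
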