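from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import isofunnel as iso

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> iso.SimConfig:
    return iso.SimConfig(n_genes=80, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """One small simulated two-condition dataset shared across tests."""
    models = iso.simulate_annotation(small_config)
    counts, truth = iso.simulate_counts(models, small_config)
    fpkm = iso.fpkm(counts.counts, iso.transcript_lengths(models))
    fr = iso.isoform_fractions(fpkm, iso.tx2gene(models))
    return {
        "config": small_config,
        "models": models,
        "counts": counts,
        "truth": truth,
        "fpkm": fpkm,
        "fr": fr,
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)


def random_chain(rng, max_exons: int = 4, strand: str = "+") -> iso.ExonChain:
    """A small random exon chain with coordinates below ~500 bp."""
    n = int(rng.integers(1, max_exons + 1))
    pos = int(rng.integers(0, 40))
    intervals = []
    for _ in range(n):
        length = int(rng.integers(10, 60))
        intervals.append((pos, pos + length))
        pos += length + int(rng.integers(5, 50))
    return iso.ExonChain(intervals=tuple(intervals), strand=strand)
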