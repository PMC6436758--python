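import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import stallscreen as ss
from stallscreen.footprints import CodonMaps

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_ribo_sim():
    """A light treated-vs-control experiment with strong, recoverable stalls."""
    cfg = ss.RiboSimConfig(
        n_transcripts=60,
        cds_length_codons=(120, 200),
        stalled_fraction=0.1,
        reads_per_transcript=800,
        seed=42,
    )
    return ss.simulate_ribo_experiment(cfg)


@pytest.fixture(scope="session")
def small_screen():
    """A light pooled screen: 40 genes (4 with drug phenotypes), 120 controls."""
    cfg = ss.ScreenSimConfig(
        n_genes=40, n_nontargeting=120, n_rho_genes=4, seed=42
    )
    counts, truth = ss.simulate_screen(cfg)
    return cfg, counts, truth


def make_maps(counts_by_sample, transcript_ids=None):
    """Build a CodonMaps directly from {(condition, replicate): [arrays]}.

    Each value is a list of per-transcript codon count arrays (same
    transcript layout for every sample).
    """
    samples = sorted(counts_by_sample)
    first = counts_by_sample[samples[0]]
    n_codons = np.array([len(a) for a in first])
    if transcript_ids is None:
        transcript_ids = np.array([f"t{i}" for i in range(len(first))])
    counts = np.vstack(
        [np.concatenate([np.asarray(a) for a in counts_by_sample[s]]) for s in samples]
    ).astype(np.int64)
    return CodonMaps(np.asarray(transcript_ids), n_codons, list(samples), counts)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
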