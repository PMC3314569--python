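"""Shared fixtures: small synthetic datasets and an end-to-end pipeline run."""

from __future__ import annotations

import numpy as np
import pytest

from mircos import pipeline as pl
from mircos.synthetic_data import SynthConfig, generate


@pytest.fixture(scope="session")
def default_synth():
    """The default synthetic study conditions (seed 7)."""
    return generate(SynthConfig())


@pytest.fixture(scope="session")
def e2e(tmp_path_factory, default_synth):
    """One full pipeline run on the default synthetic dataset.

    Returns (config, data, summary) with every stage's artifacts on disk.
    """
    outdir = tmp_path_factory.mktemp("e2e")
    cfg = pl.PipelineConfig(outdir=outdir, synth=SynthConfig(), seed=7)
    summary = pl.run_all(cfg)
    return cfg, default_synth, summary


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
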