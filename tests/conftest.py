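"""Shared fixtures: small deterministic genomes and design configs."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from crisprikit.config import RunConfig

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from crisprikit.fixtures import FixtureSpec, make_genome
from crisprikit.sequence_model import GeneModel, Replicon


@pytest.fixture(scope="session")
def small_fixture():
    """50-kb, 10-gene AT-rich genome used across design tests."""
    spec = FixtureSpec(seed=7, genome_length=50_000, n_genes=10)
    genome, genes = make_genome(spec)
    return genome, genes


@pytest.fixture(scope="session")
def run_config():
    return RunConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_seq(rng, n, gc=0.35):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


@pytest.fixture()
def toy_gene():
    """Tiny hand-checkable replicon with one + strand gene."""
    #          0         1         2         3         4
    #          0123456789012345678901234567890123456789012345678
    seq = "AAAAATTAGGATCCGGATTCAAAAGGCCAAGGTTCGGATGCCGGAAAAA"
    rep = Replicon("toy", seq)
    gene = GeneModel("g1", "toy", 30, 45, "+")
    return {"toy": rep}, gene
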