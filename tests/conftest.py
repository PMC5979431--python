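"""Shared fixtures: a hand-sized design and matrix every module can use."""

import numpy as np
import pandas as pd
import pytest

from txdrift.io import AnalysisConfig, SampleRecord


def make_samples(tissue="head", n_rep=3):
    labels = {"young": "1W", "aged": "4W", "aged_treated": "4W-IF"}
    return [
        SampleRecord(f"{tissue}_{labels[c]}_r{j + 1}", tissue, c, j + 1)
        for c in ("young", "aged", "aged_treated")
        for j in range(n_rep)
    ]


@pytest.fixture
def head_samples():
    return make_samples("head", 3)


@pytest.fixture
def small_matrix(head_samples):
    """5 genes x 9 samples with known cohort means.

    gA: young mean 10, aged mean 30 (3-fold up), treated mean 10 (restored)
    gB: flat at 20 everywhere
    gC: young mean 8, aged mean 2 (4-fold down), treated mean 8 (restored)
    gD: low expression (one replicate below 1 RPKM) -> filtered out
    gE: young mean 5, aged mean 5 but noisy, treated mean 5
    """
    rows = {
        "gA": [9.0, 10.0, 11.0, 28.0, 30.0, 32.0, 9.5, 10.0, 10.5],
        "gB": [20.0] * 9,
        "gC": [7.0, 8.0, 9.0, 1.9, 2.0, 2.1, 7.5, 8.0, 8.5],
        "gD": [0.8, 1.5, 1.2, 1.1, 1.4, 1.3, 1.2, 1.1, 1.6],
        "gE": [5.0, 5.2, 4.8, 2.0, 5.0, 8.0, 4.9, 5.0, 5.1],
    }
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[r.sample_id for r in head_samples]
    )


@pytest.fixture
def config():
    return AnalysisConfig(permutations=199, seed=11)


def random_matrix(rng, n_genes, n_samples, low=0.5, high=500.0):
    values = rng.uniform(low, high, size=(n_genes, n_samples))
    return pd.DataFrame(
        values,
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
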