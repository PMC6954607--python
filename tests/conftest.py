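"""Shared fixtures: one default simulated dataset (seed 42) reused session-wide."""

import numpy as np
import pandas as pd
import pytest

import refpick as rp


@pytest.fixture(scope="session")
def sim42():
    """Default simulated dataset: 12000 genes, 2 groups x 4 replicates, seed 42."""
    return rp.simulate_counts(seed=42)


@pytest.fixture(scope="session")
def tpm42(sim42):
    cm, lengths, _ = sim42
    return rp.counts_to_tpm(cm, lengths)


@pytest.fixture(scope="session")
def dafs42(tpm42):
    return rp.dafs_cutoffs(tpm42)


@pytest.fixture(scope="session")
def active42(tpm42, dafs42):
    return rp.active_genes(tpm42, dafs42)


@pytest.fixture(scope="session")
def refs42(tpm42, active42, dafs42):
    return rp.select_references(
        tpm42,
        active42,
        extra_params={"active_rule": "mean", "mean_cutoff": float(dafs42.cutoffs.mean())},
    )


@pytest.fixture
def tiny_counts():
    """3 genes x 2 samples, the worked parsing example."""
    df = pd.DataFrame(
        [[10, 20], [0, 5], [7, 7]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2"],
    )
    return rp.CountMatrix(df)


def make_tpm(rows: dict[str, list[float]], samples: list[str] | None = None) -> pd.DataFrame:
    """Small TPM-like matrix from explicit per-gene values (no column-sum rescale)."""
    df = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    if samples is not None:
        df.columns = samples
    else:
        df.columns = [f"s{i+1}" for i in range(df.shape[1])]
    return df
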