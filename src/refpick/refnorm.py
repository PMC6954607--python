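"""Median-of-ratios size factors restricted to a control-gene set.

The classic median-of-ratios estimator divides each sample's counts by
the per-gene geometric mean across samples and takes the per-sample
median of those ratios. Restricting the median to a trusted reference
set makes the scaling robust to global expression shifts that would
bias an all-gene median. The resulting factors are what a downstream
negative-binomial DE tool consumes as its normalization constants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import CountMatrix, GeneList

__all__ = ["SizeFactorSet", "size_factors_with_controls"]


@dataclass
class SizeFactorSet:
    """Per-sample size factors with provenance.

    Factors are rescaled to unit geometric mean so factor sets obtained
    with different reference choices are directly comparable.
    """

    size_factors: pd.Series
    reference_set: str
    n_usable_refs: int

    def __post_init__(self) -> None:
        vals = self.size_factors.to_numpy(dtype=float)
        if np.any(vals <= 0):
            raise ValueError("size factors must be positive")


def size_factors_with_controls(counts: CountMatrix, refs: GeneList) -> SizeFactorSet:
    """Median-of-ratios size factors computed on a reference-gene subset.

    References with a zero count in any sample are dropped (their
    geometric mean would be zero); the number retained is reported as
    ``n_usable_refs``. Raw per-sample factors are the median over usable
    references of ``count / geometric-mean(count)``, then rescaled to
    unit geometric mean.
    """
    df = counts.counts
    present = [g for g in refs.gene_ids if g in df.index]
    if not present:
        raise ValueError(f"no reference gene of set {refs.name!r} found in counts")
    sub = df.loc[present].to_numpy(dtype=float)
    usable_mask = (sub > 0).all(axis=1)
    usable = sub[usable_mask]
    if usable.shape[0] == 0:
        raise ValueError("no usable reference (all have a zero count)")
    log_geo = np.log(usable).mean(axis=1, keepdims=True)
    ratios = usable / np.exp(log_geo)
    raw = np.median(ratios, axis=0)
    zero_samples = np.flatnonzero(raw == 0)
    if zero_samples.size:
        raise ValueError(
            f"all reference counts are zero in sample {df.columns[zero_samples[0]]!r}"
        )
    final = raw / np.exp(np.mean(np.log(raw)))
    return SizeFactorSet(
        size_factors=pd.Series(final, index=df.columns, name="size_factor"),
        reference_set=refs.name,
        n_usable_refs=int(usable.shape[0]),
    )
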