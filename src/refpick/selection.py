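"""Active-gene determination and lowest-CV reference selection.

A gene is *active* when it is expressed above the data-adaptive cutoff;
the reference set is the small fraction of active genes (default 0.5%)
whose TPM varies least across samples. This makes the references
condition-specific: they are stable in the experiment at hand, not in a
published panel's conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dafs import DafsResult, dafs_cutoffs
from .io_formats import CountMatrix
from .quantify import counts_to_tpm, gene_cv_stats

__all__ = ["ReferenceSet", "active_genes", "select_references", "custom_references"]


@dataclass
class ReferenceSet:
    """Selected reference genes, ordered by ascending CV, with provenance."""

    gene_ids: list[str]
    mean_tpm: list[float]
    cv_percent: list[float]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene in reference set")
        cvs = np.asarray(self.cv_percent, dtype=float)
        if np.any(np.diff(cvs) < 0):
            raise ValueError("reference set must be ordered by ascending CV")

    def __len__(self) -> int:
        return len(self.gene_ids)


def active_genes(
    tpm: pd.DataFrame, dafs: DafsResult, rule: str = "mean"
) -> pd.Index:
    """Genes expressed above the data-adaptive cutoff.

    Under the default ``mean`` rule a gene is active iff all its TPM
    values are positive and its mean log2 TPM is at least the mean of
    the per-sample cutoffs. The stricter ``every-sample`` rule instead
    requires each sample's log2 TPM to clear that sample's own cutoff.
    """
    missing = [s for s in tpm.columns if s not in dafs.cutoffs.index]
    if missing:
        raise ValueError(f"no cutoff for sample {missing[0]!r}")
    vals = tpm.to_numpy(dtype=float)
    all_positive = (vals > 0).all(axis=1)
    log2 = np.log2(np.where(all_positive[:, None], vals, 1.0))  # zero-rows unused
    if rule == "mean":
        kappa_bar = float(dafs.cutoffs[tpm.columns].mean())
        mask = all_positive & (log2.mean(axis=1) >= kappa_bar)
    elif rule == "every-sample":
        cuts = dafs.cutoffs[tpm.columns].to_numpy(dtype=float)
        mask = all_positive & (log2 >= cuts[None, :]).all(axis=1)
    else:
        raise ValueError(f"unknown active rule {rule!r}")
    return tpm.index[mask]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def select_references(
    tpm: pd.DataFrame,
    active: pd.Index,
    fraction: float = 0.005,
    min_genes: int = 1,
    extra_params: dict | None = None,
) -> ReferenceSet:
    """Select the lowest-CV fraction of the active genes.

    The target size is ``max(min_genes, round_half_up(fraction * n_active))``.
    CV ties are broken by lexicographic gene ID so the selection is
    deterministic.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if len(active) == 0:
        raise ValueError("no expressed genes")
    stats = gene_cv_stats(tpm.loc[active])
    n_sel = max(int(min_genes), _round_half_up(fraction * len(active)))
    n_sel = min(n_sel, len(active))
    # deterministic ordering: CV ascending, ties by gene ID
    order = stats.assign(_gene=stats.index).sort_values(
        ["cv_percent", "_gene"], kind="stable"
    )
    chosen = order.iloc[:n_sel]
    params = {
        "fraction": float(fraction),
        "min_genes": int(min_genes),
        "n_active": int(len(active)),
        "n_selected": int(n_sel),
    }
    if extra_params:
        params.update(extra_params)
    return ReferenceSet(
        gene_ids=list(chosen.index),
        mean_tpm=[float(v) for v in chosen["mean_tpm"]],
        cv_percent=[float(v) for v in chosen["cv_percent"]],
        params=params,
    )


def custom_references(
    counts: CountMatrix,
    lengths: pd.Series,
    fraction: float = 0.005,
    min_genes: int = 1,
    active_rule: str = "mean",
) -> ReferenceSet:
    """End-to-end pipeline: counts -> TPM -> cutoff -> active genes -> lowest-CV set.

    Identical to running :func:`~refpick.quantify.counts_to_tpm`,
    :func:`~refpick.dafs.dafs_cutoffs`, :func:`active_genes` and
    :func:`select_references` in sequence.
    """
    tpm = counts_to_tpm(counts, lengths)
    dafs = dafs_cutoffs(tpm)
    active = active_genes(tpm, dafs, rule=active_rule)
    kappa_bar = float(dafs.cutoffs.mean())
    return select_references(
        tpm,
        active,
        fraction=fraction,
        min_genes=min_genes,
        extra_params={"active_rule": active_rule, "mean_cutoff": kappa_bar},
    )
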