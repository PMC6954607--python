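"""Counts-to-TPM conversion and per-gene expression summaries.

TPM (transcripts per million) divides each gene's count by its length to
get a per-base read rate and rescales the rates so every sample sums to
10^6. It is a within-sample abundance measure: comparisons across samples
still require the stability analysis downstream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_formats import CountMatrix

__all__ = ["counts_to_tpm", "gene_cv_stats"]


def counts_to_tpm(
    counts: CountMatrix,
    lengths: pd.Series,
    mean_fragment_length: float | None = None,
) -> pd.DataFrame:
    """Convert a count matrix to TPM.

    TPM_gj = 1e6 * (c_gj / L_g) / sum_i (c_ij / L_i).

    Parameters
    ----------
    counts
        Count matrix; every gene must have a length.
    lengths
        Gene lengths in base pairs, indexed by gene ID.
    mean_fragment_length
        If given, use the effective length ``max(L_g - mu_frag + 1, 1)``
        instead of the annotated length.

    Raises
    ------
    KeyError
        If a counted gene has no length.
    ValueError
        If some sample has all-zero counts (its TPM is undefined).
    """
    df = counts.counts
    missing = df.index.difference(lengths.index)
    if len(missing) > 0:
        raise KeyError(f"no length for gene {missing[0]!r}")
    L = lengths.reindex(df.index).astype(float)
    if mean_fragment_length is not None:
        L = (L - float(mean_fragment_length) + 1.0).clip(lower=1.0)
    rates = df.to_numpy(dtype=float) / L.to_numpy()[:, None]
    col_sums = rates.sum(axis=0)
    zero = np.flatnonzero(col_sums == 0)
    if zero.size:
        raise ValueError(f"sample {df.columns[zero[0]]!r} has all-zero counts")
    tpm = rates / col_sums[None, :] * 1e6
    return pd.DataFrame(tpm, index=df.index, columns=df.columns)


def gene_cv_stats(
    tpm: pd.DataFrame, sample_subset: list[str] | None = None
) -> pd.DataFrame:
    """Per-gene mean TPM, sample SD (n-1 denominator) and percent CV.

    Returns a DataFrame indexed by gene with columns ``mean_tpm``,
    ``sd_tpm``, ``cv_percent`` and ``undefined_cv``. Genes with zero mean
    have an undefined CV: they are flagged (cv_percent = NaN), not
    dropped.
    """
    sub = tpm if sample_subset is None else tpm[list(sample_subset)]
    if sub.shape[1] < 2:
        raise ValueError("CV requires at least 2 samples")
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = 100.0 * sd / mean
    undefined = mean == 0
    cv[undefined] = np.nan
    return pd.DataFrame(
        {"mean_tpm": mean, "sd_tpm": sd, "cv_percent": cv, "undefined_cv": undefined}
    )
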