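"""Synthetic count matrices with known truth labels.

The generator emulates a small two-genotype bulk RNA-seq design — by
default two groups of four replicates, the classic transgenic-line vs
control layout — with the features the selection pipeline keys on:

* a bimodal log-expression distribution (a weakly expressed
  "transcriptional noise" mode well below an expressed mode), so the
  data-adaptive cutoff has a real valley to find;
* a planted subset of genuinely stable genes (no group effect,
  near-Poisson dispersion) drawn from the upper half of the expressed
  mode, the ground truth for selection recovery;
* a planted subset of differentially expressed genes with log2 fold
  changes of magnitude at least 0.5;
* per-sample library-size factors, the ground truth for size-factor
  recovery.

Counts are negative binomial in the mean/dispersion parameterization
(variance = mu + alpha * mu^2) with the mean proportional to
TPM-scale abundance x gene length x a global depth constant chosen to
give roughly 20 million expected fragments per sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import CountMatrix

__all__ = ["SimulationTruth", "simulate_counts", "negative_binomial_counts"]

#: expected sequencing depth per sample (fragments)
TARGET_DEPTH = 20e6
#: dispersion of planted stable genes (near-Poisson)
STABLE_DISPERSION = 1e-4
#: baseline dispersion of background and DE genes
BACKGROUND_DISPERSION = 0.05
#: dispersion of weakly expressed noise genes
NOISE_DISPERSION = 0.1


@dataclass
class SimulationTruth:
    """Ground truth of one simulated dataset.

    ``genes`` is indexed by gene ID with columns ``theta`` (TPM-scale
    base abundance), ``length``, ``dispersion``, ``log2_fc`` (group 2 vs
    group 1) and ``label`` in {stable, noise, de, background}.
    ``size_factors`` and ``groups`` are per sample.
    """

    genes: pd.DataFrame
    size_factors: pd.Series
    groups: dict[str, str]


def negative_binomial_counts(
    mean: np.ndarray, dispersion: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw NB counts with variance ``mu + alpha * mu^2`` (Poisson when alpha -> 0).

    Uses the gamma-Poisson mixture: a gamma multiplier with shape
    1/alpha and unit mean, then a Poisson draw. Entries with alpha = 0
    are plain Poisson.
    """
    mean = np.asarray(mean, dtype=float)
    dispersion = np.broadcast_to(np.asarray(dispersion, dtype=float), mean.shape)
    lam = np.array(mean, copy=True)
    pos = dispersion > 0
    if np.any(pos):
        shape = 1.0 / dispersion[pos]
        lam[pos] = mean[pos] * rng.gamma(shape, 1.0 / shape)
    return rng.poisson(lam)


def simulate_counts(
    n_genes: int = 12000,
    n_reps: int = 4,
    n_groups: int = 2,
    frac_noise: float = 0.3,
    n_stable: int = 100,
    frac_de: float = 0.1,
    seed: int = 0,
) -> tuple[CountMatrix, pd.Series, SimulationTruth]:
    """Generate a count matrix with planted stable, noise and DE genes.

    Parameters
    ----------
    n_genes
        Total genes simulated.
    n_reps, n_groups
        Replicates per group and number of groups (default 4 x 2).
    frac_noise
        Fraction of genes in the weakly expressed noise mode
        (log2 abundance ~ N(-2, 1)).
    n_stable
        Number of planted stable genes (log2 fold change 0, dispersion
        1e-4), drawn from the upper half of the expressed mode
        (log2 abundance ~ N(5, 2)).
    frac_de
        Fraction of expressed, non-stable genes given a group effect
        with |log2 FC| >= 0.5.
    seed
        Seed for the pseudo-random generator; a fixed seed gives
        bit-identical output.

    Returns ``(CountMatrix, lengths, SimulationTruth)``.
    """
    if min(n_genes, n_reps, n_groups, n_stable) <= 0:
        raise ValueError("all size arguments must be positive")
    if not (0 <= frac_noise < 1 and 0 <= frac_de <= 1):
        raise ValueError("fractions out of range")
    n_noise = int(round(frac_noise * n_genes))
    n_expressed = n_genes - n_noise
    if n_stable > n_expressed:
        raise ValueError("more stable genes requested than expressed genes")
    rng = np.random.default_rng(seed)

    width = len(str(n_genes))
    gene_ids = np.array([f"G{i:0{width}d}" for i in range(1, n_genes + 1)])
    lengths = np.exp(
        rng.uniform(np.log(200.0), np.log(10000.0), size=n_genes)
    ).astype(np.int64)

    # abundance: bimodal in log2
    log2_theta = np.empty(n_genes)
    is_noise = np.zeros(n_genes, dtype=bool)
    noise_idx = rng.choice(n_genes, size=n_noise, replace=False)
    is_noise[noise_idx] = True
    log2_theta[is_noise] = rng.normal(-2.0, 1.0, size=n_noise)
    log2_theta[~is_noise] = rng.normal(5.0, 2.0, size=n_expressed)

    expressed_idx = np.flatnonzero(~is_noise)
    upper_half = expressed_idx[log2_theta[expressed_idx] >= 5.0]
    if upper_half.size < n_stable:
        raise ValueError("not enough upper-mode genes for the stable set")
    stable_idx = rng.choice(upper_half, size=n_stable, replace=False)

    label = np.full(n_genes, "background", dtype=object)
    label[is_noise] = "noise"
    label[stable_idx] = "stable"
    de_pool = np.array(
        [i for i in expressed_idx if label[i] == "background"], dtype=int
    )
    n_de = int(round(frac_de * de_pool.size))
    de_idx = rng.choice(de_pool, size=n_de, replace=False)
    label[de_idx] = "de"

    # bounded fold changes: moderate transcriptome remodeling, so no single
    # abundant transcript can swing the per-sample TPM denominator
    log2_fc = np.zeros(n_genes)
    magnitude = rng.uniform(0.5, 3.0, size=n_de)
    sign = rng.choice([-1.0, 1.0], size=n_de)
    log2_fc[de_idx] = sign * magnitude

    dispersion = np.full(n_genes, BACKGROUND_DISPERSION)
    dispersion[is_noise] = NOISE_DISPERSION
    dispersion[stable_idx] = STABLE_DISPERSION

    n_samples = n_reps * n_groups
    size_factors = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=n_samples))
    group_labels = [f"group{g + 1}" for g in range(n_groups)]
    sample_ids = [
        f"{group_labels[g]}_rep{r + 1}" for g in range(n_groups) for r in range(n_reps)
    ]
    sample_group = np.repeat(np.arange(n_groups), n_reps)

    theta = 2.0**log2_theta
    # depth constant: E[fragments per sample] ~ TARGET_DEPTH at s_j = 1
    kappa = TARGET_DEPTH / float((theta * lengths).sum())

    counts = np.empty((n_genes, n_samples), dtype=np.int64)
    for j in range(n_samples):
        fold = 2.0 ** (log2_fc * (sample_group[j] == 1))  # DE effect in group 2
        mu = size_factors[j] * theta * fold * lengths * kappa
        counts[:, j] = negative_binomial_counts(mu, dispersion, rng)

    groups = {s: group_labels[g] for s, g in zip(sample_ids, sample_group)}
    cm = CountMatrix(
        pd.DataFrame(counts, index=gene_ids, columns=sample_ids), groups=groups
    )
    truth_genes = pd.DataFrame(
        {
            "theta": theta,
            "length": lengths,
            "dispersion": dispersion,
            "log2_fc": log2_fc,
            "label": label,
        },
        index=gene_ids,
    )
    truth = SimulationTruth(
        genes=truth_genes,
        size_factors=pd.Series(size_factors, index=sample_ids, name="size_factor"),
        groups=groups,
    )
    return cm, pd.Series(lengths, index=gene_ids, name="length"), truth
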