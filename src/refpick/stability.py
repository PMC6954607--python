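"""Stability evaluation of candidate reference-gene sets.

Three complementary views of "stably expressed":

* **geNorm M** — the mean standard deviation of a gene's pairwise log
  ratios with every other candidate. A gene that co-varies with the rest
  of the set has constant ratios and a low M. Candidates are ranked by
  iteratively discarding the worst-M gene; the last two survivors share
  the top rank because M is undefined for a single gene.
* **NormFinder-style index** — a two-way (gene x sample, within group)
  variance decomposition. The intra-group variance of a gene is shrunk
  toward zero by subtracting the set-average variance (a gene cannot be
  blamed for variation the whole set shows), and the gene's systematic
  inter-group expression difference is shrunk with an empirical-Bayes
  factor before entering the index. Lower is more stable; values under
  0.5 are conventionally deemed suitable for a reference gene.
* **CV** — the plain percent coefficient of variation of linear TPM.

All log-based metrics use log2 TPM without pseudocount; genes with a
zero in any sample are excluded from them (they could not serve as
references anyway) but still appear in the CV block.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneList
from .quantify import gene_cv_stats
from .selection import ReferenceSet

__all__ = [
    "StabilityReport",
    "genorm_m",
    "genorm_rank",
    "normfinder_stability",
    "compare_reference_sets",
]

#: conventional NormFinder suitability threshold for a reference gene
SUITABILITY_THRESHOLD = 0.5


@dataclass
class StabilityReport:
    """Per-gene stability metrics for one candidate set.

    ``table`` is indexed by gene with columns ``mean_tpm``, ``cv_percent``,
    ``genorm_m``, ``genorm_rank``, ``intergroup_diff``, ``intragroup_sd``
    and ``stability``; genes excluded from log-based metrics carry NaN
    there. ``pairwise_variation`` is the geNorm V_{n,n+1} series
    (length n-2 for n ranked genes). ``components`` holds the full
    per-group NormFinder decomposition.
    """

    set_name: str
    table: pd.DataFrame
    pairwise_variation: list[float] = field(default_factory=list)
    summary: dict = field(default_factory=dict)
    components: pd.DataFrame | None = None


def _check_logexpr(logexpr: pd.DataFrame, genes: Sequence[str]) -> pd.DataFrame:
    sub = logexpr.loc[list(genes)]
    vals = sub.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        g, s = np.argwhere(~np.isfinite(vals))[0]
        raise ValueError(
            f"non-finite log expression for gene {sub.index[g]!r}, "
            f"sample {sub.columns[s]!r}"
        )
    return sub


def genorm_m(logexpr: pd.DataFrame, genes: Sequence[str]) -> pd.Series:
    """geNorm expression-stability measure M for each candidate gene.

    M_i is the mean over partners k != i of the standard deviation
    (n-1 denominator) across samples of the log ratio
    ``logexpr_i - logexpr_k``.
    """
    sub = _check_logexpr(logexpr, genes)
    if sub.shape[0] < 3:
        raise ValueError("geNorm needs at least 3 candidate genes")
    if sub.shape[1] < 2:
        raise ValueError("geNorm needs at least 2 samples")
    X = sub.to_numpy(dtype=float)
    n_genes = X.shape[0]
    # pairwise ratio SDs via broadcasting: diff[i,k,j] = X[i,j] - X[k,j]
    diff = X[:, None, :] - X[None, :, :]
    V = diff.std(axis=2, ddof=1)
    M = (V.sum(axis=1)) / (n_genes - 1)  # diagonal SD is 0
    return pd.Series(M, index=sub.index, name="genorm_m")


def genorm_rank(
    logexpr: pd.DataFrame, genes: Sequence[str]
) -> tuple[pd.Series, list[float]]:
    """Rank candidates by stepwise exclusion and compute pairwise variation.

    The gene with the largest M on the surviving set is removed at each
    step (ties broken by removing the lexicographically smallest ID
    first) until two genes remain; those two share rank 1. Rank r means
    the gene was the r-th most stable, with the worst gene at rank n.

    V_{n,n+1} is the standard deviation across samples of
    ``log2(NF_n / NF_{n+1})``, where NF_n is the per-sample geometric
    mean of the n best-ranked genes' linear TPM; the series runs from
    n=2 to n=len(genes)-1.
    """
    sub = _check_logexpr(logexpr, genes)
    surviving = list(sub.index)
    ranks: dict[str, int] = {}
    next_worst_rank = len(surviving)
    while len(surviving) > 2:
        M = genorm_m(sub, surviving)
        worst = M.max()
        tied = sorted(M.index[M == worst])
        removed = tied[0]
        ranks[removed] = next_worst_rank
        next_worst_rank -= 1
        surviving.remove(removed)
    for g in surviving:  # terminal pair shares the top rank
        ranks[g] = 1
    rank_series = pd.Series(ranks, dtype=int).reindex(sub.index)

    order = sorted(sub.index, key=lambda g: (rank_series[g], g))
    v_series: list[float] = []
    for n in range(2, len(order)):
        nf_n = sub.loc[order[:n]].mean(axis=0)  # log-scale mean == log geomean
        nf_n1 = sub.loc[order[: n + 1]].mean(axis=0)
        v = float((nf_n - nf_n1).std(ddof=1))
        v_series.append(v)
    return rank_series, v_series


def normfinder_stability(
    logexpr: pd.DataFrame,
    genes: Sequence[str],
    groups: Mapping[str, str],
) -> pd.DataFrame:
    """Model-based stability index from a two-way variance decomposition.

    Within each group the gene x sample interaction residuals give the
    raw per-gene variance, shrunk by the set average (with I candidate
    genes, ``max(0, v_ig - mean_i'(v_i'g) / (I - 1))``). The inter-group
    difference ``d_ig`` is the gene's group-mean deviation relative to
    the whole set, shrunk by the empirical-Bayes factor
    ``tau2 / (tau2 + mean_g(var_ig / n_g))``. The stability value is

        rho_i = mean_g( |d_shrunk_ig| + sqrt(var_ig / n_g) )

    and, with a single group, simply ``sqrt(var_i1)``.

    Returns a DataFrame indexed by gene with per-group columns
    ``intra_sd:<g>`` and ``intergroup_diff:<g>`` plus ``stability``.
    """
    sub = _check_logexpr(logexpr, genes)
    I = sub.shape[0]
    if I < 3:
        raise ValueError("NormFinder shrinkage needs at least 3 candidate genes")
    group_of = {s: groups[s] for s in sub.columns}
    labels = sorted(set(group_of.values()))
    samples_by_group = {
        g: [s for s in sub.columns if group_of[s] == g] for g in labels
    }
    for g, ss in samples_by_group.items():
        if len(ss) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")

    G = len(labels)
    var_shrunk = np.zeros((I, G))
    gene_group_mean = np.zeros((I, G))
    n_g = np.zeros(G)
    for j, g in enumerate(labels):
        X = sub[samples_by_group[g]].to_numpy(dtype=float)
        n = X.shape[1]
        n_g[j] = n
        gene_mean = X.mean(axis=1, keepdims=True)
        sample_mean = X.mean(axis=0, keepdims=True)
        grand = X.mean()
        resid = X - gene_mean - sample_mean + grand
        v_raw = (resid**2).sum(axis=1) / (n - 1)
        var_shrunk[:, j] = np.maximum(0.0, v_raw - v_raw.mean() / (I - 1))
        gene_group_mean[:, j] = gene_mean[:, 0]

    out = pd.DataFrame(index=sub.index)
    if G == 1:
        out["intra_sd:" + labels[0]] = np.sqrt(var_shrunk[:, 0])
        out["intergroup_diff:" + labels[0]] = 0.0
        out["stability"] = np.sqrt(var_shrunk[:, 0])
        return out

    gene_overall = sub.to_numpy(dtype=float).mean(axis=1)
    group_overall = np.array(
        [sub[samples_by_group[g]].to_numpy().mean() for g in labels]
    )
    grand_overall = float(sub.to_numpy(dtype=float).mean())
    d = (gene_group_mean - gene_overall[:, None]) - (
        group_overall - grand_overall
    )[None, :]

    sampling_var = (var_shrunk / n_g[None, :]).mean(axis=1)
    tau2 = np.maximum(0.0, d.var(axis=1, ddof=1) - sampling_var)
    gamma = np.divide(
        tau2, tau2 + sampling_var, out=np.zeros_like(tau2), where=(tau2 + sampling_var) > 0
    )
    d_shrunk = d * gamma[:, None]
    rho = (np.abs(d_shrunk) + np.sqrt(var_shrunk / n_g[None, :])).mean(axis=1)

    for j, g in enumerate(labels):
        out["intra_sd:" + g] = np.sqrt(var_shrunk[:, j])
        out["intergroup_diff:" + g] = d_shrunk[:, j]
    out["stability"] = rho
    return out


def compare_reference_sets(
    tpm: pd.DataFrame,
    groups: Mapping[str, str],
    sets: Sequence[GeneList],
    custom: ReferenceSet | None = None,
) -> dict[str, StabilityReport]:
    """Evaluate several candidate sets side by side.

    Every listed gene must exist in the TPM matrix. Genes with a zero in
    any sample are excluded from the log-based metrics with a warning
    but keep their CV row. Sets with fewer than 3 usable genes are
    skipped with a warning.
    """
    all_sets: list[tuple[str, list[str]]] = [(s.name, list(s.gene_ids)) for s in sets]
    if custom is not None:
        all_sets.append(("custom", list(custom.gene_ids)))

    with np.errstate(divide="ignore"):
        log2tpm = np.log2(tpm.where(tpm > 0))

    reports: dict[str, StabilityReport] = {}
    for name, gene_ids in all_sets:
        missing = [g for g in gene_ids if g not in tpm.index]
        if missing:
            raise KeyError(f"set {name!r}: gene {missing[0]!r} not in TPM matrix")
        usable = [g for g in gene_ids if (tpm.loc[g] > 0).all()]
        dropped = sorted(set(gene_ids) - set(usable))
        if dropped:
            warnings.warn(
                f"set {name!r}: {len(dropped)} gene(s) with zeros excluded "
                f"from log-based metrics (e.g. {dropped[0]})"
            )
        table = gene_cv_stats(tpm.loc[gene_ids])[["mean_tpm", "cv_percent"]].copy()
        for col in ("genorm_m", "genorm_rank", "intergroup_diff", "intragroup_sd", "stability"):
            table[col] = np.nan
        components = None
        v_series: list[float] = []
        if len(usable) < 3:
            warnings.warn(f"set {name!r}: fewer than 3 usable genes; log metrics skipped")
        else:
            M = genorm_m(log2tpm, usable)
            ranks, v_series = genorm_rank(log2tpm, usable)
            comp = normfinder_stability(log2tpm, usable, groups)
            table.loc[usable, "genorm_m"] = M
            table.loc[usable, "genorm_rank"] = ranks.astype(float)
            diff_cols = [c for c in comp.columns if c.startswith("intergroup_diff:")]
            sd_cols = [c for c in comp.columns if c.startswith("intra_sd:")]
            table.loc[usable, "intergroup_diff"] = comp[diff_cols].abs().mean(axis=1)
            table.loc[usable, "intragroup_sd"] = comp[sd_cols].mean(axis=1)
            table.loc[usable, "stability"] = comp["stability"]
            components = comp
        cv = table["cv_percent"]
        stab = table["stability"]
        summary = {
            "n_genes": int(len(gene_ids)),
            "n_usable": int(len(usable)),
            "cv_min": float(cv.min()),
            "cv_median": float(cv.median()),
            "cv_max": float(cv.max()),
            "n_suitable": int((stab < SUITABILITY_THRESHOLD).sum()),
            "stability_median": float(stab.median()) if stab.notna().any() else float("nan"),
        }
        reports[name] = StabilityReport(
            set_name=name,
            table=table,
            pairwise_variation=v_series,
            summary=summary,
            components=components,
        )
    return reports
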