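"""Data-adaptive cutoff separating weakly expressed from expressed genes.

Bulk RNA-seq log-expression distributions are typically bimodal: a
low-abundance mode of transcriptional noise and an expressed mode. For
each sample, this module sweeps candidate cutoffs over the lower
quantiles of the positive log2 TPM values, measures at each cutoff how
far the retained upper tail is from a single fitted normal
(Kolmogorov-Smirnov sup-norm distance), and locates the cutoff where the
distance trace bends — the point past which excluding more genes no
longer improves normality — with an adaptive piecewise-linear (hinge)
regression.

The procedure is fully deterministic: quantile grid, KS statistic and
forward stepwise knot selection involve no randomness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["DafsResult", "ks_sweep", "first_knot", "dafs_cutoffs"]

#: quantile grid step of the cutoff sweep
GRID_STEP = 0.005
#: upper end of the quantile grid
GRID_MAX = 0.50
#: minimum number of positive values required for a meaningful sweep
MIN_POSITIVE = 200
#: stop forward knot addition when the R^2 gain of a step falls below this
R2_IMPROVEMENT = 0.005
#: maximum number of basis terms (intercept + linear + hinge pairs)
MAX_TERMS = 21


@dataclass
class DafsResult:
    """Per-sample cutoffs with the diagnostics that produced them.

    Attributes
    ----------
    cutoffs
        Per-sample cutoff in log2 TPM units.
    traces
        Per-sample sweep trace: DataFrame with columns ``cut`` (log2 TPM)
        and ``ks`` (KS distance), sorted by ``cut``.
    knots
        Per-sample list of retained piecewise-linear knot locations.
    fallback
        Per-sample flag: True when no knot qualified and the cutoff fell
        back to the smallest swept cut value (effectively no filtering).
    """

    cutoffs: pd.Series
    traces: dict[str, pd.DataFrame] = field(default_factory=dict)
    knots: dict[str, list[float]] = field(default_factory=dict)
    fallback: pd.Series | None = None


def ks_sweep(sample_tpm: np.ndarray) -> pd.DataFrame:
    """Sweep cutoffs over a sample's TPM vector and score upper-tail normality.

    Zeros are dropped, the rest log2-transformed. The starting quantile
    q0 is the fraction of values tied at the minimum (rounded to 2
    decimals); the grid then runs from q0 to 0.50 in steps of 0.005.
    At each grid quantile c_q, a normal is fitted by maximum likelihood
    to the values above c_q and the KS sup-norm distance between their
    empirical CDF and the fitted normal CDF is recorded.

    Returns a DataFrame with columns ``cut`` and ``ks``, sorted by cut.
    """
    v = np.asarray(sample_tpm, dtype=float)
    pos = v[v > 0]
    if pos.size < MIN_POSITIVE:
        raise ValueError(
            f"insufficient expressed genes: {pos.size} positive values "
            f"(need >= {MIN_POSITIVE})"
        )
    x = np.log2(pos)
    x.sort()
    q0 = round(float(np.mean(x == x[0])), 2)
    qs = np.arange(q0, GRID_MAX + GRID_STEP / 2, GRID_STEP)
    cuts: list[float] = []
    ds: list[float] = []
    for q in qs:
        c = float(np.quantile(x, q))  # linear-interpolation ("type 7") quantile
        d = x[x > c]
        if d.size < 2:
            warnings.warn(f"quantile {q:.3f} leaves <2 values; skipped")
            continue
        mu = float(d.mean())
        sd = float(d.std(ddof=0))  # MLE scale
        if sd == 0:
            warnings.warn(f"zero-variance tail at quantile {q:.3f}; skipped")
            continue
        ks = stats.ks_1samp(d, stats.norm(mu, sd).cdf).statistic
        cuts.append(c)
        ds.append(float(ks))
    trace = pd.DataFrame({"cut": cuts, "ks": ds})
    return trace.sort_values("cut", kind="stable").reset_index(drop=True)


def _hinge_design(c: np.ndarray, knots: list[float]) -> np.ndarray:
    cols = [np.ones_like(c), c]
    for t in knots:
        cols.append(np.maximum(c - t, 0.0))
        cols.append(np.maximum(t - c, 0.0))
    return np.column_stack(cols)


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def first_knot(trace: pd.DataFrame) -> tuple[float, list[float], bool]:
    """Fit a hinge regression of KS distance on cut value and pick the cutoff.

    Starting from an intercept-plus-linear model, hinge pairs
    ``(max(0, c-t), max(0, t-c))`` with candidate knots t at observed cut
    values are added one pair at a time, each step taking the knot that
    most reduces the residual sum of squares; addition stops when the
    R^2 gain of a step drops below 0.005 or 21 basis terms are reached.

    The cutoff is the smallest retained knot above 0 (log2 TPM = 0, i.e.
    TPM = 1). If no knot qualifies — a degenerate or effectively linear
    trace — the smallest swept cut is returned with ``fallback=True``,
    which disables filtering.

    Returns ``(cutoff, knots, fallback)``.
    """
    if len(trace) < 10:
        raise ValueError("trace has fewer than 10 points")
    c = trace["cut"].to_numpy(dtype=float)
    y = trace["ks"].to_numpy(dtype=float)
    tss = float(((y - y.mean()) ** 2).sum())
    if tss <= 1e-20 * max(1.0, float((y**2).sum())):  # all D_q equal: nothing to fit
        return float(c.min()), [], True

    candidates = np.unique(c)[1:-1]  # interior cuts only
    knots: list[float] = []
    rss = _rss(_hinge_design(c, knots), y)
    while len(knots) * 2 + 2 + 2 <= MAX_TERMS:
        best_t, best_rss = None, rss
        for t in candidates:
            if t in knots:
                continue
            r = _rss(_hinge_design(c, knots + [float(t)]), y)
            if r < best_rss:
                best_t, best_rss = float(t), r
        if best_t is None or (rss - best_rss) / tss < R2_IMPROVEMENT:
            break
        knots.append(best_t)
        rss = best_rss
    knots.sort()
    positive = [t for t in knots if t > 0]
    if positive:
        return positive[0], knots, False
    warnings.warn("no knot above 0; falling back to the minimum swept cut")
    return float(c.min()), knots, True


def dafs_cutoffs(tpm: pd.DataFrame) -> DafsResult:
    """Apply the sweep and knot fit to every sample of a TPM matrix."""
    cutoffs: dict[str, float] = {}
    traces: dict[str, pd.DataFrame] = {}
    knots: dict[str, list[float]] = {}
    fallback: dict[str, bool] = {}
    for sample in tpm.columns:
        try:
            trace = ks_sweep(tpm[sample].to_numpy())
            cut, ks_knots, fb = first_knot(trace)
        except ValueError as exc:
            raise ValueError(f"sample {sample!r}: {exc}") from exc
        cutoffs[sample] = cut
        traces[sample] = trace
        knots[sample] = ks_knots
        fallback[sample] = fb
    return DafsResult(
        cutoffs=pd.Series(cutoffs, dtype=float),
        traces=traces,
        knots=knots,
        fallback=pd.Series(fallback, dtype=bool),
    )
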