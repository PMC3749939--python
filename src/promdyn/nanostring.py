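"""NanoString-style count normalization, fold calls and Monte Carlo FDR.

Counts are normalized per sample to the geometric mean of a housekeeping
gene set (default Gapdh, Tubb5, Cltc) on a log2 scale, then optionally
row-centered across samples.  Up/down calls use an inclusive +/- 2-fold
threshold.  The false-discovery rate of a between-group comparison of
per-sample median expression is estimated by label permutation.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_HOUSEKEEPING = ["Gapdh", "Tubb5", "Cltc"]


@dataclass
class CountMatrix:
    """Genes x samples non-negative integer counts plus a housekeeping set."""

    counts: pd.DataFrame
    housekeeping: list[str] = field(default_factory=lambda: list(DEFAULT_HOUSEKEEPING))

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = [h for h in self.housekeeping if h not in self.counts.index]
        if missing:
            raise ValueError(f"housekeeping genes absent from matrix: {missing}")


@dataclass
class NormalizedMatrix:
    """Log2-scale values with normalization provenance."""

    values: pd.DataFrame
    housekeeping: list[str]
    pseudocount: float
    centered: bool = False


def normalize_housekeeping(m: CountMatrix, pseudocount: float = 1.0) -> NormalizedMatrix:
    """log2(count + c) minus the per-sample mean log2 housekeeping value.

    Subtracting the mean of log2 housekeeping counts is division by their
    geometric mean on the linear scale; housekeeping rows average exactly
    zero per sample afterwards.
    """
    if not m.housekeeping:
        raise ValueError("housekeeping set is empty")
    arr = m.counts.to_numpy(dtype=float) + pseudocount
    if (arr <= 0).any():
        raise ValueError("count + pseudocount must be positive everywhere")
    logs = np.log2(arr)
    df = pd.DataFrame(logs, index=m.counts.index, columns=m.counts.columns)
    hk_mean = df.loc[m.housekeeping].mean(axis=0)
    return NormalizedMatrix(
        values=df.sub(hk_mean, axis=1),
        housekeeping=list(m.housekeeping),
        pseudocount=pseudocount,
    )


def center_genes(nm: NormalizedMatrix) -> NormalizedMatrix:
    """Subtract each gene's row mean across samples (idempotent)."""
    if nm.values.shape[1] < 2:
        raise ValueError("need >= 2 samples to center genes")
    centered = nm.values.sub(nm.values.mean(axis=1), axis=0)
    return NormalizedMatrix(
        values=centered,
        housekeeping=nm.housekeeping,
        pseudocount=nm.pseudocount,
        centered=True,
    )


def fold_calls(nm: NormalizedMatrix, fold: float = 2.0) -> pd.DataFrame:
    """Call up / down / none at an inclusive +/- log2(fold) threshold."""
    if fold <= 1:
        raise ValueError("fold threshold must exceed 1")
    cut = np.log2(fold)
    v = nm.values.to_numpy()
    calls = np.where(v >= cut, "up", np.where(v <= -cut, "down", "none"))
    return pd.DataFrame(calls, index=nm.values.index, columns=nm.values.columns)


def _median_statistic(values: pd.DataFrame) -> np.ndarray:
    return values.median(axis=0).to_numpy()


@dataclass
class FdrEstimate:
    fdr: float
    observed_p: float
    p_threshold: float
    n_iter: int
    seed: int
    statistic: str

    def summary(self) -> str:
        buf = _io.StringIO()
        buf.write("Monte Carlo FDR (label permutation)\n")
        buf.write("=" * 40 + "\n")
        buf.write(f"statistic:    {self.statistic}\n")
        buf.write(f"observed p:   {self.observed_p:.4g}\n")
        buf.write(f"p threshold:  {self.p_threshold:g}\n")
        buf.write(f"iterations:   {self.n_iter}\n")
        buf.write(f"FDR:          {100 * self.fdr:.2f}%\n")
        return buf.getvalue()


def monte_carlo_fdr(
    nm: NormalizedMatrix,
    group_labels: list[str] | np.ndarray,
    p_threshold: float,
    n_iter: int = 10_000,
    seed: int = 0,
    statistic: Callable[[pd.DataFrame], np.ndarray] | None = None,
) -> FdrEstimate:
    """Permutation FDR for a two-group comparison of per-sample summaries.

    The observed statistic is the unpaired equal-variance t-test p-value on
    the per-sample summary (default: median expression) between the two
    label groups.  The null is built by randomly permuting sample labels
    ``n_iter`` times; the FDR is the fraction of iterations whose null p
    falls at or below ``p_threshold``.
    """
    labels = np.asarray(group_labels)
    if len(labels) != nm.values.shape[1]:
        raise ValueError("one label per sample required")
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise ValueError("exactly two groups required")
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")
    mask_a = labels == uniq[0]
    n_a, n_b = int(mask_a.sum()), int((~mask_a).sum())
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    stat_fn = statistic or _median_statistic
    summaries = np.asarray(stat_fn(nm.values), dtype=float)

    def t_p(vals_a: np.ndarray, vals_b: np.ndarray) -> float:
        return float(stats.ttest_ind(vals_a, vals_b, equal_var=True).pvalue)

    observed_p = t_p(summaries[mask_a], summaries[~mask_a])

    # vectorized permutation t-test on the per-sample summary vector
    rng = np.random.default_rng(seed)
    n = len(summaries)
    ranks = rng.random((n_iter, n)).argsort(axis=1)
    perm = summaries[ranks]
    a, b = perm[:, :n_a], perm[:, n_a:]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    sp2 = ((n_a - 1) * va + (n_b - 1) * vb) / (n_a + n_b - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    null_p = 2.0 * stats.t.sf(np.abs(t), df=n_a + n_b - 2)
    null_p = np.where(np.isfinite(null_p), null_p, 1.0)
    fdr = float(np.mean(null_p <= p_threshold))
    return FdrEstimate(
        fdr=fdr,
        observed_p=observed_p,
        p_threshold=p_threshold,
        n_iter=n_iter,
        seed=seed,
        statistic=getattr(stat_fn, "__name__", "custom"),
    )
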