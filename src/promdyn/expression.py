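"""Expression integration with promoter chromatin classes.

Isoform RPKMs are summed per TSS as the transcriptional-output metric, fold
changes are computed with a pseudocount, and differential genes (strictly
>1.5-fold in either direction by default) are intersected with chromatin
classes via the hypergeometric test.  Class-stratified fold-change
distributions are compared with the two-sample Kolmogorov-Smirnov test, and
fold-change matrices are hierarchically clustered with a Euclidean metric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist


def sum_by_tss(isoforms: pd.DataFrame) -> pd.DataFrame:
    """Sum isoform RPKMs over each TSS, per condition.

    Expects columns isoform_id, gene_id, rpkm_A, rpkm_B (isoforms share
    their gene's TSS, so grouping is by gene_id).  Duplicate isoform ids
    are rejected.
    """
    if isoforms["isoform_id"].duplicated().any():
        dup = isoforms.loc[isoforms["isoform_id"].duplicated(), "isoform_id"].iloc[0]
        raise ValueError(f"duplicate isoform id: {dup}")
    out = (
        isoforms.groupby("gene_id", sort=True)[["rpkm_A", "rpkm_B"]]
        .sum()
        .reset_index()
    )
    return out


def log2_fold_changes(
    tss_expr: pd.DataFrame,
    pseudocount: float = 1.0,
    classes: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene log2((B + c) / (A + c)); optionally attach chromatin classes."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    fc = np.log2(
        (tss_expr["rpkm_B"] + pseudocount) / (tss_expr["rpkm_A"] + pseudocount)
    )
    out = pd.DataFrame({"gene_id": tss_expr["gene_id"], "log2_fc": fc})
    if classes is not None:
        out["chrom_class"] = out["gene_id"].map(classes)
    return out


def differential_set(fc: pd.DataFrame, threshold: float = 1.5) -> set[str]:
    """Genes with |fold change| strictly above ``threshold`` (linear scale)."""
    if threshold <= 1:
        raise ValueError("threshold must exceed 1")
    cut = np.log2(threshold)
    sel = fc["log2_fc"].abs() > cut
    return set(fc.loc[sel, "gene_id"])


@dataclass
class OverlapTest:
    """Hypergeometric upper-tail overlap test between two gene sets."""

    n_a: int
    n_b: int
    n_universe: int
    n_overlap: int
    p_value: float

    def summary(self) -> str:
        return (
            f"|A| = {self.n_a}, |B| = {self.n_b}, universe = {self.n_universe}, "
            f"overlap = {self.n_overlap}, hypergeometric p = {self.p_value:.3g}"
        )


def hypergeometric_overlap(
    set_a: set[str], set_b: set[str], universe: set[str]
) -> OverlapTest:
    """P(X >= overlap) drawing |B| genes from the universe with |A| successes."""
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("both sets must be subsets of the universe")
    k = len(set_a & set_b)
    m, na, nb = len(universe), len(set_a), len(set_b)
    p = float(stats.hypergeom.sf(k - 1, m, na, nb))
    return OverlapTest(n_a=na, n_b=nb, n_universe=m, n_overlap=k, p_value=min(p, 1.0))


@dataclass
class KsResult:
    label_a: str
    label_b: str
    d_stat: float
    p_value: float
    n_a: int
    n_b: int


def ks_stratified(
    fc: pd.DataFrame, class_column: str = "chrom_class"
) -> list[KsResult]:
    """Two-sample two-sided KS tests between class fold-change distributions.

    Compares every class pair plus each class against all genes.  Classes
    with fewer than two genes are skipped with a warning.
    """
    groups = {
        str(cls): grp["log2_fc"].to_numpy()
        for cls, grp in fc.groupby(class_column)
        if pd.notna(cls)
    }
    usable = {}
    for cls, vals in groups.items():
        if len(vals) < 2:
            warnings.warn(f"class {cls!r} has < 2 genes; skipped", stacklevel=2)
        else:
            usable[cls] = vals
    all_vals = fc["log2_fc"].to_numpy()
    results = []
    names = sorted(usable)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            ks = stats.ks_2samp(usable[a], usable[b], method="asymp")
            results.append(
                KsResult(a, b, float(ks.statistic), float(ks.pvalue),
                         len(usable[a]), len(usable[b]))
            )
        ks = stats.ks_2samp(usable[a], all_vals, method="asymp")
        results.append(
            KsResult(a, "all", float(ks.statistic), float(ks.pvalue),
                     len(usable[a]), len(all_vals))
        )
    return results


@dataclass
class MedianGroupTest:
    medians: tuple[float, float]
    t_stat: float
    p_value: float
    ns: tuple[int, int]


def median_group_test(group_a: np.ndarray, group_b: np.ndarray) -> MedianGroupTest:
    """Classic equal-variance unpaired t-test; medians reported alongside."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return MedianGroupTest(
                (float(np.median(a)), float(np.median(b))), 0.0, 1.0, (len(a), len(b))
            )
        raise ValueError("both groups degenerate with different means; p undefined")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return MedianGroupTest(
        medians=(float(np.median(a)), float(np.median(b))),
        t_stat=float(t),
        p_value=float(p),
        ns=(len(a), len(b)),
    )


@dataclass
class ClusterResult:
    linkage: np.ndarray
    leaf_order: list[str]
    method: str
    metric: str = "euclidean"


def cluster_fold_changes(
    fc_matrix: pd.DataFrame, method: str = "average"
) -> ClusterResult:
    """Agglomerative clustering of a genes x timepoints fold-change matrix.

    Euclidean distance; linkage method configurable (default average).
    Rows are pre-sorted by gene id so the tree is independent of input
    row order.
    """
    if len(fc_matrix) < 2:
        raise ValueError("need >= 2 genes to cluster")
    if not np.isfinite(fc_matrix.to_numpy()).all():
        raise ValueError("fold-change matrix contains non-finite values")
    ordered = fc_matrix.sort_index(kind="stable")
    dist = pdist(ordered.to_numpy(), metric="euclidean")
    link = hierarchy.linkage(dist, method=method)
    leaves = hierarchy.leaves_list(link)
    return ClusterResult(
        linkage=link,
        leaf_order=[str(ordered.index[i]) for i in leaves],
        method=method,
    )
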