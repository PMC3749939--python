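"""ChIP-seq enrichment calling and promoter chromatin-state classification.

The analysis chain mirrors the classical binned-Poisson approach to histone
ChIP-seq: aligned reads (5' start + strand) are extended to the average
fragment length, allocated to fixed-width genomic bins by fragment midpoint,
and each bin is tested against a Poisson background whose rate is the maximum
of the local input count and the genome-wide input mean, scaled by library
size.  Bins passing both the p-value threshold and a minimum fold-over-input
are merged into enriched regions.  Regions are then intersected with windows
around transcription start sites to classify promoters as bivalent
(H3K4me3 and H3K27me3), active (H3K4me3 only) or unmarked.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

MARKS = ("H2AZ", "H3K4me3", "H3K27me3")
CLASSES = ("bivalent", "active", "unmarked")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ReadSet:
    """Strand-annotated aligned-read intervals, per chromosome.

    ``intervals[chrom]`` is an (n, 2) int array of 0-based half-open
    [start, end) coordinates sorted by start; ``strands[chrom]`` is a boolean
    array, True for the minus strand.
    """

    chrom_sizes: dict[str, int]
    intervals: dict[str, np.ndarray]
    strands: dict[str, np.ndarray]
    label: str = "reads"

    def __post_init__(self) -> None:
        for chrom, iv in self.intervals.items():
            size = self.chrom_sizes[chrom]
            if len(iv):
                if iv[:, 0].min() < 0 or iv[:, 1].max() > size:
                    raise ValueError(f"read outside chromosome bounds on {chrom}")
                if (iv[:, 0] >= iv[:, 1]).any():
                    raise ValueError(f"empty/negative read interval on {chrom}")
                if (np.diff(iv[:, 0]) < 0).any():
                    order = np.argsort(iv[:, 0], kind="stable")
                    self.intervals[chrom] = iv[order]
                    self.strands[chrom] = self.strands[chrom][order]

    @property
    def total(self) -> int:
        return int(sum(len(v) for v in self.intervals.values()))

    def to_bed(self) -> pd.DataFrame:
        rows = []
        for chrom in sorted(self.intervals):
            iv = self.intervals[chrom]
            minus = self.strands[chrom]
            df = pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": iv[:, 0],
                    "end": iv[:, 1],
                    "name": self.label,
                    "score": 0,
                    "strand": np.where(minus, "-", "+"),
                }
            )
            rows.append(df)
        if not rows:
            return pd.DataFrame(
                columns=["chrom", "start", "end", "name", "score", "strand"]
            )
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_bed(
        cls, bed: pd.DataFrame, chrom_sizes: dict[str, int], label: str = "reads"
    ) -> "ReadSet":
        intervals: dict[str, np.ndarray] = {}
        strands: dict[str, np.ndarray] = {}
        for chrom, grp in bed.groupby("chrom", sort=True):
            grp = grp.sort_values("start", kind="stable")
            intervals[str(chrom)] = grp[["start", "end"]].to_numpy(dtype=np.int64)
            strands[str(chrom)] = (grp["strand"] == "-").to_numpy()
        for chrom in chrom_sizes:
            intervals.setdefault(chrom, np.empty((0, 2), dtype=np.int64))
            strands.setdefault(chrom, np.empty(0, dtype=bool))
        return cls(dict(chrom_sizes), intervals, strands, label=label)


@dataclass
class FragmentSet:
    """Extended-fragment intervals per chromosome (sorted by start)."""

    chrom_sizes: dict[str, int]
    intervals: dict[str, np.ndarray]
    label: str = "fragments"

    @property
    def total(self) -> int:
        return int(sum(len(v) for v in self.intervals.values()))


@dataclass
class BinTrack:
    """Fixed-width per-chromosome bin counts with totals."""

    bin_width: int
    counts: dict[str, np.ndarray]
    chrom_sizes: dict[str, int]
    label: str = "track"

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin width must be positive")

    @property
    def total(self) -> int:
        return int(sum(int(v.sum()) for v in self.counts.values()))

    @property
    def n_bins(self) -> int:
        return int(sum(len(v) for v in self.counts.values()))

    def mean_per_bin(self) -> float:
        return self.total / self.n_bins


@dataclass(frozen=True)
class EnrichmentParams:
    """Parameters of the binned-Poisson enrichment caller.

    extension
        Fragment length reads are extended to (bp).
    bin_width
        Width of counting bins (bp).
    pvalue
        Upper-tail Poisson p-value threshold for a bin to be enriched.
    min_fold
        Minimum (pseudocounted) IP/expected-input ratio.
    pseudocount
        Added to numerator and denominator of the fold ratio.
    merge_gap
        Maximum number of non-enriched bins bridged when merging regions.
    local_lambda
        If True, the Poisson rate is max(local input count, genome mean);
        if False, the genome-wide mean alone is used.
    """

    extension: int = 200
    bin_width: int = 25
    pvalue: float = 1e-9
    min_fold: float = 5.0
    pseudocount: float = 1.0
    merge_gap: int = 0
    local_lambda: bool = True

    def __post_init__(self) -> None:
        if self.extension <= 0 or self.bin_width <= 0 or self.min_fold <= 0:
            raise ValueError("extension, bin_width and min_fold must be positive")
        if not 0.0 < self.pvalue < 1.0:
            raise ValueError("pvalue threshold must lie in (0, 1)")


@dataclass
class EnrichedRegionSet:
    """Non-overlapping enriched regions with per-region min p and max fold."""

    regions: pd.DataFrame  # chrom, start, end, fold, minus_log10_p
    params: EnrichmentParams
    mark: str = ""

    def __len__(self) -> int:
        return len(self.regions)

    def to_bed(self) -> pd.DataFrame:
        """BED6+2: name/score/strand then fold and -log10 p."""
        df = self.regions
        return pd.DataFrame(
            {
                "chrom": df["chrom"],
                "start": df["start"],
                "end": df["end"],
                "name": [f"{self.mark or 'region'}_{i}" for i in range(len(df))],
                "score": 0,
                "strand": ".",
                "fold": df["fold"].round(4),
                "minus_log10_p": df["minus_log10_p"].round(4),
            }
        )


@dataclass
class MetageneProfile:
    """Mean fragment coverage on a TSS-relative offset grid."""

    offsets: np.ndarray  # bp, -halfwidth .. halfwidth-1
    density: np.ndarray  # mean coverage per TSS
    n_tss: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset_bp": self.offsets, "mean_density": self.density})


@dataclass
class OrderedDensityMatrix:
    """Genes x TSS-relative bins, rows sorted by a ranking track."""

    gene_order: list[str]
    offsets: np.ndarray  # bin left edges relative to TSS
    matrices: dict[str, np.ndarray]  # mark -> (n_genes, n_bins)
    order_mark: str
    ranking_scores: np.ndarray


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def extend_reads(reads: ReadSet, length: int) -> FragmentSet:
    """Extend each read to ``length`` bp from its 5' end, clipped to bounds.

    A plus-strand read starting at s becomes [s, s+length); a minus-strand
    read ending at e becomes [e-length, e).
    """
    out: dict[str, np.ndarray] = {}
    for chrom, iv in reads.intervals.items():
        size = reads.chrom_sizes[chrom]
        minus = reads.strands[chrom]
        if len(iv) == 0:
            out[chrom] = np.empty((0, 2), dtype=np.int64)
            continue
        starts = np.where(minus, iv[:, 1] - length, iv[:, 0])
        ends = starts + length
        starts = np.clip(starts, 0, size)
        ends = np.clip(ends, 0, size)
        frag = np.column_stack([starts, ends])
        order = np.argsort(frag[:, 0], kind="stable")
        out[chrom] = frag[order]
    return FragmentSet(dict(reads.chrom_sizes), out, label=reads.label)


def bin_counts(fragments: FragmentSet, bin_width: int, label: str | None = None) -> BinTrack:
    """Allocate each fragment to the bin containing its midpoint.

    Every fragment contributes exactly one count, so the track total equals
    the fragment count.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    counts: dict[str, np.ndarray] = {}
    for chrom, size in fragments.chrom_sizes.items():
        n_bins = -(-size // bin_width)  # ceil: last partial bin included
        iv = fragments.intervals.get(chrom)
        if iv is None or len(iv) == 0:
            counts[chrom] = np.zeros(n_bins, dtype=np.int64)
            continue
        mid = (iv[:, 0] + iv[:, 1]) // 2
        idx = np.clip(mid // bin_width, 0, n_bins - 1)
        counts[chrom] = np.bincount(idx, minlength=n_bins).astype(np.int64)
    return BinTrack(bin_width, counts, dict(fragments.chrom_sizes),
                    label=label or fragments.label)


def _call_one_chrom(
    k: np.ndarray, inp: np.ndarray, global_mean: float, scale: float,
    params: EnrichmentParams,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if params.local_lambda:
        lam = np.maximum(inp, global_mean) * scale
    else:
        lam = np.full_like(inp, global_mean, dtype=float) * scale
    pval = stats.poisson.sf(k - 1, lam)
    eps = params.pseudocount
    fold = (k + eps) / (lam + eps)
    enriched = (pval < params.pvalue) & (fold >= params.min_fold)
    return enriched, pval, fold


def _merge_runs(mask: np.ndarray, gap: int) -> list[tuple[int, int]]:
    """Runs of True bins, bridging up to ``gap`` consecutive False bins."""
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > gap + 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(idx) - 1]])
    return [(int(idx[a]), int(idx[b]) + 1) for a, b in zip(starts, ends)]


def call_enriched(
    ip: BinTrack, input_track: BinTrack, params: EnrichmentParams | None = None
) -> EnrichedRegionSet:
    """Call enriched regions with a Poisson model against the input track.

    Per bin with IP count k, the background rate is
    lambda = max(local input count, genome-wide input mean per bin) scaled by
    the IP/input library-size ratio; the bin is enriched iff the upper-tail
    Poisson probability P(X >= k; lambda) falls below the threshold and the
    pseudocounted fold over the scaled input reaches ``min_fold``.  Adjacent
    enriched bins are merged into regions.
    """
    params = params or EnrichmentParams()
    if ip.bin_width != input_track.bin_width:
        raise ValueError("IP and input tracks use different bin widths")
    if ip.chrom_sizes != input_track.chrom_sizes:
        raise ValueError("IP and input tracks cover different chromosomes")
    if input_track.total == 0:
        raise ValueError("input track has zero total count; cannot scale")
    scale = ip.total / input_track.total
    global_mean = input_track.mean_per_bin()
    rows = []
    for chrom in sorted(ip.counts):
        k = ip.counts[chrom].astype(np.int64)
        inp = input_track.counts[chrom].astype(float)
        enriched, pval, fold = _call_one_chrom(k, inp, global_mean, scale, params)
        for b0, b1 in _merge_runs(enriched, params.merge_gap):
            sel = slice(b0, b1)
            sub_p = pval[sel][enriched[sel]]
            sub_f = fold[sel][enriched[sel]]
            minp = float(sub_p.min())
            rows.append(
                {
                    "chrom": chrom,
                    "start": b0 * ip.bin_width,
                    "end": min(b1 * ip.bin_width, ip.chrom_sizes[chrom]),
                    "fold": float(sub_f.max()),
                    "minus_log10_p": float(-np.log10(minp)) if minp > 0 else np.inf,
                }
            )
    regions = pd.DataFrame(rows, columns=["chrom", "start", "end", "fold", "minus_log10_p"])
    return EnrichedRegionSet(regions, params)


def min_enriched_count(lam: float, threshold: float = 1e-9) -> int:
    """Smallest count k with upper-tail Poisson P(X >= k; lambda) < threshold."""
    k = 0
    while stats.poisson.sf(k - 1, lam) >= threshold:
        k += 1
        if k > 10_000:
            raise RuntimeError("threshold unreachable")
    return k


class PoissonEnrichmentModel:
    """Model object pairing an IP and an input bin track.

    ``fit`` runs the binned-Poisson caller and returns an
    :class:`EnrichmentResults` carrying the region table and a summary.
    """

    def __init__(self, ip: BinTrack, input_track: BinTrack, mark: str = "") -> None:
        self.ip = ip
        self.input_track = input_track
        self.mark = mark

    def fit(self, params: EnrichmentParams | None = None) -> "EnrichmentResults":
        params = params or EnrichmentParams()
        regions = call_enriched(self.ip, self.input_track, params)
        regions.mark = self.mark
        return EnrichmentResults(self, regions, params)


class EnrichmentResults:
    def __init__(
        self,
        model: PoissonEnrichmentModel,
        regions: EnrichedRegionSet,
        params: EnrichmentParams,
    ) -> None:
        self.model = model
        self.regions = regions
        self.params = params

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def summary(self) -> str:
        df = self.regions.regions
        buf = _io.StringIO()
        buf.write("Poisson enrichment caller\n")
        buf.write("=" * 48 + "\n")
        buf.write(f"mark:            {self.model.mark or '(unlabelled)'}\n")
        buf.write(f"IP fragments:    {self.model.ip.total}\n")
        buf.write(f"input fragments: {self.model.input_track.total}\n")
        buf.write(f"bin width:       {self.params.bin_width} bp\n")
        buf.write(f"p threshold:     {self.params.pvalue:g}\n")
        buf.write(f"min fold:        {self.params.min_fold:g}\n")
        buf.write(f"regions called:  {len(df)}\n")
        if len(df):
            buf.write(f"median width:    {float((df['end'] - df['start']).median()):.0f} bp\n")
            buf.write(f"max fold:        {float(df['fold'].max()):.2f}\n")
        return buf.getvalue()


def annotate_promoters(
    regions_by_mark: dict[str, EnrichedRegionSet],
    genes: pd.DataFrame,
    window: int = 2000,
) -> pd.DataFrame:
    """Flag TSSs whose window contains an enriched-region boundary; classify.

    A mark flags a TSS iff either boundary of one of its regions lies within
    [TSS-window, TSS+window).  Class is bivalent iff H3K4me3 and H3K27me3,
    active iff H3K4me3 only, unmarked otherwise.  ``genes`` needs columns
    gene_id, chrom, tss, strand.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    for required in ("H3K4me3", "H3K27me3"):
        if required not in regions_by_mark:
            raise KeyError(f"required mark missing: {required}")
    table = genes[["gene_id", "chrom", "tss", "strand"]].copy()
    for mark, regset in regions_by_mark.items():
        flags = np.zeros(len(table), dtype=bool)
        reg = regset.regions
        for chrom, grp in reg.groupby("chrom"):
            sel = table["chrom"] == chrom
            if not sel.any():
                continue
            tss = table.loc[sel, "tss"].to_numpy()
            bounds = np.concatenate([grp["start"].to_numpy(), grp["end"].to_numpy()])
            bounds.sort()
            lo = np.searchsorted(bounds, tss - window, side="left")
            hi = np.searchsorted(bounds, tss + window, side="left")
            flags[np.flatnonzero(sel.to_numpy())] |= hi > lo
        table[mark] = flags
    k4 = table["H3K4me3"].to_numpy()
    k27 = table["H3K27me3"].to_numpy()
    table["chrom_class"] = np.select(
        [k4 & k27, k4 & ~k27], ["bivalent", "active"], default="unmarked"
    )
    return table


def metagene_profile(
    fragments: FragmentSet,
    promoters: pd.DataFrame,
    halfwidth: int = 2000,
    class_filter: str | None = None,
    statistic: str = "coverage",
    bin_width: int = 25,
) -> MetageneProfile:
    """Average fragment density around TSSs, strand-oriented.

    ``statistic="coverage"`` accumulates per-bp fragment coverage;
    ``statistic="midpoint"`` counts fragment midpoints in ``bin_width`` bins
    (the allocation the binned enrichment tracks use, which preserves the
    bimodal flanking pattern that full-fragment coverage blurs).
    Minus-strand genes are flipped so positive offsets always point
    downstream of transcription.
    """
    if statistic not in ("coverage", "midpoint"):
        raise ValueError("statistic must be 'coverage' or 'midpoint'")
    table = promoters
    if class_filter is not None:
        table = table[table["chrom_class"] == class_filter]
    if len(table) == 0:
        raise ValueError("no TSS passes the class filter")
    if statistic == "midpoint":
        return _midpoint_profile(fragments, table, halfwidth, bin_width)
    width = 2 * halfwidth
    acc = np.zeros(width)
    max_len = max(
        (int((iv[:, 1] - iv[:, 0]).max()) for iv in fragments.intervals.values() if len(iv)),
        default=0,
    )
    for chrom, grp in table.groupby("chrom"):
        iv = fragments.intervals.get(chrom)
        if iv is None or len(iv) == 0:
            continue
        starts = iv[:, 0]
        for tss, strand in zip(grp["tss"].to_numpy(), grp["strand"].to_numpy()):
            lo = np.searchsorted(starts, tss - halfwidth - max_len, side="left")
            hi = np.searchsorted(starts, tss + halfwidth, side="left")
            if hi <= lo:
                continue
            s = np.clip(iv[lo:hi, 0] - (tss - halfwidth), 0, width)
            e = np.clip(iv[lo:hi, 1] - (tss - halfwidth), 0, width)
            diff = np.zeros(width + 1)
            np.add.at(diff, s, 1.0)
            np.add.at(diff, e, -1.0)
            cov = np.cumsum(diff[:-1])
            acc += cov if strand == "+" else cov[::-1]
    offsets = np.arange(-halfwidth, halfwidth)
    return MetageneProfile(offsets, acc / len(table), n_tss=len(table))


def _midpoint_profile(
    fragments: FragmentSet, table: pd.DataFrame, halfwidth: int, bin_width: int
) -> MetageneProfile:
    n_bins = 2 * halfwidth // bin_width
    acc = np.zeros(n_bins)
    for chrom, grp in table.groupby("chrom"):
        iv = fragments.intervals.get(chrom)
        if iv is None or len(iv) == 0:
            continue
        mids = np.sort((iv[:, 0] + iv[:, 1]) // 2)
        for tss, strand in zip(grp["tss"].to_numpy(), grp["strand"].to_numpy()):
            lo = np.searchsorted(mids, tss - halfwidth, side="left")
            hi = np.searchsorted(mids, tss + halfwidth, side="left")
            if hi <= lo:
                continue
            rel = mids[lo:hi] - (tss - halfwidth)
            counts = np.bincount(rel // bin_width, minlength=n_bins)[:n_bins]
            acc += counts if strand == "+" else counts[::-1]
    offsets = np.arange(-halfwidth, halfwidth, bin_width)
    return MetageneProfile(offsets, acc / len(table), n_tss=len(table))


def ordered_density_matrix(
    track_by_mark: dict[str, BinTrack],
    promoters: pd.DataFrame,
    halfwidth: int = 4000,
    order_mark: str = "H3K27me3",
) -> OrderedDensityMatrix:
    """Per-gene TSS-window density rows ordered by a ranking mark.

    The ranking score is the summed density of ``order_mark`` over the
    window; rows are sorted descending, ties broken by gene id.
    """
    if order_mark not in track_by_mark:
        raise KeyError(f"ordering mark not provided: {order_mark}")
    width = next(iter(track_by_mark.values())).bin_width
    n_bins = 2 * halfwidth // width
    genes = promoters.sort_values("gene_id", kind="stable").reset_index(drop=True)
    mats = {m: np.zeros((len(genes), n_bins)) for m in track_by_mark}
    for mark, track in track_by_mark.items():
        if track.bin_width != width:
            raise ValueError("all tracks must share a bin width")
        for i, row in genes.iterrows():
            counts = track.counts.get(row["chrom"])
            if counts is None:
                continue
            b0 = (int(row["tss"]) - halfwidth) // width
            window = np.zeros(n_bins)
            lo, hi = max(b0, 0), min(b0 + n_bins, len(counts))
            if hi > lo:
                window[lo - b0 : hi - b0] = counts[lo:hi]
            mats[mark][i] = window if row["strand"] == "+" else window[::-1]
    scores = mats[order_mark].sum(axis=1)
    # descending score, ties by gene id (rows pre-sorted by id, stable sort)
    order = np.argsort(-scores, kind="stable")
    return OrderedDensityMatrix(
        gene_order=list(genes["gene_id"].to_numpy()[order]),
        offsets=np.arange(-halfwidth, halfwidth, width),
        matrices={m: a[order] for m, a in mats.items()},
        order_mark=order_mark,
        ranking_scores=scores[order],
    )
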