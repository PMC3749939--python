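"""Synthetic data generators with known ground truth.

Every downstream stage of the pipeline can be exercised on output of this
module: a toy genome with class-labelled genes (bivalent / active /
unmarked), strand-oriented bimodal ChIP enrichment over a uniform Poisson
background, class-shifted two-condition isoform expression, NanoString-style
count matrices anchored on housekeeping genes, and single-exponential FRAP
recovery curves with an immobile fraction.

All generators are pure functions of their seed and parameters.  Per-gene
random sub-streams are derived from (seed, gene index) so enlarging a gene
set does not reshuffle the draws of existing genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .chip import CLASSES, MARKS, ReadSet
from .frap import FrapCurve
from .nanostring import CountMatrix

MIN_GENE_SPACING = 5_000  # bp between TSSs; keeps promoter windows disjoint


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

@dataclass
class GenomeModel:
    """Chromosome sizes plus a gene table with true chromatin classes.

    ``genes`` columns: gene_id, chrom, tss, strand, true_class.
    """

    chrom_sizes: dict[str, int]
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        g = self.genes
        if g["gene_id"].duplicated().any():
            raise ValueError("gene ids must be unique")
        for chrom, grp in g.groupby("chrom"):
            size = self.chrom_sizes[str(chrom)]
            if (grp["tss"] < 0).any() or (grp["tss"] >= size).any():
                raise ValueError(f"TSS outside chromosome bounds on {chrom}")
        bad = set(g["true_class"]) - set(CLASSES)
        if bad:
            raise ValueError(f"unknown chromatin class: {bad}")

    @property
    def total_length(self) -> int:
        return int(sum(self.chrom_sizes.values()))

    def classes(self) -> pd.Series:
        return self.genes.set_index("gene_id")["true_class"]


class CapacityError(ValueError):
    """Requested genes cannot be placed with the minimum spacing."""


def gen_genome(
    n_chrom: int,
    chrom_len: int,
    n_genes: int,
    class_probs: tuple[float, float, float],
    seed: int,
) -> GenomeModel:
    """Place ``n_genes`` TSSs with >= 5 kb spacing; draw classes i.i.d.

    ``class_probs`` orders (bivalent, active, unmarked) and must sum to 1.
    """
    probs = np.asarray(class_probs, dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
        raise ValueError("class_probs must be a probability triple")
    chrom_sizes = {f"chr{i + 1}": int(chrom_len) for i in range(n_chrom)}
    if n_genes * MIN_GENE_SPACING > n_chrom * chrom_len:
        raise CapacityError(
            f"cannot place {n_genes} genes with {MIN_GENE_SPACING} bp spacing "
            f"in {n_chrom * chrom_len} bp"
        )
    # spread genes over chromosomes as evenly as capacity allows
    per_chrom = [n_genes // n_chrom] * n_chrom
    for i in range(n_genes % n_chrom):
        per_chrom[i] += 1
    cap = chrom_len // MIN_GENE_SPACING
    if any(k > cap for k in per_chrom):
        raise CapacityError("per-chromosome capacity exceeded")

    rng_pos = np.random.default_rng([seed, 0])
    rows = []
    gi = 0
    for ci, (chrom, k) in enumerate(zip(chrom_sizes, per_chrom)):
        if k == 0:
            continue
        slack = chrom_len - k * MIN_GENE_SPACING
        offsets = np.sort(rng_pos.integers(0, slack + 1, size=k))
        tss = offsets + np.arange(k) * MIN_GENE_SPACING
        for t in tss:
            rng_g = np.random.default_rng([seed, 1, gi])
            cls = CLASSES[rng_g.choice(3, p=probs)]
            strand = "+" if rng_g.random() < 0.5 else "-"
            rows.append(
                {
                    "gene_id": f"g{gi:05d}",
                    "chrom": chrom,
                    "tss": int(t),
                    "strand": strand,
                    "true_class": cls,
                }
            )
            gi += 1
    return GenomeModel(chrom_sizes, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# ChIP reads
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationParams:
    """Read-simulation parameters for one ChIP library pair.

    fold_by_class maps chromatin class -> IP/input enrichment fold over the
    TSS +/-(peak_offset + 2*peak_sd) window (folds are defined at
    depletion 0).  The +1-nucleosome (downstream) component is scaled by
    (1 - plus_one_depletion).
    """

    total_reads: int
    fold_by_class: dict[str, float] = field(
        default_factory=lambda: {"bivalent": 1.0, "active": 1.0, "unmarked": 1.0}
    )
    background_rate: float = 1.0  # relative reads per bp
    peak_offset: int = 100  # bp from TSS to each mixture component
    peak_sd: float = 50.0  # bp
    plus_one_depletion: float = 0.0
    read_length: int = 36
    fragment_length: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_reads <= 0:
            raise ValueError("total_reads must be positive")
        if any(f < 1.0 for f in self.fold_by_class.values()):
            raise ValueError("enrichment folds must be >= 1")
        if not 0.0 <= self.plus_one_depletion <= 1.0:
            raise ValueError("plus_one_depletion must lie in [0, 1]")
        if self.read_length > self.fragment_length:
            raise ValueError("read_length cannot exceed fragment_length")


def default_mark_folds(mark: str, fold: float) -> dict[str, float]:
    """Class folds matching promoter biology for each supported mark.

    H3K4me3 (and H2A.Z) sit at bivalent and active promoters; H3K27me3 only
    at bivalent ones.
    """
    if mark not in MARKS:
        raise ValueError(f"unknown mark: {mark!r}")
    if mark == "H3K27me3":
        return {"bivalent": fold, "active": 1.0, "unmarked": 1.0}
    return {"bivalent": fold, "active": fold, "unmarked": 1.0}


def _reads_from_centers(
    centers: np.ndarray, chrom_len: int, params: SimulationParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Fragment centers -> sequenced-read intervals and strands."""
    frag = params.fragment_length
    fs = np.rint(centers).astype(np.int64) - frag // 2
    fs = np.clip(fs, 0, max(chrom_len - frag, 0))
    minus = rng.random(len(fs)) < 0.5
    starts = np.where(minus, fs + frag - params.read_length, fs)
    ends = starts + params.read_length
    return np.column_stack([starts, ends]), minus


def gen_chip_reads(
    genome: GenomeModel, params: SimulationParams, mark: str
) -> tuple[ReadSet, ReadSet]:
    """Simulate an IP ReadSet and a matched uniform input ReadSet.

    The IP library is a mixture of a uniform background and, at each enriched
    TSS, two Gaussian fragment-center components at +/-peak_offset
    (strand-oriented; downstream scaled by 1 - depletion).  Component masses
    are solved jointly so that the expected IP/input density ratio over the
    TSS window equals the class fold at depletion 0.  Exactly
    ``total_reads`` reads are emitted for each library.
    """
    if mark not in MARKS:
        raise ValueError(f"unknown mark: {mark!r}")
    b = params.background_rate
    L = genome.total_length
    off, sd = params.peak_offset, params.peak_sd
    half = off + 2.0 * sd
    # fraction of the (equal-mass) two-component mixture inside the window
    in_frac = float(
        0.5 * (stats.norm.cdf((half - off) / sd) - stats.norm.cdf((-half - off) / sd))
        + 0.5 * (stats.norm.cdf((half + off) / sd) - stats.norm.cdf((-half + off) / sd))
    )
    unit = b * (2.0 * half) / in_frac  # peak mass giving +1x background in-window

    genes = genome.genes
    folds = genes["true_class"].map(params.fold_by_class).to_numpy(dtype=float)
    enriched = folds > 1.0
    W_bg = b * L
    G = int(enriched.sum())
    denom = W_bg - unit * float(folds[enriched].sum())
    if G and denom <= 0:
        raise ValueError("requested enrichment mass exceeds genome capacity; "
                         "lower folds or enlarge the genome")
    s = (W_bg - G * unit) / denom if G else 1.0
    peak_mass = np.where(enriched, (folds * s - 1.0) * unit, 0.0)

    d = params.plus_one_depletion
    weights = [W_bg]
    comps: list[tuple[str, float, float]] = []  # chrom, center, sd
    for i, row in enumerate(genes.itertuples(index=False)):
        if not enriched[i]:
            continue
        sign = 1 if row.strand == "+" else -1
        upstream = row.tss - sign * off
        downstream = row.tss + sign * off
        weights.append(peak_mass[i] / 2.0)
        comps.append((row.chrom, float(upstream), sd))
        weights.append(peak_mass[i] / 2.0 * (1.0 - d))
        comps.append((row.chrom, float(downstream), sd))

    mark_idx = MARKS.index(mark)
    rng = np.random.default_rng([params.seed, 2, mark_idx])
    w = np.asarray(weights, dtype=float)
    counts = rng.multinomial(params.total_reads, w / w.sum())

    chrom_names = list(genome.chrom_sizes)
    chrom_lens = np.array([genome.chrom_sizes[c] for c in chrom_names], dtype=float)
    per_chrom_centers: dict[str, list[np.ndarray]] = {c: [] for c in chrom_names}
    # background: uniform over the concatenated genome
    n_bg = counts[0]
    u = rng.random(n_bg) * L
    edges = np.concatenate([[0.0], np.cumsum(chrom_lens)])
    ci = np.searchsorted(edges, u, side="right") - 1
    for j, c in enumerate(chrom_names):
        per_chrom_centers[c].append(u[ci == j] - edges[j])
    for (chrom, center, csd), n in zip(comps, counts[1:]):
        if n:
            per_chrom_centers[chrom].append(rng.normal(center, csd, size=n))

    intervals: dict[str, np.ndarray] = {}
    strands: dict[str, np.ndarray] = {}
    for c in chrom_names:
        centers = (
            np.concatenate(per_chrom_centers[c]) if per_chrom_centers[c] else np.empty(0)
        )
        centers = np.clip(centers, 0, genome.chrom_sizes[c] - 1)
        iv, minus = _reads_from_centers(centers, genome.chrom_sizes[c], params, rng)
        order = np.argsort(iv[:, 0], kind="stable")
        intervals[c] = iv[order]
        strands[c] = minus[order]
    ip = ReadSet(dict(genome.chrom_sizes), intervals, strands, label=f"{mark}_IP")

    # matched input: pure background at the same depth
    rng_in = np.random.default_rng([params.seed, 3, mark_idx])
    u = rng_in.random(params.total_reads) * L
    ci = np.searchsorted(edges, u, side="right") - 1
    intervals_in: dict[str, np.ndarray] = {}
    strands_in: dict[str, np.ndarray] = {}
    for j, c in enumerate(chrom_names):
        centers = np.clip(u[ci == j] - edges[j], 0, genome.chrom_sizes[c] - 1)
        iv, minus = _reads_from_centers(centers, genome.chrom_sizes[c], params, rng_in)
        order = np.argsort(iv[:, 0], kind="stable")
        intervals_in[c] = iv[order]
        strands_in[c] = minus[order]
    inp = ReadSet(dict(genome.chrom_sizes), intervals_in, strands_in, label=f"{mark}_input")
    return ip, inp


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def gen_expression(
    genome: GenomeModel,
    class_shift_log2: dict[str, float],
    n_isoforms_per_gene: int = 2,
    base_rpkm_median: float = 10.0,
    base_rpkm_sd_log2: float = 1.5,
    noise_sd_log2: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-condition isoform RPKM table with class-dependent shifts.

    Condition B = condition A x 2^shift(class) x 2^N(0, noise_sd_log2),
    per isoform.  Isoforms share their gene's TSS.  Columns: isoform_id,
    gene_id, chrom, tss, strand, rpkm_A, rpkm_B.
    """
    for cls, sh in class_shift_log2.items():
        if cls not in CLASSES:
            raise ValueError(f"unknown class: {cls}")
        if not np.isfinite(sh):
            raise ValueError("class shifts must be finite")
    rows = []
    for gi, row in enumerate(genome.genes.itertuples(index=False)):
        rng = np.random.default_rng([seed, 4, gi])
        shift = class_shift_log2.get(row.true_class, 0.0)
        for k in range(n_isoforms_per_gene):
            base = base_rpkm_median * 2.0 ** rng.normal(0.0, base_rpkm_sd_log2)
            noise = 2.0 ** rng.normal(0.0, noise_sd_log2) if noise_sd_log2 > 0 else 1.0
            rows.append(
                {
                    "isoform_id": f"{row.gene_id}.{k + 1}",
                    "gene_id": row.gene_id,
                    "chrom": row.chrom,
                    "tss": row.tss,
                    "strand": row.strand,
                    "rpkm_A": base,
                    "rpkm_B": base * 2.0 ** shift * noise,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# FRAP
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrapSimParams:
    """Single-exponential recovery with an immobile fraction.

    Post-bleach intensity (normalized to pre-bleach = 1):
    I(t) = I_dip + MF * (1 - I_dip) * (1 - exp(-k t)) + noise.
    ``cell_sd`` spreads the true mobile fraction across cells.
    """

    mobile_fraction: float = 0.13
    rate_constant: float = 0.01  # 1/s
    bleach_depth: float = 0.5  # I_dip
    frame_interval: float = 30.0  # s
    n_frames: int = 31
    n_prebleach: int = 2
    noise_sd: float = 0.01
    cell_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mobile_fraction <= 1.0:
            raise ValueError("mobile_fraction must lie in [0, 1]")
        if not 0.0 < self.bleach_depth < 1.0:
            raise ValueError("bleach_depth must lie in (0, 1)")
        if self.rate_constant <= 0 or self.frame_interval <= 0:
            raise ValueError("rate_constant and frame_interval must be positive")
        if self.n_frames < self.n_prebleach + 2:
            raise ValueError("n_frames too small to contain bleach and recovery")
        if self.n_prebleach < 1:
            raise ValueError("need at least one pre-bleach frame")


def frap_intensity(t: np.ndarray, mf: float, k: float, i_dip: float) -> np.ndarray:
    """Noiseless recovery curve at post-bleach times t (t=0 at the dip)."""
    return i_dip + mf * (1.0 - i_dip) * (1.0 - np.exp(-k * np.asarray(t, dtype=float)))


def gen_frap_curves(params: FrapSimParams, n_cells: int) -> list[FrapCurve]:
    """Simulate normalized per-cell recovery traces on a shared time grid."""
    curves = []
    n_post = params.n_frames - params.n_prebleach
    times = np.arange(params.n_frames) * params.frame_interval
    t_post = np.arange(n_post) * params.frame_interval
    for ci in range(n_cells):
        rng = np.random.default_rng([params.seed, 5, ci])
        mf = params.mobile_fraction
        if params.cell_sd > 0:
            mf = float(np.clip(rng.normal(mf, params.cell_sd), 0.0, 1.0))
        pre = np.ones(params.n_prebleach)
        post = frap_intensity(t_post, mf, params.rate_constant, params.bleach_depth)
        intensity = np.concatenate([pre, post])
        if params.noise_sd > 0:
            intensity = intensity + rng.normal(0.0, params.noise_sd, params.n_frames)
        curves.append(
            FrapCurve(
                times=times.copy(),
                intensities=intensity,
                bleach_index=params.n_prebleach,
                cell_id=f"cell{ci:03d}",
            )
        )
    return curves


# ---------------------------------------------------------------------------
# NanoString
# ---------------------------------------------------------------------------

def gen_nanostring(
    n_genes: int,
    n_samples: int,
    housekeeping: tuple[str, ...] = ("Gapdh", "Tubb5", "Cltc"),
    sample_scales: np.ndarray | None = None,
    gene_effects_log2: dict[str, np.ndarray] | None = None,
    base_mean: float = 500.0,
    base_sd_log2: float = 1.0,
    noise_sd_log2: float = 0.05,
    seed: int = 0,
) -> CountMatrix:
    """NanoString-style count matrix anchored on zero-effect housekeepers.

    counts(g, s) = round(scale_s * base_g * 2^effect(g, s) * 2^N(0, noise)).
    Housekeeping genes always have zero effect.  Gene ids are the
    housekeeping names followed by t001, t002, ...
    """
    gene_ids = list(housekeeping) + [f"t{i:03d}" for i in range(n_genes - len(housekeeping))]
    if n_genes < len(housekeeping):
        raise ValueError("n_genes smaller than the housekeeping set")
    sample_ids = [f"s{j + 1}" for j in range(n_samples)]
    scales = np.ones(n_samples) if sample_scales is None else np.asarray(sample_scales, float)
    if len(scales) != n_samples:
        raise ValueError("sample_scales length mismatch")
    effects = np.zeros((n_genes, n_samples))
    if gene_effects_log2:
        for g, eff in gene_effects_log2.items():
            if g in housekeeping:
                continue  # housekeeping effects fixed at 0
            if g not in gene_ids:
                raise ValueError(f"unknown gene in effects: {g}")
            effects[gene_ids.index(g)] = np.asarray(eff, dtype=float)
    counts = np.zeros((n_genes, n_samples), dtype=np.int64)
    for gi in range(n_genes):
        rng = np.random.default_rng([seed, 6, gi])
        base = base_mean * 2.0 ** rng.normal(0.0, base_sd_log2)
        noise = (
            2.0 ** rng.normal(0.0, noise_sd_log2, n_samples)
            if noise_sd_log2 > 0
            else np.ones(n_samples)
        )
        counts[gi] = np.rint(scales * base * 2.0 ** effects[gi] * noise).astype(np.int64)
    df = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    return CountMatrix(df, housekeeping=list(housekeeping))
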