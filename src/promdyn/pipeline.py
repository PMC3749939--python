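"""End-to-end orchestration: simulate -> call -> classify -> integrate -> report.

A single YAML config drives a deterministic run: a synthetic genome is
generated, ChIP libraries for H3K4me3/H3K27me3 (and optionally H2A.Z) are
simulated and called, promoters are classified, class-shifted expression is
simulated and stratified, FRAP groups are simulated and compared, and a JSON
report summarizes class counts, overlap statistics and mobile fractions.
Every output file starts with a provenance header; reruns with the same
config and seed are byte-identical.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, io as pio
from .chip import (
    EnrichmentParams,
    PoissonEnrichmentModel,
    annotate_promoters,
    bin_counts,
    extend_reads,
)
from .expression import (
    differential_set,
    hypergeometric_overlap,
    ks_stratified,
    log2_fold_changes,
    sum_by_tss,
)
from .frap import compare_mobile_fractions, mobile_fraction, normalize_curve
from .synthetic import (
    FrapSimParams,
    SimulationParams,
    default_mark_folds,
    gen_chip_reads,
    gen_expression,
    gen_frap_curves,
    gen_genome,
)

logger = logging.getLogger("promdyn")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Configuration for one reproducible pipeline run."""

    outdir: str = "promdyn_run"
    seed: int = 42
    # genome
    n_chrom: int = 1
    chrom_len: int = 2_000_000
    n_genes: int = 200
    class_probs: tuple[float, float, float] = (0.3, 0.5, 0.2)
    # ChIP simulation + calling
    marks: tuple[str, ...] = ("H3K4me3", "H3K27me3")
    total_reads: int = 1_000_000
    enrichment_fold: float = 20.0
    enrichment: EnrichmentParams = field(default_factory=EnrichmentParams)
    tss_window: int = 2000
    # expression
    class_shift_log2: dict = field(default_factory=lambda: {"bivalent": 1.0})
    expression_noise_sd_log2: float = 0.1
    fc_pseudocount: float = 1.0
    fc_threshold: float = 1.5
    # FRAP
    frap_groups: dict = field(
        default_factory=lambda: {"WT": 0.13, "AP3": 0.20}
    )
    frap_n_cells: int = 14
    frap_cell_sd: float = 0.03
    frap_noise_sd: float = 0.01

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        enr = raw.pop("enrichment", None)
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if enr:
            cfg.enrichment = EnrichmentParams(**enr)
        if isinstance(cfg.class_probs, list):
            cfg.class_probs = tuple(cfg.class_probs)
        if isinstance(cfg.marks, list):
            cfg.marks = tuple(cfg.marks)
        return cfg


def _setup_logging(outdir: Path, verbose: bool) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    handlers = [
        logging.StreamHandler(sys.stderr),
        logging.FileHandler(outdir / "run.log"),
    ]
    fmt = logging.Formatter("%(asctime)s [%(name)s] %(levelname)s %(message)s")
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)
    logger.handlers.clear()
    for h in handlers:
        h.setFormatter(fmt)
        logger.addHandler(h)


def run_pipeline(config: PipelineConfig, verbose: bool = False) -> dict:
    """Execute all stages in dependency order; return the run report."""
    outdir = Path(config.outdir)
    _setup_logging(outdir, verbose)
    report: dict = {"version": __version__, "seed": config.seed}
    t0 = time.time()

    def stage(name):
        logger.info("stage %s", name)

    try:
        stage("simulate.genome")
        genome = gen_genome(
            config.n_chrom, config.chrom_len, config.n_genes,
            config.class_probs, seed=config.seed,
        )
        header = pio.provenance_header(
            "simulate.genome", config.seed,
            {"n_genes": config.n_genes, "chrom_len": config.chrom_len},
        )
        pio.write_tsv(genome.genes, outdir / "genes.tsv", header)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("simulate.genome", str(exc)) from exc

    regions_by_mark = {}
    try:
        for mark in config.marks:
            stage(f"chip.{mark}")
            params = SimulationParams(
                total_reads=config.total_reads,
                fold_by_class=default_mark_folds(mark, config.enrichment_fold),
                seed=config.seed,
            )
            ip, inp = gen_chip_reads(genome, params, mark)
            frag_ip = extend_reads(ip, config.enrichment.extension)
            frag_in = extend_reads(inp, config.enrichment.extension)
            track_ip = bin_counts(frag_ip, config.enrichment.bin_width)
            track_in = bin_counts(frag_in, config.enrichment.bin_width)
            results = PoissonEnrichmentModel(track_ip, track_in, mark=mark).fit(
                config.enrichment
            )
            regions_by_mark[mark] = results.regions
            hdr = pio.provenance_header(
                f"chip.call.{mark}", config.seed,
                {"pvalue": config.enrichment.pvalue,
                 "min_fold": config.enrichment.min_fold,
                 "bin": config.enrichment.bin_width,
                 "extension": config.enrichment.extension},
            )
            pio.write_bed6(results.regions.to_bed(), outdir / f"{mark}_regions.bed", hdr)
            logger.info("%s: %d regions", mark, results.n_regions)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"chip.{mark}", str(exc)) from exc

    try:
        stage("annotate")
        promoters = annotate_promoters(regions_by_mark, genome.genes, config.tss_window)
        promoters = promoters.merge(
            genome.genes[["gene_id", "true_class"]], on="gene_id"
        )
        pio.write_tsv(
            promoters, outdir / "promoters.tsv",
            pio.provenance_header("annotate", config.seed,
                                  {"window": config.tss_window}),
        )
        class_counts = promoters["chrom_class"].value_counts().to_dict()
        true_counts = promoters["true_class"].value_counts().to_dict()
        report["promoter_classes"] = {k: int(v) for k, v in sorted(class_counts.items())}
        report["true_classes"] = {k: int(v) for k, v in sorted(true_counts.items())}
        confusion = (
            promoters.groupby(["true_class", "chrom_class"]).size().reset_index(name="n")
        )
        report["class_confusion"] = [
            {"true": r.true_class, "called": r.chrom_class, "n": int(r.n)}
            for r in confusion.itertuples()
        ]
    except KeyError as exc:
        raise StageError("annotate", f"missing mark {exc}") from exc
    except Exception as exc:
        raise StageError("annotate", str(exc)) from exc

    try:
        stage("expression")
        isoforms = gen_expression(
            genome, config.class_shift_log2,
            noise_sd_log2=config.expression_noise_sd_log2, seed=config.seed,
        )
        pio.write_tsv(isoforms, outdir / "expression.tsv",
                      pio.provenance_header("simulate.expression", config.seed))
        tss_expr = sum_by_tss(isoforms)
        fc = log2_fold_changes(
            tss_expr, pseudocount=config.fc_pseudocount,
            classes=promoters.set_index("gene_id")["chrom_class"],
        )
        pio.write_tsv(fc, outdir / "fold_changes.tsv",
                      pio.provenance_header("expression.fc", config.seed,
                                            {"pseudocount": config.fc_pseudocount}))
        diff = differential_set(fc, threshold=config.fc_threshold)
        universe = set(fc["gene_id"])
        bivalent = set(fc.loc[fc["chrom_class"] == "bivalent", "gene_id"])
        overlaps = {}
        if bivalent:
            ov = hypergeometric_overlap(diff, bivalent, universe)
            overlaps["differential_vs_bivalent"] = {
                "overlap": ov.n_overlap, "n_diff": ov.n_a,
                "n_bivalent": ov.n_b, "universe": ov.n_universe,
                "p": ov.p_value,
            }
        report["differential_genes"] = len(diff)
        report["overlaps"] = overlaps
        report["ks"] = [
            {"a": r.label_a, "b": r.label_b, "D": round(r.d_stat, 6), "p": r.p_value}
            for r in ks_stratified(fc)
        ]
    except Exception as exc:
        raise StageError("expression", str(exc)) from exc

    try:
        stage("frap")
        mfs = {}
        for gi, (name, mf_true) in enumerate(sorted(config.frap_groups.items())):
            params = FrapSimParams(
                mobile_fraction=mf_true, noise_sd=config.frap_noise_sd,
                cell_sd=config.frap_cell_sd, seed=config.seed + 1000 * (gi + 1),
            )
            curves = [normalize_curve(c) for c in
                      gen_frap_curves(params, config.frap_n_cells)]
            pio.write_frap_csv(curves, outdir / f"frap_{name}.csv",
                               pio.provenance_header(f"simulate.frap.{name}",
                                                     config.seed))
            mfs[name] = [mobile_fraction(c).mf for c in curves]
        names = sorted(mfs)
        report["frap"] = {
            name: {"mean_mf": float(np.mean(v)),
                   "sem": float(np.std(v, ddof=1) / np.sqrt(len(v))),
                   "n": len(v)}
            for name, v in mfs.items()
        }
        if len(names) == 2:
            cmp_res = compare_mobile_fractions(mfs[names[0]], mfs[names[1]],
                                               labels=(names[0], names[1]))
            report["frap"]["comparison"] = {
                "labels": list(cmp_res.labels), "t": cmp_res.t_stat,
                "p": cmp_res.p_value,
            }
    except Exception as exc:
        raise StageError("frap", str(exc)) from exc

    stage("report")
    report["elapsed_s"] = round(time.time() - t0, 2)
    with open(outdir / "report.json", "w") as fh:
        # elapsed time varies between reruns; keep it out of the file
        stable = {k: v for k, v in report.items() if k != "elapsed_s"}
        json.dump(stable, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("done in %.1f s", report["elapsed_s"])
    return report
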