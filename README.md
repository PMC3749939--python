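# promdyn

Quantitative analysis toolkit for promoter chromatin state and histone
dynamics in embryonic stem cells, built for studies of histone-variant
(e.g. H2A.Z acidic-patch) mutants. It packages, as tested reusable code,
the analysis stack such experiments need:

* **ChIP-seq enrichment calling** — reads extended to the mean fragment
  length (200 bp), allocated to 25-bp bins by midpoint, and tested per bin
  against a Poisson background, `P(X ≥ k; λ) < 10⁻⁹` with
  `λ = max(local input, genome-wide input mean) × N_IP/N_input`, plus a
  ≥5-fold-over-input filter; adjacent enriched bins merge into regions.
* **Promoter bivalency classification** — a mark flags a TSS when an
  enriched-region boundary falls within ±2 kb; promoters are *bivalent*
  (H3K4me3 ∧ H3K27me3), *active* (H3K4me3 only) or *unmarked*.
* **Expression stratification** — isoform RPKMs summed per TSS,
  pseudocounted log₂ fold changes, strict >1.5-fold differential sets,
  hypergeometric set overlaps, two-sample Kolmogorov–Smirnov comparisons of
  class-stratified fold-change distributions, Euclidean hierarchical
  clustering.
* **NanoString normalization** — log₂ counts normalized to the geometric
  mean of housekeeping genes (Gapdh, Tubb5, Cltc), gene row centering,
  inclusive ±2-fold calls, and a label-permutation Monte Carlo FDR for
  group comparisons of per-sample median expression.
* **FRAP mobile fractions** — traces normalized to the pre-bleach maximum;
  `MF = (I_sat − I_dip)/(1 − I_dip)` with `I_dip` the first post-bleach
  intensity and `I_sat` the end of the monitored recovery; optional
  single-exponential fit `I(t) = I_dip + A(1 − e^{−kt})`; unpaired t-tests
  between groups of cells.
* **Targeted quantification** — ChIP-qPCR
  `% Input = 2^(Cp(WCE) − Cp(IP)) × %WCE`, control-gene relative
  expression, and western-blot densitometry fold changes.

A first-class `synthetic` module generates every input with known ground
truth (bimodal promoter ChIP signal over a Poisson background,
class-shifted expression, housekeeping-anchored counts, exponential FRAP
recovery), so the whole pipeline is testable without any sequencing data.

## Worked example

Densitometry fold changes from transgene/H3 band ratios (wild type 0.439;
mutant replicates 0.255 and 0.219):

```bash
$ promdyn quant densfc --wt 0.439 --mut 0.255 --mut 0.219
R1: 1.72
R2: 2.00
average: 1.85
```

Per replicate the fold is WT ratio ÷ mutant ratio (0.439/0.255 = 1.72,
0.439/0.219 = 2.00); the headline average is the ratio of means,
0.439/mean(0.255, 0.219) = 1.85 — i.e. the wild-type transgene is on
average 1.85-fold more chromatin-associated than the mutant.

A full synthetic run (simulate → call → classify → integrate → report):

```bash
$ promdyn run --outdir demo --seed 42
{
  "differential_genes": 60,
  "overlaps": {
    "differential_vs_bivalent": {
      "n_bivalent": 60, "n_diff": 60, "overlap": 60,
      "p": 1.420352689770306e-52, "universe": 200
    }
  },
  "promoter_classes": {"active": 102, "bivalent": 60, "unmarked": 38}
}
```

All 60 truly bivalent promoters are recovered as bivalent, the
differential expression set coincides with them (hypergeometric
p ≈ 1.4 × 10⁻⁵², the desk-scale analogue of a genome-scale bivalent
overlap), and `demo/report.json` additionally carries the FRAP group
comparison (simulated mobile fractions 0.13 vs 0.20, n = 14 cells/group,
t-test p ≈ 2 × 10⁻⁴).

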