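"""Generator contracts: determinism, bounds, conservation, calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from promdyn.chip import bin_counts, extend_reads
from promdyn.synthetic import (
    CapacityError,
    FrapSimParams,
    SimulationParams,
    default_mark_folds,
    gen_chip_reads,
    gen_expression,
    gen_frap_curves,
    gen_genome,
    gen_nanostring,
)


class TestGenGenome:
    def test_bounds_spacing_and_determinism(self):
        g1 = gen_genome(1, 1_000_000, 50, (0.3, 0.5, 0.2), seed=7)
        g2 = gen_genome(1, 1_000_000, 50, (0.3, 0.5, 0.2), seed=7)
        pd.testing.assert_frame_equal(g1.genes, g2.genes)
        tss = g1.genes["tss"].to_numpy()
        assert len(g1.genes) == 50
        assert (tss >= 0).all() and (tss < 1_000_000).all()
        assert (np.diff(np.sort(tss)) >= 5_000).all()

    def test_degenerate_class_distribution(self):
        g = gen_genome(1, 500_000, 20, (1.0, 0.0, 0.0), seed=0)
        assert (g.genes["true_class"] == "bivalent").all()

    def test_capacity_error(self):
        with pytest.raises(CapacityError):
            gen_genome(1, 100_000, 50, (0.3, 0.5, 0.2), seed=0)

    def test_class_marginals_converge(self):
        """Empirical class frequencies match class_probs (chi-square)."""
        probs = (0.3, 0.5, 0.2)
        g = gen_genome(5, 10_000_000, 10_000, probs, seed=2)
        obs = g.genes["true_class"].value_counts()
        counts = [obs.get(c, 0) for c in ("bivalent", "active", "unmarked")]
        p = stats.chisquare(counts, f_exp=[p_ * 10_000 for p_ in probs]).pvalue
        assert p > 0.001


class TestGenChipReads:
    def test_read_count_conservation_and_determinism(self, small_genome):
        params = SimulationParams(
            total_reads=50_000,
            fold_by_class=default_mark_folds("H3K27me3", 8.0),
            seed=5,
        )
        ip1, in1 = gen_chip_reads(small_genome, params, "H3K27me3")
        ip2, _ = gen_chip_reads(small_genome, params, "H3K27me3")
        assert ip1.total == in1.total == 50_000
        for chrom in ip1.intervals:
            np.testing.assert_array_equal(ip1.intervals[chrom], ip2.intervals[chrom])

    def test_unknown_mark_rejected(self, small_genome):
        params = SimulationParams(total_reads=1000, seed=0)
        with pytest.raises(ValueError, match="unknown mark"):
            gen_chip_reads(small_genome, params, "H4K20me3")

    def test_null_configuration_matches_input(self, small_genome):
        """fold = 1 everywhere: IP and input differ only by sampling noise."""
        params = SimulationParams(total_reads=100_000, seed=9)
        ip, inp = gen_chip_reads(small_genome, params, "H2AZ")
        tss = small_genome.genes["tss"].iloc[0]
        chrom = small_genome.genes["chrom"].iloc[0]

        def window_count(rs):
            iv = rs.intervals[chrom]
            return int(((iv[:, 0] < tss + 1000) & (iv[:, 1] > tss - 1000)).sum())

        k_ip, k_in = window_count(ip), window_count(inp)
        p = stats.binomtest(k_ip, k_ip + k_in, 0.5).pvalue
        assert p > 0.001

    def test_window_fold_calibration(self, small_genome, enriched_readsets):
        """Mean IP/input density ratio over TSS+-200 approximates the fold."""
        ip, inp = enriched_readsets
        ti = bin_counts(extend_reads(ip, 200), 25)
        tn = bin_counts(extend_reads(inp, 200), 25)
        genes = small_genome.genes
        sel = genes["true_class"].isin(["bivalent", "active"])
        ratios = []
        for r in genes[sel].itertuples():
            b0, b1 = (r.tss - 200) // 25, (r.tss + 200) // 25
            ki = ti.counts[r.chrom][b0:b1].sum()
            kn = max(tn.counts[r.chrom][b0:b1].sum(), 1)
            ratios.append(ki / kn)
        assert abs(np.mean(ratios) - 20.0) / 20.0 < 0.25

    def test_full_depletion_removes_downstream_peak(self, small_genome):
        """depletion = 1: downstream/upstream peak-mass ratio < 0.1."""
        params = SimulationParams(
            total_reads=400_000,
            fold_by_class=default_mark_folds("H3K4me3", 20.0),
            plus_one_depletion=1.0,
            seed=4,
        )
        ip, _ = gen_chip_reads(small_genome, params, "H3K4me3")
        frag = extend_reads(ip, 200)
        up = down = 0
        genes = small_genome.genes
        for r in genes[genes["true_class"].isin(["bivalent", "active"])].itertuples():
            iv = frag.intervals[r.chrom]
            mid = (iv[:, 0] + iv[:, 1]) // 2
            sign = 1 if r.strand == "+" else -1
            rel = (mid - r.tss) * sign
            up += int(((rel >= -200) & (rel < 0)).sum())
            down += int(((rel >= 0) & (rel < 200)).sum())
        assert down / up < 0.1


class TestGenExpression:
    def test_zero_shift_zero_noise_identity(self, small_genome):
        tab = gen_expression(small_genome, {}, noise_sd_log2=0.0, seed=1)
        np.testing.assert_allclose(tab["rpkm_A"], tab["rpkm_B"])

    def test_shift_doubles_exactly_without_noise(self, small_genome):
        tab = gen_expression(
            small_genome, {"bivalent": 1.0}, noise_sd_log2=0.0, seed=1
        )
        cls = small_genome.classes()
        biv = tab[tab["gene_id"].map(cls) == "bivalent"]
        np.testing.assert_allclose(biv["rpkm_B"], 2.0 * biv["rpkm_A"])

    def test_mean_log2fc_recovers_shift(self):
        genome = gen_genome(1, 2_000_000, 200, (1.0, 0.0, 0.0), seed=3)
        tab = gen_expression(genome, {"bivalent": 1.0}, noise_sd_log2=0.1, seed=3)
        per_gene = tab.groupby("gene_id")[["rpkm_A", "rpkm_B"]].sum()
        fc = np.log2(per_gene["rpkm_B"] / per_gene["rpkm_A"])
        assert abs(fc.mean() - 1.0) < 0.05


class TestGenFrap:
    def test_noiseless_round_trip(self):
        from promdyn.frap import mobile_fraction

        params = FrapSimParams(
            mobile_fraction=0.2, rate_constant=0.05, n_frames=202,
            n_prebleach=2, noise_sd=0.0, frame_interval=1.0, seed=0,
        )  # k*T = 10
        curve = gen_frap_curves(params, 1)[0]
        assert abs(mobile_fraction(curve).mf - 0.2) < 1e-3

    def test_immobile_pool_stays_flat(self):
        params = FrapSimParams(
            mobile_fraction=0.0, noise_sd=0.0, n_frames=20, seed=0
        )
        curve = gen_frap_curves(params, 1)[0]
        np.testing.assert_allclose(curve.post_bleach, 0.5)

    def test_closed_form_endpoint_value(self):
        """I(end) = 0.5 + 0.13*0.5*(1 - e^-9) for MF=0.13, I_dip=0.5, kT=9."""
        params = FrapSimParams(
            mobile_fraction=0.13, rate_constant=0.01, bleach_depth=0.5,
            frame_interval=30.0, n_frames=32, n_prebleach=1, noise_sd=0.0, seed=0,
        )  # 31 post frames: last at t = 900 s
        curve = gen_frap_curves(params, 1)[0]
        expected = 0.5 + 0.13 * 0.5 * (1 - np.exp(-9.0))
        assert curve.intensities[-1] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.565, abs=1e-3)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            FrapSimParams(n_frames=3, n_prebleach=2)


class TestGenNanostring:
    def test_flat_matrix_centers_to_zero(self):
        from promdyn.nanostring import center_genes, normalize_housekeeping

        cm = gen_nanostring(10, 6, noise_sd_log2=0.0, seed=1)
        nm = center_genes(normalize_housekeeping(cm, pseudocount=0.0))
        np.testing.assert_allclose(nm.values.to_numpy(), 0.0, atol=1e-12)

    def test_sample_scale_invariance(self):
        # invariance is exact up to the integer rounding of simulated counts
        from promdyn.nanostring import normalize_housekeeping

        base = gen_nanostring(10, 4, noise_sd_log2=0.0, seed=2)
        scaled = gen_nanostring(
            10, 4, sample_scales=np.array([10.0, 1, 1, 1]),
            noise_sd_log2=0.0, seed=2,
        )
        a = normalize_housekeeping(base, 0.0).values
        b = normalize_housekeeping(scaled, 0.0).values
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=0.02)

    def test_effect_recovered(self):
        effect = np.array([1.0] * 10 + [0.0] * 10)
        cm = gen_nanostring(
            20, 20, gene_effects_log2={"t005": effect},
            noise_sd_log2=0.05, seed=4,
        )
        logs = np.log2(cm.counts.loc["t005"].to_numpy(dtype=float))
        diff = logs[:10].mean() - logs[10:].mean()
        assert abs(diff - 1.0) < 0.1

    def test_housekeeping_effects_pinned_to_zero(self):
        effect = np.ones(6)
        cm = gen_nanostring(
            8, 6, gene_effects_log2={"Gapdh": effect}, noise_sd_log2=0.0, seed=5
        )
        gapdh = cm.counts.loc["Gapdh"].to_numpy(dtype=float)
        assert np.allclose(gapdh, gapdh[0])
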