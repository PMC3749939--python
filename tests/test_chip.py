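"""Unit and property tests for read extension, binning and the Poisson caller."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from promdyn import chip
from promdyn.chip import (
    BinTrack,
    EnrichedRegionSet,
    EnrichmentParams,
    FragmentSet,
    PoissonEnrichmentModel,
    ReadSet,
    annotate_promoters,
    bin_counts,
    call_enriched,
    extend_reads,
    metagene_profile,
    min_enriched_count,
    ordered_density_matrix,
)

SIZES = {"chr1": 100_000}


def make_readset(rows, sizes=SIZES):
    """rows: (start, end, strand) tuples on chr1."""
    iv = np.array([[s, e] for s, e, _ in rows], dtype=np.int64)
    minus = np.array([st == "-" for _, _, st in rows])
    return ReadSet(dict(sizes), {"chr1": iv}, {"chr1": minus})


def make_track(counts, bin_width=25, sizes=None, label="t"):
    counts = np.asarray(counts, dtype=np.int64)
    sizes = sizes or {"chr1": len(counts) * bin_width}
    return BinTrack(bin_width, {"chr1": counts}, sizes, label=label)


@pytest.mark.parametrize(
    "read,expected",
    [
        ((1000, 1036, "+"), (1000, 1200)),  # plus: [s, s+L)
        ((964, 1000, "-"), (800, 1000)),  # minus: [e-L, e)
        ((114, 150, "-"), (0, 150)),  # minus near chrom start: clipped
    ],
)
def test_extend_reads_definition_and_clipping(read, expected):
    frags = extend_reads(make_readset([read]), 200)
    assert tuple(frags.intervals["chr1"][0]) == expected


def test_bin_counts_midpoint_assignment():
    """Fragment [1000, 1200) has midpoint 1100 -> bin 44 at 25 bp."""
    frags = FragmentSet(SIZES, {"chr1": np.array([[1000, 1200]])})
    track = bin_counts(frags, 25)
    assert track.counts["chr1"][44] == 1
    assert track.counts["chr1"].sum() == 1


def test_bin_counts_empty_and_stacked():
    empty = bin_counts(FragmentSet(SIZES, {"chr1": np.empty((0, 2), int)}), 25)
    assert empty.total == 0
    stacked = bin_counts(
        FragmentSet(SIZES, {"chr1": np.tile([[500, 520]], (10, 1))}), 25
    )
    assert stacked.counts["chr1"][20] == 10 and stacked.total == 10


@settings(max_examples=50, derandomize=True)
@given(
    starts=st.lists(st.integers(0, 90_000), min_size=0, max_size=60),
    width=st.sampled_from([1, 10, 25, 200]),
)
def test_bin_counts_conservation(starts, width):
    """Every fragment is counted exactly once, for any input."""
    iv = np.array([[s, s + 150] for s in sorted(starts)], int).reshape(-1, 2)
    frags = FragmentSet(SIZES, {"chr1": iv})
    assert bin_counts(frags, width).total == len(starts)


def test_min_enriched_count_matches_exact_tail_sum():
    """Independent oracle: P(X>=k; 1) = 1 - e^-1 sum_{j<k} 1/j!."""

    def upper_tail(k, lam=1.0):
        return 1.0 - math.exp(-lam) * sum(lam**j / math.factorial(j) for j in range(k))

    threshold = 1e-9
    k_oracle = next(k for k in range(50) if upper_tail(k) < threshold)
    assert k_oracle == 12
    assert upper_tail(12) < threshold < upper_tail(11)
    assert min_enriched_count(1.0, threshold) == 12


def test_caller_identical_tracks_yield_nothing():
    """Fold filter >= 5 is unsatisfiable when IP equals input."""
    counts = np.random.default_rng(0).poisson(5, size=10_000)
    track = make_track(counts)
    regions = call_enriched(track, make_track(counts.copy()), EnrichmentParams())
    assert len(regions) == 0


def test_caller_zero_input_total_errors():
    with pytest.raises(ValueError, match="zero total"):
        call_enriched(make_track([1, 2, 3]), make_track([0, 0, 0]))


def test_caller_pvalue_monotone_in_ip_count():
    """At fixed lambda the tail p is non-increasing as the IP count grows."""
    from scipy import stats

    ks = np.arange(0, 40)
    p = stats.poisson.sf(ks - 1, 3.0)
    assert (np.diff(p) <= 0).all()


def test_caller_detects_spiked_bins_and_merges_adjacent():
    counts = np.full(1000, 2)
    ip = counts.copy()
    ip[100:103] = 60  # three adjacent hot bins
    regions = call_enriched(make_track(ip), make_track(counts)).regions
    assert len(regions) == 1
    assert regions.loc[0, "start"] == 100 * 25 and regions.loc[0, "end"] == 103 * 25
    assert regions.loc[0, "fold"] >= 5


@pytest.mark.parametrize("threshold", [1e-2, 1e-3])
def test_caller_null_calibration(threshold):
    """On i.i.d. Poisson nulls the pre-fold enrichment rate <= 1.5x threshold."""
    from scipy import stats

    total_bins, hits = 0, 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        ip = rng.poisson(2.0, 50_000)
        inp = rng.poisson(2.0, 50_000)
        lam = np.maximum(inp, inp.mean()) * (ip.sum() / inp.sum())
        p = stats.poisson.sf(ip - 1, lam)
        hits += int((p < threshold).sum())
        total_bins += len(ip)
    assert hits / total_bins <= 1.5 * threshold


def test_enrichment_model_summary_reports_counts():
    counts = np.full(400, 2)
    ip = counts.copy()
    ip[50] = 80
    res = PoissonEnrichmentModel(make_track(ip), make_track(counts), mark="H3K4me3").fit()
    assert res.n_regions == 1
    text = res.summary()
    assert "H3K4me3" in text and "regions called:  1" in text


def regionset(intervals, mark=""):
    df = pd.DataFrame(
        [{"chrom": "chr1", "start": a, "end": b, "fold": 10.0, "minus_log10_p": 12.0}
         for a, b in intervals]
    )
    if not len(intervals):
        df = pd.DataFrame(columns=["chrom", "start", "end", "fold", "minus_log10_p"])
    return EnrichedRegionSet(df, EnrichmentParams(), mark=mark)


class TestAnnotatePromoters:
    def test_active_and_bivalent_classification(self, tiny_genes):
        k4 = regionset([(9_900, 10_300), (49_950, 50_100)])
        k27 = regionset([(49_900, 50_500)])
        table = annotate_promoters({"H3K4me3": k4, "H3K27me3": k27}, tiny_genes)
        by_id = table.set_index("gene_id")["chrom_class"]
        assert by_id["gA"] == "active"
        assert by_id["gB"] == "bivalent"
        assert by_id["gC"] == "unmarked"

    def test_boundary_inclusion_rule(self, tiny_genes):
        """A region [TSS+1990, TSS+2400] is flagged: its start is in-window."""
        k27 = regionset([(11_990, 12_400)])  # gA TSS = 10000
        table = annotate_promoters(
            {"H3K4me3": regionset([]), "H3K27me3": k27}, tiny_genes
        )
        assert table.set_index("gene_id").loc["gA", "H3K27me3"]
        # a region fully spanning the window without a boundary inside: not flagged
        spanning = regionset([(5_000, 15_000)])
        table2 = annotate_promoters(
            {"H3K4me3": regionset([]), "H3K27me3": spanning}, tiny_genes
        )
        assert not table2.set_index("gene_id").loc["gA", "H3K27me3"]

    def test_missing_required_mark_named(self, tiny_genes):
        with pytest.raises(KeyError, match="H3K27me3"):
            annotate_promoters({"H3K4me3": regionset([])}, tiny_genes)


class TestMetageneProfile:
    def promoters(self, strand):
        return pd.DataFrame(
            {"gene_id": ["g"], "chrom": ["chr1"], "tss": [50_000],
             "strand": [strand], "chrom_class": ["bivalent"]}
        )

    def test_plus_strand_single_fragment(self):
        frags = FragmentSet(SIZES, {"chr1": np.array([[50_050, 50_250]])})
        prof = metagene_profile(frags, self.promoters("+"), halfwidth=2000)
        covered = prof.offsets[prof.density > 0]
        assert covered.min() == 50 and covered.max() == 249
        assert prof.density.sum() == 200

    def test_minus_strand_fragment_is_reflected(self):
        frags = FragmentSet(SIZES, {"chr1": np.array([[50_050, 50_250]])})
        prof = metagene_profile(frags, self.promoters("-"), halfwidth=2000)
        covered = prof.offsets[prof.density > 0]
        assert covered.min() == -250 and covered.max() == -51
        assert prof.density.sum() == 200

    def test_strand_mirror_symmetry(self, small_genome, enriched_readsets):
        """Mirroring every gene strand reflects the profile exactly."""
        ip, _ = enriched_readsets
        frags = extend_reads(ip, 200)
        prom = small_genome.genes.rename(columns={"true_class": "chrom_class"})
        flipped = prom.copy()
        flipped["strand"] = np.where(prom["strand"] == "+", "-", "+")
        a = metagene_profile(frags, prom, 1000)
        b = metagene_profile(frags, flipped, 1000)
        np.testing.assert_allclose(a.density, b.density[::-1])

    def test_bimodal_signal_has_two_flanking_maxima(self, small_genome, enriched_readsets):
        """Midpoint density around enriched TSSs peaks near -100 and +100 bp."""
        ip, _ = enriched_readsets
        frags = extend_reads(ip, 200)
        prom = small_genome.genes.rename(columns={"true_class": "chrom_class"})
        prof = metagene_profile(
            frags, prom, 1000, class_filter="bivalent",
            statistic="midpoint", bin_width=25,
        )
        centers = prof.offsets + 12
        dens = prof.density
        up = centers[np.argmax(np.where(centers < 0, dens, -1.0))]
        down = centers[np.argmax(np.where(centers > 0, dens, -1.0))]
        assert -175 <= up <= -25 and 25 <= down <= 175
        # genuine local maxima: a dip at the TSS separates the two modes
        at_tss = dens[np.abs(centers) <= 25].mean()
        assert at_tss < dens.max() * 0.9

    def test_empty_class_errors(self):
        frags = FragmentSet(SIZES, {"chr1": np.array([[0, 200]])})
        with pytest.raises(ValueError, match="no TSS"):
            metagene_profile(frags, self.promoters("+"), 1000, class_filter="active")


class TestOrderedDensityMatrix:
    def promoters(self):
        return pd.DataFrame(
            {"gene_id": ["g1", "g2", "g3"], "chrom": ["chr1"] * 3,
             "tss": [10_000, 40_000, 70_000], "strand": ["+"] * 3}
        )

    def track_with_sums(self, sums, width=25, halfwidth=4000):
        counts = np.zeros(100_000 // width, dtype=np.int64)
        for tss, s in zip([10_000, 40_000, 70_000], sums):
            counts[tss // width] = s
        return make_track(counts, width)

    def test_rows_sorted_by_ranking_score(self):
        track = self.track_with_sums([10, 5, 20])
        mat = ordered_density_matrix({"H3K27me3": track}, self.promoters())
        assert mat.gene_order == ["g3", "g1", "g2"]

    def test_ties_break_by_gene_id(self):
        track = self.track_with_sums([7, 7, 7])
        mat = ordered_density_matrix({"H3K27me3": track}, self.promoters())
        assert mat.gene_order == ["g1", "g2", "g3"]

    def test_constant_offset_preserves_order(self):
        t1 = self.track_with_sums([10, 5, 20])
        t2 = make_track(t1.counts["chr1"] + 3, 25)
        m1 = ordered_density_matrix({"H3K27me3": t1}, self.promoters())
        m2 = ordered_density_matrix({"H3K27me3": t2}, self.promoters())
        assert m1.gene_order == m2.gene_order
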