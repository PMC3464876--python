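"""Hotspot classification, expression binning, occupancy and aggregation."""

import numpy as np
import pandas as pd
import pytest

import tachseq as tq
from tachseq.core import GenomicInterval, GeneModel, Hotspot, HotspotSet


def hs(start, end, contig="c1", density=1.0):
    return Hotspot(GenomicInterval(contig, start, end), 3, density, 9.0)


@pytest.fixture
def genes():
    return [
        GeneModel("g1", "c1", "+", 10_000, 20_000, exons=[(10_000, 10_500), (19_000, 20_000)]),
        GeneModel("g2", "c1", "-", 50_000, 40_000, exons=[(40_000, 41_000), (49_500, 50_000)]),
    ]


def brute_classify(mid, genes, promoter_len=2000, downstream_len=2000):
    """Independent midpoint classifier enumerating every category."""
    cats = set()
    for g in genes:
        lo, hi = min(g.tss, g.tts), max(g.tss, g.tts)
        if g.strand == "+":
            if g.tss - promoter_len <= mid < g.tss:
                cats.add("promoter")
            if g.tts < mid <= g.tts + downstream_len:
                cats.add("downstream")
        else:
            if g.tss < mid <= g.tss + promoter_len:
                cats.add("promoter")
            if g.tts - downstream_len <= mid < g.tts:
                cats.add("downstream")
        if lo <= mid <= hi:
            if any(s <= mid < e for s, e in g.exons):
                cats.add("exon")
            else:
                cats.add("intron")
    for cat in ("promoter", "exon", "intron", "downstream"):
        if cat in cats:
            return cat
    return "distal"


class TestClassifyHotspot:
    def test_promoter_upstream_plus(self, genes):
        assert tq.classify_hotspot(hs(8950, 9050), genes) == "promoter"

    def test_promoter_upstream_minus(self, genes):
        # upstream of g2's TSS (50,000, minus strand) means positions > TSS
        assert tq.classify_hotspot(hs(50_950, 51_050), genes) == "promoter"

    def test_distal_far_from_genes(self, genes):
        assert tq.classify_hotspot(hs(200_000, 200_100), genes) == "distal"

    def test_exon_beats_intron_across_genes(self):
        gs = [
            GeneModel("a", "c1", "+", 1000, 3000, exons=[(1900, 2100)]),
            GeneModel("b", "c1", "+", 1500, 4000, exons=[(3500, 4000)]),
        ]
        # midpoint 2000 is exon of a, intron of b -> exon wins
        assert tq.classify_hotspot(hs(1950, 2050), gs) == "exon"

    def test_matches_brute_force_over_positions(self, genes, rng):
        for mid in rng.integers(0, 60_000, size=300):
            mid = int(mid)
            got = tq.classify_hotspot(hs(mid - 10, mid + 10), genes)
            assert got == brute_classify(mid, genes), mid


class TestFeatureDistribution:
    def test_empty_all_zero(self, genes):
        dist = tq.feature_distribution(HotspotSet([]), genes)
        assert dist.total == 0 and set(dist.counts.values()) == {0}

    def test_all_promoter(self, genes):
        spots = HotspotSet([hs(9000, 9100), hs(9500, 9600)])
        dist = tq.feature_distribution(spots, genes)
        assert dist.fractions["promoter"] == 1.0

    def test_counts_sum_and_match_per_hotspot(self, genes, rng):
        spots = HotspotSet([hs(int(p), int(p) + 20) for p in rng.choice(
            np.arange(0, 60_000, 100), size=30, replace=False)])
        dist = tq.feature_distribution(spots, genes)
        assert dist.total == len(spots)
        want = {}
        for h in spots:
            c = brute_classify(h.interval.midpoint, genes)
            want[c] = want.get(c, 0) + 1
        assert {k: v for k, v in dist.counts.items() if v} == want


class TestBinExpression:
    def _table(self, values):
        return pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(len(values))],
             "transcripts_per_cell": values}
        )

    def test_zero_is_nd(self):
        b = tq.bin_expression(self._table([0.0, 2.0]))
        assert b.assignment["g0"] == "nd"

    def test_sixteen_transcripts_in_boundary_bin(self):
        b = tq.bin_expression(self._table([16.0, 17.0]))
        assert b.assignment["g0"] == "(3, 4]"  # log2(16) = 4, right-closed
        assert b.assignment["g1"] == "> 4"  # "more than 16 transcripts" class

    def test_eight_bins_plus_nd(self):
        vals = [0.0] + [2.0**k for k in range(-3, 6)]
        b = tq.bin_expression(self._table(vals))
        assert len(b.labels_ordered) == 9  # nd + 8
        assert b.labels_ordered[0] == "nd"

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            tq.bin_expression(self._table([-1.0]))

    def test_deciles_match_bruteforce_ranking(self, rng):
        vals = rng.lognormal(0, 2, size=20).round(3).tolist()
        vals[3] = 0.0
        table = self._table(vals)
        b = tq.bin_expression(table, scheme="decile")
        order = sorted(
            table["gene_id"], key=lambda g: (-table.set_index("gene_id").loc[g, "transcripts_per_cell"], g)
        )
        want = {}
        for i, gid in enumerate(order):
            want[gid] = f"d{i // 2 + 1:02d}"  # 20 genes -> 2 per decile
        assert dict(b.assignment) == want


class TestTssOccupancy:
    def _binning(self, mapping):
        from tachseq.annotate import ExpressionBinning

        return ExpressionBinning(pd.Series(mapping), ["nd", "low", "high"], "custom")

    def test_no_hotspots_zero_everywhere(self, genes):
        binning = self._binning({"g1": "low", "g2": "high"})
        out = tq.tss_occupancy(genes, [HotspotSet([])], binning)
        occupied = out.dropna(subset=["occupied_fraction"])
        assert (occupied["occupied_fraction"] == 0.0).all()

    def test_multi_tss_gene_scored_on_any(self):
        gs = [
            GeneModel("g1", "c1", "+", 1000, 5000),
            GeneModel("g1", "c1", "+", 3000, 5000),  # alternative TSS
        ]
        binning = self._binning({"g1": "high"})
        spots = HotspotSet([hs(2900, 3100)])  # covers only the second TSS
        out = tq.tss_occupancy(gs, [spots], binning)
        row = out[out["bin"] == "high"].iloc[0]
        assert row["occupied_fraction"] == 1.0

    def test_point_in_interval_rule(self):
        gs = [GeneModel("g1", "c1", "+", 1000, 5000)]
        binning = self._binning({"g1": "high"})
        inside = HotspotSet([hs(950, 1001)])  # 1000 in [950, 1001)
        boundary = HotspotSet([hs(900, 1000)])  # 1000 not in [900, 1000)
        assert tq.tss_occupancy(gs, [inside], binning).iloc[2]["occupied_fraction"] == 1.0
        assert tq.tss_occupancy(gs, [boundary], binning).iloc[2]["occupied_fraction"] == 0.0


class TestAggregateDensity:
    def test_single_tag_at_anchor_in_center_bin(self, make_lib):
        lib = make_lib("c1", cuts_plus=[5000])
        anchors = [GenomicInterval("c1", 4950, 5050)]  # midpoint 5000
        prof = tq.aggregate_density(anchors, lib, flank=500, bin_width=50)
        idx = np.flatnonzero(prof.density)
        assert list(prof.bin_starts[idx]) == [0]

    def test_mirror_tags_symmetric_profile(self, make_lib):
        offs = [10, 60, 110, 450]
        cuts = [5000 + o for o in offs] + [5000 - 1 - o for o in offs]
        lib = make_lib("c1", cuts_plus=cuts)
        anchors = [GenomicInterval("c1", 4950, 5050)]
        prof = tq.aggregate_density(anchors, lib, flank=500, bin_width=50)
        assert np.allclose(prof.density, prof.density[::-1])

    def test_anchor_order_invariant(self, make_lib, rng):
        cuts = rng.integers(0, 50_000, size=2000).tolist()
        lib = make_lib("c1", cuts_plus=cuts)
        anchors = [GenomicInterval("c1", int(p), int(p) + 100)
                   for p in rng.integers(2000, 40_000, size=6)]
        a = tq.aggregate_density(anchors, lib, flank=1000, bin_width=100)
        b = tq.aggregate_density(anchors[::-1], lib, flank=1000, bin_width=100)
        assert np.allclose(a.density, b.density)

    def test_minus_strand_tss_flipped(self, make_lib):
        # one cut 100 bp downstream of a minus-strand TSS must appear at a
        # positive offset
        g = GeneModel("g1", "c1", "-", 5000, 1000)
        lib = make_lib("c1", cuts_plus=[4900])
        prof = tq.aggregate_density([g], lib, flank=500, bin_width=50,
                                    anchor_mode="tss-strand-oriented")
        idx = np.flatnonzero(prof.density)
        assert (prof.bin_starts[idx] >= 0).all()

    def test_no_anchors_rejected(self, make_lib):
        lib = make_lib("c1", cuts_plus=[100])
        with pytest.raises(ValueError, match="anchors"):
            tq.aggregate_density([], lib)


class TestHeatmapMatrix:
    def test_column_means_equal_aggregate(self, make_lib, rng):
        cuts = rng.integers(0, 50_000, size=3000).tolist()
        lib = make_lib("c1", cuts_plus=cuts)
        anchors = [GenomicInterval("c1", int(p), int(p) + 100)
                   for p in rng.integers(2000, 40_000, size=7)]
        mat = tq.density_heatmap_matrix(anchors, lib, flank=1000, bin_width=100,
                                        anchor_mode="midpoint")
        prof = tq.aggregate_density(anchors, lib, flank=1000, bin_width=100,
                                    anchor_mode="midpoint")
        assert np.allclose(mat.mean(axis=0), prof.density)

    def test_rows_conserve_tag_counts(self, make_lib, rng):
        cuts = rng.integers(0, 20_000, size=500).tolist()
        lib = make_lib("c1", cuts_plus=cuts)
        anchors = [GenomicInterval("c1", 5000, 5100), GenomicInterval("c1", 9000, 9100)]
        flank, bw = 1000, 50
        mat = tq.density_heatmap_matrix(anchors, lib, flank=flank, bin_width=bw,
                                        anchor_mode="midpoint")
        arr = np.asarray(cuts)
        for row, a in zip(mat, anchors):
            mid = a.midpoint
            want = ((arr >= mid - flank) & (arr < mid + flank)).sum()
            assert row.sum() * bw * (lib.size / 1e6) == pytest.approx(want)

    def test_empty_library_zero_matrix(self, make_lib):
        lib = make_lib("c1", cuts_plus=[100])  # library must be non-empty
        anchors = [GenomicInterval("c2", 5000, 5100)]  # but anchors elsewhere
        mat = tq.density_heatmap_matrix(anchors, lib, flank=500, bin_width=50,
                                        anchor_mode="midpoint")
        assert np.count_nonzero(mat) == 0


class TestOccupancyMonotonicity:
    def test_coupled_simulation_direction(self):
        """Promoter-coupled landscape: top expression bin occupancy exceeds
        the "nd" bin, and mean TSS density of top-decile genes exceeds that
        of undetected genes."""
        genome, _ = tq.generate_genome(contig_len=4_000_000, gc_levels=(0.5,), seed=5)
        land, genes, expr = tq.generate_landscape(genome, n_regions=120, seed=5)
        lib = tq.simulate_digestion(genome, land, tq.preset_bias("uniform"),
                                    300_000, seed=5)
        spots = tq.call_hotspots(lib, genome.lengths, seed=5)
        genes = tq.attach_expression(genes, expr)
        binning = tq.bin_expression(expr, scheme="log2")
        occ = tq.tss_occupancy(genes, [spots], binning).set_index("bin")
        top = occ.dropna().iloc[-1]["occupied_fraction"]
        nd = occ.loc["nd", "occupied_fraction"]
        assert top > nd
        dec = tq.bin_expression(expr, scheme="decile")
        top_genes = [g for g in genes if dec.assignment[g.gene_id] == "d01"]
        nd_genes = [g for g in genes if (g.transcripts_per_cell or 0) == 0]
        p_top = tq.aggregate_density(top_genes, lib, flank=1000, bin_width=100,
                                     anchor_mode="tss-strand-oriented")
        p_nd = tq.aggregate_density(nd_genes, lib, flank=1000, bin_width=100,
                                    anchor_mode="tss-strand-oriented")
        assert p_top.density.mean() > p_nd.density.mean()
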