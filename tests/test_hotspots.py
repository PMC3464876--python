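"""Hotspot scan statistic, FDR-0 threshold, calling and mode filter.

The key check is oracle equivalence: an independent pure-Python
recomputation of the scan, merge, trim and mode-filter pipeline must agree
with the vectorised implementation on small random instances.
"""

import math

import numpy as np
import pytest

import tachseq as tq
from tachseq.hotspots import HotspotParams, apply_mode_threshold


from oracles import brute_call, brute_scan


class TestScanZscores:
    def test_formula_example(self, make_lib):
        """n=100 of N=200 tags in a 250 bp window of an unclipped 200 kb
        background gives z = (100 - 0.25)/sqrt(0.25 * 0.99875) ~ 199.6."""
        # window [150000, 150250) centred in a 300 kb contig: background
        # [50125, 250125) lies fully inside, so p = 250/200000 exactly
        cuts = [150_000 + i % 250 for i in range(100)]
        cuts += [150_500 + i * 390 for i in range(100)]  # rest of background
        lib = make_lib("chr1", cuts_plus=cuts)
        df = tq.scan_zscores(lib, {"chr1": 300_000}, 250, 200_000, 250)
        row = df[df["start"] == 150_000].iloc[0]
        assert row["n"] == 100 and row["N"] == 200
        p = 250 / 200_000
        assert row["z"] == pytest.approx(
            (100 - 200 * p) / math.sqrt(200 * p * (1 - p))
        )
        assert row["z"] == pytest.approx(199.6, abs=0.1)

    def test_clipped_background_adjusts_p(self, make_lib):
        """Near a contig edge the background is clipped and p recomputed."""
        cuts = [5000 + i % 250 for i in range(20)] + [30_000 + 97 * i for i in range(50)]
        lib = make_lib("chr1", cuts_plus=cuts)
        df = tq.scan_zscores(lib, {"chr1": 200_000}, 250, 200_000, 250)
        row = df[df["start"] == 5000].iloc[0]
        # effective background: [0, 5125 + 100000)
        eff = 5125 + 100_000
        p = 250 / eff
        n, N = row["n"], row["N"]
        assert row["z"] == pytest.approx((n - N * p) / math.sqrt(N * p * (1 - p)))

    def test_empty_background_windows_skipped(self, make_lib):
        lib = make_lib("chr1", cuts_plus=[100])
        df = tq.scan_zscores(lib, {"chr1": 1_000_000}, 250, 2000, 250)
        # windows more than 1 kb from the single tag have N = 0
        assert df["start"].max() <= 1100
        assert (df["N"] > 0).all()

    def test_empty_library_rejected(self):
        lib = tq.TagLibrary.from_arrays([], [], [], [])
        with pytest.raises(ValueError, match="no tags"):
            tq.scan_zscores(lib, {"chr1": 10_000})

    def test_matches_brute_force(self, rng, make_lib):
        for trial in range(10):
            length = int(rng.integers(1000, 10_000))
            n_tags = int(rng.integers(1, 300))
            cuts = rng.integers(0, length, size=n_tags)
            lib = make_lib("chr1", cuts_plus=cuts.tolist())
            df = tq.scan_zscores(lib, {"chr1": length}, 250, 2000, 50)
            expect = brute_scan(cuts.tolist(), length, 250, 2000, 50)
            assert len(df) == len(expect)
            for (_, row), (s, n, N, z) in zip(df.iterrows(), expect):
                assert row["start"] == s and row["n"] == n and row["N"] == N
                assert row["z"] == pytest.approx(z)


class TestFdr0Threshold:
    def test_deterministic(self):
        a = tq.estimate_fdr0_threshold(5000, {"chr1": 1_000_000}, seed=3)
        b = tq.estimate_fdr0_threshold(5000, {"chr1": 1_000_000}, seed=3)
        assert a == b

    def test_exceeds_every_random_z(self):
        lengths = {"chr1": 500_000}
        params = HotspotParams(n_randomizations=5)
        thr = tq.estimate_fdr0_threshold(2000, lengths, params, seed=7)
        # re-draw the same randomizations and verify strict dominance
        from tachseq.hotspots import _max_scan_z, _uniform_cut_map
        rng = np.random.default_rng(7)
        for _ in range(5):
            cm = _uniform_cut_map(rng, 2000, lengths)
            assert _max_scan_z(cm, lengths, params) < thr

    def test_relaxes_toward_gaussian_regime_with_depth(self):
        """Monte-Carlo over three library sizes: sparse libraries produce
        inflated thresholds (the discrete Poisson tail of near-empty windows
        makes single-tag excursions many s.d. large), which relax toward the
        Gaussian max-of-windows level as depth grows."""
        lengths = {"chr1": 200_000}
        params = HotspotParams(n_randomizations=2)
        means = []
        for size in (50, 5000, 50_000):
            vals = [
                tq.estimate_fdr0_threshold(size, lengths, params, seed=s)
                for s in range(10)
            ]
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]
        assert 3.0 < means[2] < 8.0


class TestCallHotspots:
    def test_planted_spike_found(self, rng, make_lib):
        bg = rng.integers(0, 1_000_000, size=1000).tolist()
        spike = rng.integers(40_000, 40_300, size=500).tolist()
        lib = make_lib("chr1", cuts_plus=bg + spike)
        hs = tq.call_hotspots(lib, {"chr1": 1_000_000}, seed=1)
        assert len(hs) == 1
        h = hs[0]
        assert h.interval.start <= 40_000 and h.interval.end >= 40_290
        assert h.tag_count >= 500

    def test_uniform_library_no_hotspots(self):
        """FDR-0 construction keeps uniform libraries hotspot-free (mostly)."""
        lengths = {"chr1": 2_000_000}
        rng = np.random.default_rng(1)
        counts = []
        for rep in range(3):
            cuts = rng.integers(0, 2_000_000, size=20_000)
            lib = tq.TagLibrary.from_arrays(
                ["chr1"] * len(cuts), cuts, cuts + 36, ["+"] * len(cuts)
            )
            try:
                hs = tq.call_hotspots(lib, lengths, seed=100 + rep)
                counts.append(len(hs))
            except ValueError:
                counts.append(0)
        assert np.mean(counts) <= 0.34  # at most 1 stray hotspot in 3 libraries

    def test_doubled_tags_same_intervals(self, rng, make_lib):
        """Duplicating every record scales every window z by exactly sqrt(2)
        (n and N double, p is unchanged), so with the threshold scaled the
        same way the passing windows — hence intervals and densities — are
        identical while tag counts double."""
        bg = rng.integers(0, 500_000, size=800).tolist()
        spike = rng.integers(100_000, 100_250, size=300).tolist()
        lib = make_lib("chr1", cuts_plus=bg + spike)
        doubled = make_lib("chr1", cuts_plus=(bg + spike) * 2)
        thr = 6.0
        a = tq.call_hotspots(lib, {"chr1": 500_000}, z_threshold=thr, seed=1)
        b = tq.call_hotspots(
            doubled, {"chr1": 500_000}, z_threshold=thr * math.sqrt(2), seed=1
        )
        assert a.intervals == b.intervals
        for ha, hb in zip(a, b):
            assert hb.tag_count == 2 * ha.tag_count
            assert hb.density == pytest.approx(ha.density)

    def test_mito_excluded_before_calling(self, rng):
        cuts = rng.integers(0, 16_000, size=2000)
        frame_contig = ["chrM"] * 2000 + ["chr1"] * 100
        starts = cuts.tolist() + rng.integers(0, 100_000, size=100).tolist()
        lib = tq.TagLibrary.from_arrays(
            frame_contig, starts, [s + 36 for s in starts], ["+"] * 2100
        )
        hs = tq.call_hotspots(lib, {"chr1": 100_000, "chrM": 16_000}, z_threshold=5.0, seed=1)
        assert all(h.interval.contig != "chrM" for h in hs)
        assert hs.params["library_size"] == 100

    def test_oracle_equivalence_random_instances(self, rng, make_lib):
        """Called intervals, counts, densities and z equal brute force."""
        params = HotspotParams(small_window=250, background_window=2000, step=50)
        for trial in range(15):
            length = int(rng.integers(2000, 10_000))
            n_tags = int(rng.integers(10, 500))
            # mix of background and a clump to exercise merging
            cuts = rng.integers(0, length, size=n_tags).tolist()
            clump_at = int(rng.integers(0, max(1, length - 300)))
            cuts += rng.integers(clump_at, clump_at + 100, size=60).tolist()
            lib = make_lib("chr1", cuts_plus=cuts)
            thr = float(rng.uniform(3, 8))
            got = tq.call_hotspots(lib, {"chr1": length}, params, z_threshold=thr, seed=0)
            want = brute_call(cuts, length, 250, 2000, 50, thr, 250, len(cuts))
            assert len(got) == len(want)
            for h, w in zip(got, want):
                assert (h.interval.start, h.interval.end) == (w["start"], w["end"])
                assert h.tag_count == w["count"]
                assert h.density == pytest.approx(w["density"])
                assert h.z_score == pytest.approx(w["z"])


class TestModeThreshold:
    def _mk(self, densities):
        return [
            tq.Hotspot(tq.GenomicInterval("c", 1000 * i + 1, 1000 * i + 101), 10, d, 9.9)
            for i, d in enumerate(densities)
        ]

    def test_all_equal_nothing_removed(self):
        kept, cutoff = apply_mode_threshold(self._mk([5.0] * 6))
        assert len(kept) == 6

    def test_bimodal_removes_low_mode(self):
        kept, cutoff = apply_mode_threshold(self._mk([1, 1, 1, 10, 10, 10, 10]))
        assert sorted(h.density for h in kept) == [10, 10, 10, 10]
        assert cutoff == pytest.approx(10.0)

    def test_single_hotspot_unchanged(self):
        hs = self._mk([3.0])
        kept, _ = apply_mode_threshold(hs)
        assert kept == hs

    def test_output_subset_identical_intervals(self, rng):
        hs = self._mk(rng.lognormal(2, 1, size=40).tolist())
        kept, _ = apply_mode_threshold(hs)
        assert set(id(h) for h in kept) <= set(id(h) for h in hs)


class TestMitoFraction:
    def test_cases(self, make_lib):
        lib = make_lib("chr1", cuts_plus=range(100, 150))
        assert tq.mito_fraction(lib) == 0.0
        contigs = ["chrM"] * 5 + ["chr1"] * 45
        starts = list(range(50))
        lib2 = tq.TagLibrary.from_arrays(contigs, starts, [s + 36 for s in starts], ["+"] * 50)
        assert tq.mito_fraction(lib2) == pytest.approx(0.1)
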