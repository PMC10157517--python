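"""Signed border offsets, metaplot profiles, feature overlap statistics."""

import numpy as np
import pandas as pd
import pytest

from methfidelity import (assign_border_offsets, border_enrichment_profile,
                          feature_distribution, nucleosome_occupancy_profile,
                          overlap_enrichment, signed_border_offset)

from conftest import intervals_df


def sites(positions, chrom="chr1"):
    return pd.DataFrame({"chrom": chrom, "pos": list(positions), "strand": "+"})


class TestSignedOffset:
    @pytest.mark.parametrize("pos,expected", [
        (1050, 50),    # inside, nearest left border
        (950, -50),    # outside, left border
        (1190, 9),     # inside, nearest right border at end-1 = 1199
        (1000, 0),     # on the left border counts as inside
        (1199, 0),     # on the right border (end - 1)
        (1200, -1),    # at end: outside by half-open convention
    ])
    def test_single_island_offsets(self, pos, expected):
        assert signed_border_offset(pos, 1000, 1200) == expected

    def test_window_cutoff_returns_none(self):
        assert signed_border_offset(100, 5000, 6000, window=1500) is None
        assert signed_border_offset(3500, 5000, 6000, window=1500) == -1500

    def test_matches_exhaustive_pairwise_search(self):
        """Vectorized nearest-border assignment equals a brute-force scan
        over every (site, island, border) with the same tie-break key."""
        rng = np.random.default_rng(31)
        for _ in range(100):
            n_cgi = int(rng.integers(1, 20))
            starts = np.sort(rng.choice(20_000, n_cgi, replace=False))
            lengths = rng.integers(50, 2000, n_cgi)
            cgis = intervals_df([("chr1", int(s), int(s + l))
                                 for s, l in zip(starts, lengths)])
            pos = rng.integers(0, 22_000, int(rng.integers(1, 60)))
            window = int(rng.choice([500, 1500]))
            got = assign_border_offsets(sites(pos), cgis, window=window)
            for p, o in zip(pos, got):
                best = None
                for s, e in zip(cgis.start, cgis.end):
                    for side, b in enumerate((s, e - 1)):
                        d = abs(int(p) - b)
                        key = (d, b, side, s, e)
                        if best is None or key < best[0]:
                            off = d if s <= p < e else -d
                            best = (key, off)
                want = best[1] if best[0][0] <= window else None
                if want is None:
                    assert np.isnan(o)
                else:
                    assert o == want


class TestEnrichmentProfile:
    CGIS = intervals_df([("chr1", 10_000 * k + 3000, 10_000 * k + 6000)
                         for k in range(10)])

    def _uniform_bg(self, rng, n):
        return sites(rng.integers(0, 100_000, n))

    def test_uniform_subsample_is_flat(self):
        rng = np.random.default_rng(2)
        bg = self._uniform_bg(rng, 30_000)
        fg = bg.sample(frac=0.7, random_state=5)
        prof = border_enrichment_profile(fg, bg, self.CGIS,
                                         restrict_to_fg_cgis=False)
        assert len(prof.values) == 60
        vals = prof.values[~np.isnan(prof.values)]
        assert np.all(np.abs(vals - 1.0) < 0.35)  # binomial noise only

    def test_point_mass_foreground_lands_in_one_bin(self):
        """All fg at offset +25 -> the [0,50) bin carries the whole fg mass
        and its fold is 1 / (bg share of that bin), by direct counting."""
        bg_pos = [3000 + 50 * i for i in range(10)]  # offsets 0,50,..,450
        fg = sites([3025])
        bg = sites(bg_pos + [3025])
        prof = border_enrichment_profile(fg, bg, self.CGIS.iloc[:1])
        bin_idx = (0 + 1500) // 50  # offset-0 bin
        n_bg_bin = prof.n_bg[bin_idx]
        assert prof.n_fg.sum() == 1 and prof.n_fg[bin_idx] == 1
        expected_fold = 1.0 / (n_bg_bin / prof.n_bg.sum())
        assert prof.values[bin_idx] == pytest.approx(expected_fold)

    def test_window_and_bin_width_set_bin_count(self):
        rng = np.random.default_rng(3)
        bg = self._uniform_bg(rng, 5000)
        prof = border_enrichment_profile(bg.iloc[:100], bg, self.CGIS,
                                         window=1500, bin_width=50,
                                         restrict_to_fg_cgis=False)
        assert len(prof.values) == 2 * 1500 // 50 == 60
        assert prof.bin_edges[0] == -1500 and prof.bin_edges[-1] == 1500

    def test_mass_conservation(self):
        rng = np.random.default_rng(4)
        bg = self._uniform_bg(rng, 8000)
        fg = bg.sample(frac=0.25, random_state=1)
        prof = border_enrichment_profile(fg, bg, self.CGIS,
                                         restrict_to_fg_cgis=False)
        offs = assign_border_offsets(fg, self.CGIS, 1500)
        assert prof.n_fg.sum() == (~np.isnan(offs)).sum()
        offs_bg = assign_border_offsets(bg, self.CGIS, 1500)
        assert prof.n_bg.sum() == (~np.isnan(offs_bg)).sum()

    def test_symmetric_sites_give_symmetric_profile(self):
        cgi = intervals_df([("chr1", 50_000, 53_000)])
        # mid-bin offsets so each value mirrors into the reflected bin
        offsets = np.array([-925, -525, -125, 125, 525, 925])
        pos = 50_000 + offsets  # symmetric about the left border
        bg = sites(np.concatenate([pos, 50_000 + np.arange(-1500, 1500, 10)]))
        prof = border_enrichment_profile(sites(pos), bg, cgi)
        n = prof.n_fg
        assert np.array_equal(n, n[::-1])

    def test_foreground_must_be_subset(self):
        bg = sites([1, 2, 3])
        with pytest.raises(ValueError, match="subset"):
            border_enrichment_profile(sites([99]), bg, self.CGIS,
                                      restrict_to_fg_cgis=False)
        with pytest.raises(ValueError, match="non-empty"):
            border_enrichment_profile(sites([]), bg, self.CGIS)


class TestOccupancyProfile:
    def test_fragment_midpoint_offset(self):
        cgi = intervals_df([("chr1", 1000, 1200)])
        frags = pd.DataFrame({"chrom": ["chr1"], "start": [980], "end": [1120]})
        prof = nucleosome_occupancy_profile(frags, cgi)
        bin_idx = (50 + 1500) // 50  # midpoint 1050 -> offset +50
        assert prof.n_fg[bin_idx] == 1

    def test_uniform_midpoints_flat_at_one(self):
        rng = np.random.default_rng(6)
        cgi = intervals_df([("chr1", 10_000 * k + 3000, 10_000 * k + 6000)
                            for k in range(10)])
        mids = rng.integers(0, 100_000, 60_000)
        frags = pd.DataFrame({"chrom": "chr1", "start": mids - 75,
                              "end": mids + 75})
        prof = nucleosome_occupancy_profile(frags, cgi)
        assert prof.values.mean() == pytest.approx(1.0)
        assert np.all(np.abs(prof.values - 1.0) < 0.30)

    def test_border_point_mass_value_equals_bin_count(self):
        cgi = intervals_df([("chr1", 1000, 4000)])
        frags = pd.DataFrame({"chrom": ["chr1"] * 50, "start": 1000 - 75,
                              "end": 1000 + 75})  # all midpoints at offset 0
        prof = nucleosome_occupancy_profile(frags, cgi)
        bin_idx = 1500 // 50
        assert prof.values[bin_idx] == pytest.approx(len(prof.values))
        assert prof.values.sum() == pytest.approx(len(prof.values))

    def test_no_midpoint_in_window_is_an_error(self):
        cgi = intervals_df([("chr1", 100_000, 103_000)])
        frags = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [150]})
        with pytest.raises(ValueError, match="window"):
            nucleosome_occupancy_profile(frags, cgi)


class TestFeatureDistribution:
    GENES = intervals_df([("chr1", 100, 500, "g1"), ("chr1", 900, 1200, "g2")])

    def test_all_sites_inside_one_interval(self):
        out = feature_distribution(sites([150, 200, 499]),
                                   {"gene_body": self.GENES})
        assert out.set_index("feature").loc["gene_body", "fraction"] == 1.0

    def test_half_open_end_coordinate_not_overlapping(self):
        out = feature_distribution(sites([500]), {"gene_body": self.GENES})
        assert out.set_index("feature").loc["gene_body", "n_sites"] == 0

    def test_counting_and_partition_remainder(self):
        out = feature_distribution(sites([150, 950, 700]),
                                   {"gene_body": self.GENES})
        assert out.set_index("feature").loc["gene_body", "fraction"] \
            == pytest.approx(2 / 3)
        part = feature_distribution(
            sites([150, 950, 700]),
            {"gene_body": self.GENES,
             "promoter": intervals_df([("chr1", 50, 160)])},
            partition_order=["promoter", "gene_body"])
        by = part.set_index("feature")
        # site 150 assigned to promoter first, 950 to gene_body, 700 unassigned
        assert by.loc["promoter", "n_sites"] == 1
        assert by.loc["gene_body", "n_sites"] == 1
        assert by.loc["unassigned", "n_sites"] == 1

    def test_empty_sites_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            feature_distribution(sites([]), {"gene_body": self.GENES})


class TestOverlapEnrichment:
    IVS = intervals_df([("chr1", 0, 100)])

    def test_fold_two_when_fg_all_inside_bg_half(self):
        bg = sites([10, 20, 200, 300])
        fg = sites([10, 20])
        fold, p = overlap_enrichment(fg, self.IVS, bg)
        assert fold == pytest.approx(2.0)
        assert 0.0 < p <= 1.0

    def test_fg_equal_bg_fold_one(self):
        bg = sites([10, 200])
        fold, p = overlap_enrichment(bg, self.IVS, bg)
        assert fold == 1.0 and p == pytest.approx(1.0)

    def test_zero_background_overlap_undefined(self):
        bg = sites([200, 300])
        with pytest.raises(ValueError, match="undefined"):
            overlap_enrichment(sites([200]), self.IVS, bg)

    def test_null_subsamples_give_unit_fold_and_calibrated_p(self):
        """fg drawn at random from bg: fold ~ 1 and p rarely small."""
        rng = np.random.default_rng(12)
        bg = sites(rng.integers(0, 1000, 400))
        ivs = intervals_df([("chr1", 0, 500)])
        folds, small_p = [], 0
        for _ in range(200):
            fg = bg.sample(n=100, random_state=rng.integers(2**31))
            fold, p = overlap_enrichment(fg, ivs, bg)
            folds.append(fold)
            small_p += p < 0.05
        assert np.mean(folds) == pytest.approx(1.0, abs=0.05)
        assert small_p / 200 <= 0.08  # exact test is conservative
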