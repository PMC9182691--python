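"""Feature computations: GC, positions, profiles, multiplicity, inter-site."""
from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import site, utr
from mirfeat.errors import ValidationError
from mirfeat.feat import (
    background_gc_profile,
    gc_content,
    gc_profile_around_sites,
    intersite_features,
    multiplicity_table,
    site_features,
    utr_length_stats,
)
from mirfeat.model import BindingSite
from mirfeat.pairs import group_pairs
from mirfeat.synth import SynthConfig, generate_dataset


class TestGcContent:
    @pytest.mark.parametrize("seq,expected", [
        ("GGCC", 1.0), ("ATAT", 0.0), ("ATGC", 0.5), ("ANGN", 0.5),
    ])
    def test_fraction(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    def test_empty_and_all_n_are_undefined_not_zero(self):
        assert math.isnan(gc_content(""))
        assert math.isnan(gc_content("NNN"))


class TestSiteFeatures:
    def test_arithmetic(self):
        f = site_features(site("f", "g", 10), utr("g", "A" * 100))
        assert (f.dist_start, f.dist_end, f.rel_pos) == (10, 83, 0.10)

    def test_boundaries(self):
        u = utr("g", "A" * 100)
        assert site_features(site("f", "g", 0), u).rel_pos == 0.0
        assert site_features(site("f", "g", 93), u).dist_end == 0

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValidationError):
            site_features(site("f", "g", 95), utr("g", "A" * 100))

    @settings(derandomize=True, max_examples=200)
    @given(st.data())
    def test_positional_identity(self, data):
        L = data.draw(st.integers(8, 3000))
        start = data.draw(st.integers(0, L - 7))
        slen = data.draw(st.integers(1, min(20, L - start)))
        s = BindingSite("f", "g", "t", "9606", start, start + slen)
        f = site_features(s, utr("g", "A" * L))
        assert f.dist_start + f.dist_end + s.length == L
        assert f.rel_pos == pytest.approx(start / L)


class TestUtrLengthStats:
    def test_single_and_pair(self):
        utrs = [utr("g1", "A" * 100), utr("g2", "A" * 300)]
        s1 = utr_length_stats(utrs, {"g1"})
        assert (s1.n, s1.mean, s1.sd) == (1, 100.0, 0.0)
        assert utr_length_stats(utrs, {"g1", "g2"}).mean == 200.0

    def test_missing_gene_excluded_with_count(self):
        s = utr_length_stats([utr("g1", "A" * 50)], {"g1", "gX"})
        assert s.n == 1 and s.n_missing == 1

    def test_synthetic_mean_matches_generator(self):
        cfg = SynthConfig(n_genes=4000, n_families=0, site_rate=0.0,
                          enriched_families=(), rng_seed=8)
        ds = generate_dataset(cfg)
        stats = utr_length_stats(ds.utrs, {u.gene_id for u in ds.utrs})
        mean = np.exp(cfg.utr_len_log_mean + cfg.utr_len_log_sd ** 2 / 2)
        assert abs(stats.mean - mean) < 3 * stats.sd / np.sqrt(stats.n)


def _blocks_utr(n_blocks=21, block=50):
    """Sequence of 50-nt blocks where block i has GC fraction i/25."""
    seq = "".join("G" * (2 * i) + "A" * (block - 2 * i)
                  for i in range(n_blocks))
    return utr("g", seq)


class TestGcProfile:
    def test_all_g_utr_gives_unit_bins(self):
        u = utr("g", "G" * 1200)
        prof = gc_profile_around_sites(
            [site("f", "g", 600)], {"g": u})
        assert np.allclose(prof.mean_gc, 1.0)

    def test_block_fixture_bins_exact(self):
        """A 50-nt site aligned to 50-nt composition blocks: bins are exact."""
        u = _blocks_utr()
        s = BindingSite("f", "g", "t", "9606", 500, 550, "unknown")
        prof = gc_profile_around_sites([s], {"g": u})
        expected = [i / 25 for i in range(10)] + \
            [(i + 1) / 25 for i in range(10, 20)]
        assert np.allclose(prof.mean_gc, expected)
        assert (prof.n_obs == 1).all()

    def test_site_at_utr_start_has_no_upstream_contribution(self):
        prof = gc_profile_around_sites([site("f", "g", 0)],
                                       {"g": utr("g", "G" * 1000)})
        assert (prof.n_obs[:10] == 0).all()
        assert np.isnan(prof.mean_gc[:10]).all()
        assert (prof.n_obs[10:] == 1).all()

    def test_truncated_bin_counts_covered_part_only(self):
        # 30-nt UTR: only the first downstream bin is (partially) covered
        prof = gc_profile_around_sites([site("f", "g", 0)],
                                       {"g": utr("g", "G" * 30)})
        assert prof.n_obs[10] == 1 and (prof.n_obs[11:] == 0).all()
        assert prof.mean_gc[10] == pytest.approx(1.0)

    def test_drop_truncated_excludes_near_edge_sites(self):
        u = utr("g", "G" * 1200)
        sites = [site("f", "g", 10), site("f", "g", 600)]
        prof = gc_profile_around_sites(sites, {"g": u}, drop_truncated=True)
        assert (prof.n_obs == 1).all()  # only the centered site survives


class TestBackgroundProfile:
    def test_all_c_utrs(self):
        prof = background_gc_profile([utr("g", "C" * 1500)], n_regions=20,
                                     rng_seed=0)
        assert np.allclose(prof.mean_gc, 1.0)

    def test_negative_gradient_recovered_in_slope(self):
        cfg = SynthConfig(n_genes=300, n_families=0, site_rate=0.0,
                          enriched_families=(), gc_gradient_per_kb=-0.05,
                          utr_len_log_mean=7.8, rng_seed=21)
        ds = generate_dataset(cfg)
        prof = background_gc_profile(ds.utrs, n_regions=500, rng_seed=3)
        centers = np.array([(a + b) / 2 for a, b in prof.bin_offsets])
        slope = np.polyfit(centers, prof.mean_gc, 1)[0]
        assert slope < 0

    def test_deterministic_under_seed(self):
        utrs = [utr("g1", "GACT" * 300), utr("g2", "GGAT" * 400)]
        a = background_gc_profile(utrs, n_regions=50, rng_seed=9)
        b = background_gc_profile(utrs, n_regions=50, rng_seed=9)
        assert np.array_equal(a.mean_gc, b.mean_gc)

    def test_no_eligible_utr_is_error(self):
        with pytest.raises(ValidationError):
            background_gc_profile([utr("g", "ACGT" * 10)], n_regions=5,
                                  rng_seed=0)


class TestMultiplicity:
    def test_small_cases(self):
        groups = group_pairs([site("f", "g1", 0), site("h", "g2", 0),
                              site("f", "g3", 0), site("f", "g3", 10),
                              site("f", "g3", 20)])
        mc = multiplicity_table(groups)
        assert (mc.pairs_total, mc.pairs_multi) == (3, 1)
        empty = multiplicity_table([])
        assert (empty.pairs_total, empty.pairs_multi) == (0, 0)

    def test_twelve_group_fixture_manual_tally(self):
        sites = []
        # famA: g0..g5 with multiplicities 1,1,2,3,1,2  -> 6 pairs, 3 multi
        for gi, mult in enumerate([1, 1, 2, 3, 1, 2]):
            sites += [site("famA", f"g{gi}", 10 * k) for k in range(mult)]
        # famB: g0..g5 all single -> 6 pairs, 0 multi
        sites += [site("famB", f"g{gi}", 0) for gi in range(6)]
        mc = multiplicity_table(group_pairs(sites))
        assert (mc.pairs_total, mc.pairs_multi) == (12, 3)
        per = mc.per_family.set_index("family_id")
        assert per.loc["famA", "pairs_multi"] == 3
        assert per.loc["famB", "pairs_multi"] == 0


class TestIntersite:
    def test_gap_and_gap_gc(self):
        seq = "A" * 17 + "G" * 33 + "A" * 50
        group = group_pairs([site("f", "g", 10), site("f", "g", 50)])[0]
        feats, excluded = intersite_features(group, utr("g", seq))
        assert excluded == 0
        assert len(feats) == 1
        assert feats[0].gap == 33
        assert feats[0].gap_gc == pytest.approx(1.0)

    def test_three_sites_two_entries(self):
        group = group_pairs([site("f", "g", 0), site("f", "g", 20),
                             site("f", "g", 40)])[0]
        feats, _ = intersite_features(group, utr("g", "A" * 100))
        assert [f.gap for f in feats] == [13, 13]

    def test_overlapping_sites_excluded(self):
        group = group_pairs([site("f", "g", 0), site("f", "g", 3)])[0]
        feats, excluded = intersite_features(group, utr("g", "A" * 50))
        assert feats == [] and excluded == 1

    def test_singleton_group_yields_nothing(self):
        group = group_pairs([site("f", "g", 0)])[0]
        assert intersite_features(group, utr("g", "A" * 50)) == ([], 0)

    def test_entry_count_identity(self, small_dataset):
        by_gene = small_dataset.utr_by_gene()
        for g in group_pairs(small_dataset.sites):
            feats, excluded = intersite_features(g, by_gene[g.gene_id])
            assert len(feats) == g.multiplicity - 1 - excluded
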