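"""Ratio-resampling test, Fisher tests, and the summary-row assembly."""
from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest
from scipy.stats import hypergeom

from mirfeat.errors import ValidationError
from mirfeat.pairs import group_pairs
from mirfeat.stats import (
    compare_feature,
    fisher_multiplicity,
    per_family_fisher,
    ratio_permutation_test,
)
from mirfeat.synth import generate_dataset
from mirfeat.conditions import multiplicity_conditions


def exact_ratio_tail(values_a, values_b, pool_a, pool_b):
    """Exhaustive enumeration over all without-replacement draw pairs."""
    z = np.mean(values_a) / np.mean(values_b)
    n_a, n_b = len(values_a), len(values_b)
    succ = total = 0
    for da in combinations(pool_a, n_a):
        xa = np.mean(da)
        for db in combinations(pool_b, n_b):
            zs = xa / np.mean(db)
            total += 1
            if (zs > z) if z > 1 else (zs < z):
                succ += 1
    return succ / total, z


def two_sided_fisher_oracle(table):
    """Direct hypergeometric sum: P of all tables as or less probable."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    rv = hypergeom(r1 + r2, r1, c1)
    support = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(a)
    return float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())


class TestRatioTest:
    def test_degenerate_constant_data(self):
        r = ratio_permutation_test([5, 5], [5, 5], [5] * 6, [5] * 6,
                                   n_iter=50, rng_seed=0)
        assert r.z == 1.0 and r.p == 1.0

    def test_swapping_roles_inverts_ratio(self):
        a, b = [2.0, 4.0], [1.0, 3.0]
        pa, pb = [1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0]
        r1 = ratio_permutation_test(a, b, pa, pb, n_iter=50, rng_seed=1)
        r2 = ratio_permutation_test(b, a, pb, pa, n_iter=50, rng_seed=1)
        assert r2.z == pytest.approx(1 / r1.z)

    def test_matches_exhaustive_enumeration(self):
        pool_a = [5, 6, 7, 8, 9, 10, 11, 12]
        pool_b = [1, 2, 3, 4, 5, 6, 7, 8]
        values_a, values_b = [9, 11, 12], [2, 3, 5]
        q, z = exact_ratio_tail(values_a, values_b, pool_a, pool_b)
        assert z > 1
        res = ratio_permutation_test(values_a, values_b, pool_a, pool_b,
                                     n_iter=20_000, rng_seed=42)
        expected = (1 + res.n_iter * q) / (res.n_iter + 1)
        se = np.sqrt(q * (1 - q) / res.n_iter)
        assert abs(res.p - expected) <= 3 * se + 1e-12

    def test_lower_tail_matches_enumeration(self):
        pool_a = [1, 2, 3, 4, 5, 6, 7, 8]
        pool_b = [5, 6, 7, 8, 9, 10, 11, 12]
        values_a, values_b = [1, 2, 4], [10, 11, 12]
        q, z = exact_ratio_tail(values_a, values_b, pool_a, pool_b)
        assert z < 1
        res = ratio_permutation_test(values_a, values_b, pool_a, pool_b,
                                     n_iter=20_000, rng_seed=43)
        expected = (1 + res.n_iter * q) / (res.n_iter + 1)
        se = np.sqrt(q * (1 - q) / res.n_iter)
        assert abs(res.p - expected) <= 3 * se + 1e-12

    def test_reproducible_and_order_invariant(self):
        rng = np.random.default_rng(0)
        pa, pb = rng.random(30) + 1, rng.random(30) + 1
        va, vb = pa[:10], pb[:10]
        r1 = ratio_permutation_test(va, vb, pa, pb, n_iter=300, rng_seed=7)
        r2 = ratio_permutation_test(va, vb, pa[::-1], pb[::-1], n_iter=300,
                                    rng_seed=7)
        assert r1.p == r2.p and r1.z == r2.z

    def test_pool_smaller_than_sample_is_error(self):
        with pytest.raises(ValidationError):
            ratio_permutation_test([1, 2, 3], [1, 2], [1, 2], [1, 2, 3],
                                   n_iter=10, rng_seed=0)

    def test_zero_denominator_mean_is_error(self):
        with pytest.raises(ValidationError):
            ratio_permutation_test([1.0], [0.0], [1.0, 2.0], [0.0, 0.0],
                                   n_iter=10, rng_seed=0)

    def test_null_rejection_rate_is_stable_across_seeds(self):
        """Calibration is characterized empirically: the rejection rate at
        alpha=0.05 under a shared generating distribution is a stable
        constant (agreement between independent batches within 3 SE)."""
        def batch(seed0, n_rep=250):
            rng = np.random.default_rng(seed0)
            hits = 0
            for rep in range(n_rep):
                pool = rng.lognormal(7.5, 0.7, 60)
                pool2 = rng.lognormal(7.5, 0.7, 60)
                va = rng.choice(pool, 15, replace=False)
                vb = rng.choice(pool2, 15, replace=False)
                res = ratio_permutation_test(va, vb, pool, pool2, n_iter=200,
                                             rng_seed=int(rng.integers(2**31)))
                hits += res.p < 0.05
            return hits / n_rep

        r1, r2 = batch(1), batch(2)
        pbar = (r1 + r2) / 2
        se = np.sqrt(2 * max(pbar * (1 - pbar), 1e-4) / 250)
        assert abs(r1 - r2) <= 3 * se, (r1, r2)
        assert pbar < 0.15  # not wildly anticonservative


class TestFisher:
    def test_balanced_table_p_one(self):
        assert fisher_multiplicity((1, 1), (1, 1)).p == pytest.approx(1.0)

    def test_published_scale_contingency_is_significant(self):
        res = fisher_multiplicity((1855, 13154), (7871, 86369))
        assert res.p < 0.001
        assert res.odds_ratio > 1

    def test_negative_count_rejected(self):
        with pytest.raises(ValidationError):
            fisher_multiplicity((-1, 5), (2, 3))

    def test_matches_hypergeometric_oracle_on_random_tables(self):
        rng = np.random.default_rng(11)
        for _ in range(60):
            a, b, c, d = rng.integers(0, 12, 4)
            if a + b == 0 or c + d == 0:
                continue
            table = ((int(a), int(b)), (int(c), int(d)))
            assert fisher_multiplicity(*table).p == pytest.approx(
                two_sided_fisher_oracle(table), abs=1e-10)


class TestPerFamilyFisher:
    def test_delegation_identity(self):
        from conftest import site

        sel = group_pairs(
            [site("famA", f"s{i}", 0) for i in range(10)]
            + [s for i in range(10)
               for s in (site("famA", f"m{i}", 0), site("famA", f"m{i}", 20))])
        bg_sites = [site("famB", f"b{i}", 0) for i in range(900)]
        bg_sites += [s for i in range(100)
                     for s in (site("famB", f"bm{i}", 0),
                               site("famB", f"bm{i}", 20))]
        bg = group_pairs(bg_sites)
        df, _ = per_family_fisher(sel, bg)
        expected = fisher_multiplicity((10, 10), (100, 900))
        assert df.loc[0, "p"] == pytest.approx(expected.p)

    def test_recovers_planted_multiplicity_boost(self):
        """Families with extra sites planted only in factor genes are the
        significant ones; flat families stay at alpha-level error."""
        ds = generate_dataset(multiplicity_conditions())
        groups = group_pairs(ds.sites)
        sel = [g for g in groups if g.gene_id in ds.factor_genes]
        bg = [g for g in groups if g.gene_id not in ds.factor_genes]
        df, _ = per_family_fisher(sel, bg)
        df = df.set_index("family_id")
        boosted = sorted(ds.truth["enriched_families"])
        for fam in boosted:
            assert df.loc[fam, "p"] < 0.05
        flat = [f for f in df.index if f not in boosted]
        n_false = int((df.loc[flat, "p"] < 0.05).sum())
        assert n_false <= max(1, int(0.05 * len(flat)) + 2)


class TestCompareFeature:
    def test_identical_vectors(self):
        vals = [1.0, 2.0, 3.0]
        row = compare_feature(vals, vals, vals * 2, vals * 2, "x",
                              n_iter=50, rng_seed=0)
        assert row.z == 1.0 and row.p == 1.0

    def test_empty_vector_yields_undefined_row(self):
        row = compare_feature([], [1.0], [1.0], [1.0], "x", n_iter=10,
                              rng_seed=0)
        assert np.isnan(row.p) and np.isnan(row.mean_a)

    def test_planted_length_difference_is_detected(self):
        """The selected values are extreme relative to their own complete
        dataset (a mixture that also contains background-like values), so
        the resampled ratio rarely reaches the observed one."""
        rng = np.random.default_rng(5)
        long_pop = rng.lognormal(8.1, 0.7, 150)   # longer-UTR selected group
        bg_pop = rng.lognormal(7.55, 0.7, 800)
        pool_a = np.concatenate([long_pop, bg_pop[:300]])
        row = compare_feature(long_pop, bg_pop[300:600], pool_a, bg_pop,
                              "utr_length", n_iter=2000, rng_seed=9)
        assert row.z > 1
        assert row.p < 0.05
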