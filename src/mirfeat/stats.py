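"""Significance machinery: ratio-resampling test, Fisher tests, summary rows.

The ratio test compares two sample means through their ratio z = x / y. The
null is built by drawing, in each of n_iter iterations, samples of the same
sizes without replacement from each group's complete dataset independently
(no label pooling), forming z* = x* / y*. For z > 1 the p-value counts
iterations with z* > z; for z < 1, iterations with z* < z; z = 1 gives p = 1.
The add-one convention p = (1 + k) / (n_iter + 1) avoids exact zeros.

This resampling scheme is nonstandard — it samples subsets of each group's
own pool rather than permuting labels — so its null calibration is
characterized empirically in the test suite rather than assumed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError
from .model import PairGroup

logger = logging.getLogger(__name__)

DEFAULT_N_ITER = 10_000

_CHUNK_BUDGET = 4_000_000


@dataclass(frozen=True)
class RatioTestResult:
    """Observed ratio of means and its resampled one-sided p-value."""

    n_a: int
    n_b: int
    x: float       # mean of group A values
    y: float       # mean of group B values
    z: float       # x / y
    n_iter: int
    p: float
    rng_seed: int
    n_degenerate: int = 0  # iterations redrawn because y* was zero


def _sample_means(
    rng: np.random.Generator, pool: np.ndarray, n_draw: int, n_iter: int
) -> np.ndarray:
    """Means of ``n_iter`` without-replacement draws of size ``n_draw``."""
    n_pool = len(pool)
    if n_draw == n_pool:
        return np.full(n_iter, pool.mean())
    out = np.empty(n_iter)
    chunk = max(1, _CHUNK_BUDGET // n_pool)
    filled = 0
    while filled < n_iter:
        c = min(chunk, n_iter - filled)
        keys = rng.random((c, n_pool))
        idx = np.argpartition(keys, n_draw - 1, axis=1)[:, :n_draw]
        out[filled:filled + c] = pool[idx].mean(axis=1)
        filled += c
    return out


def ratio_permutation_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    pool_a: Sequence[float],
    pool_b: Sequence[float],
    n_iter: int = DEFAULT_N_ITER,
    rng_seed: int | None = None,
) -> RatioTestResult:
    """Resampled one-sided p-value for the ratio of two sample means.

    ``pool_a``/``pool_b`` are the complete datasets the observed samples come
    from; each iteration draws len(values_a) from pool_a and len(values_b)
    from pool_b, both without replacement and independently.
    """
    if rng_seed is None:
        raise ValidationError("ratio_permutation_test requires an explicit rng_seed")
    if n_iter < 1:
        raise ValidationError(f"n_iter must be >= 1, got {n_iter}")
    va = np.asarray(list(values_a), dtype=float)
    vb = np.asarray(list(values_b), dtype=float)
    # pools are sorted canonically so p is invariant to input ordering
    pa = np.sort(np.asarray(list(pool_a), dtype=float))
    pb = np.sort(np.asarray(list(pool_b), dtype=float))
    for name, arr in (("values_a", va), ("values_b", vb),
                      ("pool_a", pa), ("pool_b", pb)):
        if arr.size == 0:
            raise ValidationError(f"{name} is empty")
        if not np.all(np.isfinite(arr)):
            raise ValidationError(f"{name} contains non-finite values")
    if len(va) > len(pa) or len(vb) > len(pb):
        raise ValidationError("pool smaller than the observed sample")
    x = float(va.mean())
    y = float(vb.mean())
    if y == 0:
        raise ValidationError("denominator group has zero mean")
    z = x / y

    if z == 1.0:
        return RatioTestResult(len(va), len(vb), x, y, z, n_iter, 1.0,
                               int(rng_seed))

    rng = np.random.default_rng(rng_seed)
    xs = _sample_means(rng, pa, len(va), n_iter)
    ys = _sample_means(rng, pb, len(vb), n_iter)
    n_degenerate = 0
    bad = ys == 0
    guard = 0
    while bad.any():
        n_degenerate += int(bad.sum())
        xs[bad] = _sample_means(rng, pa, len(va), int(bad.sum()))
        ys[bad] = _sample_means(rng, pb, len(vb), int(bad.sum()))
        bad = ys == 0
        guard += 1
        if guard > 1000:
            raise ValidationError("pool_b produces zero-mean draws persistently")
    if n_degenerate:
        logger.info("ratio_permutation_test: redrew %d zero-denominator "
                    "iterations", n_degenerate)
    zstar = xs / ys
    if z > 1:
        k = int((zstar > z).sum())
    else:
        k = int((zstar < z).sum())
    p = (1 + k) / (n_iter + 1)
    return RatioTestResult(len(va), len(vb), x, y, z, n_iter, p, int(rng_seed),
                           n_degenerate)


@dataclass(frozen=True)
class FisherResult:
    """Two-by-two Fisher's exact test on multi/single-site pair counts."""

    table: tuple[tuple[int, int], tuple[int, int]]
    p: float
    odds_ratio: float


def fisher_multiplicity(
    counts_selected: tuple[int, int],
    counts_background: tuple[int, int],
    alternative: str = "two-sided",
) -> FisherResult:
    """Fisher's exact test on (multi, single) counts for the two pair sets."""
    table = (tuple(int(c) for c in counts_selected),
             tuple(int(c) for c in counts_background))
    for row in table:
        if any(c < 0 for c in row):
            raise ValidationError(f"negative count in {table}")
        if sum(row) == 0:
            raise ValidationError("each row of the table must have total > 0")
    odds, p = sps.fisher_exact(table, alternative=alternative)
    return FisherResult(table=table, p=float(p), odds_ratio=float(odds))


def per_family_fisher(
    groups_selected: Sequence[PairGroup],
    groups_background: Sequence[PairGroup],
    alpha: float = 0.05,
    alternative: str = "two-sided",
    family_matched: bool = False,
) -> tuple[pd.DataFrame, int]:
    """Per-family multiplicity test against the background pair set.

    For each family with selected pairs: the family's selected (multi, single)
    counts against the pooled background counts (or, with ``family_matched``,
    the background counts of the same family). Returns the per-family table
    and the number of families with p < ``alpha``.
    """
    from .feat import multiplicity_table  # local import to avoid a cycle

    sel_per_fam: dict[str, list[int]] = {}
    for g in groups_selected:
        tm = sel_per_fam.setdefault(g.family_id, [0, 0])
        tm[0] += 1
        if g.multiplicity >= 2:
            tm[1] += 1

    if family_matched:
        bg_per_fam: dict[str, list[int]] = {}
        for g in groups_background:
            tm = bg_per_fam.setdefault(g.family_id, [0, 0])
            tm[0] += 1
            if g.multiplicity >= 2:
                tm[1] += 1
    else:
        bg_all = multiplicity_table(groups_background)
        bg_counts = (bg_all.pairs_multi, bg_all.pairs_total - bg_all.pairs_multi)

    rows = []
    for fam in sorted(sel_per_fam):
        total, multi = sel_per_fam[fam]
        if total == 0:
            logger.info("per_family_fisher: family %s has no selected pairs, "
                        "skipped", fam)
            continue
        if family_matched:
            bt, bm = bg_per_fam.get(fam, [0, 0])
            bg = (bm, bt - bm)
            if bt == 0:
                logger.info("per_family_fisher: family %s has no background "
                            "pairs, skipped", fam)
                continue
        else:
            bg = bg_counts
        res = fisher_multiplicity((multi, total - multi), bg,
                                  alternative=alternative)
        rows.append({
            "family_id": fam,
            "selected_multi": multi, "selected_single": total - multi,
            "background_multi": bg[0], "background_single": bg[1],
            "odds_ratio": res.odds_ratio, "p": res.p,
        })
    df = pd.DataFrame(rows, columns=[
        "family_id", "selected_multi", "selected_single", "background_multi",
        "background_single", "odds_ratio", "p"])
    n_sig = int((df["p"] < alpha).sum()) if len(df) else 0
    return df, n_sig


@dataclass(frozen=True)
class Table1Row:
    """One analysis/contrast line of the descriptive-statistics table."""

    analysis: str
    set_a: str
    set_b: str
    n_a: int
    mean_a: float
    sd_a: float
    n_b: int
    mean_b: float
    sd_b: float
    z: float
    p: float


def compare_feature(
    values_selected: Sequence[float],
    values_background: Sequence[float],
    pool_selected: Sequence[float],
    pool_background: Sequence[float],
    label: str,
    set_a: str = "selected",
    set_b: str = "background",
    n_iter: int = DEFAULT_N_ITER,
    rng_seed: int | None = None,
) -> Table1Row:
    """Descriptive statistics for both sets plus the ratio-test p-value."""
    va = np.asarray(list(values_selected), dtype=float)
    vb = np.asarray(list(values_background), dtype=float)
    if va.size == 0 or vb.size == 0:
        return Table1Row(label, set_a, set_b,
                         int(va.size), float("nan"), float("nan"),
                         int(vb.size), float("nan"), float("nan"),
                         float("nan"), float("nan"))
    res = ratio_permutation_test(va, vb, pool_selected, pool_background,
                                 n_iter=n_iter, rng_seed=rng_seed)
    return Table1Row(
        analysis=label, set_a=set_a, set_b=set_b,
        n_a=len(va), mean_a=float(va.mean()),
        sd_a=float(va.std(ddof=1)) if len(va) > 1 else 0.0,
        n_b=len(vb), mean_b=float(vb.mean()),
        sd_b=float(vb.std(ddof=1)) if len(vb) > 1 else 0.0,
        z=res.z, p=res.p,
    )
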