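"""Per-UTR and per-site features: lengths, positions, GC profiles, multiplicity.

Positional conventions: for a site [start, end) in a UTR of length L,
``dist_start = start`` (5' UTR end to site start), ``dist_end = L - end``
(site end to 3' UTR end) and ``rel_pos = start / L``, so that
``dist_start + dist_end + site length = L`` holds exactly for every site.

GC profiles are measured in 50-nt bins spanning 500 nt on each side of the
site, excluding the site body. Bins truncated by UTR boundaries contribute
only their covered nucleotides; a site contributes to a bin only when at
least one nucleotide of the bin is covered.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .model import BindingSite, PairGroup, UtrRecord

logger = logging.getLogger(__name__)

#: z-quantile for the 99% two-sided normal CI of a mean.
Z99 = 2.5758293035489004


def gc_content(sequence: str) -> float:
    """Fraction (G+C) / (non-N length); NaN for empty or all-N slices."""
    seq = sequence.upper()
    denom = len(seq) - seq.count("N")
    if denom <= 0:
        return float("nan")
    return (seq.count("G") + seq.count("C")) / denom


@dataclass(frozen=True)
class SiteFeatures:
    """Positional features of one site within its UTR."""

    dist_start: int
    dist_end: int
    rel_pos: float


def site_features(site: BindingSite, utr: UtrRecord) -> SiteFeatures:
    """Distances to the UTR's 5' and 3' ends and the relative position."""
    if site.end > utr.length or site.start < 0:
        raise ValidationError(
            f"site [{site.start},{site.end}) outside UTR {utr.gene_id} "
            f"of length {utr.length}"
        )
    return SiteFeatures(
        dist_start=site.start,
        dist_end=utr.length - site.end,
        rel_pos=site.start / utr.length,
    )


@dataclass
class LengthStats:
    """Summary of UTR lengths over a gene set."""

    n: int
    mean: float
    sd: float
    values: np.ndarray
    n_missing: int  # genes without a UTR record


def utr_length_stats(
    utrs: Mapping[str, UtrRecord] | Sequence[UtrRecord],
    gene_set: Iterable[str],
) -> LengthStats:
    """Length statistics over the unique genes in ``gene_set``."""
    by_gene = utrs if isinstance(utrs, Mapping) else {u.gene_id: u for u in utrs}
    genes = sorted(set(gene_set))
    if not genes:
        raise ValidationError("gene_set is empty")
    values, missing = [], 0
    for g in genes:
        if g in by_gene:
            values.append(by_gene[g].length)
        else:
            missing += 1
    if missing:
        logger.info("utr_length_stats: %d genes without UTR record excluded",
                    missing)
    arr = np.asarray(values, dtype=float)
    return LengthStats(
        n=len(arr),
        mean=float(arr.mean()) if len(arr) else float("nan"),
        sd=float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
        values=arr,
        n_missing=missing,
    )


@dataclass
class GcProfile:
    """Binned GC means around sites (or along background windows).

    ``bin_offsets`` are signed nt ranges relative to the site: negative bins
    count back from the site start, positive bins forward from the site end.
    """

    bin_offsets: list[tuple[int, int]]
    mean_gc: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_obs: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_start": [a for a, _ in self.bin_offsets],
            "bin_end": [b for _, b in self.bin_offsets],
            "mean_gc": self.mean_gc,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_obs": self.n_obs,
        })


def profile_bin_offsets(half_window: int = 500, bin_size: int = 50
                        ) -> list[tuple[int, int]]:
    """The signed bin ranges, upstream then downstream, site body excluded."""
    k = half_window // bin_size
    ups = [(-bin_size * j, -bin_size * (j - 1)) for j in range(k, 0, -1)]
    downs = [(bin_size * (j - 1), bin_size * j) for j in range(1, k + 1)]
    return ups + downs


def _summarize_bins(per_bin: list[list[float]],
                    offsets: list[tuple[int, int]]) -> GcProfile:
    mean = np.full(len(per_bin), np.nan)
    lo = np.full(len(per_bin), np.nan)
    hi = np.full(len(per_bin), np.nan)
    n_obs = np.zeros(len(per_bin), dtype=int)
    for i, vals in enumerate(per_bin):
        vals = [v for v in vals if np.isfinite(v)]
        n_obs[i] = len(vals)
        if not vals:
            continue
        arr = np.asarray(vals)
        mean[i] = arr.mean()
        if len(vals) >= 2:
            se = arr.std(ddof=1) / np.sqrt(len(vals))
            lo[i] = mean[i] - Z99 * se
            hi[i] = mean[i] + Z99 * se
    return GcProfile(bin_offsets=offsets, mean_gc=mean, ci_low=lo, ci_high=hi,
                     n_obs=n_obs)


def gc_profile_around_sites(
    sites: Sequence[BindingSite],
    utrs: Mapping[str, UtrRecord] | Sequence[UtrRecord],
    half_window: int = 500,
    bin_size: int = 50,
    drop_truncated: bool = False,
) -> GcProfile:
    """Mean GC per 50-nt bin around sites, with 99% normal CIs of the mean.

    With ``drop_truncated`` a site contributes only when every bin is fully
    inside the UTR; by default partial bins contribute their covered part.
    """
    by_gene = utrs if isinstance(utrs, Mapping) else {u.gene_id: u for u in utrs}
    offsets = profile_bin_offsets(half_window, bin_size)
    per_bin: list[list[float]] = [[] for _ in offsets]
    for s in sites:
        utr = by_gene.get(s.gene_id)
        if utr is None:
            continue
        L = utr.length
        if drop_truncated and (s.start < half_window or s.end + half_window > L):
            continue
        for i, (a, b) in enumerate(offsets):
            if a < 0:  # upstream of site start
                lo, hi = s.start + a, s.start + b
            else:      # downstream of site end
                lo, hi = s.end + a, s.end + b
            lo, hi = max(0, lo), min(L, hi)
            if hi <= lo:
                continue
            per_bin[i].append(gc_content(utr.sequence[lo:hi]))
    return _summarize_bins(per_bin, offsets)


def background_gc_profile(
    utrs: Sequence[UtrRecord],
    region_len: int = 1000,
    n_regions: int = 10_000,
    rng_seed: int | None = None,
    bin_size: int = 50,
) -> GcProfile:
    """GC profile of random fixed-length windows drawn from the UTR set.

    Each window is drawn by first choosing an eligible UTR (length >=
    ``region_len``) uniformly, then a start position uniformly within it; the
    window is split into ``region_len / bin_size`` bins. Bin offsets are
    reported centered, aligning with :func:`gc_profile_around_sites`.
    """
    if rng_seed is None:
        raise ValidationError("background_gc_profile requires an explicit rng_seed")
    if n_regions < 1:
        raise ValidationError(f"n_regions must be >= 1, got {n_regions}")
    eligible = [u for u in utrs if u.length >= region_len]
    if not eligible:
        raise ValidationError(
            f"no UTR of length >= {region_len} available for background windows"
        )
    rng = np.random.default_rng(rng_seed)
    half = region_len // 2
    offsets = profile_bin_offsets(half, bin_size)
    per_bin: list[list[float]] = [[] for _ in offsets]
    for _ in range(n_regions):
        u = eligible[int(rng.integers(0, len(eligible)))]
        start = int(rng.integers(0, u.length - region_len + 1))
        for i in range(len(offsets)):
            lo = start + i * bin_size
            per_bin[i].append(gc_content(u.sequence[lo:lo + bin_size]))
    return _summarize_bins(per_bin, offsets)


@dataclass
class MultiplicityCounts:
    """Pair-level multiplicity summary, overall and per family."""

    pairs_total: int
    pairs_multi: int  # pairs with >= 2 sites of the family
    per_family: pd.DataFrame  # family_id, pairs_total, pairs_multi


def multiplicity_table(groups: Sequence[PairGroup]) -> MultiplicityCounts:
    """Count pairs with multiple same-family sites, overall and per family."""
    rows: dict[str, list[int]] = {}
    for g in groups:
        tot_multi = rows.setdefault(g.family_id, [0, 0])
        tot_multi[0] += 1
        if g.multiplicity >= 2:
            tot_multi[1] += 1
    per_family = pd.DataFrame(
        [{"family_id": f, "pairs_total": t, "pairs_multi": m}
         for f, (t, m) in sorted(rows.items())]
    )
    if per_family.empty:
        per_family = pd.DataFrame(columns=["family_id", "pairs_total",
                                           "pairs_multi"])
    return MultiplicityCounts(
        pairs_total=int(per_family["pairs_total"].sum()) if len(per_family) else 0,
        pairs_multi=int(per_family["pairs_multi"].sum()) if len(per_family) else 0,
        per_family=per_family,
    )


@dataclass(frozen=True)
class InterSiteFeatures:
    """Gap between consecutive same-family sites and the GC of the gap."""

    gap: int
    gap_gc: float


def intersite_features(
    group: PairGroup, utr: UtrRecord
) -> tuple[list[InterSiteFeatures], int]:
    """Consecutive-pair gaps and gap GC for one multi-site group.

    Only strictly positive gaps are emitted; adjacent or overlapping
    consecutive sites are excluded and their count returned alongside.
    """
    if group.multiplicity < 2:
        return [], 0
    out: list[InterSiteFeatures] = []
    excluded = 0
    for cur, nxt in zip(group.sites, group.sites[1:]):
        gap = nxt.start - cur.end
        if gap <= 0:
            excluded += 1
            continue
        out.append(InterSiteFeatures(
            gap=gap, gap_gc=gc_content(utr.sequence[cur.end:nxt.start])
        ))
    if excluded:
        logger.debug("intersite_features(%s/%s): excluded %d non-positive gaps",
                     group.family_id, group.gene_id, excluded)
    return out, excluded


# ---------------------------------------------------------------------------
# tabular aggregation helpers used by the pipeline


def site_feature_table(
    sites: Sequence[BindingSite],
    utrs: Mapping[str, UtrRecord],
) -> pd.DataFrame:
    """Tidy per-site table of positional features."""
    rows = []
    for s in sites:
        utr = utrs.get(s.gene_id)
        if utr is None:
            continue
        f = site_features(s, utr)
        rows.append({
            "family_id": s.family_id, "gene_id": s.gene_id,
            "start": s.start, "end": s.end,
            "dist_start": f.dist_start, "dist_end": f.dist_end,
            "rel_pos": f.rel_pos, "utr_length": utr.length,
        })
    cols = ["family_id", "gene_id", "start", "end", "dist_start", "dist_end",
            "rel_pos", "utr_length"]
    return pd.DataFrame(rows, columns=cols)


def intersite_table(
    groups: Sequence[PairGroup],
    utrs: Mapping[str, UtrRecord],
) -> pd.DataFrame:
    """Tidy inter-site table over all multi-site groups."""
    rows = []
    for g in groups:
        utr = utrs.get(g.gene_id)
        if utr is None or g.multiplicity < 2:
            continue
        feats, _ = intersite_features(g, utr)
        for f in feats:
            rows.append({"family_id": g.family_id, "gene_id": g.gene_id,
                         "gap": f.gap, "gap_gc": f.gap_gc})
    return pd.DataFrame(rows, columns=["family_id", "gene_id", "gap", "gap_gc"])
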