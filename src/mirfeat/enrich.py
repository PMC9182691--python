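"""Corrected Monte-Carlo over-representation test for miRNA families.

For a factor-bound gene set of size n inside the prediction universe, with m
of those genes targeted by a family, the null is built by repeatedly drawing
n genes uniformly without replacement from the universe and counting the
targeted genes z in each draw. Because factor-bound genes may carry more
predictions overall (e.g. through longer 3'-UTRs), each null count is scaled
by a correction factor r = (total predicted sites in the factor-bound genes) /
(total predicted sites in the draw), giving z* = z * r. The upper-tail
p-value uses the add-one convention p = (1 + #{z* >= m}) / (n_iter + 1).

Multiple families are adjusted per dataset by Benjamini-Hochberg and selected
at a configurable level, by default when significant in any dataset.
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .model import BindingSite

logger = logging.getLogger(__name__)

#: Iterations used throughout unless overridden.
DEFAULT_N_ITER = 10_000

# keep chunks of random keys around ~4M doubles
_CHUNK_BUDGET = 4_000_000


@dataclass(frozen=True)
class EnrichmentResult:
    """Outcome of the corrected Monte-Carlo test for one (family, dataset)."""

    family_id: str
    dataset_id: str
    n: int              # factor-bound genes inside the universe
    m: int              # of those, genes targeted by the family
    n_iter: int
    null_mean: float    # mean of corrected null counts z*
    null_sd: float
    p_raw: float
    rng_seed: int
    p_adj: float | None = None
    n_degenerate: int = 0  # draws resampled because r was undefined


@dataclass(frozen=True)
class FamilySelection:
    """Families called enriched, with the per-dataset evidence table."""

    selected: frozenset[str]
    alpha: float
    rule: str
    evidence: pd.DataFrame  # dataset_id, family_id, n, m, null stats, p_raw, p_adj


def count_family_targets(
    sites: Sequence[BindingSite], family_id: str, gene_set: Iterable[str]
) -> int:
    """Number of genes in ``gene_set`` with >=1 site of ``family_id``.

    Gene-level: a gene with many sites of the family counts once.
    """
    fam_genes = {s.gene_id for s in sites if s.family_id == family_id}
    if not fam_genes and family_id not in {s.family_id for s in sites}:
        raise LookupError(f"family {family_id!r} has no sites in the collection")
    return len(fam_genes & set(gene_set))


def _site_totals(sites: Sequence[BindingSite], r_mode: str) -> Counter:
    """Per-gene prediction totals used by the correction factor r.

    ``site`` counts every predicted site; ``pair`` counts distinct families.
    """
    if r_mode == "site":
        return Counter(s.gene_id for s in sites)
    if r_mode == "pair":
        return Counter(g for (_f, g) in {(s.family_id, s.gene_id) for s in sites})
    raise ValidationError(f"unknown r_mode {r_mode!r}")


def enrichment_test(
    sites: Sequence[BindingSite],
    family_id: str,
    factor_genes: Iterable[str],
    universe_genes: Iterable[str],
    n_iter: int = DEFAULT_N_ITER,
    rng_seed: int | None = None,
    dataset_id: str = "default",
    tail: str = "upper",
    r_mode: str = "site",
) -> EnrichmentResult:
    """Corrected Monte-Carlo over-representation test for one family.

    ``tail="upper"`` (default) counts null draws with z* >= m, matching the
    selection rule's semantics; ``tail="literal"`` counts z* < m, the
    literal reading of the procedure's prose, kept for audit only.
    """
    if rng_seed is None:
        raise ValidationError("enrichment_test requires an explicit rng_seed")
    if n_iter < 1:
        raise ValidationError(f"n_iter must be >= 1, got {n_iter}")
    if tail not in ("upper", "literal"):
        raise ValidationError(f"unknown tail {tail!r}")

    universe = sorted(set(universe_genes))
    fset = set(factor_genes) & set(universe)
    n = len(fset)
    if n == 0:
        raise ValidationError("no factor-bound genes inside the universe")
    if n > len(universe):
        raise ValidationError(
            f"universe ({len(universe)}) smaller than factor set ({n})"
        )

    m = count_family_targets(sites, family_id, fset)
    totals = _site_totals(sites, r_mode)
    counts = np.array([totals.get(g, 0) for g in universe], dtype=float)
    fam_genes = {s.gene_id for s in sites if s.family_id == family_id}
    targeted = np.array([g in fam_genes for g in universe], dtype=float)
    numerator = float(sum(totals.get(g, 0) for g in fset))

    rng = np.random.default_rng(rng_seed)
    n_universe = len(universe)
    chunk = max(1, min(n_iter, _CHUNK_BUDGET // max(n_universe, 1)))

    zstar = np.empty(n_iter, dtype=float)
    filled = 0
    n_degenerate = 0
    guard = 0
    while filled < n_iter:
        c = min(chunk, (n_iter - filled) * 2 + 8)
        keys = rng.random((c, n_universe))
        idx = np.argpartition(keys, n - 1, axis=1)[:, :n]
        denom = counts[idx].sum(axis=1)
        valid = denom > 0
        n_degenerate += int((~valid).sum())
        z = targeted[idx[valid]].sum(axis=1)
        r = numerator / denom[valid]
        vals = z * r
        take = min(len(vals), n_iter - filled)
        zstar[filled:filled + take] = vals[:take]
        filled += take
        guard += 1
        if guard > 1000:
            raise ValidationError(
                "could not draw gene sets with any predictions; universe has "
                "too few predicted sites"
            )
    if n_degenerate:
        logger.info("enrichment_test(%s): resampled %d draws with zero "
                    "predictions", family_id, n_degenerate)

    if tail == "upper":
        k = int((zstar >= m).sum())
    else:
        k = int((zstar < m).sum())
    p_raw = (1 + k) / (n_iter + 1)

    return EnrichmentResult(
        family_id=family_id,
        dataset_id=dataset_id,
        n=n,
        m=m,
        n_iter=n_iter,
        null_mean=float(zstar.mean()),
        null_sd=float(zstar.std(ddof=1)) if n_iter > 1 else 0.0,
        p_raw=p_raw,
        rng_seed=int(rng_seed),
        n_degenerate=n_degenerate,
    )


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def adjust_results(results: Sequence[EnrichmentResult]) -> list[EnrichmentResult]:
    """BH-adjust raw p-values within one dataset's results."""
    adj = bh_adjust([r.p_raw for r in results])
    return [replace(r, p_adj=q) for r, q in zip(results, adj)]


def select_families(
    results_by_dataset: Mapping[str, Sequence[EnrichmentResult]],
    alpha: float = 0.05,
    rule: str = "any_dataset",
) -> FamilySelection:
    """Select families with adjusted p below ``alpha``.

    ``any_dataset`` (default) selects a family significant in at least one
    dataset; ``all_datasets`` requires significance everywhere the family was
    tested. Adjustment is applied per dataset if not already present.
    """
    if not results_by_dataset:
        raise ValidationError("no enrichment results to select from")
    if rule not in ("any_dataset", "all_datasets"):
        raise ValidationError(f"unknown selection rule {rule!r}")
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")

    rows = []
    hits: dict[str, list[bool]] = {}
    for ds_id, results in results_by_dataset.items():
        if not results:
            raise ValidationError(f"dataset {ds_id!r} has no results")
        if any(r.p_adj is None for r in results):
            results = adjust_results(list(results))
        for r in results:
            rows.append({
                "dataset_id": ds_id, "family_id": r.family_id, "n": r.n,
                "m": r.m, "n_iter": r.n_iter, "null_mean": r.null_mean,
                "null_sd": r.null_sd, "p_raw": r.p_raw, "p_adj": r.p_adj,
            })
            hits.setdefault(r.family_id, []).append(r.p_adj < alpha)

    if rule == "any_dataset":
        selected = frozenset(f for f, h in hits.items() if any(h))
    else:
        selected = frozenset(f for f, h in hits.items() if all(h))

    evidence = pd.DataFrame(rows).sort_values(
        ["dataset_id", "p_adj", "family_id"]).reset_index(drop=True)
    return FamilySelection(selected=selected, alpha=alpha, rule=rule,
                           evidence=evidence)
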