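"""Grouping of sites into (family, gene) pairs and the selected/background split.

The "selected" set holds pairs whose family was called enriched in the
factor-bound genes AND whose gene is factor-bound; every other pair is
"background". The background pairs that nevertheless sit in factor-bound
genes' UTRs form a control subset used to separate UTR effects from
family-selection effects.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .model import BindingSite, PairGroup

logger = logging.getLogger(__name__)


@dataclass
class PairSets:
    """The disjoint selected/background partition plus the in-factor control."""

    selected: list[PairGroup]
    background: list[PairGroup]
    background_in_factor_utrs: list[PairGroup]

    def all_groups(self) -> list[PairGroup]:
        return self.selected + self.background


def group_pairs(sites: Sequence[BindingSite]) -> list[PairGroup]:
    """One group per distinct (family, gene) key, sites sorted by start."""
    by_key: dict[tuple[str, str], list[BindingSite]] = {}
    for s in sites:
        by_key.setdefault((s.family_id, s.gene_id), []).append(s)
    return [
        PairGroup(family_id=f, gene_id=g, sites=by_key[(f, g)])
        for f, g in sorted(by_key)
    ]


def split_sets(
    groups: Sequence[PairGroup],
    selected_families: Iterable[str],
    factor_genes: Iterable[str],
) -> PairSets:
    """Partition pair groups into selected and background sets.

    A group is selected iff its family is in ``selected_families`` and its
    gene is in ``factor_genes``; both conditions are required. Deterministic
    and order-independent (groups are kept in canonical key order).
    """
    fams = set(selected_families)
    genes = set(factor_genes)
    ordered = sorted(groups, key=lambda g: (g.family_id, g.gene_id))
    selected = [g for g in ordered if g.family_id in fams and g.gene_id in genes]
    background = [g for g in ordered
                  if not (g.family_id in fams and g.gene_id in genes)]
    in_factor = [g for g in background if g.gene_id in genes]
    if not selected:
        logger.warning("split_sets: selected set is empty")
    logger.info(
        "split_sets: %d selected pairs (%d sites), %d background pairs "
        "(%d sites), %d background pairs in factor UTRs",
        len(selected), sum(g.multiplicity for g in selected),
        len(background), sum(g.multiplicity for g in background),
        len(in_factor),
    )
    return PairSets(selected=selected, background=background,
                    background_in_factor_utrs=in_factor)


def flatten(groups: Sequence[PairGroup]) -> list[BindingSite]:
    """Site-level view of a collection of pair groups."""
    return [s for g in groups for s in g.sites]
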