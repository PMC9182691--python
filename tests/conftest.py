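"""Shared fixtures: tiny hand-built universes and a small synthetic dataset."""
from __future__ import annotations

import pytest

from mirfeat.model import BindingSite, UtrRecord
from mirfeat.synth import SynthConfig, generate_dataset


def site(fam: str, gene: str, start: int, end: int | None = None,
         species: str = "9606") -> BindingSite:
    end = start + 7 if end is None else end
    return BindingSite(fam, gene, f"t-{gene}", species, start, end, "7mer-m8")


def utr(gene: str, sequence: str, species: str = "9606") -> UtrRecord:
    return UtrRecord(gene, f"t-{gene}", gene.upper(), species, sequence)


@pytest.fixture(scope="session")
def six_gene_fixture():
    """Six genes, two families; used by manual-tally and enumeration tests.

    Site-level totals per gene: g1:3, g2:1, g3:2, g4:1, g5:2, g6:1.
    famA targets g1, g2, g3; famB targets g1, g3, g4, g5, g6.
    """
    sites = [
        site("famA", "g1", 0), site("famA", "g1", 10), site("famA", "g2", 5),
        site("famA", "g3", 7),
        site("famB", "g1", 20), site("famB", "g3", 30), site("famB", "g4", 0),
        site("famB", "g5", 0), site("famB", "g5", 10), site("famB", "g6", 2),
    ]
    universe = ["g1", "g2", "g3", "g4", "g5", "g6"]
    return sites, universe


@pytest.fixture(scope="session")
def small_dataset():
    """A modest synthetic dataset reused by read-only tests."""
    cfg = SynthConfig(n_genes=120, n_families=6, site_rate=0.15,
                      enriched_families=(0,), enrichment_factor=3.0,
                      rng_seed=42)
    return generate_dataset(cfg)
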