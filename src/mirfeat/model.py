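"""Shared record types for 3'-UTRs, miRNA families, binding sites and pairs.

Coordinates are 0-based half-open on the ungapped representative 3'-UTR
throughout the package. TargetScan-style 1-based inclusive columns are
converted at the I/O boundary (see :mod:`mirfeat.tsio`).
"""
from __future__ import annotations

from dataclasses import dataclass, field

VALID_ALPHABET = frozenset("ACGTUN")

#: Canonical seed-match site types, in increasing predicted efficacy.
SITE_TYPES = ("7mer-a1", "7mer-m8", "8mer")

CONSERVATION_CLASSES = ("broadly_conserved", "conserved", "poorly_conserved")

#: Taxon ids used by the TargetScan flat files.
HUMAN = "9606"
MOUSE = "10090"


@dataclass(frozen=True, slots=True)
class UtrRecord:
    """One gene's ungapped representative 3'-UTR sequence."""

    gene_id: str
    transcript_id: str
    symbol: str
    species: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence) - VALID_ALPHABET
        if bad:
            raise ValueError(
                f"UTR {self.gene_id}: invalid characters {sorted(bad)!r} in sequence"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, slots=True)
class MirnaFamily:
    """A miRNA seed family with its TargetScan conservation class."""

    family_id: str
    seed: str
    conservation_class: str

    def __post_init__(self) -> None:
        if len(self.seed) != 7:
            raise ValueError(
                f"family {self.family_id}: seed must be 7 nt, got {len(self.seed)}"
            )
        if self.conservation_class not in CONSERVATION_CLASSES:
            raise ValueError(
                f"family {self.family_id}: unknown conservation class "
                f"{self.conservation_class!r}"
            )


@dataclass(frozen=True, slots=True)
class BindingSite:
    """One predicted miRNA binding site on an ungapped 3'-UTR.

    ``start``/``end`` are 0-based half-open offsets. ``site_type`` is one of
    :data:`SITE_TYPES` or ``"unknown"``.
    """

    family_id: str
    gene_id: str
    transcript_id: str
    species: str
    start: int
    end: int
    site_type: str = "unknown"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"site {self.family_id}/{self.gene_id}: bad span "
                f"[{self.start}, {self.end})"
            )
        if self.site_type != "unknown" and self.site_type not in SITE_TYPES:
            raise ValueError(f"unknown site type {self.site_type!r}")
        if self.site_type != "unknown" and not 6 <= self.end - self.start <= 8:
            raise ValueError(
                f"site {self.family_id}/{self.gene_id}: length "
                f"{self.end - self.start} incompatible with type {self.site_type}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def sort_key(self) -> tuple:
        return (self.gene_id, self.family_id, self.start, self.end)


@dataclass(slots=True)
class PairGroup:
    """All sites for one (miRNA family, gene) pair, sorted by start."""

    family_id: str
    gene_id: str
    sites: list[BindingSite] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError("PairGroup requires at least one site")
        for s in self.sites:
            if (s.family_id, s.gene_id) != (self.family_id, self.gene_id):
                raise ValueError(
                    f"site {s.family_id}/{s.gene_id} does not belong to group "
                    f"{self.family_id}/{self.gene_id}"
                )
        self.sites = sorted(self.sites, key=lambda s: (s.start, s.end))

    @property
    def multiplicity(self) -> int:
        return len(self.sites)


def normalize_site_type(raw: str) -> str:
    """Map TargetScan seed-match labels onto the canonical site types."""
    t = raw.strip().lower().replace("_", "-")
    if t in {"8mer", "8mer-1a", "8mer-a1"}:
        return "8mer"
    if t == "7mer-m8":
        return "7mer-m8"
    if t in {"7mer-1a", "7mer-a1"}:
        return "7mer-a1"
    return "unknown"
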