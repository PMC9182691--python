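"""Readers for TargetScan-7.2-dialect flat files and the internal TSV dialects.

TargetScan distributes tab-delimited tables: a gapped multi-species UTR
alignment table (one row per transcript x species), a predicted-targets table
with 1-based inclusive UTR coordinates, and a family-info table with a
numeric conservation code. These readers restrict to one species, degap and
normalize sequences (U -> T, uppercase), convert coordinates to the package's
0-based half-open convention, and validate sites against their UTRs.

The internal dialect written by :func:`mirfeat.synth.write_dataset`
(``utrs.tsv`` + ``utrs.fasta``, ``sites.tsv``, ``factor_genes.txt``,
``families.tsv``) round-trips losslessly through the ``read_internal_*``
functions.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .errors import ConfigError, ParseError
from .model import (
    CONSERVATION_CLASSES,
    BindingSite,
    MirnaFamily,
    UtrRecord,
    normalize_site_type,
)

logger = logging.getLogger(__name__)

_GAP_RE = re.compile(r"[-.]")


def _norm_species(s: str) -> str:
    return s.strip()


def _clean_sequence(raw: str) -> str:
    """Remove alignment gaps, uppercase, and normalize U to T."""
    return _GAP_RE.sub("", raw.strip()).upper().replace("U", "T")


def _split_header(line: str) -> dict[str, int] | None:
    """Map normalized column names to indices if the line looks like a header."""
    cols = [re.sub(r"[^a-z0-9]", "", c.lower()) for c in line.rstrip("\n").split("\t")]
    if not any(c in {"speciesid", "species"} for c in cols):
        return None
    return {c: i for i, c in enumerate(cols)}


def read_utr_table(path: str | Path, species: str) -> list[UtrRecord]:
    """Read a TargetScan UTR-sequences table restricted to one species.

    Expected columns (header optional): transcript id, gene id, gene symbol,
    species id, gapped sequence. Gap characters are removed and the length
    recomputed from the degapped sequence. One record is kept per gene
    (first transcript row wins; the distributed file carries one
    representative transcript per gene).
    """
    species = _norm_species(species)
    records: list[UtrRecord] = []
    seen: set[str] = set()
    n_dup = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            if lineno == 1 and _split_header(line) is not None:
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 5:
                raise ParseError(
                    f"expected 5 tab-separated columns, got {len(fields)}", lineno
                )
            tx, gene, sym, sp, seq = fields
            if _norm_species(sp) != species:
                continue
            if gene in seen:
                n_dup += 1
                continue
            seen.add(gene)
            records.append(UtrRecord(gene, tx, sym, species, _clean_sequence(seq)))
    if n_dup:
        logger.info("read_utr_table: skipped %d duplicate gene rows", n_dup)
    if not records:
        logger.warning("read_utr_table: no UTR records for species %s in %s",
                       species, path)
    return records


@dataclass
class SiteRejects:
    """Sites dropped during validation, kept for reporting rather than failing."""

    unknown_gene: int = 0
    out_of_bounds: int = 0
    examples: list[str] = field(default_factory=list)

    @property
    def total(self) -> int:
        return self.unknown_gene + self.out_of_bounds


_TS_SITE_POSITIONAL = (
    "mirfamily", "geneid", "genesymbol", "transcriptid", "speciesid",
    "msastart", "msaend", "utrstart", "utrend", "seedmatch",
)


def read_site_table(
    path: str | Path,
    species: str,
    utrs: list[UtrRecord] | None = None,
) -> tuple[list[BindingSite], SiteRejects]:
    """Read a TargetScan predicted-targets table restricted to one species.

    The UTR start/end columns are 1-based inclusive on the ungapped
    representative UTR and are converted to 0-based half-open. When ``utrs``
    is given, sites referencing unknown genes or exceeding their UTR's
    degapped length are collected into the :class:`SiteRejects` report.
    """
    species = _norm_species(species)
    lengths = {u.gene_id: u.length for u in utrs} if utrs is not None else None
    sites: list[BindingSite] = []
    rejects = SiteRejects()
    colmap: dict[str, int] | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            if lineno == 1:
                colmap = _split_header(line)
                if colmap is not None:
                    continue
            fields = line.rstrip("\n").split("\t")

            def col(name: str, default: str | None = None) -> str:
                if colmap is not None and name in colmap:
                    idx = colmap[name]
                else:
                    idx = _TS_SITE_POSITIONAL.index(name)
                if idx >= len(fields):
                    if default is not None:
                        return default
                    raise ParseError(f"missing column {name!r}", lineno)
                return fields[idx]

            if len(fields) < 9:
                raise ParseError(
                    f"expected >=9 tab-separated columns, got {len(fields)}", lineno
                )
            if _norm_species(col("speciesid")) != species:
                continue
            gene = col("geneid")
            try:
                start = int(col("utrstart")) - 1
                end = int(col("utrend"))
            except ValueError as exc:
                raise ParseError(f"non-integer UTR coordinate ({exc})", lineno) from None
            site_type = normalize_site_type(col("seedmatch", default="unknown"))
            if lengths is not None:
                if gene not in lengths:
                    rejects.unknown_gene += 1
                    if len(rejects.examples) < 5:
                        rejects.examples.append(f"line {lineno}: unknown gene {gene}")
                    continue
                if end > lengths[gene] or start < 0:
                    rejects.out_of_bounds += 1
                    if len(rejects.examples) < 5:
                        rejects.examples.append(
                            f"line {lineno}: [{start},{end}) outside UTR "
                            f"of length {lengths[gene]}"
                        )
                    continue
            sites.append(BindingSite(col("mirfamily"), gene, col("transcriptid"),
                                     species, start, end, site_type))
    if rejects.total:
        logger.info("read_site_table: rejected %d sites (%d unknown gene, "
                    "%d out of bounds)", rejects.total, rejects.unknown_gene,
                    rejects.out_of_bounds)
    return sites, rejects


def to_targetscan_coords(site: BindingSite) -> tuple[int, int]:
    """Back-convert a site span to TargetScan 1-based inclusive columns."""
    return site.start + 1, site.end


_CONSERVATION_CODE = {
    "2": "broadly_conserved",
    "1": "conserved",
    "0": "poorly_conserved",
    "-1": "poorly_conserved",
}
_CONSERVATION_RANK = {"poorly_conserved": 0, "conserved": 1, "broadly_conserved": 2}


def read_family_info(path: str | Path, species: str | None = None) -> list[MirnaFamily]:
    """Read a family-info table (family, seed, conservation class).

    Accepts both the TargetScan numeric conservation codes (2/1/0/-1) and the
    internal dialect's class names. The TargetScan file has one row per mature
    miRNA; rows are deduplicated per family keeping the highest conservation
    class seen.
    """
    best: dict[str, MirnaFamily] = {}
    colmap: dict[str, int] | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if lineno == 1:
                cols = [re.sub(r"[^a-z0-9]", "", c.lower()) for c in fields]
                if any("family" in c or "seed" in c for c in cols):
                    colmap = {c: i for i, c in enumerate(cols)}
                    continue
            if colmap is not None:
                def col(*names: str) -> str | None:
                    for n in names:
                        for key, idx in colmap.items():
                            if n in key and idx < len(fields):
                                return fields[idx]
                    return None
                fam = col("family")
                seed = col("seed")
                sp = col("species")
                cons = col("conservation")
            else:
                if len(fields) < 3:
                    raise ParseError(
                        f"expected >=3 tab-separated columns, got {len(fields)}",
                        lineno,
                    )
                fam, seed, cons = fields[0], fields[1], fields[-1]
                sp = None
            if fam is None or seed is None or cons is None:
                raise ParseError("missing family/seed/conservation column", lineno)
            if species is not None and sp is not None and _norm_species(sp) != \
                    _norm_species(species):
                continue
            cons = cons.strip()
            klass = _CONSERVATION_CODE.get(cons, cons)
            if klass not in CONSERVATION_CLASSES:
                raise ParseError(f"unknown conservation class {cons!r}", lineno)
            rec = MirnaFamily(fam, seed[:7], klass)
            prev = best.get(fam)
            if prev is None or _CONSERVATION_RANK[klass] > \
                    _CONSERVATION_RANK[prev.conservation_class]:
                best[fam] = rec
    return [best[k] for k in sorted(best)]


@dataclass
class FilterReport:
    """Counts surviving the prediction filters."""

    n_families: int
    n_pairs: int
    n_sites: int


def filter_predictions(
    sites: list[BindingSite],
    families: list[MirnaFamily],
    require_mouse_conservation: bool = False,
    mouse_sites: list[BindingSite] | None = None,
) -> tuple[list[BindingSite], FilterReport]:
    """Apply the prediction filters: broadly conserved families only and,
    optionally, (family, gene) pairs that also have >=1 predicted site in mouse.

    Idempotent: filtering an already-filtered collection is a no-op.
    """
    broad = {f.family_id for f in families
             if f.conservation_class == "broadly_conserved"}
    kept = [s for s in sites if s.family_id in broad]
    if require_mouse_conservation:
        if mouse_sites is None:
            raise ConfigError(
                "require_mouse_conservation is set but no mouse site collection "
                "was provided"
            )
        mouse_pairs = {(s.family_id, s.gene_id) for s in mouse_sites}
        kept = [s for s in kept if (s.family_id, s.gene_id) in mouse_pairs]
    pairs = {(s.family_id, s.gene_id) for s in kept}
    report = FilterReport(
        n_families=len({s.family_id for s in kept}),
        n_pairs=len(pairs),
        n_sites=len(kept),
    )
    logger.info("filter_predictions: %d families, %d unique pairs, %d sites survive",
                report.n_families, report.n_pairs, report.n_sites)
    return kept, report


# ---------------------------------------------------------------------------
# internal dialect


def read_internal_utrs(tsv_path: str | Path, fasta_path: str | Path) -> list[UtrRecord]:
    """Rebuild UTR records from the internal ``utrs.tsv`` + ``utrs.fasta`` pair."""
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    records: list[UtrRecord] = []
    with open(tsv_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["gene_id", "transcript_id", "symbol", "species", "length"]
        if header != expected:
            raise ParseError(f"unexpected utrs.tsv header {header!r}", 1)
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 5:
                raise ParseError(
                    f"expected 5 tab-separated columns, got {len(fields)}", lineno
                )
            gene, tx, sym, sp, length = fields
            if gene not in seqs:
                raise ParseError(f"gene {gene} missing from FASTA", lineno)
            seq = seqs[gene]
            if len(seq) != int(length):
                raise ParseError(
                    f"gene {gene}: FASTA length {len(seq)} != recorded {length}",
                    lineno,
                )
            records.append(UtrRecord(gene, tx, sym, sp, seq))
    return records


def read_internal_sites(path: str | Path) -> list[BindingSite]:
    """Read the internal ``sites.tsv`` dialect (0-based half-open coordinates)."""
    sites: list[BindingSite] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["family_id", "gene_id", "transcript_id", "species", "start",
                    "end", "site_type"]
        if header != expected:
            raise ParseError(f"unexpected sites.tsv header {header!r}", 1)
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 7:
                raise ParseError(
                    f"expected 7 tab-separated columns, got {len(fields)}", lineno
                )
            fam, gene, tx, sp, start, end, st = fields
            sites.append(BindingSite(fam, gene, tx, sp, int(start), int(end), st))
    return sites


def read_factor_genes(path: str | Path) -> set[str]:
    """Read a factor-bound gene list, one gene id per line."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def read_internal_dataset(data_dir: str | Path) -> tuple[
    list[UtrRecord], list[BindingSite], set[str], list[MirnaFamily]
]:
    """Read a full internal bundle written by :func:`mirfeat.synth.write_dataset`."""
    d = Path(data_dir)
    utrs = read_internal_utrs(d / "utrs.tsv", d / "utrs.fasta")
    sites = read_internal_sites(d / "sites.tsv")
    factor = read_factor_genes(d / "factor_genes.txt")
    families = read_family_info(d / "families.tsv")
    return utrs, sites, factor, families
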