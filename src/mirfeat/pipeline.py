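"""End-to-end orchestration: prepare -> enrich -> pairs -> features -> stats.

Every stage reads its inputs from, and writes its outputs to, a single run
directory, so stages compose from the command line and a rerun of one stage
reproduces its exact output. One root seed drives everything; each stage
derives its own sub-seed deterministically, and identical config + seed
yields byte-identical output files.

In ``synthetic`` mode the run starts by generating a dataset; in
``targetscan`` mode it starts by reading the TargetScan flat files, applying
the prediction filters (broadly conserved families; optionally human-mouse
conserved targets) and normalizing everything into the same internal dialect,
after which the two modes are indistinguishable.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .enrich import EnrichmentResult, adjust_results, enrichment_test, select_families
from .errors import ConfigError
from .feat import (
    background_gc_profile,
    gc_profile_around_sites,
    intersite_table,
    multiplicity_table,
    site_feature_table,
    gc_content,
)
from .model import BindingSite, PairGroup, UtrRecord
from .pairs import PairSets, flatten, group_pairs, split_sets
from .stats import (
    Table1Row,
    compare_feature,
    fisher_multiplicity,
    per_family_fisher,
)
from .synth import SynthConfig, config_to_dict, generate_dataset, write_dataset
from . import tsio

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"

_STAGE_IDS = {"prepare": 1, "enrich": 2, "pairs": 3, "features": 4, "stats": 5}


def derive_seed(root: int, *keys: int) -> int:
    """Deterministic sub-seed below 2**31 from a root seed and integer keys."""
    ss = np.random.SeedSequence([int(root)] + [int(k) for k in keys])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    output_dir: Path
    mode: str = "synthetic"                  # "synthetic" or "targetscan"
    rng_seed: int = 0
    species: str = "9606"
    mouse_species: str = "10090"
    n_iter_enrich: int = 10_000
    n_iter_ratio: int = 10_000
    alpha: float = 0.05
    selection_rule: str = "any_dataset"      # or "all_datasets"
    enrich_tail: str = "upper"               # or "literal"
    r_mode: str = "site"                     # or "pair"
    fisher_alternative: str = "two-sided"
    family_matched_fisher: bool = False
    drop_truncated_bins: bool = False
    require_mouse_conservation: bool = False
    n_background_regions: int = 2000
    background_region_len: int = 1000
    synth: SynthConfig = field(default_factory=SynthConfig)
    # targetscan-mode inputs
    utr_path: Path | None = None
    site_path: Path | None = None
    family_path: Path | None = None
    mouse_site_path: Path | None = None
    factor_gene_paths: list[Path] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)
        for name in ("utr_path", "site_path", "family_path", "mouse_site_path"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, Path(v))
        self.factor_gene_paths = [Path(p) for p in self.factor_gene_paths]

    def validate(self) -> None:
        if self.mode not in ("synthetic", "targetscan"):
            raise ConfigError(f"mode must be synthetic or targetscan, got "
                              f"{self.mode!r}")
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.n_iter_enrich < 1 or self.n_iter_ratio < 1:
            raise ConfigError("iteration counts must be >= 1")
        if self.mode == "targetscan":
            required = {"utr_path": self.utr_path, "site_path": self.site_path,
                        "family_path": self.family_path}
            if self.require_mouse_conservation:
                required["mouse_site_path"] = self.mouse_site_path
            for name, p in required.items():
                if p is None:
                    raise ConfigError(f"targetscan mode requires {name}")
                if not Path(p).exists():
                    raise ConfigError(f"{name} does not exist: {p}")
            if not self.factor_gene_paths:
                raise ConfigError("targetscan mode requires factor_gene_paths")
            for p in self.factor_gene_paths:
                if not Path(p).exists():
                    raise ConfigError(f"factor gene list does not exist: {p}")
        self.synth.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        synth_raw = raw.pop("synth", {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        synth_known = {f.name for f in dataclasses.fields(SynthConfig)}
        unknown = set(synth_raw) - synth_known
        if unknown:
            raise ConfigError(f"unknown synth config keys: {sorted(unknown)}")
        if "enriched_families" in synth_raw:
            synth_raw["enriched_families"] = tuple(synth_raw["enriched_families"])
        return cls(synth=SynthConfig(**synth_raw), **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["output_dir"] = str(self.output_dir)
        for name in ("utr_path", "site_path", "family_path", "mouse_site_path"):
            if d[name] is not None:
                d[name] = str(d[name])
        d["factor_gene_paths"] = [str(p) for p in self.factor_gene_paths]
        d["synth"] = config_to_dict(self.synth)
        return d


@dataclass
class RunData:
    """In-memory view of the normalized run inputs."""

    utrs: list[UtrRecord]
    sites: list[BindingSite]
    factor_sets: dict[str, set[str]]   # dataset id -> gene set

    def utr_by_gene(self) -> dict[str, UtrRecord]:
        return {u.gene_id: u for u in self.utrs}

    @property
    def factor_union(self) -> set[str]:
        out: set[str] = set()
        for s in self.factor_sets.values():
            out |= s
        return out

    @property
    def universe(self) -> set[str]:
        return {s.gene_id for s in self.sites}


def _data_dir(cfg: RunConfig) -> Path:
    return cfg.output_dir / "data"


# ---------------------------------------------------------------------------
# stage: prepare


def stage_prepare(cfg: RunConfig) -> RunData:
    """Generate (synthetic) or read+filter (targetscan) the run inputs and
    normalize them into the internal dialect under ``<out>/data``."""
    cfg.validate()
    data = _data_dir(cfg)
    data.mkdir(parents=True, exist_ok=True)

    if cfg.mode == "synthetic":
        synth_cfg = dataclasses.replace(
            cfg.synth, rng_seed=derive_seed(cfg.rng_seed, _STAGE_IDS["prepare"]))
        ds = generate_dataset(synth_cfg)
        write_dataset(ds, data)
        factor_sets = {"synthetic": set(ds.factor_genes)}
        _write_factor_sets(data, factor_sets)
        return RunData(ds.utrs, ds.sites, factor_sets)

    utrs = tsio.read_utr_table(cfg.utr_path, cfg.species)
    families = tsio.read_family_info(cfg.family_path)
    sites, rejects = tsio.read_site_table(cfg.site_path, cfg.species, utrs)
    mouse_sites = None
    if cfg.require_mouse_conservation:
        mouse_sites, _ = tsio.read_site_table(cfg.mouse_site_path,
                                              cfg.mouse_species)
    sites, report = tsio.filter_predictions(
        sites, families, require_mouse_conservation=cfg.require_mouse_conservation,
        mouse_sites=mouse_sites)
    logger.info("prepare: %d UTRs; filters keep %d families / %d pairs / %d "
                "sites; %d sites rejected", len(utrs), report.n_families,
                report.n_pairs, report.n_sites, rejects.total)

    factor_sets = {}
    universe = {u.gene_id for u in utrs}
    for p in cfg.factor_gene_paths:
        factor_sets[Path(p).stem] = tsio.read_factor_genes(p) & universe

    from .synth import SyntheticDataset  # reuse the internal-dialect writer
    fam_table = [f for f in families
                 if f.conservation_class == "broadly_conserved"]
    bundle = SyntheticDataset(cfg.synth, utrs, sites,
                              set().union(*factor_sets.values()),
                              fam_table, truth={})
    write_dataset(bundle, data)
    _write_factor_sets(data, factor_sets)
    return RunData(utrs, sites, factor_sets)


def _write_factor_sets(data: Path, factor_sets: dict[str, set[str]]) -> None:
    d = data / "factor_sets"
    d.mkdir(parents=True, exist_ok=True)
    for ds_id, genes in sorted(factor_sets.items()):
        with open(d / f"{ds_id}.txt", "w") as fh:
            for g in sorted(genes):
                fh.write(g + "\n")


def load_run_data(cfg: RunConfig) -> RunData:
    """Re-read the normalized inputs written by :func:`stage_prepare`."""
    data = _data_dir(cfg)
    if not data.exists():
        raise ConfigError(f"run data not found under {data}; run prepare first")
    utrs, sites, _factor_union, _families = tsio.read_internal_dataset(data)
    factor_sets = {
        p.stem: tsio.read_factor_genes(p)
        for p in sorted((data / "factor_sets").glob("*.txt"))
    }
    return RunData(utrs, sites, factor_sets)


# ---------------------------------------------------------------------------
# stage: enrich


def stage_enrich(cfg: RunConfig, data: RunData | None = None) -> frozenset[str]:
    """Per-(dataset, family) corrected Monte-Carlo tests, BH, and selection."""
    data = data or load_run_data(cfg)
    universe = sorted(data.universe)
    families = sorted({s.family_id for s in data.sites})
    results_by_dataset: dict[str, list[EnrichmentResult]] = {}
    for d_idx, (ds_id, factor) in enumerate(sorted(data.factor_sets.items())):
        results = []
        for f_idx, fam in enumerate(families):
            seed = derive_seed(cfg.rng_seed, _STAGE_IDS["enrich"], d_idx, f_idx)
            results.append(enrichment_test(
                data.sites, fam, factor, universe,
                n_iter=cfg.n_iter_enrich, rng_seed=seed, dataset_id=ds_id,
                tail=cfg.enrich_tail, r_mode=cfg.r_mode))
        results_by_dataset[ds_id] = adjust_results(results)

    selection = select_families(results_by_dataset, alpha=cfg.alpha,
                                rule=cfg.selection_rule)
    out = cfg.output_dir
    selection.evidence.to_csv(out / "enrichment.tsv", sep="\t", index=False,
                              float_format=_FLOAT_FMT)
    with open(out / "selected_families.txt", "w") as fh:
        for fam in sorted(selection.selected):
            fh.write(fam + "\n")
    logger.info("enrich: %d of %d families selected at alpha=%g",
                len(selection.selected), len(families), cfg.alpha)
    return selection.selected


def load_selected_families(cfg: RunConfig) -> set[str]:
    p = cfg.output_dir / "selected_families.txt"
    if not p.exists():
        raise ConfigError(f"{p} not found; run the enrich stage first")
    return tsio.read_factor_genes(p)  # same one-id-per-line format


# ---------------------------------------------------------------------------
# stage: pairs


def _spans(group: PairGroup) -> str:
    return ";".join(f"{s.start}-{s.end}" for s in group.sites)


def stage_pairs(cfg: RunConfig, data: RunData | None = None,
                selected_families: set[str] | None = None) -> PairSets:
    """Build and write the selected/background pair sets."""
    data = data or load_run_data(cfg)
    if selected_families is None:
        selected_families = load_selected_families(cfg)
    groups = group_pairs(data.sites)
    pair_sets = split_sets(groups, selected_families, data.factor_union)
    out = cfg.output_dir
    for name, gs in (("pairs_selected.tsv", pair_sets.selected),
                     ("pairs_background.tsv", pair_sets.background),
                     ("pairs_background_in_factor.tsv",
                      pair_sets.background_in_factor_utrs)):
        with open(out / name, "w") as fh:
            fh.write("family_id\tgene_id\tmultiplicity\tsite_spans\n")
            for g in gs:
                fh.write(f"{g.family_id}\t{g.gene_id}\t{g.multiplicity}\t"
                         f"{_spans(g)}\n")
    return pair_sets


def _rebuild_pair_sets(cfg: RunConfig, data: RunData) -> PairSets:
    """Recompute the (deterministic) split instead of re-parsing span strings."""
    return split_sets(group_pairs(data.sites), load_selected_families(cfg),
                      data.factor_union)


# ---------------------------------------------------------------------------
# stage: features

_SET_NAMES = ("selected", "background", "background_in_factor")


def stage_features(cfg: RunConfig, data: RunData | None = None,
                   pair_sets: PairSets | None = None) -> None:
    """Write per-gene, per-site, GC-profile, multiplicity and inter-site tables."""
    data = data or load_run_data(cfg)
    if pair_sets is None:
        pair_sets = _rebuild_pair_sets(cfg, data)
    out = cfg.output_dir
    by_gene = data.utr_by_gene()
    universe = data.universe
    factor = data.factor_union & universe

    # gene-level features for the three gene sets entering the length/GC rows
    gene_sets = {
        "selected": {g.gene_id for g in pair_sets.selected},
        "factor": factor,
        "all": universe,
    }
    for name, genes in gene_sets.items():
        rows = [{"gene_id": g, "length": by_gene[g].length,
                 "gc": gc_content(by_gene[g].sequence)}
                for g in sorted(genes) if g in by_gene]
        pd.DataFrame(rows, columns=["gene_id", "length", "gc"]).to_csv(
            out / f"gene_features_{name}.tsv", sep="\t", index=False,
            float_format=_FLOAT_FMT)

    group_map = {
        "selected": pair_sets.selected,
        "background": pair_sets.background,
        "background_in_factor": pair_sets.background_in_factor_utrs,
    }
    for name in _SET_NAMES:
        groups = group_map[name]
        sites = flatten(groups)
        site_feature_table(sites, by_gene).to_csv(
            out / f"site_features_{name}.tsv", sep="\t", index=False,
            float_format=_FLOAT_FMT)
        gc_profile_around_sites(
            sites, by_gene, drop_truncated=cfg.drop_truncated_bins
        ).to_frame().to_csv(out / f"gc_profile_{name}.tsv", sep="\t",
                            index=False, float_format=_FLOAT_FMT)
        mc = multiplicity_table(groups)
        mc.per_family.to_csv(out / f"multiplicity_{name}.tsv", sep="\t",
                             index=False)
        intersite_table(groups, by_gene).to_csv(
            out / f"intersite_{name}.tsv", sep="\t", index=False,
            float_format=_FLOAT_FMT)

    # random-window background GC profiles for factor-bound vs all UTRs
    for i, (name, genes) in enumerate((("factor", factor), ("all", universe))):
        utrs = [by_gene[g] for g in sorted(genes) if g in by_gene]
        seed = derive_seed(cfg.rng_seed, _STAGE_IDS["features"], 90 + i)
        try:
            prof = background_gc_profile(
                utrs, region_len=cfg.background_region_len,
                n_regions=cfg.n_background_regions, rng_seed=seed)
        except Exception as exc:  # e.g. no eligible UTR in a tiny run
            logger.warning("background profile (%s) skipped: %s", name, exc)
            continue
        prof.to_frame().to_csv(out / f"gc_background_{name}.tsv", sep="\t",
                               index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# stage: stats


def _read_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _concat(frames: list[pd.DataFrame]) -> pd.DataFrame:
    nonempty = [f for f in frames if not f.empty]
    return pd.concat(nonempty) if nonempty else frames[0]


def stage_stats(cfg: RunConfig) -> pd.DataFrame:
    """Assemble the descriptive-statistics table with ratio-test p-values,
    plus the overall and per-family Fisher multiplicity tests."""
    out = cfg.output_dir
    gene = {n: _read_tsv(out / f"gene_features_{n}.tsv")
            for n in ("selected", "factor", "all")}
    site = {n: _read_tsv(out / f"site_features_{n}.tsv") for n in _SET_NAMES}
    inter = {n: _read_tsv(out / f"intersite_{n}.tsv") for n in _SET_NAMES}

    site_pool_factor = _concat([site["selected"], site["background_in_factor"]])
    site_pool_all = _concat([site["selected"], site["background"]])
    inter_pool_factor = _concat([inter["selected"],
                                 inter["background_in_factor"]])
    inter_pool_all = _concat([inter["selected"], inter["background"]])

    rows: list[Table1Row] = []
    k = 0

    def _next_seed() -> int:
        nonlocal k
        k += 1
        return derive_seed(cfg.rng_seed, _STAGE_IDS["stats"], k)

    def add(label, va, vb, pa, pb, set_a="selected", set_b="background"):
        rows.append(compare_feature(
            list(va), list(vb), list(pa), list(pb), label,
            set_a=set_a, set_b=set_b, n_iter=cfg.n_iter_ratio,
            rng_seed=_next_seed()))

    add("utr_length", gene["selected"]["length"], gene["all"]["length"],
        gene["factor"]["length"], gene["all"]["length"], set_b="all")
    add("utr_gc", gene["selected"]["gc"], gene["all"]["gc"],
        gene["factor"]["gc"], gene["all"]["gc"], set_b="all")
    for col in ("dist_start", "dist_end", "rel_pos"):
        add(col, site["selected"][col], site["background"][col],
            site_pool_factor[col], site_pool_all[col])
    for col, label in (("gap", "intersite_distance"), ("gap_gc", "intersite_gc")):
        vals = {n: inter[n][col].dropna() for n in _SET_NAMES}
        add(label, vals["selected"], vals["background"],
            inter_pool_factor[col].dropna(), inter_pool_all[col].dropna())
        add(label, vals["background_in_factor"], vals["background"],
            inter_pool_factor[col].dropna(), inter_pool_all[col].dropna(),
            set_a="background_in_factor")

    table1 = pd.DataFrame([dataclasses.asdict(r) for r in rows])
    table1.to_csv(out / "table1.tsv", sep="\t", index=False,
                  float_format=_FLOAT_FMT)

    # Fisher tests on multiplicity proportions
    mult = {n: _read_tsv(out / f"multiplicity_{n}.tsv") for n in
            ("selected", "background")}

    def _totals(df: pd.DataFrame) -> tuple[int, int]:
        if df.empty:
            return (0, 0)
        multi = int(df["pairs_multi"].sum())
        total = int(df["pairs_total"].sum())
        return (multi, total - multi)

    sel_counts, bg_counts = _totals(mult["selected"]), _totals(mult["background"])
    if sum(sel_counts) > 0 and sum(bg_counts) > 0:
        overall = fisher_multiplicity(sel_counts, bg_counts,
                                      alternative=cfg.fisher_alternative)
        pd.DataFrame([{
            "selected_multi": sel_counts[0], "selected_single": sel_counts[1],
            "background_multi": bg_counts[0], "background_single": bg_counts[1],
            "odds_ratio": overall.odds_ratio, "p": overall.p,
        }]).to_csv(out / "fisher_overall.tsv", sep="\t", index=False,
                   float_format=_FLOAT_FMT)
    else:
        logger.warning("stats: empty multiplicity table, overall Fisher skipped")

    data = load_run_data(cfg)
    pair_sets = _rebuild_pair_sets(cfg, data)
    per_fam, n_sig = per_family_fisher(
        pair_sets.selected, pair_sets.background, alpha=cfg.alpha,
        alternative=cfg.fisher_alternative,
        family_matched=cfg.family_matched_fisher)
    per_fam.to_csv(out / "fisher_per_family.tsv", sep="\t", index=False,
                   float_format=_FLOAT_FMT)
    logger.info("stats: %d of %d selected families significant in per-family "
                "Fisher", n_sig, len(per_fam))
    return table1


# ---------------------------------------------------------------------------
# report and manifest


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


def write_manifest(cfg: RunConfig) -> Path:
    """Echo the config, derived stage seeds, library versions and input
    checksums; contains nothing wall-clock so reruns are byte-identical."""
    import Bio
    import scipy
    import statsmodels

    inputs = {}
    if cfg.mode == "targetscan":
        for name in ("utr_path", "site_path", "family_path", "mouse_site_path"):
            p = getattr(cfg, name)
            if p is not None and Path(p).exists():
                inputs[name] = _sha256(Path(p))
        for p in cfg.factor_gene_paths:
            inputs[f"factor:{Path(p).stem}"] = _sha256(Path(p))
    manifest = {
        "mirfeat_version": __version__,
        "versions": {
            "numpy": np.__version__, "scipy": scipy.__version__,
            "pandas": pd.__version__, "statsmodels": statsmodels.__version__,
            "biopython": Bio.__version__,
        },
        "config": cfg.to_dict(),
        "stage_seeds": {name: derive_seed(cfg.rng_seed, sid)
                        for name, sid in _STAGE_IDS.items()},
        "input_checksums": inputs,
    }
    path = cfg.output_dir / "run_manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def make_report(out_dir: str | Path) -> str:
    """Human-readable summary of a run directory's result tables."""
    out = Path(out_dir)
    lines: list[str] = ["mirfeat run report", "=" * 60, ""]

    def section(title: str, fname: str, formatter) -> None:
        lines.append(title)
        lines.append("-" * len(title))
        p = out / fname
        if not p.exists():
            lines.append(f"[missing: {fname}]")
        else:
            try:
                formatter(_read_tsv(p))
            except Exception as exc:
                lines.append(f"[unreadable: {fname}: {exc}]")
        lines.append("")

    def fmt_table1(df: pd.DataFrame) -> None:
        if df.empty:
            lines.append("[empty contrast table]")
            return
        lines.append(df.to_string(index=False, float_format=lambda v: f"{v:.4g}"))

    section("Descriptive statistics and ratio-test p-values", "table1.tsv",
            fmt_table1)

    def fmt_profile(df: pd.DataFrame) -> None:
        lines.append(df.to_string(index=False,
                                  float_format=lambda v: f"{v:.4f}"))

    for name in _SET_NAMES:
        section(f"GC profile around sites ({name})", f"gc_profile_{name}.tsv",
                fmt_profile)
    for name in ("factor", "all"):
        section(f"Background GC profile, random windows ({name} UTRs)",
                f"gc_background_{name}.tsv", fmt_profile)

    def fmt_fisher(df: pd.DataFrame) -> None:
        if df.empty:
            lines.append("[no multiplicity contrast available]")
            return
        lines.append(df.to_string(index=False,
                                  float_format=lambda v: f"{v:.4g}"))

    section("Multiplicity: overall Fisher test", "fisher_overall.tsv",
            fmt_fisher)
    section("Multiplicity: per-family Fisher tests", "fisher_per_family.tsv",
            fmt_fisher)

    def fmt_inter(df: pd.DataFrame) -> None:
        if df.empty:
            lines.append("[no multi-site pairs]")
            return
        lines.append(f"n={len(df)}  mean gap={df['gap'].mean():.1f} nt  "
                     f"mean gap GC={df['gap_gc'].mean():.4f}")

    for name in _SET_NAMES:
        section(f"Inter-site summary ({name})", f"intersite_{name}.tsv",
                fmt_inter)
    return "\n".join(lines)


def stage_report(cfg: RunConfig) -> Path:
    text = make_report(cfg.output_dir)
    path = cfg.output_dir / "report.txt"
    path.write_text(text)
    return path


def run_pipeline(cfg: RunConfig) -> Path:
    """Run every stage in order and write the manifest; returns the run dir."""
    cfg.validate()
    cfg.output_dir.mkdir(parents=True, exist_ok=True)
    data = stage_prepare(cfg)
    selected = stage_enrich(cfg, data)
    pair_sets = stage_pairs(cfg, data, selected)
    stage_features(cfg, data, pair_sets)
    stage_stats(cfg)
    stage_report(cfg)
    write_manifest(cfg)
    return cfg.output_dir
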