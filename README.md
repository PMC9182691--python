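# mirfeat

Sequence-based miRNA target predictions carry high false-positive rates. One
way to concentrate true positives without new experiments is to intersect the
predictions with an independent layer of the gene-regulatory network: take a
transcription factor with a large ChIP-seq-derived target set, find the miRNA
families whose predicted targets are over-represented among the factor-bound
genes, and treat those (family, gene) pairs as an enriched-for-true subset.
Comparing binding-site features between that subset and the remaining
predictions then points to properties that discriminate real sites — useful
to anyone building or filtering miRNA target predictors.

`mirfeat` implements that strategy as a tested pipeline over TargetScan-style
flat files, together with a synthetic-data generator so every stage is
testable offline:

- **Family enrichment** (`mirfeat.enrich`). For n factor-bound genes in the
  prediction universe, m of them targeted by a family, the null draws n genes
  uniformly without replacement, counts the targeted genes z, and scales by a
  correction factor r = (sites in the factor-bound genes)/(sites in the draw)
  that absorbs the tendency of factor-bound genes to carry more predictions
  (e.g. longer 3'-UTRs): z\* = z·r, p = (1 + #{z\* ≥ m})/(n_iter + 1),
  Benjamini–Hochberg across families, selection at adjusted p < 0.05.
- **Pair sets** (`mirfeat.pairs`). Selected pairs = enriched family AND
  factor-bound gene; everything else is background; background pairs inside
  factor-bound UTRs serve as a control for UTR composition.
- **Features** (`mirfeat.feat`). 3'-UTR length and GC; per-site distances to
  the UTR ends and relative position (dist_start + dist_end + site length =
  UTR length, exactly); GC in 50-nt bins out to 500 nt around each site with
  99% CIs, against random 1000-nt background windows; multiplicity of
  same-family sites per pair; gaps between consecutive same-family sites and
  the GC of the gap.
- **Significance** (`mirfeat.stats`). A ratio-of-means resampling test
  (z = x/y observed; null z\* = x\*/y\* from without-replacement draws out of
  each group's complete dataset; one-sided by the direction of z) and
  Fisher's exact tests on multi-site proportions, overall and per family.
- **Synthetic data** (`mirfeat.synth`). Log-normal UTR lengths, positional GC
  with optional 5'→3' gradient, seed-match sites planted per family at
  Poisson rates, configurable enrichment inside a factor-bound subset,
  multi-site boost, and a GC dip around planted sites — all deterministic
  under one seed.

## Worked example

```bash
cd analysis
python 01_simulate.py && python 02_enrichment.py
```

prints (seed 1, desk-scale defaults):

```
genes:                500
predicted sites:      3864
unique (family,gene): 3033
factor-bound genes:   92
planted enriched:     ['fam-000', 'fam-001']

dataset_id family_id  n  m  n_iter  null_mean  null_sd     p_raw    p_adj
 synthetic   fam-000 89 56    2000       32.7    4.162 0.0004998 0.005997
 synthetic   fam-001 89 59    2000         34    4.543 0.0004998 0.005997
 synthetic   fam-002 89 24    2000      27.16    4.128    0.7761    0.995
 ...
selected families: ['fam-000', 'fam-001']
missed: none;  spurious: none
```

Family fam-000 targets m = 56 of the n = 89 factor-bound genes against a
corrected null of 32.7 ± 4.2, so it is selected; the 22 families planted
without enrichment all stay above the threshold. `03_pair_sets.py` through
`05_significance.py` continue the analysis: the 115 selected pairs show a
higher multi-site fraction than the 2,918 background pairs (0.478 vs 0.200,
Fisher p = 9.1e-11), shorter inter-site gaps, and a measured GC depression
of 0.062 in the two 50-nt bins flanking the sites (near-site mean 0.311 vs
outermost 0.373). At this deliberately dense desk-scale site rate the
outermost bins are themselves lowered by the dip windows of neighbouring
sites, so the apparent depression understates the planted 0.10; the sparse
regime used by the acceptance checks recovers the full depth.

The same pipeline runs on real TargetScan 7.2 downloads via
`mirfeat run-all --config cfg.yaml` with `mode: targetscan` (UTR sequence
table, predicted-targets table, family info table, and one factor-bound gene
list per ChIP-seq dataset).

## Layout

- `src/mirfeat/` — library (generator, readers, enrichment, pair sets,
  features, statistics, pipeline, CLI)
- `analysis/` — numbered narrative drivers over one shared run directory
- `tests/` — pytest suite incl. enumeration oracles and recovery checks
- `docs/methods.md` — models, conventions, parameter choices, limitations
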