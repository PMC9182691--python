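# Methods

This note documents the models and procedures `mirfeat` implements, the
conventions it fixes where the underlying method is ambiguous, the synthetic
data it is validated on, and its known limitations.

## The enrichment model

The unit of analysis is the (miRNA family, gene) pair: a family (miRNAs
sharing a seed, nucleotides 2–8) predicted to bind one or more sites in a
gene's representative 3'-UTR. Given a prediction universe — all genes with at
least one predicted site — and a factor-bound gene set from ChIP-seq, the
question is whether a family's targets are over-represented among the
factor-bound genes.

For one family and one factor dataset, let n be the number of factor-bound
genes in the universe and m the number of those targeted by the family
(gene-level: a gene with several sites counts once). Each Monte-Carlo
iteration draws n genes uniformly without replacement from the universe and
counts the targeted genes z. Factor-bound gene sets are not composition-
matched: they may carry systematically more predictions (longer 3'-UTRs are
the obvious mechanism), which would inflate m for every family. The
correction factor

    r = (total predicted sites, all families, in the factor-bound genes)
      / (total predicted sites, all families, in the draw)

rescales each null count to z\* = z·r, so the null inherits the factor set's
overall prediction load. The p-value is upper-tail with an add-one
pseudo-count, p = (1 + #{z\* ≥ m}) / (n_iter + 1); permutation p-values of
exactly zero are statistically improper and break the subsequent BH step.
Draws with zero total predictions (r undefined) are redrawn and counted.
Within a dataset, families are BH-adjusted; a family is selected when its
adjusted p falls below α = 0.05 in at least one dataset (`any_dataset`;
`all_datasets` is available). Defaults: n_iter = 10,000; the seed is always
explicit — there is no silent default RNG state.

Conventions fixed here:

- **Tail direction.** The procedure's prose counts null iterations with
  z\* *smaller* than m, yet small p-values are the ones treated as
  significant — internally inconsistent. The implementation uses the upper
  tail, which matches the selection rule's semantics; the literal variant is
  kept behind `tail="literal"` for audit.
- **r granularity.** "All predictions" is counted at site level, not pair
  level, because the confound being corrected (longer UTRs carry more sites)
  acts at site level; `r_mode="pair"` switches to distinct-family counts.
- **Universe.** Factor-bound genes are not excluded from the sampling
  universe, and draws are without replacement.

A structural property worth knowing: r absorbs the factor set's *average*
site excess, whatever its cause. When few families are enriched, their
contribution to the site totals is small, r stays near the UTR-length-driven
value, and the test has power. When enriched families dominate the site
totals, r cancels the very signal under test. This is a property of the
method; the desk-scale conditions below keep the enriched families a small
share of all families for exactly this reason.

## Pair sets and features

Selected pairs require both conditions — enriched family AND factor-bound
gene; all other pairs are background. Background pairs that sit in
factor-bound UTRs form a control subset that separates UTR-composition
effects from family-selection effects. The partition is exact: every unique
(family, gene) key lands in exactly one of selected/background.

Coordinates are 0-based half-open on the ungapped representative UTR
throughout; TargetScan's 1-based inclusive UTR columns are converted at the
I/O boundary and back-converted exactly. For a site [start, end) in a UTR of
length L:

    dist_start = start        (5' UTR end to site start)
    dist_end   = L − end      (site end to 3' UTR end)
    rel_pos    = start / L

so dist_start + dist_end + site length = L holds exactly per site, and the
same identity holds for the means over any site set. This is the only
anchoring under which the two mean distances and the mean site length add up
exactly to the mean UTR length, which keeps summary tables internally
consistent and auditable.

GC content is (G+C)/(non-N length); empty or all-N slices are undefined
(NaN), never 0. Site-flanking profiles use 50-nt bins spanning 500 nt on
each side, upstream bins measured back from the site start and downstream
bins forward from the site end, the site body excluded. Bins truncated by
UTR boundaries contribute their covered nucleotides; a site contributes to a
bin only when ≥ 1 nt is covered. The alternative — dropping near-edge sites
entirely — is available (`drop_truncated_bins`) but not default, since it
biases against short UTRs. Background profiles draw fixed 1000-nt windows:
an eligible UTR (length ≥ 1000) is chosen uniformly, then a start uniformly
within it; the two-level scheme weights genes rather than nucleotides, which
matches how the site-flanking profile weights sites. Per-bin 99% CIs are
normal-approximation: mean ± 2.576·sd/√n, undefined for n < 2.

Multiplicity counts pairs with ≥ 2 same-family sites. Inter-site features
use consecutive pairs (not all pairs) sorted by start — gap = next.start −
current.end, gap GC over the intervening sequence — and only strictly
positive gaps are emitted (adjacent/overlapping sites are counted and
excluded). Consecutive-pair counting yields at most multiplicity − 1
observations per pair, keeping the observation count linear in the number of
sites and each gap a disjoint stretch of sequence; all-pairs counting would
grow quadratically and double-count intervening sequence.

## The ratio-of-means resampling test

To compare a feature between the selected and background sets, the statistic
is the ratio of sample means z = x/y. Each of n_iter iterations draws
samples of the observed sizes without replacement from each group's
*complete dataset* (for the selected side: all values in factor-bound UTRs;
for the background side: all values), independently — there is no label
pooling — and forms z\* = x\*/y\*. For z > 1, p = (1 + #{z\* > z})/(n_iter
+ 1); for z < 1 the lower tail; z = 1 gives p = 1 by definition. Pools are
sorted internally so the result is invariant to input ordering, and a seed
makes it bit-reproducible.

This is not a classical permutation test: the null measures whether the
observed subsample is extreme *relative to its own pool*, not whether the
group labels are exchangeable. Its calibration is therefore characterized
empirically in the test suite (stable rejection rate near the nominal level
under a shared generating distribution) rather than assumed. One consequence
worth flagging: when the compared groups' pools genuinely differ, z\* is
centred near the pool-level ratio, so the test asks whether the selected
values deviate beyond their pool — a deliberate feature of the design it
reproduces.

Fisher's exact tests on the 2×2 of (multi, single) pair counts are
two-sided by default (sidedness is not specified by the source procedure;
one-sided is a flag). The per-family variant contrasts each selected
family's counts against the pooled background, not a family-matched
background (`family_matched` flag available).

## The synthetic generator

The generator emulates the statistical structure the analysis assumes, not
the biology of any particular genome:

- **UTR lengths**: log-normal, default log-mean 7.55 and log-sd 0.73, i.e.
  mean ≈ 2.5 kb with sd ≈ 2.1 kb — the length regime of genome-scale
  representative-UTR sets.
- **Composition**: per-position GC probability = base_gc (default 0.44,
  typical of 3'-UTR backgrounds) + a signed 5'→3' gradient per kb (default
  −0.02, a mild decrease) − gc_dip_depth (default 0.10) within
  dip_halfwidth (default 50 nt) of each planted site. The dip is realized by
  adjusting the G+C probability during sampling, never by editing sequence
  after the fact; site bodies are exempt, so every planted seed survives
  verbatim.
- **Sites**: each family has a distinct random 7-mer; per (family, gene) the
  site count is Poisson with mean site_rate × length(kb), multiplied by
  enrichment_factor when the family is enriched and the gene factor-bound.
  A multi-site boost adds Poisson(λ·(boost − 1)) further sites to pairs that
  already have one; `multi_site_boost_enriched` confines the boost to
  enriched-family × factor-gene pairs for recovery tests. The default boost
  is 1: at the desk-scale site rate the Poisson process alone already yields
  a realistic multi-site fraction (~14% of pairs, vs ~8–12% in genome-scale
  prediction sets).
- **Placement**: uniform, left-to-right, rejecting overlap with *any*
  already-planted site in the gene. Real prediction sets do contain
  cross-family overlaps, and the readers accept them; the generator avoids
  creating them because planting a second seed over the first would corrupt
  it and break the planted-coordinates ground truth.
- **Determinism**: one integer seed; per-gene sub-streams keyed by gene
  index, so increasing n_genes leaves earlier genes bit-identical.

What the generator does not emulate: cross-species conservation, site-type
efficacy ranking, realistic seed taxonomies, correlated gene families, or
any coupling between factor binding and UTR length. Passing recovery tests
therefore show that the pipeline detects the structures it models — planted
enrichment, planted dips, planted multiplicity — not that those structures
exist in any real dataset.

## Desk-scale conditions

The named conditions in `mirfeat/conditions.py` were fixed once, by power
reasoning, before being wired into the checks:

- **recovery**: 500 genes, 24 families, 2 enriched four-fold, site rate 0.12
  /kb/family, 20% factor-bound. At 500 genes — 26× fewer than a ~13,000-gene
  universe — scaling the per-kb density literally would leave ~4 targeted
  factor genes per family; instead the rate is raised so per-family target
  counts sit in the tens, the same regime as the full-scale data. Two of 24
  enriched keeps the enriched share of site totals near 8%, so r ≈ 1.2 and
  the expected margin between m and the corrected null is ≈ 4σ.
- **null**: as above with nothing planted; 8 families suffice for rate
  estimation across replicates.
- **gc-dip**: 3,000 genes, 4 families at 0.02 /kb, gradient disabled. Sparse
  sites keep other sites' dip windows out of the outermost bins (< 1% of
  outer-bin nucleotides), and the flat background avoids the gradient ×
  edge-truncation interaction that otherwise shifts near and outer bins'
  site populations apart; per-bin SE ≈ 0.003.

## Numerical and implementation notes

- Monte-Carlo sampling draws without replacement by taking the n smallest of
  a row of uniform keys (argpartition), chunked to bound memory; identical
  seeds give identical draws regardless of chunking.
- BH adjustment delegates to statsmodels' step-up implementation and is
  verified against the literal formula; Fisher's exact test delegates to
  scipy and is verified against a direct hypergeometric enumeration.
- All result files are plain TSV/JSON with fixed float formatting and no
  timestamps; a rerun with the same config and seed is byte-identical. The
  run manifest records config echo, derived stage seeds, library versions
  and input checksums.
- Degenerate inputs: empty feature vectors yield rows with undefined stats
  and p (never fabricated zeros); an empty selected set downgrades to a
  warning and the report marks the empty contrast; sites outside their UTR
  are rejected into a counted report at read time.

## Limitations

- The enrichment test self-penalizes when enriched families dominate the
  factor set's site totals (see above); interpret selections accordingly.
- The ratio test's null is nonstandard; its p-values are calibrated only in
  the empirical sense characterized by the test suite.
- The per-family Fisher test against a pooled background conflates family
  composition with multiplicity differences; the family-matched flag exists
  but has lower power at small counts.
- Full-scale runs depend on externally downloaded TargetScan 7.2 tables and
  factor-bound gene lists; the repository validates the machinery on
  synthetic data only.
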