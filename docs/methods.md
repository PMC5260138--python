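# Methods

## The gene-level methylation measurement

The per-cytosine level is the bisulfite read ratio `c_i = #C / (#C + #T)`.
A region's level is the **unweighted arithmetic mean of `c_i` over its
qualifying sites** — deliberately not the pooled-count ratio
`ΣC / Σ(C+T)`. The two coincide only under homogeneous coverage; pooling
lets a single deeply covered cytosine dominate a region, which the mean of
site levels avoids. The pooled estimator is available behind
`pooled=True` in `summarize_region`/`build_profiles` for users who want
read-weighted averages, but it is off by default and untested beyond its
distinctness.

A site qualifies for a (region, context) cell when

1. its context token matches (CG/CHG/CHH),
2. its position lies in the region interval (1-based, inclusive; **both
   strands count** — a CG dyad's two cytosines are two observations), and
3. its coverage is ≥ `min_coverage` (default 4 reads).

The cell is `NaN` unless ≥ `min_sites` (default 5) sites qualify. The site
count is taken **after** the coverage filter: a cytosine seen by fewer
than four reads contributes no observation at all, so it cannot help a
region reach the five-observation minimum. Both thresholds are
configurable; the defaults encode the intent that each reported average
rests on at least five observations of at least four read events each.
Because a level is undefined at zero coverage, the effective coverage
floor is never below 1 even if a caller passes 0.

### Intervals

* Gene body: the full annotated `gene` feature span. No exon/intron
  distinction is made.
* Promoter: TSS −2500 to TSS +500, strand-aware (the TSS of a '−' gene is
  the feature end, and the offsets mirror). The downstream 500 bp
  deliberately overlaps the start of the gene body. The lower bound is
  clamped at coordinate 1; no upper clamp is applied, since no
  chromosome-length source is required and an interval running past the
  last cytosine simply collects no sites.
* Promoter cells of structural-RNA genes (rRNA, tRNA/pre-tRNA, snRNA,
  snoRNA, miRNA, other RNA biotypes) and transposable elements are forced
  to `NaN` (site count 0). Only the promoter cells: the exclusion reflects
  that these genes' upstream regions are not ordinary Pol II promoters,
  which says nothing against their gene-body levels. The exclusion set is
  configurable.

## Input dialects

The two supported per-cytosine report layouts follow the emitting tools:

* CGmap (BS-Seeker2), 8 columns; the nucleotide column (`C`/`G`) encodes
  the strand, counts come from columns 7–8, and the precomputed level
  column is ignored (it is redundant with the counts). CGmaps contain
  covered sites only.
* CX_report (Bismark), 7 columns; coverage is the sum of the methylated
  and unmethylated columns. The genome-wide report includes uncovered
  sites; the parser retains them (the coverage filter removes them later),
  which is why both dialects of the same methylome reduce to identical
  mtables.

The mtable is tab-separated with a fixed header
(`gene_id pmt_CG pmt_CHG pmt_CHH gene_CG gene_CHG gene_CHH`), values at 4
decimal places, missing cells as the literal `NaN`. The reader accepts a
headerless variant via `header=False`. Writing is deterministic
(byte-identical re-writes), which makes dialect-equivalence and
reproducibility checks exact.

## Selection semantics

* DMG selection: pool value = unweighted mean over member datasets. A gene
  is evaluable only when non-NaN in every member of both pools
  (`require_complete=True`, the default) so a pool mean can never be
  driven by one replicate; `require_complete=False` switches to
  mean-of-available. The delta comparison is inclusive (`≥ Δ`), so
  boundary genes are selected. `direction='hyper'` means pool B above
  pool A.
* Threshold selection: `above` is `≥`, `below` is `≤` (both inclusive);
  NaN never satisfies a cutoff, hence fails `mode='all'` and is simply
  ignored by `mode='any'`.

These are deterministic filters, not statistical tests; no replicate
variance model is fitted.

## Enrichment

The p-value of a term is the upper-tail hypergeometric probability of
drawing at least the observed overlap in a random sample of the annotated
test-set size from the background — the point pmf alone (exposed as
`hypergeom_pmf` for testing) would *decrease* for overwhelming overlaps
and is not a significance measure. Binomial coefficients are computed in
log space (`gammaln`) so genome-scale backgrounds do not overflow;
out-of-support overlaps get probability 0, while impossible parameter
shapes (x > m, n > N, ...) raise.

The background N is the set of genes present in the annotation table, not
the whole genome: unannotated genes can never contribute to a term, so
counting them would deflate every p-value by a constant factor unrelated
to the annotation. Test-set genes absent from the background are dropped
and counted in the report's `n_dropped` diagnostic. Benjamini–Hochberg
adjusted p-values are computed over all tested terms
(`scipy.stats.false_discovery_control`) and reported in their own field;
the selection cutoff applies to the raw p-value.

## Clustering

Both axes of the gene × dataset matrix are clustered independently by
single linkage under Euclidean distance (scipy's implementation behind
the module surface), with the naive O(n³) agglomeration and the
minimum-spanning-tree edge-weight identity serving as independent test
oracles. Single linkage is monotone, so Newick branch lengths derived as
height differences are non-negative. NaN cells cannot be clustered; the
default policy drops incomplete genes (complete-case) and reports the
count, with a fill-value alternative behind `na_policy='fill'`. Leaf
order is the plain merge-induced order — no optimal-leaf-ordering
rotation is attempted, matching simple dendrogram renderers. Ties are
resolved deterministically by the implementation's scan order, so
repeated runs are identical; permuting the input can permute tie-broken
orderings but never the multiset of merge distances.

## The simulator

`simulate_methylome` emulates a small plant-like genome: by default 50
genes on 2 chromosomes of 250 kb, gene lengths 1–3 kb, biotypes 84%
protein-coding / 8% transposable element / 4% miRNA / 4% rRNA. Each
gene × compartment × context cell draws a true probability p from a Beta
distribution (concentration 8) around context means that follow the plant
pattern — gene body CG 0.55, CHG 0.15, CHH 0.05; promoter CG 0.30,
CHG 0.12, CHH 0.06. Site densities are 0.010/0.010/0.020 sites per bp for
CG/CHG/CHH, giving roughly 8–10 k sites per methylome (~150–200 per
gene). Coverage is Poisson with mean 10, with a 2% per-site dropout to
zero coverage representing unmappable cytosines — these exercise the
dialect difference, since Bismark reports them and BS-Seeker2 omits them.
Methylated counts are Binomial(coverage, p). Everything is driven by one
`numpy` Generator, so a seed fixes every output byte.

Design choices worth knowing:

* **No sites in the promoter/body overlap.** The promoter interval runs
  500 bp into the gene body, so a site there would contribute to both
  region averages, each with its own truth p. The generator leaves that
  stretch empty, making every site attributable to exactly one
  compartment; the parameter-recovery check can then compare each
  estimate against a single truth value. Real methylomes do have
  cytosines there — the measurement handles them fine (they simply enter
  both averages); only the truth bookkeeping wants them gone.
* **Genes are spaced so promoters never overlap neighboring genes**, for
  the same attribution reason. Real genomes overlap; the measurement does
  not care, the recovery harness does.
* **Context is a token, not a sequence.** No nucleotide sequence is
  synthesized; the di-/trinucleotide columns carry fixed consistent
  fillers. Downstream code never reads sequence.
* `resample_reads` redraws coverage and calls over the same genes and
  truth (a technical replicate); its `shift` argument moves selected
  genes' p, emulating a perturbed condition such as a silencing mutant.

What passing tests on this generator do **not** show: robustness to
chromosome-name mismatches between annotation and methylome, to spatial
autocorrelation of methylation, to bisulfite non-conversion error, or to
the bimodal gene-body CG landscape of real plant genomes. The generator
is a correctness harness, not a realism benchmark.

## Numerical and size choices

* Region averaging is exact summation (numpy mean over ≤ a few hundred
  site levels); the oracle comparison tolerance of 1e-12 reflects pure
  float-order effects.
* mtable serialization truncates to 4 decimals; round-trip tests assert
  equality at that precision (5e-5).
* Hypergeometric log-space evaluation is verified to 1e-10 relative
  against exact integer arithmetic over the full N ≤ 20 grid, and its
  pmf normalization to 1e-12 up to N = 500.
* Test and acceptance runs use 50-gene, ~10 k-site methylomes and 10–20
  seeds per property — large enough that every code path (NaN cells,
  excluded biotypes, clamped promoters, zero-coverage sites) occurs, while
  the whole suite stays fast.

## Limitations

* No statistical DMG testing (no Fisher/beta-binomial models), no DMR
  calling, no smoothing — selection is the deterministic delta/cutoff
  logic by design.
* No GO DAG propagation: terms are flat classes; ancestors are not
  credited.
* Promoters running past a chromosome end are not clamped upward.
* Single linkage chains: elongated clusters can absorb intermediates; that
  is a property of the linkage choice, kept deliberately.
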