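# methgene

Gene-level summarization and downstream analysis of whole-genome bisulfite
sequencing (WGBS) methylomes, in the three plant cytosine contexts.

## The problem

A WGBS experiment resolves 5-methylcytosine at single-base resolution: after
bisulfite conversion, an unmethylated C reads as T, so the methylation level
of cytosine *i* over the reads mapped to it is

    c_i = #C / (#C + #T)

A plant methylome report (BS-Seeker2 `CGmap` or Bismark `CX_report`) holds
tens of millions of such per-cytosine rows across the CG, CHG and CHH
sequence contexts (H = A, C or T), each maintained by a different enzymatic
pathway. That resolution is far finer than most comparative questions need
and far too bulky to pass around. `methgene` reduces a methylome to **six
numbers per gene** — the average level in each context over two
compartments, the promoter (TSS −2500 to +500, strand-aware) and the gene
body (the annotated gene span):

    level(region, context) = (1/k) * sum over qualifying sites of c_i

where a site qualifies when its context matches, it lies in the region, and
it is covered by at least 4 reads; the average is reported only when at
least k ≥ 5 sites qualify, and is `NaN` otherwise. Averaging at least five
observations, each based on at least four read events, damps the influence
of any single cytosine; a shift of 0.1 in a measurement reflects a
methylation-state change at ~10% of the observed sites. Promoter
measurements of structural-RNA genes (rRNA, tRNA, sn/snoRNA, miRNA, ...)
and transposable elements are suppressed, since their upstream regions are
not ordinary promoters.

The six measurements per gene are written to a small tab-delimited
**mtable** (`gene_id`, `pmt_CG`, `pmt_CHG`, `pmt_CHH`, `gene_CG`,
`gene_CHG`, `gene_CHH`), the exchange format for everything downstream:

- **DMG selection** — pairwise comparison of two dataset pools; a gene is a
  differentially methylated gene when |mean(pool B) − mean(pool A)| ≥ Δ
  (default 0.15) for a chosen measurement.
- **Threshold selection** — genes above/below a cutoff in any or all
  datasets.
- **Gene-list algebra** — Venn-region decomposition of up to four lists and
  Boolean combinations (`|`, `&`, `-`, `^`).
- **Enrichment** — hypergeometric over-representation of a list against a
  gene→term table: p = Σ_{k≥x} C(m,k)·C(N−m,n−k)/C(N,n) for a list of m
  annotated genes hitting x of a term's n members in a background of N.
- **2D clustering** — single-linkage agglomeration with Euclidean distance
  over genes and datasets, for heatmap presentation (merge trees exported
  as Newick).

A seeded simulator generates coherent toy inputs (GTF, paired
CGmap/CX_report, annotations) with known ground truth, so the whole
pipeline runs and is tested without any external data.

## Worked example

```python
from methgene.simulate import SimulationConfig, simulate_methylome
from methgene import parse_cgmap, read_gene_models, build_profiles, write_mtable, read_mtable

sim = simulate_methylome(SimulationConfig(seed=7, n_genes=50), "demo")
sites = list(parse_cgmap(sim.cgmap_path))
genes = read_gene_models(sim.gtf_path)          # promoter = TSS-2500 .. TSS+500
profiles = build_profiles(sites, genes)         # coverage >= 4, >= 5 sites per cell
write_mtable(profiles, "demo/leaf.mtable")
print(read_mtable("demo/leaf.mtable").head(5).to_string(float_format="%.3f"))
```

prints

```
          pmt_CG  pmt_CHG  pmt_CHH  gene_CG  gene_CHG  gene_CHH
gene_id
SIMG0000   0.592    0.230    0.013    0.490     0.203     0.028
SIMG0001     NaN      NaN      NaN    0.679     0.221     0.263
SIMG0002   0.477    0.066    0.237    0.434     0.104     0.025
SIMG0003   0.520    0.047    0.000    0.629     0.025     0.239
SIMG0004   0.310    0.160    0.041    0.520     0.151     0.000
```

Each row is one gene's six-measurement methylation profile. CG levels are
the highest and CHH the lowest, the canonical plant pattern the simulator
emulates; `SIMG0001` is a transposable-element gene, so its promoter cells
are suppressed to `NaN` while its gene-body cells are kept.

The same flow from a shell, plus a pool comparison:

```sh
methgene simulate --seed 7 -o fixtures/
methgene mtable -i fixtures/sim.cgmap --gtf fixtures/sim.gtf -o leaf.mtable
methgene dmg --pool-a ctl1.mtable,ctl2.mtable --pool-b mutant.mtable \
         --measurement gene_CHH --delta 0.15 -o dmgs.tsv
methgene enrich --genes list.txt --annotations fixtures/annotations.tsv -o enriched.tsv
methgene cluster --mtables ctl1.mtable,ctl2.mtable,mutant.mtable \
         --measurement gene_CHH -o heatmap/
```

`methgene mtable` also writes a `.summary.json` with the per-measurement
usable (non-NaN) counts — the first thing to check on real data, since a
low percentage of analyzable genes signals mismatched annotation or thin
coverage.

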