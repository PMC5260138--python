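"""Synthetic methylome generator.

Produces a coherent toy dataset — GTF gene annotation, ground-truth
methylome, paired CGmap and CX_report encodings of the same site set, and
gene → term annotation tables — so every part of the toolkit can be
exercised without downloading anything.

The generative model:

* Genes are laid out non-overlapping along each chromosome with enough
  spacing that no promoter interval touches another gene's intervals.
* Each gene × compartment × context cell draws a true methylation
  probability ``p`` from a Beta distribution whose mean follows the plant
  pattern (CG high, CHG intermediate, CHH low; gene bodies more CG-
  methylated than promoters).
* Cytosine sites are scattered uniformly at a per-context density.  Site
  coverage is Poisson with a configurable mean depth; methylated read
  counts are Binomial(coverage, p).  No real sequence is synthesized —
  downstream code only ever reads the context token.
* Sites are never placed in the 501-bp stretch where the promoter
  interval (which runs to TSS+500) overlaps the gene body, so every site
  is attributable to exactly one compartment and each region estimate can
  be compared against a single truth value.

Bismark reports every cytosine, covered or not, while BS-Seeker2 reports
only covered sites; the emitted CX_report therefore keeps zero-coverage
sites and the CGmap omits them, exercising both parser behaviors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from .core import (
    COMPARTMENTS,
    CONTEXTS,
    DEFAULT_PROMOTER_DOWNSTREAM,
    DEFAULT_PROMOTER_UPSTREAM,
    derive_promoter,
)
from .formats import CytosineSite, GeneModel


class ConfigError(ValueError):
    """The simulation configuration is infeasible."""


#: Plant-like context pattern: CG strongly methylated (more so in gene
#: bodies), CHG intermediate, CHH low.
DEFAULT_METHYLATION_PROBS: dict[tuple[str, str], float] = {
    ("promoter", "CG"): 0.30,
    ("promoter", "CHG"): 0.12,
    ("promoter", "CHH"): 0.06,
    ("gene_body", "CG"): 0.55,
    ("gene_body", "CHG"): 0.15,
    ("gene_body", "CHH"): 0.05,
}

DEFAULT_SITE_DENSITY: dict[str, float] = {"CG": 0.010, "CHG": 0.010, "CHH": 0.020}

DEFAULT_BIOTYPE_PROPORTIONS: dict[str, float] = {
    "protein_coding": 0.84,
    "transposable_element": 0.08,
    "miRNA": 0.04,
    "rRNA": 0.04,
}

# Deterministic filler tokens for the sequence-context columns the parsers
# never interpret.
_DINUC = {"CG": "CG", "CHG": "CA", "CHH": "CT"}
_TRINUC = {"CG": "CGA", "CHG": "CAG", "CHH": "CTT"}


@dataclass
class SimulationConfig:
    """Shape and noise parameters of a simulated methylome."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 250_000
    n_genes: int = 50
    gene_length: tuple[int, int] = (1000, 3000)
    biotype_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BIOTYPE_PROPORTIONS)
    )
    methylation_probs: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_METHYLATION_PROBS)
    )
    dispersion: float = 8.0       # Beta concentration of per-gene p around the context mean
    mean_depth: float = 10.0      # Poisson mean read coverage per site
    dropout: float = 0.02         # chance a site is unmappable and gets zero coverage
    site_density: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_SITE_DENSITY))
    promoter_upstream: int = DEFAULT_PROMOTER_UPSTREAM
    promoter_downstream: int = DEFAULT_PROMOTER_DOWNSTREAM
    edge_cases: bool = False      # add a TSS-near-origin gene per chromosome

    def __post_init__(self) -> None:
        for key, p in self.methylation_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"methylation probability {key} = {p} outside [0, 1]")
        if self.gene_length[0] > self.gene_length[1] or self.gene_length[0] < 1:
            raise ConfigError(f"bad gene_length range {self.gene_length}")
        if self.mean_depth < 0:
            raise ConfigError("mean_depth must be non-negative")


@dataclass
class RegionTruth:
    """Ground truth of one gene × compartment × context cell."""

    p: float
    sites: list[CytosineSite]

    @property
    def n_methylated(self) -> int:
        return sum(s.n_methylated for s in self.sites)

    @property
    def n_total(self) -> int:
        return sum(s.n_total for s in self.sites)


@dataclass
class GroundTruth:
    genes: list[GeneModel]
    regions: dict[tuple[str, str, str], RegionTruth]  # (gene_id, compartment, context)

    def all_sites(self) -> list[CytosineSite]:
        sites = [s for rt in self.regions.values() for s in rt.sites]
        sites.sort(key=lambda s: (s.chrom, s.pos))
        return sites


@dataclass
class SimulatedMethylome:
    gtf_path: Path
    cgmap_path: Path
    cx_path: Path
    truth: GroundTruth


def _place_genes(config: SimulationConfig, rng: np.random.Generator) -> list[GeneModel]:
    """Lay genes along chromosomes with promoter-safe spacing."""
    min_len, max_len = config.gene_length
    flank = config.promoter_upstream + config.promoter_downstream  # worst-case promoter reach
    spacing_lo, spacing_hi = 2 * flank - 1000, 2 * flank  # keeps promoters disjoint
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1
    needed = max(per_chrom) * (max_len + spacing_hi) + flank + 2000
    if needed > config.chrom_length:
        raise ConfigError(
            f"chrom_length {config.chrom_length} too short for {max(per_chrom)} genes "
            f"(need about {needed} bp)"
        )
    biotypes = list(config.biotype_proportions)
    probs = np.array([config.biotype_proportions[b] for b in biotypes], dtype=float)
    probs /= probs.sum()

    genes: list[GeneModel] = []
    idx = 0
    for c in range(config.n_chroms):
        chrom = f"Chr{c + 1}"
        cursor = flank + 500
        if config.edge_cases:
            # one '+' gene whose promoter clamps at coordinate 1
            length = int(rng.integers(min_len, max_len + 1))
            genes.append(_make_gene(f"SIMG{idx:04d}", "protein_coding", chrom, "+", 100, 100 + length - 1, config))
            idx += 1
            cursor = 100 + length + spacing_hi
        for _ in range(per_chrom[c]):
            length = int(rng.integers(min_len, max_len + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            biotype = biotypes[int(rng.choice(len(biotypes), p=probs))]
            genes.append(
                _make_gene(f"SIMG{idx:04d}", biotype, chrom, strand, cursor, cursor + length - 1, config)
            )
            idx += 1
            cursor += length + int(rng.integers(spacing_lo, spacing_hi + 1))
    return genes


def _make_gene(
    gene_id: str, biotype: str, chrom: str, strand: str, start: int, end: int, config: SimulationConfig
) -> GeneModel:
    tss = start if strand == "+" else end
    pstart, pend = derive_promoter(
        tss, strand, config.promoter_upstream, config.promoter_downstream
    )
    return GeneModel(gene_id, biotype, chrom, strand, start, end, pstart, pend)


def _site_zones(gene: GeneModel) -> dict[str, tuple[int, int]]:
    """Disjoint intervals in which to place each compartment's sites.

    The promoter interval extends past the TSS into the gene body; sites
    are confined to the upstream-only part of the promoter and the
    non-promoter part of the body so the two region averages measure
    distinct truths.
    """
    if gene.strand == "+":
        promoter = (gene.promoter_start, gene.body_start - 1)
        body = (max(gene.body_start, gene.promoter_end + 1), gene.body_end)
    else:
        promoter = (gene.body_end + 1, gene.promoter_end)
        body = (gene.body_start, min(gene.body_end, gene.promoter_start - 1))
    return {"promoter": promoter, "gene_body": body}


def simulate_truth(config: SimulationConfig) -> GroundTruth:
    """Draw the full ground truth: genes, per-cell p, realized site counts."""
    rng = np.random.default_rng(config.seed)
    genes = _place_genes(config, rng)
    regions: dict[tuple[str, str, str], RegionTruth] = {}
    contexts = list(CONTEXTS)
    densities = np.array([config.site_density[c] for c in contexts])
    for gene in genes:
        zones = _site_zones(gene)
        for comp in COMPARTMENTS:
            start, end = zones[comp]
            length = max(end - start + 1, 0)
            counts = rng.poisson(densities * length)
            total_sites = int(counts.sum())
            if total_sites > length:  # extremely dense config; cap
                counts = np.minimum(counts, length // len(contexts))
                total_sites = int(counts.sum())
            positions = (
                rng.choice(length, size=total_sites, replace=False) + start
                if total_sites
                else np.empty(0, dtype=int)
            )
            offset = 0
            for ctx, k in zip(contexts, counts):
                k = int(k)
                p0 = config.methylation_probs[(comp, ctx)]
                a = max(p0 * config.dispersion, 1e-6)
                b = max((1 - p0) * config.dispersion, 1e-6)
                p = float(rng.beta(a, b)) if 0 < p0 < 1 else float(p0)
                pos = np.sort(positions[offset : offset + k])
                offset += k
                sites = []
                for pp in pos:
                    strand = "+" if rng.random() < 0.5 else "-"
                    if rng.random() < config.dropout:
                        total = 0  # unmappable site: reported by Bismark, absent from CGmap
                    else:
                        total = int(rng.poisson(config.mean_depth))
                    meth = int(rng.binomial(total, p)) if total else 0
                    sites.append(CytosineSite(gene.chrom, int(pp), strand, ctx, meth, total))
                regions[(gene.gene_id, comp, ctx)] = RegionTruth(p=p, sites=sites)
    return GroundTruth(genes=genes, regions=regions)


def write_gtf(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
            fh.write(
                "\t".join(
                    [g.chrom, "methgene_sim", "gene", str(g.body_start), str(g.body_end),
                     ".", g.strand, ".", attrs]
                )
                + "\n"
            )


def write_cgmap(sites: list[CytosineSite], path: str | Path) -> None:
    """BS-Seeker2 dialect: covered sites only, nucleotide column encodes strand."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for s in sites:
            if s.n_total == 0:
                continue
            nuc = "C" if s.strand == "+" else "G"
            level = f"{s.n_methylated / s.n_total:.4f}"
            fh.write(
                "\t".join(
                    [s.chrom, nuc, str(s.pos), s.context, _DINUC[s.context], level,
                     str(s.n_methylated), str(s.n_total)]
                )
                + "\n"
            )


def write_cx_report(sites: list[CytosineSite], path: str | Path) -> None:
    """Bismark dialect: every site, including uncovered ones."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for s in sites:
            fh.write(
                "\t".join(
                    [s.chrom, str(s.pos), s.strand, str(s.n_methylated),
                     str(s.n_total - s.n_methylated), s.context, _TRINUC[s.context]]
                )
                + "\n"
            )


def simulate_methylome(config: SimulationConfig, outdir: str | Path) -> SimulatedMethylome:
    """Simulate one methylome and write its GTF, CGmap and CX_report files.

    Deterministic given ``config.seed``: repeated runs are byte-identical.
    The CGmap and CX_report encode the identical covered-site set.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = simulate_truth(config)
    sites = truth.all_sites()
    gtf = outdir / "sim.gtf"
    cgmap = outdir / "sim.cgmap"
    cx = outdir / "sim.cx_report.txt"
    write_gtf(truth.genes, gtf)
    write_cgmap(sites, cgmap)
    write_cx_report(sites, cx)
    return SimulatedMethylome(gtf_path=gtf, cgmap_path=cgmap, cx_path=cx, truth=truth)


def resample_reads(truth: GroundTruth, seed: int, shift: Mapping[str, float] | None = None) -> GroundTruth:
    """Redraw coverage and methylation calls over the same genes and truth p.

    Emulates a replicate (same underlying methylome, fresh reads) or, with
    ``shift`` mapping gene ids to additive changes in p (clipped to
    [0, 1]), a perturbed condition such as a silencing mutant.
    """
    rng = np.random.default_rng(seed)
    regions: dict[tuple[str, str, str], RegionTruth] = {}
    for key, rt in truth.regions.items():
        gene_id = key[0]
        p = rt.p
        if shift and gene_id in shift:
            p = float(np.clip(p + shift[gene_id], 0.0, 1.0))
        sites = []
        for s in rt.sites:
            total = int(rng.poisson(max(s.n_total, 1)))  # similar depth to the original site
            meth = int(rng.binomial(total, p)) if total else 0
            sites.append(replace(s, n_methylated=meth, n_total=total))
        regions[key] = RegionTruth(p=p, sites=sites)
    return GroundTruth(genes=truth.genes, regions=regions)


def simulate_annotations(
    gene_ids: list[str],
    seed: int = 0,
    n_terms: int = 15,
    term_size_range: tuple[int, int] = (5, 40),
    planted: Mapping[str, list[str]] | None = None,
) -> dict[str, frozenset[str]]:
    """Random gene → term classes, optionally with planted term memberships.

    Every gene receives at least one term so the annotated background
    equals the input gene list.
    """
    rng = np.random.default_rng(seed)
    terms: dict[str, set[str]] = {}
    lo, hi = term_size_range
    hi = min(hi, len(gene_ids))
    for t in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(gene_ids), size=size, replace=False)
        terms[f"TERM:{t:03d}"] = {gene_ids[i] for i in members}
    if planted:
        for term, members in planted.items():
            terms[term] = set(members)
    covered = set().union(*terms.values()) if terms else set()
    orphan_term = terms.setdefault("TERM:other", set())
    orphan_term.update(g for g in gene_ids if g not in covered)
    if not orphan_term:
        del terms["TERM:other"]
    return {t: frozenset(g) for t, g in terms.items()}


def write_annotation_tsv(terms: Mapping[str, frozenset[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for term in sorted(terms):
            for gene in sorted(terms[term]):
                fh.write(f"{gene}\t{term}\n")
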