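"""Gene-level methylation summarization.

The central reduction implemented here collapses a per-cytosine WGBS
methylation report to six numbers per gene: the average methylation level
in each of the three plant sequence contexts (CG, CHG, CHH) over two
compartments (promoter, gene body).

The per-site level is the classic bisulfite ratio

    c_i = (# reads calling C) / (# reads calling C or T)

and the region level is the *unweighted arithmetic mean* of ``c_i`` over
the qualifying sites in the region — not the pooled-count ratio
``sum(C) / sum(C+T)``.  A site qualifies when its sequence context matches,
its position falls inside the region (either strand), and its read coverage
is at least ``min_coverage`` (default 4).  A region measurement is reported
as NaN unless at least ``min_sites`` (default 5) sites qualify; averaging
over at least five observed cytosines damps the influence of any single
site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .formats import CytosineSite, GeneModel

CONTEXTS = ("CG", "CHG", "CHH")
COMPARTMENTS = ("promoter", "gene_body")

#: Column order of the six per-gene measurements, promoter first.
MEASUREMENTS = ("pmt_CG", "pmt_CHG", "pmt_CHH", "gene_CG", "gene_CHG", "gene_CHH")

#: measurement name -> (compartment, context)
MEASUREMENT_KEYS: dict[str, tuple[str, str]] = {
    **{f"pmt_{c}": ("promoter", c) for c in CONTEXTS},
    **{f"gene_{c}": ("gene_body", c) for c in CONTEXTS},
}

DEFAULT_MIN_COVERAGE = 4
DEFAULT_MIN_SITES = 5
DEFAULT_PROMOTER_UPSTREAM = 2500
DEFAULT_PROMOTER_DOWNSTREAM = 500

#: Biotypes whose *promoter* measurements are suppressed: structural RNA
#: genes and transposable elements, whose upstream regions are not ordinary
#: Pol II promoters.  Gene-body measurements are kept.
DEFAULT_EXCLUDED_PROMOTER_BIOTYPES = frozenset(
    {
        "rRNA",
        "tRNA",
        "pre_tRNA",
        "pre-tRNA",
        "snRNA",
        "snoRNA",
        "miRNA",
        "ncRNA",
        "lncRNA",
        "antisense_RNA",
        "otherRNA",
        "other_RNA",
        "transposable_element",
        "transposable_element_gene",
    }
)


class DataError(ValueError):
    """Inputs are structurally valid but unusable (empty stream, bad interval...)."""


@dataclass
class MethylationProfile:
    """The six measurements of one gene in one dataset (one mtable row).

    ``values`` maps (compartment, context) to a level in [0, 1] or NaN;
    ``n_sites`` holds the qualifying-site count behind each cell.  A cell is
    NaN exactly when its count fell below the site threshold (or the cell
    was suppressed by the promoter biotype exclusion, in which case the
    count is 0).
    """

    gene_id: str
    values: dict[tuple[str, str], float] = field(default_factory=dict)
    n_sites: dict[tuple[str, str], int] = field(default_factory=dict)

    def as_row(self) -> list[float]:
        """The six values in mtable column order."""
        return [self.values[MEASUREMENT_KEYS[m]] for m in MEASUREMENTS]

    def __getitem__(self, measurement: str) -> float:
        return self.values[MEASUREMENT_KEYS[measurement]]


def site_level(site: "CytosineSite") -> float:
    """Methylation level of a single cytosine: methylated / total reads."""
    if site.n_total < 1:
        raise DataError(
            f"site {site.chrom}:{site.pos} has zero coverage; level is undefined"
        )
    return site.n_methylated / site.n_total


def derive_promoter(
    tss: int,
    strand: str,
    upstream: int = DEFAULT_PROMOTER_UPSTREAM,
    downstream: int = DEFAULT_PROMOTER_DOWNSTREAM,
) -> tuple[int, int]:
    """Strand-aware promoter interval around a transcription start site.

    On '+' the promoter is ``[tss - upstream, tss + downstream]``; on '−'
    the offsets mirror.  The lower bound is clamped at coordinate 1; no
    upper clamp is applied (chromosome lengths are not required).
    """
    if strand == "+":
        return (max(1, tss - upstream), tss + downstream)
    if strand in ("-", "−"):
        return (max(1, tss - downstream), tss + upstream)
    raise ValueError(f"unknown strand {strand!r}")


def summarize_region(
    sites: Iterable["CytosineSite"],
    chrom: str,
    start: int,
    end: int,
    context: str,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    min_sites: int = DEFAULT_MIN_SITES,
    pooled: bool = False,
) -> tuple[float, int]:
    """Average methylation level over one region and context.

    Returns ``(level, n_qualifying)``; ``level`` is NaN when fewer than
    ``min_sites`` sites qualify.  With ``pooled=True`` the pooled-count
    ratio sum(C)/sum(C+T) is returned instead of the mean of site levels
    (off by default; the two differ under heterogeneous coverage).
    """
    if start > end:
        raise DataError(f"invalid interval [{start}, {end}] on {chrom}")
    if context not in CONTEXTS:
        raise ValueError(f"unknown context {context!r}")
    # a site's level is undefined at zero coverage, so the effective floor
    # is never below 1 even if the caller passes 0
    min_coverage = max(min_coverage, 1)
    levels: list[float] = []
    meth = tot = 0
    for s in sites:
        if (
            s.chrom == chrom
            and s.context == context
            and start <= s.pos <= end
            and s.n_total >= min_coverage
        ):
            levels.append(s.n_methylated / s.n_total)
            meth += s.n_methylated
            tot += s.n_total
    k = len(levels)
    if k < min_sites:
        return (math.nan, k)
    if pooled:
        return (meth / tot, k)
    return (sum(levels) / k, k)


class _SiteIndex:
    """Position-sorted per-(chrom, context) arrays for fast interval queries."""

    def __init__(self, sites: Iterable["CytosineSite"]):
        buckets: dict[tuple[str, str], list[tuple[int, int, int]]] = {}
        for s in sites:
            buckets.setdefault((s.chrom, s.context), []).append(
                (s.pos, s.n_methylated, s.n_total)
            )
        self._arrays: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for key, rows in buckets.items():
            rows.sort()
            arr = np.asarray(rows, dtype=np.int64)
            self._arrays[key] = (arr[:, 0], arr[:, 1], arr[:, 2])

    def query(
        self, chrom: str, context: str, start: int, end: int, min_coverage: int
    ) -> tuple[float, int]:
        """(mean site level or NaN-if-empty placeholder handled by caller, count)."""
        entry = self._arrays.get((chrom, context))
        if entry is None:
            return (math.nan, 0)
        pos, meth, tot = entry
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="right")
        m, t = meth[lo:hi], tot[lo:hi]
        mask = t >= max(min_coverage, 1)
        k = int(mask.sum())
        if k == 0:
            return (math.nan, 0)
        return (float(np.mean(m[mask] / t[mask])), k)

    def query_pooled(
        self, chrom: str, context: str, start: int, end: int, min_coverage: int
    ) -> tuple[float, int]:
        entry = self._arrays.get((chrom, context))
        if entry is None:
            return (math.nan, 0)
        pos, meth, tot = entry
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="right")
        m, t = meth[lo:hi], tot[lo:hi]
        mask = t >= max(min_coverage, 1)
        k = int(mask.sum())
        if k == 0:
            return (math.nan, 0)
        return (float(m[mask].sum() / t[mask].sum()), k)


def build_profiles(
    sites: Iterable["CytosineSite"],
    genes: Iterable["GeneModel"],
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    min_sites: int = DEFAULT_MIN_SITES,
    excluded_promoter_biotypes: frozenset[str] | set[str] = DEFAULT_EXCLUDED_PROMOTER_BIOTYPES,
    pooled: bool = False,
) -> list[MethylationProfile]:
    """Compute one :class:`MethylationProfile` per gene.

    Each of the six cells is the region average over the gene's promoter or
    gene-body interval in one context.  Promoter cells of genes whose
    biotype is in ``excluded_promoter_biotypes`` are forced to NaN with a
    site count of 0; gene-body cells are always computed.  Genes on
    chromosomes absent from the site stream come back all-NaN.
    """
    index = _SiteIndex(sites)
    query = index.query_pooled if pooled else index.query
    profiles: list[MethylationProfile] = []
    for g in genes:
        prof = MethylationProfile(gene_id=g.gene_id)
        intervals = {
            "promoter": (g.promoter_start, g.promoter_end),
            "gene_body": (g.body_start, g.body_end),
        }
        promoter_excluded = g.biotype in excluded_promoter_biotypes
        for comp, (start, end) in intervals.items():
            for ctx in CONTEXTS:
                key = (comp, ctx)
                if comp == "promoter" and promoter_excluded:
                    prof.values[key] = math.nan
                    prof.n_sites[key] = 0
                    continue
                level, k = query(g.chrom, ctx, start, end, min_coverage)
                prof.n_sites[key] = k
                prof.values[key] = level if k >= min_sites else math.nan
        profiles.append(prof)
    return profiles


def profile_summary(profiles: Iterable[MethylationProfile]) -> dict:
    """Usable-measurement report: per-measurement non-NaN counts and percentages."""
    profiles = list(profiles)
    n = len(profiles)
    per = {}
    for m in MEASUREMENTS:
        key = MEASUREMENT_KEYS[m]
        usable = sum(1 for p in profiles if not math.isnan(p.values[key]))
        per[m] = {
            "usable": usable,
            "percent": round(100.0 * usable / n, 2) if n else 0.0,
        }
    return {"genes_total": n, "measurements": per}
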