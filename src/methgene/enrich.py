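"""Hypergeometric over-representation analysis of gene lists.

A gene list of size ``m`` (after intersecting with the annotated
background of ``N`` genes) is tested against each annotation term (class
size ``n``, overlap ``x``) with the upper-tail hypergeometric probability

    p = sum_{k=x}^{min(m, n)} C(m, k) C(N-m, n-k) / C(N, n),

the chance of drawing at least ``x`` class members in a random size-``m``
sample from the background.  The point pmf is exposed separately.
Binomial coefficients are evaluated in log space (gammaln) so genome-scale
backgrounds do not overflow.

The background is the set of genes present in the annotation table, not
the whole genome: genes that carry no annotation cannot contribute to any
term and are dropped from the test set (their count is reported as a
diagnostic).  Benjamini–Hochberg adjusted p-values are reported alongside
the raw ones but play no role in the default cutoff selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

from scipy.special import gammaln
from scipy.stats import false_discovery_control

from .sets import GeneSet


@dataclass
class AnnotationTable:
    """Gene → term mapping with optional human-readable term labels."""

    gene_to_terms: dict[str, frozenset[str]]
    labels: dict[str, str] = field(default_factory=dict)

    @property
    def background(self) -> frozenset[str]:
        return frozenset(self.gene_to_terms)

    @property
    def N(self) -> int:
        """Background size: number of distinct annotated genes."""
        return len(self.gene_to_terms)

    def term_to_genes(self) -> dict[str, frozenset[str]]:
        inverted: dict[str, set[str]] = {}
        for gene, terms in self.gene_to_terms.items():
            for term in terms:
                inverted.setdefault(term, set()).add(gene)
        return {t: frozenset(g) for t, g in inverted.items()}

    @classmethod
    def from_tsv(cls, path: str | Path, labels_path: str | Path | None = None) -> "AnnotationTable":
        """Load a 2-column (gene_id, term_id) TSV, plus an optional
        2-column (term_id, label) TSV."""
        mapping: dict[str, set[str]] = {}
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise ValueError(f"{path}: line {lineno}: expected 2 tab-separated columns")
                gene, term = fields[0], fields[1]
                mapping.setdefault(gene, set()).add(term)
        labels: dict[str, str] = {}
        if labels_path is not None:
            with open(labels_path, encoding="utf-8") as fh:
                for line in fh:
                    line = line.rstrip("\n")
                    if not line:
                        continue
                    term, _, label = line.partition("\t")
                    labels[term] = label
        return cls({g: frozenset(t) for g, t in mapping.items()}, labels)


@dataclass
class EnrichmentResult:
    """One term's over-representation evidence: counts and tail probability."""

    term: str
    label: str
    x: int          # test-set genes carrying the term
    m: int          # annotated test-set size
    n: int          # term's class size in the background
    N: int          # background size
    p_value: float
    p_adjusted: float | None = None
    genes: frozenset[str] = frozenset()


def _check_bounds(x: int, N: int, m: int, n: int) -> None:
    if not (0 <= x <= m <= N and 0 <= n <= N):
        raise ValueError(f"hypergeometric bounds violated: x={x}, N={N}, m={m}, n={n}")


def _log_comb(a: float, b: float) -> float:
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def hypergeom_pmf(x: int, N: int, m: int, n: int) -> float:
    """P(exactly x of the m test genes fall in a class of n, background N).

    Overlaps outside the feasible support (x > n, or so small that the
    remaining n - x class members could not fit among the N - m non-test
    genes) have probability 0.
    """
    _check_bounds(x, N, m, n)
    if x > n or n - x > N - m:
        return 0.0
    return float(
        math.exp(_log_comb(m, x) + _log_comb(N - m, n - x) - _log_comb(N, n))
    )


def hypergeom_tail(x: int, N: int, m: int, n: int) -> float:
    """Upper tail P(overlap >= x); the enrichment p-value."""
    _check_bounds(x, N, m, n)
    total = 0.0
    for k in range(x, min(m, n) + 1):
        total += hypergeom_pmf(k, N, m, n)
    return min(total, 1.0)


@dataclass
class EnrichmentReport:
    """Results of one enrichment run plus bookkeeping diagnostics."""

    results: list[EnrichmentResult]
    m: int            # annotated test-set size used
    N: int            # background size
    n_dropped: int    # test genes absent from the annotated background


def enrich(
    test_set: GeneSet,
    annotations: AnnotationTable,
    p_cutoff: float = 0.05,
) -> EnrichmentReport:
    """Terms over-represented in a gene list, at a raw p-value cutoff.

    Every term with at least one test-set member is tested; results with
    ``p_value <= p_cutoff`` are returned sorted by (p_value, term id).
    ``p_adjusted`` carries the Benjamini–Hochberg value computed over all
    tested terms; it does not affect the cutoff.
    """
    background = annotations.background
    annotated = test_set.genes & background
    n_dropped = len(test_set.genes) - len(annotated)
    if not annotated:
        raise ValueError("no annotated genes in list")
    m, N = len(annotated), annotations.N

    tested: list[EnrichmentResult] = []
    for term, class_genes in sorted(annotations.term_to_genes().items()):
        hits = annotated & class_genes
        x = len(hits)
        if x < 1:
            continue
        n = len(class_genes)
        tested.append(
            EnrichmentResult(
                term=term,
                label=annotations.labels.get(term, term),
                x=x,
                m=m,
                n=n,
                N=N,
                p_value=hypergeom_tail(x, N, m, n),
                genes=hits,
            )
        )
    if tested:
        adjusted = false_discovery_control([r.p_value for r in tested], method="bh")
        for r, adj in zip(tested, adjusted):
            r.p_adjusted = float(adj)
    selected = [r for r in tested if r.p_value <= p_cutoff]
    selected.sort(key=lambda r: (r.p_value, r.term))
    return EnrichmentReport(results=selected, m=m, N=N, n_dropped=n_dropped)
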