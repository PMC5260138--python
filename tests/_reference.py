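"""Independent naive reference implementations used as test oracles.

Everything here is written with plain loops and direct set/combinatorial
algebra, deliberately sharing no code path with the package.
"""

import math
from itertools import combinations

import numpy as np


def naive_region_level(sites, chrom, start, end, context, min_coverage=4, min_sites=5):
    """Plain-loop filter-and-average of per-site levels."""
    levels = []
    for s in sites:
        if s.chrom != chrom or s.context != context:
            continue
        if s.pos < start or s.pos > end:
            continue
        if s.n_total < min_coverage:
            continue
        levels.append(s.n_methylated / s.n_total)
    if len(levels) < min_sites:
        return math.nan, len(levels)
    return sum(levels) / len(levels), len(levels)


def naive_profiles(sites, genes, min_coverage=4, min_sites=5, excluded=frozenset()):
    """Double-loop gene-level profiles: {gene_id: {measurement: value}}."""
    out = {}
    for g in genes:
        row = {}
        for comp, (start, end) in (
            ("promoter", (g.promoter_start, g.promoter_end)),
            ("gene_body", (g.body_start, g.body_end)),
        ):
            for ctx in ("CG", "CHG", "CHH"):
                name = ("pmt_" if comp == "promoter" else "gene_") + ctx
                if comp == "promoter" and g.biotype in excluded:
                    row[name] = math.nan
                    continue
                level, _ = naive_region_level(
                    sites, g.chrom, start, end, ctx, min_coverage, min_sites
                )
                row[name] = level
        out[g.gene_id] = row
    return out


def naive_dmg(frames_a, frames_b, measurement, delta, direction="both"):
    """Brute-force DMG scan over the union of gene ids.

    frames_a/frames_b: lists of {gene_id: value-or-nan} dicts.
    Returns {gene_id: (mean_a, mean_b, diff)}.
    """
    genes = set()
    for f in frames_a + frames_b:
        genes |= set(f)
    out = {}
    for g in sorted(genes):
        va = [f.get(g, math.nan) for f in frames_a]
        vb = [f.get(g, math.nan) for f in frames_b]
        if any(math.isnan(v) for v in va + vb):
            continue
        ma, mb = sum(va) / len(va), sum(vb) / len(vb)
        diff = mb - ma
        if abs(diff) < delta:
            continue
        if direction == "hyper" and diff <= 0:
            continue
        if direction == "hypo" and diff >= 0:
            continue
        out[g] = (ma, mb, diff)
    return out


def naive_threshold(frames, measurement_values, cutoff, side, mode):
    """Truth-table evaluation of the any/all threshold logic.

    frames: list of {gene_id: value-or-nan}.
    """
    genes = set()
    for f in frames:
        genes |= set(f)
    out = set()
    for g in genes:
        hits = []
        for f in frames:
            v = f.get(g, math.nan)
            if math.isnan(v):
                hits.append(False)
            elif side == "above":
                hits.append(v >= cutoff)
            else:
                hits.append(v <= cutoff)
        ok = any(hits) if mode == "any" else all(hits)
        if ok:
            out.add(g)
    return out


def enumerate_hypergeom(N, m, n):
    """Exact overlap distribution by enumerating every size-n draw.

    The background is range(N); the test set is its first m elements.
    Returns {x: probability} with exact rational arithmetic denominators.
    """
    from math import comb

    counts = {}
    total = 0
    test = set(range(m))
    for draw in combinations(range(N), n):
        x = len(test.intersection(draw))
        counts[x] = counts.get(x, 0) + 1
        total += 1
    return {x: c / total for x, c in sorted(counts.items())}, total


def exact_hypergeom_pmf(x, N, m, n):
    """Exact pmf via Python integer binomial coefficients."""
    from fractions import Fraction
    from math import comb

    if x > n or x > m or n - x > N - m:
        return 0.0
    return float(Fraction(comb(m, x) * comb(N - m, n - x), comb(N, n)))


def naive_single_linkage(points):
    """O(n^3) agglomerative single linkage over Euclidean row vectors.

    Returns (sorted merge-distance list, cluster history as frozensets).
    """
    points = np.asarray(points, dtype=float)
    clusters = [frozenset([i]) for i in range(len(points))]
    dist = lambda a, b: float(np.linalg.norm(points[a] - points[b]))
    merges = []
    history = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = min(dist(a, b) for a in clusters[i] for b in clusters[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
        merges.append(d)
        history.append(merged)
    return merges, history


def mst_edge_weights(points):
    """Sorted Euclidean MST edge weights (Prim's, plain loops)."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    in_tree = {0}
    weights = []
    best = {
        j: float(np.linalg.norm(points[0] - points[j])) for j in range(1, n)
    }
    while len(in_tree) < n:
        j = min(best, key=best.get)
        weights.append(best.pop(j))
        in_tree.add(j)
        for k in list(best):
            d = float(np.linalg.norm(points[j] - points[k]))
            if d < best[k]:
                best[k] = d
    return sorted(weights)


def component_partition(points, threshold):
    """Single-linkage flat clusters at a distance threshold, via connected
    components of the <=threshold graph (union-find)."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            if float(np.linalg.norm(points[i] - points[j])) <= threshold:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return {frozenset(g) for g in groups.values()}
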