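"""Single-linkage hierarchical clustering of the gene × dataset methylation matrix.

Used to organize heatmap presentations: genes (rows) and datasets
(columns) are each clustered agglomeratively with Euclidean distance on
their level vectors, inter-cluster distance being the minimum pairwise
item distance (single linkage).  Single linkage is monotone — merge
distances never decrease — and its merge distances coincide with the
sorted edge weights of the Euclidean minimum spanning tree.

The matrix must be NaN-free: by default genes with a missing level in any
selected dataset are dropped (complete-case), with the dropped count
reported; a fill-value alternative is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage, to_tree

from .core import MEASUREMENTS


@dataclass
class MethylationMatrix:
    """Rectangular, NaN-free gene × dataset level matrix for one measurement."""

    data: pd.DataFrame
    measurement: str
    n_dropped: int = 0


@dataclass
class Dendrogram:
    """An agglomerative merge tree over labelled items.

    ``linkage_matrix`` is in scipy's standard (n-1, 4) encoding: each row
    merges two node ids (originals are 0..n-1, merged clusters n, n+1, ...)
    at a given distance.
    """

    linkage_matrix: np.ndarray
    labels: list[str]

    @property
    def merges(self) -> list[tuple[int, int, float]]:
        return [(int(a), int(b), float(d)) for a, b, d, _ in self.linkage_matrix]

    @property
    def distances(self) -> np.ndarray:
        return self.linkage_matrix[:, 2].copy()

    @property
    def leaf_order(self) -> list[int]:
        """Original item indices in dendrogram left-to-right order."""
        return [int(i) for i in leaves_list(self.linkage_matrix)]

    @property
    def ordered_labels(self) -> list[str]:
        return [self.labels[i] for i in self.leaf_order]

    def to_newick(self) -> str:
        """Newick serialization with linkage distances as node heights.

        A leaf's branch length is its parent's merge distance; an internal
        node's branch length is the height difference to its parent (the
        root gets 0).  Heights are non-negative because single linkage is
        monotone.
        """
        root = to_tree(self.linkage_matrix)

        def fmt(node, parent_dist: float) -> str:
            length = max(parent_dist - node.dist, 0.0) if not node.is_leaf() else parent_dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = fmt(node.left, node.dist)
            right = fmt(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return fmt(root, root.dist) + ";"


def prepare_matrix(
    datasets: Mapping[str, pd.DataFrame],
    measurement: str,
    genes: Sequence[str] | None = None,
    na_policy: str = "drop_genes",
    fill_value: float = 0.0,
) -> MethylationMatrix:
    """Assemble the gene × dataset matrix for one measurement.

    ``genes`` optionally restricts rows to a selected gene list (order
    preserved, unknown ids ignored).  ``na_policy='drop_genes'`` removes
    genes with any missing level and reports how many were dropped;
    ``'fill'`` substitutes ``fill_value`` instead.  At least 2 rows and 2
    columns must remain.
    """
    if measurement not in MEASUREMENTS:
        raise ValueError(f"unknown measurement {measurement!r}; expected one of {MEASUREMENTS}")
    if na_policy not in ("drop_genes", "fill"):
        raise ValueError(f"na_policy must be drop_genes/fill, got {na_policy!r}")
    mat = pd.DataFrame({name: frame[measurement] for name, frame in datasets.items()})
    if genes is not None:
        keep = [g for g in genes if g in mat.index]
        mat = mat.loc[keep]
    if na_policy == "drop_genes":
        complete = mat.dropna()
        n_dropped = len(mat) - len(complete)
        mat = complete
    else:
        n_dropped = 0
        mat = mat.fillna(fill_value)
    if mat.shape[0] < 2 or mat.shape[1] < 2:
        raise ValueError(
            f"matrix too small to cluster: {mat.shape[0]} genes x {mat.shape[1]} datasets remain"
        )
    return MethylationMatrix(data=mat, measurement=measurement, n_dropped=n_dropped)


def single_linkage(matrix: pd.DataFrame | np.ndarray, labels: Sequence[str] | None = None) -> Dendrogram:
    """Single-linkage agglomeration of the rows of ``matrix`` under
    Euclidean distance."""
    if isinstance(matrix, pd.DataFrame):
        labels = list(matrix.index) if labels is None else list(labels)
        values = matrix.to_numpy(dtype=float)
    else:
        values = np.asarray(matrix, dtype=float)
        labels = [str(i) for i in range(values.shape[0])] if labels is None else list(labels)
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    if np.isnan(values).any():
        raise ValueError("matrix contains NaN; run prepare_matrix first")
    z = linkage(values, method="single", metric="euclidean")
    return Dendrogram(linkage_matrix=z, labels=labels)


def cluster_heatmap(
    matrix: MethylationMatrix,
) -> tuple[Dendrogram, Dendrogram, pd.DataFrame]:
    """Cluster both axes and reorder the matrix by the two leaf orders.

    Returns (row dendrogram over genes, column dendrogram over datasets,
    reordered matrix).
    """
    rows = single_linkage(matrix.data)
    cols = single_linkage(matrix.data.T)
    reordered = matrix.data.iloc[rows.leaf_order, cols.leaf_order]
    return rows, cols, reordered


def write_heatmap_dir(
    matrix: MethylationMatrix, outdir: str | Path
) -> tuple[Dendrogram, Dendrogram, pd.DataFrame]:
    """Run :func:`cluster_heatmap` and serialize matrix + trees to ``outdir``.

    Writes ``matrix.tsv`` (reordered levels), ``genes.nwk`` and
    ``datasets.nwk`` (Newick merge trees with distances as heights).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows, cols, reordered = cluster_heatmap(matrix)
    reordered.to_csv(outdir / "matrix.tsv", sep="\t", float_format="%.4f", index_label="gene_id")
    (outdir / "genes.nwk").write_text(rows.to_newick() + "\n", encoding="utf-8")
    (outdir / "datasets.nwk").write_text(cols.to_newick() + "\n", encoding="utf-8")
    return rows, cols, reordered
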