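"""Selecting genes by methylation values across datasets.

Two deterministic workflows:

* **DMG selection** — a pairwise comparison of two dataset pools.  Each
  pool's value for a gene is the unweighted mean of its member datasets'
  values for one of the six measurements; a gene is a differentially
  methylated gene (DMG) when the pool difference reaches a user delta
  (inclusive) in the requested direction.  This is a delta filter, not a
  statistical test.
* **Threshold selection** — genes whose measurement is above or below a
  cutoff in at least one (``any``) or every (``all``) dataset.

NaN policy: by default a gene is evaluable for DMG selection only when its
measurement is non-NaN in *every* member of both pools, so a pool mean is
never driven by a single replicate; ``require_complete=False`` switches to
the mean of the available members.  NaN never satisfies a threshold, and a
NaN in any dataset fails ``mode='all'``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import MEASUREMENTS
from .sets import GeneSet

DEFAULT_DELTA = 0.15  # the demo criterion: pool difference >= 0.15


@dataclass
class DatasetPool:
    """An experimental condition: a label plus its member datasets' mtables."""

    label: str
    members: Mapping[str, pd.DataFrame]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"pool {self.label!r} has no member datasets")


@dataclass
class SelectionCriterion:
    """What counts as differentially methylated.

    ``direction``: 'hyper' keeps genes where pool B exceeds pool A,
    'hypo' the reverse, 'both' either sign.  ``biotypes``/``chroms`` are
    optional allow-lists applied after the value filter (they need
    ``gene_info``; see :func:`select_dmgs`).
    """

    measurement: str
    delta: float = DEFAULT_DELTA
    direction: str = "both"
    biotypes: Sequence[str] | None = None
    chroms: Sequence[str] | None = None

    def __post_init__(self) -> None:
        if self.measurement not in MEASUREMENTS:
            raise ValueError(
                f"unknown measurement {self.measurement!r}; expected one of {MEASUREMENTS}"
            )
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError(f"delta must be in [0, 1], got {self.delta}")
        if self.direction not in ("hyper", "hypo", "both"):
            raise ValueError(f"direction must be hyper/hypo/both, got {self.direction!r}")


def _pool_matrix(pool: DatasetPool, measurement: str) -> pd.DataFrame:
    cols = {name: frame[measurement] for name, frame in pool.members.items()}
    return pd.DataFrame(cols)


def _apply_allow_lists(
    genes: pd.Index,
    criterion: SelectionCriterion,
    gene_info: pd.DataFrame | None,
) -> pd.Index:
    if criterion.biotypes is None and criterion.chroms is None:
        return genes
    if gene_info is None:
        raise ValueError("biotype/chrom filters need a gene_info table")
    keep = pd.Series(True, index=genes)
    info = gene_info.reindex(genes)
    if criterion.biotypes is not None:
        keep &= info["biotype"].isin(set(criterion.biotypes))
    if criterion.chroms is not None:
        keep &= info["chrom"].isin(set(criterion.chroms))
    return genes[keep.fillna(False).to_numpy()]


def select_dmgs(
    pool_a: DatasetPool,
    pool_b: DatasetPool,
    criterion: SelectionCriterion,
    gene_info: pd.DataFrame | None = None,
    require_complete: bool = True,
) -> GeneSet:
    """Differentially methylated genes between two pools.

    Returns a :class:`GeneSet` whose ``table`` records, for each selected
    gene, ``mean_a``, ``mean_b`` and the signed difference
    ``diff = mean_b - mean_a``.  The delta comparison is inclusive
    (``|diff| >= delta`` selects).
    """
    mat_a = _pool_matrix(pool_a, criterion.measurement)
    mat_b = _pool_matrix(pool_b, criterion.measurement)
    genes = mat_a.index.union(mat_b.index)
    mat_a, mat_b = mat_a.reindex(genes), mat_b.reindex(genes)

    if require_complete:
        evaluable = mat_a.notna().all(axis=1) & mat_b.notna().all(axis=1)
    else:
        evaluable = mat_a.notna().any(axis=1) & mat_b.notna().any(axis=1)
    mean_a = mat_a.mean(axis=1)[evaluable]
    mean_b = mat_b.mean(axis=1)[evaluable]
    diff = mean_b - mean_a

    selected = diff.abs() >= criterion.delta
    if criterion.direction == "hyper":
        selected &= diff > 0
    elif criterion.direction == "hypo":
        selected &= diff < 0
    index = diff.index[selected]
    index = _apply_allow_lists(index, criterion, gene_info)

    table = pd.DataFrame(
        {"mean_a": mean_a[index], "mean_b": mean_b[index], "diff": diff[index]}
    ).rename_axis("gene_id")
    provenance = (
        f"dmg {criterion.measurement} |{pool_b.label} - {pool_a.label}| >= {criterion.delta} "
        f"({criterion.direction})"
    )
    return GeneSet(
        name=f"dmg_{pool_a.label}_{pool_b.label}",
        genes=frozenset(index),
        provenance=provenance,
        table=table,
    )


def select_by_threshold(
    datasets: Mapping[str, pd.DataFrame],
    measurement: str,
    cutoff: float,
    side: str = "above",
    mode: str = "any",
    gene_info: pd.DataFrame | None = None,
    biotypes: Sequence[str] | None = None,
    chroms: Sequence[str] | None = None,
) -> GeneSet:
    """Genes whose measurement clears a cutoff across datasets.

    ``side='above'`` keeps values >= cutoff, ``'below'`` values <= cutoff
    (both inclusive).  ``mode='any'`` requires at least one dataset to
    satisfy the cutoff, ``'all'`` every dataset; NaN never satisfies, so a
    NaN in any dataset fails ``mode='all'``.
    """
    if measurement not in MEASUREMENTS:
        raise ValueError(f"unknown measurement {measurement!r}; expected one of {MEASUREMENTS}")
    if not datasets:
        raise ValueError("no datasets given")
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff must be in [0, 1], got {cutoff}")
    if side not in ("above", "below"):
        raise ValueError(f"side must be above/below, got {side!r}")
    if mode not in ("any", "all"):
        raise ValueError(f"mode must be any/all, got {mode!r}")

    mat = pd.DataFrame({name: frame[measurement] for name, frame in datasets.items()})
    satisfies = (mat >= cutoff) if side == "above" else (mat <= cutoff)
    satisfies &= mat.notna()  # NaN comparisons are already False; be explicit
    hit = satisfies.any(axis=1) if mode == "any" else satisfies.all(axis=1)
    index = mat.index[hit]
    criterion = SelectionCriterion(measurement, 0.0, "both", biotypes, chroms)
    index = _apply_allow_lists(index, criterion, gene_info)

    provenance = f"threshold {measurement} {side} {cutoff} mode={mode}"
    return GeneSet(
        name=f"threshold_{measurement}",
        genes=frozenset(index),
        provenance=provenance,
        table=mat.loc[index].rename_axis("gene_id"),
    )
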