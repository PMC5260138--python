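"""Single-linkage clustering: oracles, invariants, and heatmap preparation."""

import math

import numpy as np
import pandas as pd
import pytest

from _reference import mst_edge_weights, naive_single_linkage
from methgene.cluster import (
    Dendrogram,
    MethylationMatrix,
    cluster_heatmap,
    prepare_matrix,
    single_linkage,
    write_heatmap_dir,
)
from methgene.core import MEASUREMENTS


def mtable_frame(values, genes, measurement="gene_CHH"):
    data = pd.DataFrame(0.0, index=genes, columns=list(MEASUREMENTS))
    data[measurement] = values
    return data


class TestPrepareMatrix:
    def test_nan_genes_dropped_and_counted(self):
        genes = ["G0", "G1", "G2"]
        frames = {
            "d1": mtable_frame([0.1, 0.2, 0.3], genes),
            "d2": mtable_frame([0.1, math.nan, 0.3], genes),
        }
        mat = prepare_matrix(frames, "gene_CHH")
        assert mat.data.shape == (2, 2)
        assert mat.n_dropped == 1
        assert list(mat.data.index) == ["G0", "G2"]

    def test_fill_policy_keeps_all_genes(self):
        genes = ["G0", "G1"]
        frames = {
            "d1": mtable_frame([0.1, math.nan], genes),
            "d2": mtable_frame([0.2, 0.3], genes),
        }
        mat = prepare_matrix(frames, "gene_CHH", na_policy="fill", fill_value=0.0)
        assert mat.data.loc["G1", "d1"] == 0.0 and mat.n_dropped == 0

    def test_all_nan_measurement_errors(self):
        genes = ["G0", "G1"]
        frames = {
            "d1": mtable_frame([math.nan, math.nan], genes),
            "d2": mtable_frame([0.1, 0.2], genes),
        }
        with pytest.raises(ValueError, match="too small"):
            prepare_matrix(frames, "gene_CHH")

    def test_cells_pass_through_verbatim(self, rng):
        genes = [f"G{i}" for i in range(10)]
        values = {f"d{j}": rng.random(10) for j in range(3)}
        frames = {k: mtable_frame(v, genes) for k, v in values.items()}
        mat = prepare_matrix(frames, "gene_CHH")
        for k, v in values.items():
            np.testing.assert_array_equal(mat.data[k].to_numpy(), v)

    def test_gene_list_restriction_preserves_order(self, rng):
        genes = [f"G{i}" for i in range(10)]
        frames = {f"d{j}": mtable_frame(rng.random(10), genes) for j in range(2)}
        mat = prepare_matrix(frames, "gene_CHH", genes=["G5", "G2", "G7", "NOPE"])
        assert list(mat.data.index) == ["G5", "G2", "G7"]


class TestSingleLinkage:
    def test_identical_rows_merge_at_zero(self):
        dend = single_linkage(np.array([[0.5, 0.5], [0.5, 0.5]]))
        (merge,) = dend.merges
        assert merge[2] == 0.0

    def test_one_dimensional_chain(self):
        dend = single_linkage(np.array([[0.0], [1.0], [3.0]]))
        assert [round(d, 10) for d in dend.distances] == [1.0, 2.0]

    @pytest.mark.parametrize("seed", range(5))
    def test_distances_match_naive_reference_and_mst(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.random((10, 3))
        dend = single_linkage(x)
        naive_dists, _ = naive_single_linkage(x)
        np.testing.assert_allclose(sorted(dend.distances), sorted(naive_dists), atol=1e-12)
        np.testing.assert_allclose(sorted(dend.distances), mst_edge_weights(x), atol=1e-12)

    def test_monotone_merges(self, rng):
        x = rng.random((15, 4))
        d = single_linkage(x).distances
        assert np.all(np.diff(d) >= -1e-12)

    def test_permutation_invariance_of_distance_multiset(self, rng):
        x = rng.random((12, 3))
        perm = rng.permutation(12)
        d1 = sorted(single_linkage(x).distances)
        d2 = sorted(single_linkage(x[perm]).distances)
        np.testing.assert_allclose(d1, d2, atol=1e-12)

    def test_too_few_items(self):
        with pytest.raises(ValueError, match="at least 2"):
            single_linkage(np.array([[1.0, 2.0]]))

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            single_linkage(np.array([[1.0], [math.nan]]))


class TestClusterHeatmap:
    def _block_matrix(self, rng, n_low=6, n_high=6, n_cols=4, noise=0.02):
        low = rng.normal(0.1, noise, (n_low, n_cols))
        high = rng.normal(0.9, noise, (n_high, n_cols))
        values = np.clip(np.vstack([low, high]), 0, 1)
        perm = rng.permutation(n_low + n_high)
        genes = [f"G{i}" for i in range(n_low + n_high)]
        frame = pd.DataFrame(values[perm], index=[genes[i] for i in perm],
                             columns=[f"d{j}" for j in range(n_cols)])
        labels = {genes[i]: ("low" if i < n_low else "high") for i in range(n_low + n_high)}
        return frame, labels

    def test_planted_blocks_contiguous_in_leaf_order(self, rng):
        frame, labels = self._block_matrix(rng)
        mat = MethylationMatrix(frame, "gene_CHH")
        rows, _, reordered = cluster_heatmap(mat)
        ordered_groups = [labels[g] for g in reordered.index]
        switches = sum(a != b for a, b in zip(ordered_groups, ordered_groups[1:]))
        assert switches == 1  # the two groups form contiguous runs

    def test_replicates_merge_before_distinct_conditions(self, rng):
        """Columns simulated as two control replicates + three distinct mutants:
        the replicates join first in the column tree."""
        n = 40
        base = rng.random(n)
        cols = {
            "ctl1": base + rng.normal(0, 0.01, n),
            "ctl2": base + rng.normal(0, 0.01, n),
            "mutA": rng.random(n),
            "mutB": rng.random(n),
            "mutC": rng.random(n),
        }
        frame = pd.DataFrame(cols, index=[f"G{i}" for i in range(n)]).clip(0, 1)
        _, col_dend, _ = cluster_heatmap(MethylationMatrix(frame, "gene_CHH"))
        first_a, first_b, _ = col_dend.merges[0]
        merged = {col_dend.labels[first_a], col_dend.labels[first_b]}
        assert merged == {"ctl1", "ctl2"}

    def test_reordered_matrix_is_a_permutation(self, rng):
        frame, _ = self._block_matrix(rng)
        mat = MethylationMatrix(frame, "gene_CHH")
        rows, cols, reordered = cluster_heatmap(mat)
        assert sorted(reordered.index) == sorted(frame.index)
        assert sorted(reordered.columns) == sorted(frame.columns)
        np.testing.assert_array_equal(
            reordered.to_numpy(),
            frame.loc[reordered.index, reordered.columns].to_numpy(),
        )

    def test_heatmap_dir_outputs_parse(self, tmp_path, rng):
        frame, _ = self._block_matrix(rng)
        mat = MethylationMatrix(frame, "gene_CHH")
        rows, cols, _ = write_heatmap_dir(mat, tmp_path)
        back = pd.read_csv(tmp_path / "matrix.tsv", sep="\t", index_col=0)
        assert back.shape == frame.shape
        # Newick trees are readable by an independent library and carry all leaves
        import skbio

        tree = skbio.TreeNode.read(str(tmp_path / "genes.nwk"))
        assert {t.name for t in tree.tips()} == set(frame.index)
        tree_cols = skbio.TreeNode.read(str(tmp_path / "datasets.nwk"))
        assert {t.name for t in tree_cols.tips()} == set(frame.columns)
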