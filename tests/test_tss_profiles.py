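"""TSS-centred profile matrices: orientation, normalization, averages, deltas."""

import numpy as np
import pandas as pd
import pytest

from regenmeth.exceptions import AlignmentError
from regenmeth.meth_io import MethylCallTable, merge_cpg_strands
from regenmeth.tss_profiles import (
    ProfileMatrix,
    average_profile,
    delta_matrix,
    profile_matrix,
    sort_rows,
    write_matrix_tsv,
)


def _genes(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss"])


def _table(rows, sample_id="s"):
    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "context", "trinucleotide", "meth", "unmeth"]
    ).sort_values(["chrom", "pos"]).reset_index(drop=True)
    return MethylCallTable(sample_id, "", df)


class TestOrientation:
    def test_site_upstream_lands_in_same_bin_for_both_strands(self):
        # one site 100 bp 5' of each TSS: genomic -100 for +, +100 for -
        genes = _genes([("gp", "chrA", "+", 5000), ("gm", "chrB", "-", 5000)])
        table = _table(
            [
                ("chrA", 4900, "+", "CpG", "CGA", 6, 4),
                ("chrB", 5100, "+", "CpG", "CGA", 6, 4),
            ]
        )
        mat = profile_matrix(table, genes)
        np.testing.assert_allclose(mat.values[0], mat.values[1])
        bin_idx = np.flatnonzero(mat.values[0])
        assert bin_idx == [(-100 + 2000) // 50]

    def test_strand_reflection_leaves_row_unchanged(self):
        rng = np.random.default_rng(3)
        tss = 10_000
        pos = np.sort(rng.choice(np.arange(tss - 1999, tss + 2000), 150, replace=False))
        meth = rng.integers(0, 10, len(pos))
        rows = [("chr1", int(p), "+", "CpG", "CGA", int(m), 3) for p, m in zip(pos, meth)]
        refl = [("chr1", int(2 * tss - p), "+", "CpG", "CGA", int(m), 3)
                for p, m in zip(pos, meth)]
        fwd = profile_matrix(_table(rows), _genes([("g", "chr1", "+", tss)]))
        rev = profile_matrix(_table(refl), _genes([("g", "chr1", "-", tss)]))
        np.testing.assert_allclose(fwd.values, rev.values)

    def test_tss_sits_at_start_of_first_downstream_bin(self):
        genes = _genes([("g", "chr1", "+", 5000)])
        table = _table([("chr1", 5000, "+", "CpG", "CGA", 5, 5)])
        mat = profile_matrix(table, genes)
        assert np.flatnonzero(mat.values[0]) == [mat.tss_bin()] == [40]


class TestShapeAndNormalization:
    def test_default_geometry_is_80_bins(self, small_dataset):
        table = merge_cpg_strands(small_dataset.samples[0].subset_context("CpG"))
        mat = profile_matrix(table, small_dataset.genes)
        assert mat.values.shape == (len(small_dataset.genes), 80)

    def test_coarser_bins_halve_the_columns(self, small_dataset):
        table = merge_cpg_strands(small_dataset.samples[0].subset_context("CpG"))
        mat = profile_matrix(table, small_dataset.genes, bin_size=100)
        assert mat.n_bins == 40

    def test_empty_window_gives_zero_row(self):
        genes = _genes([("g", "chr9", "+", 50_000)])
        table = _table([("chr1", 100, "+", "CpG", "CGA", 5, 5)])
        mat = profile_matrix(table, genes)
        np.testing.assert_allclose(mat.values[0], 0.0)

    def test_normalization_uses_sample_wide_total(self):
        genes = _genes([("g", "chr1", "+", 5000)])
        # in-window site contributes; distant site only inflates the denominator
        table = _table(
            [
                ("chr1", 5010, "+", "CpG", "CGA", 10, 0),
                ("chr1", 40_000, "+", "CpG", "CGA", 40, 50),
            ]
        )
        mat = profile_matrix(table, genes)
        assert mat.values[0, mat.tss_bin()] == pytest.approx(10 * 1e6 / 100)

    def test_out_of_chromosome_bins_are_missing(self):
        genes = _genes([("g", "chr1", "+", 500)])  # window [-1500, 2500)
        table = _table([("chr1", 510, "+", "CpG", "CGA", 5, 5)])
        mat = profile_matrix(table, genes, chrom_lengths={"chr1": 100_000})
        assert np.isnan(mat.values[0, :30]).all()  # 1500/50 upstream bins missing
        assert np.isfinite(mat.values[0, 30:]).all()


class TestAveragesAndDeltas:
    def test_average_of_identical_rows_is_any_row(self):
        mat = ProfileMatrix(["a", "b"], np.tile(np.arange(80.0), (2, 1)))
        curves, sizes = average_profile(mat, {"a": "g", "b": "g"})
        np.testing.assert_allclose(curves["g"], np.arange(80.0))
        assert sizes["g"] == 2

    def test_group_means_are_permutation_invariant(self):
        rng = np.random.default_rng(5)
        values = rng.uniform(size=(6, 80))
        mat = ProfileMatrix([f"g{i}" for i in range(6)], values)
        perm = [3, 1, 5, 0, 4, 2]
        mat_p = ProfileMatrix([f"g{i}" for i in perm], values[perm])
        curves1, _ = average_profile(mat, {f"g{i}": "x" for i in range(6)})
        curves2, _ = average_profile(mat_p, {f"g{i}": "x" for i in range(6)})
        np.testing.assert_allclose(curves1["x"], curves2["x"])

    def test_quartile_well_depth_ordering(self, small_dataset):
        """The central methylation well is deepest for the most expressed
        genes (Q1) and shallowest for Q4, in an uninjured sample."""
        table = merge_cpg_strands(
            small_dataset.samples[0].subset_context("CpG")  # regenerative control rep1
        )
        mat = profile_matrix(table, small_dataset.genes)
        grouping = small_dataset.truth.set_index("gene_id")["quartile"]
        curves, _ = average_profile(mat, grouping)
        lo = mat.tss_bin() - 14  # central +/- 700 bp
        hi = mat.tss_bin() + 14
        depth = {q: np.nanmean(c[lo:hi]) for q, c in curves.items()}
        assert depth["Q1"] < depth["Q2"] < depth["Q3"] < depth["Q4"]

    def test_delta_antisymmetry(self):
        rng = np.random.default_rng(6)
        a = ProfileMatrix(["a"], rng.uniform(size=(1, 80)))
        b = ProfileMatrix(["a"], rng.uniform(size=(1, 80)))
        np.testing.assert_allclose(
            delta_matrix(a, b).values, -delta_matrix(b, a).values
        )

    def test_delta_requires_alignment(self):
        a = ProfileMatrix(["a"], np.zeros((1, 80)))
        b = ProfileMatrix(["b"], np.zeros((1, 80)))
        with pytest.raises(AlignmentError):
            delta_matrix(a, b)

    def test_planted_hypermethylation_shows_positive_island_delta(self, small_dataset):
        """Injured-vs-control delta over the central island bins is positive
        for genes with a planted positive promoter effect."""
        def pooled(condition):
            tables = [
                merge_cpg_strands(t.subset_context("CpG"))
                for t in small_dataset.samples
                if t.condition == condition
            ]
            df = pd.concat([t.df for t in tables], ignore_index=True)
            df = (
                df.groupby(["chrom", "pos", "strand", "context", "trinucleotide"],
                           as_index=False)[["meth", "unmeth"]].sum()
                .sort_values(["chrom", "pos"]).reset_index(drop=True)
            )
            return MethylCallTable(condition, condition, df)

        mat_inj = profile_matrix(pooled("regenerative_injured"), small_dataset.genes)
        mat_ctl = profile_matrix(pooled("regenerative_control"), small_dataset.genes)
        delta = delta_matrix(mat_inj, mat_ctl)
        affected_up = small_dataset.truth.query("effect_sign == 1")["gene_id"]
        rows = [delta.gene_ids.index(g) for g in affected_up]
        lo, hi = delta.tss_bin() - 5, delta.tss_bin() + 5  # central +/- 250 bp
        assert np.nanmean(delta.values[rows][:, lo:hi]) > 0


def test_sort_rows_orders_by_intensity():
    values = np.array([[1.0] * 80, [3.0] * 80, [2.0] * 80])
    mat = sort_rows(ProfileMatrix(["a", "b", "c"], values))
    assert mat.gene_ids == ["b", "c", "a"]


def test_matrix_tsv_round_trip(tmp_path, small_dataset):
    table = merge_cpg_strands(small_dataset.samples[0].subset_context("CpG"))
    mat = profile_matrix(table, small_dataset.genes.head(5))
    path = write_matrix_tsv(mat, tmp_path / "m.tsv")
    back = pd.read_csv(path, sep="\t", index_col="gene_id")
    assert back.shape == (5, 80)
    np.testing.assert_allclose(back.to_numpy(), mat.values, rtol=1e-5)
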