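"""Sliding-window CNV inference, clone clustering and subtype scoring."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from clonotype.cnv_rna import (
    baseline_profile,
    cluster_cells_into_clones,
    cnv_profiles,
    compare_clone_scores,
    linkage_to_newick,
    normalize_to_baseline,
    read_gmt,
    score_significance,
    subtype_scores,
)
from clonotype.synthetic_data import gen_scrna_dataset


def toy_dataset(**kwargs):
    defaults = dict(
        n_normal_cells=30,
        clone_spec=[
            {"name": "gain7", "n_cells": 30, "events": [("chr3", 0.585)]},
            {"name": "loss5", "n_cells": 30, "events": [("chr5", -1.0)]},
        ],
        n_genes=1500,
        n_chromosomes=5,
        seed=7,
    )
    defaults.update(kwargs)
    return gen_scrna_dataset(**defaults)


@pytest.fixture(scope="module")
def dataset():
    return toy_dataset()


@pytest.fixture(scope="module")
def profiles(dataset):
    return cnv_profiles(dataset["matrix"], dataset["gene_order"])


class TestProfiles:
    def test_constant_matrix_gives_zero_profiles(self):
        genes = [f"g{i}" for i in range(300)]
        expr = pd.DataFrame(1.0, index=genes, columns=["c1", "c2"])
        order = pd.DataFrame(
            {"gene": genes, "chromosome": "chr1", "position": range(300)}
        )
        prof = cnv_profiles(expr, order)
        assert np.allclose(prof.values.to_numpy(), 0.0)

    def test_single_window_chromosome_centres_to_zero(self):
        genes = [f"g{i}" for i in range(101)]
        expr = pd.DataFrame(1.0, index=genes, columns=["c"])
        order = pd.DataFrame(
            {"gene": genes, "chromosome": "chr1", "position": range(101)}
        )
        prof = cnv_profiles(expr, order)
        assert prof.values.shape == (1, 1)
        assert prof.values.iloc[0, 0] == pytest.approx(0.0)

    def test_windows_do_not_straddle_chromosomes(self, dataset, profiles):
        sizes = dataset["gene_order"].groupby("chromosome").size()
        expected = int((sizes - 101 + 1).clip(lower=0).sum())
        assert len(profiles.windows) == expected
        assert (profiles.windows.groupby("chromosome").size() == sizes - 100).all()

    def test_clipping_bounds_extreme_values(self):
        genes = [f"g{i}" for i in range(150)]
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(
            rng.normal(0, 10, size=(150, 3)), index=genes, columns=list("abc")
        )
        order = pd.DataFrame({"gene": genes, "chromosome": "chr1", "position": range(150)})
        prof = cnv_profiles(expr, order, clip=3.0)
        # window means of values clipped to [-3,3], then centred: bounded by 6
        assert prof.values.abs().to_numpy().max() <= 6.0

    def test_invariant_to_per_cell_constant(self):
        # low-noise dataset so no value reaches the clip boundary, where
        # the invariance would be broken by the non-linearity
        data = toy_dataset(noise_sd=0.2, seed=11)
        expr = data["matrix"]
        shifted = expr + np.arange(expr.shape[1])[None, :] * 0.01
        a = cnv_profiles(expr, data["gene_order"]).values
        b = cnv_profiles(shifted, data["gene_order"]).values
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-9)

    def test_injected_gain_elevates_chromosome_windows(self, dataset, profiles):
        # per-cell centring spreads 1/n_chromosomes of the shift across the
        # rest of the profile, so the measured contrast between shifted and
        # normal cells is shift * (1 - chr_windows/total_windows)
        labels = dataset["cell_labels"]
        chr3 = (profiles.windows.chromosome == "chr3").to_numpy()
        gain_cells = labels[labels == "gain7"].index
        normal_cells = labels[labels == "normal"].index
        elevation = (
            profiles.values.loc[chr3, gain_cells].to_numpy().mean()
            - profiles.values.loc[chr3, normal_cells].to_numpy().mean()
        )
        expected = 0.585 * (1 - chr3.mean())
        assert elevation == pytest.approx(expected, abs=0.03)

    def test_small_chromosome_warns_and_is_skipped(self):
        genes = [f"g{i}" for i in range(120)]
        order = pd.DataFrame(
            {
                "gene": genes,
                "chromosome": ["chr1"] * 110 + ["chr2"] * 10,
                "position": list(range(110)) + list(range(10)),
            }
        )
        expr = pd.DataFrame(0.0, index=genes, columns=["c"])
        with pytest.warns(UserWarning, match="chr2"):
            prof = cnv_profiles(expr, order)
        assert (prof.windows.chromosome == "chr1").all()


class TestBaseline:
    def test_cell_equal_to_baseline_zeroes_out(self, dataset, profiles):
        normals = dataset["cell_labels"][dataset["cell_labels"] == "normal"].index
        base = baseline_profile(profiles, normals)
        norm = normalize_to_baseline(profiles, base)
        # normal cells deviate from their own average only within noise,
        # so nearly all their positions fall inside the dead zone
        frac_zero = (norm.values[normals].to_numpy() == 0).mean()
        assert frac_zero > 0.95

    def test_dead_zone_rule(self, profiles):
        base = pd.Series(0.0, index=range(len(profiles.values)))
        shifted = type(profiles)(
            values=profiles.values * 0 + 0.2, windows=profiles.windows
        )
        norm = normalize_to_baseline(shifted, base, dead_zone=0.3)
        assert (norm.values.to_numpy() == 0).all()
        shifted2 = type(profiles)(
            values=profiles.values * 0 + 0.585, windows=profiles.windows
        )
        norm2 = normalize_to_baseline(shifted2, base, dead_zone=0.3)
        assert np.allclose(norm2.values.to_numpy(), 0.585)

    def test_positional_mismatch_rejected(self, profiles):
        with pytest.raises(ValueError):
            normalize_to_baseline(profiles, pd.Series([0.0, 1.0]))


class TestClustering:
    def test_two_separable_clones_recovered_exactly(self, dataset, profiles):
        labels = dataset["cell_labels"]
        normals = labels[labels == "normal"].index
        base = baseline_profile(profiles, normals)
        norm = normalize_to_baseline(profiles, base)
        tumour = labels[labels != "normal"].index
        tumour_prof = type(norm)(values=norm.values[tumour], windows=norm.windows)
        called, link = cluster_cells_into_clones(tumour_prof, k=2)
        assert adjusted_rand_score(labels[tumour], called) == 1.0

    def test_duplicated_profiles_merge_at_zero_height(self, profiles):
        dup = type(profiles)(
            values=profiles.values.iloc[:, [0, 0, 1]], windows=profiles.windows
        )
        dup.values.columns = ["a", "a2", "b"]
        _, link = cluster_cells_into_clones(dup, k=2)
        assert link[0, 2] == pytest.approx(0.0)

    def test_ward_heights_monotone(self, profiles):
        _, link = cluster_cells_into_clones(profiles, k=2)
        heights = link[:, 2]
        assert (np.diff(heights) >= -1e-9).all()

    def test_k_exceeding_cells_rejected(self, profiles):
        with pytest.raises(ValueError):
            cluster_cells_into_clones(profiles, k=10_000)

    def test_newick_export_is_parseable(self, profiles):
        small = type(profiles)(
            values=profiles.values.iloc[:, :6], windows=profiles.windows
        )
        labels, link = cluster_cells_into_clones(small, k=2)
        newick = linkage_to_newick(link, list(small.values.columns))
        from io import StringIO

        from Bio import Phylo

        tree = Phylo.read(StringIO(newick), "newick")
        assert {t.name for t in tree.get_terminals()} == set(small.values.columns)


class TestSubtypeScores:
    def test_all_genes_set_scores_zero(self, dataset):
        expr = dataset["matrix"]
        scores = subtype_scores(expr, {"all": list(expr.index)})
        assert np.allclose(scores["all"], 0.0, atol=1e-12)

    def test_uniform_cell_scores_zero(self):
        expr = pd.DataFrame(2.0, index=[f"g{i}" for i in range(10)], columns=["c"])
        scores = subtype_scores(expr, {"s": ["g0", "g3", "g7"]})
        assert scores.loc["c", "s"] == pytest.approx(0.0)

    def test_hand_computed_difference(self):
        expr = pd.DataFrame(
            {"c": [1.0, 2.0, 3.0, 4.0, 10.0]}, index=[f"g{i}" for i in range(5)]
        )
        scores = subtype_scores(expr, {"s": ["g0", "g1", "g2"]})
        assert scores.loc["c", "s"] == pytest.approx(2.0 - 4.0)

    def test_empty_gene_set_rejected(self, dataset):
        with pytest.raises(ValueError):
            subtype_scores(dataset["matrix"], {"s": ["not_a_gene"]})

    def test_expression_loaders(self, tmp_path, dataset):
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix

        from clonotype.cnv_rna import read_expression_matrix

        expr = dataset["matrix"].iloc[:50, :5]
        tsv = tmp_path / "expr.tsv"
        expr.to_csv(tsv, sep="\t")
        back = read_expression_matrix(tsv)
        pd.testing.assert_frame_equal(back, expr)

        mtx = tmp_path / "expr.mtx"
        mmwrite(mtx, csr_matrix(expr.to_numpy()))
        cells = tmp_path / "cells.txt"
        cells.write_text("\n".join(expr.columns) + "\n")
        order = dataset["gene_order"].iloc[:50]
        back = read_expression_matrix(mtx, gene_order=order, cells_path=cells)
        assert np.allclose(back.to_numpy(), expr.to_numpy(), atol=1e-6)
        assert list(back.columns) == list(expr.columns)

    def test_gmt_round_trip(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("setA\tdesc\tg1\tg2\ng3\nsetB\tdesc\tg4\t\n")
        sets = read_gmt(path)
        assert sets["setA"] == ["g1", "g2"]
        assert sets["setB"] == ["g4"]


class TestScoreSignificance:
    def test_random_set_calibration(self):
        data = toy_dataset(
            clone_spec=[{"name": "t", "n_cells": 100, "events": []}],
            n_normal_cells=0, n_genes=1000, seed=3,
        )
        expr = data["matrix"]
        rng = np.random.default_rng(0)
        gene_set = list(expr.index[rng.choice(1000, 40, replace=False)])
        calls = score_significance(expr, gene_set, n_random=100, seed=1)
        enriched_rate = (calls == "enriched").mean()
        assert 0.0 <= enriched_rate <= 0.12

    def test_shifted_program_called_enriched(self):
        data = toy_dataset(
            clone_spec=[
                {"name": "hot", "n_cells": 40, "events": []},
                {"name": "cold", "n_cells": 40, "events": []},
            ],
            subtype_spec=[
                {"name": "prog", "n_genes": 50, "shift_by_clone": {"hot": 2.0}}
            ],
            n_normal_cells=0, seed=5,
        )
        expr, labels = data["matrix"], data["cell_labels"]
        calls = score_significance(expr, data["gene_sets"]["prog"], n_random=100, seed=2)
        hot = calls[labels[labels == "hot"].index]
        assert (hot == "enriched").mean() > 0.9

    def test_constant_expression_neither(self):
        expr = pd.DataFrame(0.0, index=[f"g{i}" for i in range(100)], columns=["c1", "c2"])
        calls = score_significance(expr, [f"g{i}" for i in range(10)], n_random=50, seed=0)
        assert (calls == "neither").all()

    def test_few_random_sets_warns(self, dataset):
        with pytest.warns(UserWarning):
            score_significance(
                dataset["matrix"], list(dataset["matrix"].index[:5]), n_random=10, seed=0
            )


class TestCloneScoreComparison:
    def test_shifted_clone_detected(self):
        rng = np.random.default_rng(0)
        scores = pd.DataFrame(
            {"s": np.concatenate([rng.normal(0, 1, 50), rng.normal(1, 1, 50)])},
            index=[f"c{i}" for i in range(100)],
        )
        labels = pd.Series(["a"] * 50 + ["b"] * 50, index=scores.index)
        out = compare_clone_scores(scores, labels)
        assert out.loc["s", "p_value"] < 1e-3

    def test_null_is_calibrated(self):
        rng = np.random.default_rng(1)
        pvals = []
        for _ in range(50):
            scores = pd.DataFrame(
                {"s": rng.normal(size=60)}, index=[f"c{i}" for i in range(60)]
            )
            labels = pd.Series(["a"] * 30 + ["b"] * 30, index=scores.index)
            pvals.append(compare_clone_scores(scores, labels).loc["s", "p_value"])
        from scipy import stats

        _, p = stats.kstest(pvals, "uniform")
        assert p > 0.01

    def test_matches_scipy_on_small_groups(self):
        from scipy import stats

        scores = pd.DataFrame({"s": [1.0, 2.0, 3.0, 10.0, 11.0, 12.0]},
                              index=[f"c{i}" for i in range(6)])
        labels = pd.Series(["a"] * 3 + ["b"] * 3, index=scores.index)
        out = compare_clone_scores(scores, labels)
        h, p = stats.kruskal(scores["s"][:3], scores["s"][3:])
        assert out.loc["s", "H"] == pytest.approx(h)
        assert out.loc["s", "p_value"] == pytest.approx(p)

    def test_single_clone_rejected(self):
        scores = pd.DataFrame({"s": [1.0, 2.0, 3.0]}, index=list("abc"))
        labels = pd.Series(["x", "x", "x"], index=scores.index)
        with pytest.raises(ValueError):
            compare_clone_scores(scores, labels)

    def test_small_clones_excluded_with_warning(self):
        scores = pd.DataFrame({"s": [1.0, 2.0, 3.0, 4.0, 5.0]}, index=list("abcde"))
        labels = pd.Series(["x", "x", "y", "y", "z"], index=scores.index)
        with pytest.warns(UserWarning, match="excluding"):
            compare_clone_scores(scores, labels)
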