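import subprocess
import textwrap

import dendropy
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from assemblage.assembly_null import (
    AssemblyResult,
    _beta_mntd_matrix,
    assembly_processes,
    beta_mntd,
    bnti,
    classify_process,
    patristic_distances,
    raup_crick_bray,
)
from assemblage.core_io import OtuTable
from assemblage.synthetic_data import simulate_phylogeny

FOUR_TIP_NEWICK = "((A:1,B:2):0.5,(C:1.5,D:0.5):1);"


def _tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)


def brute_force_beta_mntd(abund_a, abund_b, D):
    """Exhaustive tip-pair computation of abundance-weighted beta-MNTD."""
    a = np.asarray(abund_a, float) / np.sum(abund_a)
    b = np.asarray(abund_b, float) / np.sum(abund_b)
    ka = np.flatnonzero(a)
    kb = np.flatnonzero(b)
    term1 = sum(a[i] * min(D[i, j] for j in kb) for i in ka)
    term2 = sum(b[j] * min(D[i, j] for i in ka) for j in kb)
    return 0.5 * (term1 + term2)


class TestPatristicDistances:
    def test_hand_built_tree(self):
        D, labels = patristic_distances(_tree(FOUR_TIP_NEWICK))
        d = pd.DataFrame(D, index=labels, columns=labels)
        assert d.loc["A", "B"] == pytest.approx(3.0)
        assert d.loc["A", "C"] == pytest.approx(4.0)
        assert d.loc["B", "C"] == pytest.approx(5.0)
        assert d.loc["C", "D"] == pytest.approx(2.0)

    @pytest.mark.parametrize("n_tips", [5, 17, 40])
    def test_matches_dendropy_oracle(self, n_tips):
        """Postorder-merge distances equal dendropy's tree-traversal ones."""
        tree, _ = simulate_phylogeny(n_tips, seed=n_tips)
        D, labels = patristic_distances(tree)
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for i in range(0, n_tips, 3):
            for j in range(i + 1, n_tips, 5):
                expected = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
                assert D[i, j] == pytest.approx(expected, rel=1e-9)

    def test_metric_axioms_on_tips(self):
        tree, _ = simulate_phylogeny(12, seed=3)
        D, _ = patristic_distances(tree)
        np.testing.assert_allclose(D, D.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(D), 0.0)
        assert (D[~np.eye(12, dtype=bool)] > 0).all()


class TestBetaMntd:
    def test_identical_communities_zero(self):
        tree = _tree(FOUR_TIP_NEWICK)
        v = beta_mntd([2, 2, 0, 0], [2, 2, 0, 0], tree, ["A", "B", "C", "D"])
        assert v == pytest.approx(0.0)

    def test_single_otu_pair_gives_patristic_distance(self):
        tree = _tree(FOUR_TIP_NEWICK)
        v = beta_mntd([1, 0, 0, 0], [0, 0, 1, 0], tree, ["A", "B", "C", "D"])
        assert v == pytest.approx(4.0)  # A-C path length

    def test_hand_computed_four_tip_value(self):
        tree = _tree(FOUR_TIP_NEWICK)
        v = beta_mntd([2, 2, 0, 0], [0, 0, 1, 3], tree, ["A", "B", "C", "D"])
        # 0.5*[0.5*3 + 0.5*4 + 0.25*4 + 0.75*3]
        assert v == pytest.approx(3.375)

    def test_matches_brute_force_on_random_communities(self):
        tree, _ = simulate_phylogeny(15, seed=9)
        D, labels = patristic_distances(tree)
        rng = np.random.default_rng(4)
        abund = rng.integers(0, 6, size=(6, 15))
        abund[abund.sum(axis=1) == 0, 0] = 1
        fast = _beta_mntd_matrix(abund.astype(float), D)
        for i in range(6):
            for j in range(i + 1, 6):
                assert fast[i, j] == pytest.approx(
                    brute_force_beta_mntd(abund[i], abund[j], D)
                )

    def test_missing_otu_named(self):
        tree = _tree(FOUR_TIP_NEWICK)
        with pytest.raises(ValueError, match="ghost"):
            beta_mntd([1, 1], [1, 1], tree, ["A", "ghost"])

    def test_matches_picante_comdistnt(self, tmp_path):
        """Independent R oracle: picante's abundance-weighted comdistnt."""
        tree, _ = simulate_phylogeny(10, seed=13)
        rng = np.random.default_rng(21)
        abund = rng.integers(0, 9, size=(4, 10)).astype(float)
        abund[abund.sum(axis=1) == 0, 0] = 1
        rel = abund / abund.sum(axis=1, keepdims=True)
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        otu_ids = [f"OTU{i + 1:04d}" for i in range(10)]
        table = OtuTable(counts=np.zeros((4, 10), int),
                         sample_ids=list("wxyz"), otu_ids=otu_ids)
        order = [otu_ids.index(lab) for lab in labels]  # identity here
        tree_path = tmp_path / "t.nwk"
        tree.write(path=str(tree_path), schema="newick", suppress_rooting=True)
        comm_path = tmp_path / "comm.tsv"
        pd.DataFrame(rel, index=list("wxyz"), columns=otu_ids).to_csv(
            comm_path, sep="\t"
        )
        out_path = tmp_path / "out.tsv"
        rscript = textwrap.dedent(f"""
            suppressMessages(library(picante))
            tree <- read.tree("{tree_path}")
            comm <- as.matrix(read.table("{comm_path}", header=TRUE,
                              row.names=1, sep="\\t", check.names=FALSE))
            d <- cophenetic(tree)
            res <- as.matrix(comdistnt(comm, d, abundance.weighted=TRUE))
            write.table(res, "{out_path}", sep="\\t", quote=FALSE)
        """)
        subprocess.run(["Rscript", "-e", rscript], check=True,
                       capture_output=True, text=True)
        r_res = pd.read_csv(out_path, sep="\t", index_col=0)
        D, dlabels = patristic_distances(tree)
        pos = {lab: k for k, lab in enumerate(dlabels)}
        perm = [pos[o] for o in otu_ids]
        mine = _beta_mntd_matrix(rel, D[np.ix_(perm, perm)])
        for i, a in enumerate("wxyz"):
            for j, b in enumerate("wxyz"):
                if i < j:
                    assert mine[i, j] == pytest.approx(
                        float(r_res.loc[a, b]), rel=1e-6
                    )


class TestBnti:
    def _table_tree(self, seed=2, n_otus=20, n_samples=6, depth=300):
        tree, _ = simulate_phylogeny(n_otus, seed=seed)
        rng = np.random.default_rng(seed)
        counts = rng.multinomial(depth, np.ones(n_otus) / n_otus, size=n_samples)
        table = OtuTable(
            counts=counts,
            sample_ids=[f"s{i}" for i in range(n_samples)],
            otu_ids=[f"OTU{i + 1:04d}" for i in range(n_otus)],
        )
        return table, tree

    def test_reproducible_for_fixed_seed(self):
        table, tree = self._table_tree()
        a = bnti(table, tree, n_null=99, seed=5)
        b = bnti(table, tree, n_null=99, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_symmetric_with_zero_diagonal(self):
        table, tree = self._table_tree()
        z = bnti(table, tree, n_null=99, seed=5).to_numpy()
        np.testing.assert_allclose(z, z.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(z), 0.0)

    def test_null_permutation_equals_relabelled_tree(self):
        """The index-permutation trick equals recomputing beta-MNTD on a
        jointly row/column-shuffled distance matrix."""
        table, tree = self._table_tree(seed=6, n_otus=12, n_samples=4)
        from assemblage.assembly_null import _align_distance

        D = _align_distance(table, tree)
        abund = table.counts.astype(float)
        rel = abund / abund.sum(axis=1, keepdims=True)
        rng = np.random.default_rng(0)
        perm = rng.permutation(12)
        expected = _beta_mntd_matrix(abund, D[np.ix_(perm, perm)])
        minvec = np.empty((4, 12))
        for k in range(4):
            present = np.flatnonzero(abund[k] > 0)
            minvec[k] = D[:, perm[present]].min(axis=1)[perm]
        got = np.zeros((4, 4))
        for k in range(4):
            for l in range(k + 1, 4):
                got[k, l] = got[l, k] = 0.5 * (
                    rel[k] @ minvec[l] + rel[l] @ minvec[k]
                )
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_observed_table_not_mutated(self):
        table, tree = self._table_tree()
        before = table.counts.copy()
        bnti(table, tree, n_null=99, seed=1)
        np.testing.assert_array_equal(table.counts, before)

    def test_star_tree_yields_nan_with_diagnostic(self):
        tree = _tree("(A:1,B:1,C:1,D:1);")
        table = OtuTable(
            counts=np.array([[5, 5, 0, 0], [0, 0, 5, 5]]),
            sample_ids=["s1", "s2"],
            otu_ids=["A", "B", "C", "D"],
        )
        with pytest.warns(UserWarning, match="zero spread"):
            z = bnti(table, tree, n_null=99, seed=0)
        assert np.isnan(z.iloc[0, 1])


class TestRaupCrick:
    def test_identical_samples_give_minus_one(self):
        rng = np.random.default_rng(3)
        row = rng.multinomial(200, np.ones(12) / 12)
        table = OtuTable(counts=np.vstack([row, row]),
                         sample_ids=["a", "b"],
                         otu_ids=[f"o{i}" for i in range(12)])
        rc = raup_crick_bray(table, n_null=99, seed=1)
        assert rc.loc["a", "b"] == pytest.approx(-1.0)

    def test_disjoint_high_richness_samples_give_plus_one(self):
        counts = np.zeros((2, 20), dtype=int)
        counts[0, :10] = 10
        counts[1, 10:] = 10
        table = OtuTable(counts=counts, sample_ids=["a", "b"],
                         otu_ids=[f"o{i}" for i in range(20)])
        rc = raup_crick_bray(table, n_null=99, seed=2)
        assert rc.loc["a", "b"] == pytest.approx(1.0)

    def test_bounds_symmetry_and_determinism(self, tiny_neutral):
        table, _ = tiny_neutral
        sub = table.select(sample_ids=table.sample_ids[:4])
        a = raup_crick_bray(sub, n_null=99, seed=7)
        b = raup_crick_bray(sub, n_null=99, seed=7)
        pd.testing.assert_frame_equal(a, b)
        vals = a.to_numpy()
        assert ((vals >= -1) & (vals <= 1)).all()
        np.testing.assert_allclose(vals, vals.T, atol=1e-12)

    def test_single_sample_rejected(self):
        table = OtuTable(counts=np.array([[1, 2]]), sample_ids=["a"],
                         otu_ids=["x", "y"])
        with pytest.raises(ValueError):
            raup_crick_bray(table, n_null=99, seed=0)


class TestClassifyProcess:
    @pytest.mark.parametrize(
        "z, rc, expected",
        [
            (-3.0, 0.1, "homogeneous_selection"),
            (3.0, 0.1, "variable_selection"),
            (1.0, 0.97, "dispersal_limitation"),
            (0.0, -0.97, "homogenizing_dispersal"),
            (0.5, 0.2, "undominated"),
            # deterministic boundary handling
            (2.0, 0.0, "variable_selection"),
            (-2.0, 0.0, "homogeneous_selection"),
            (0.0, 0.95, "dispersal_limitation"),
            (0.0, -0.95, "homogenizing_dispersal"),
        ],
    )
    def test_decision_rules(self, z, rc, expected):
        assert classify_process(z, rc) == expected

    @given(st.floats(-10, 10), st.floats(-1, 1))
    @settings(max_examples=200, deadline=None)
    def test_total_and_single_valued(self, z, rc):
        from assemblage.assembly_null import PROCESSES

        assert classify_process(z, rc) in PROCESSES

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            classify_process(float("nan"), 0.0)


class TestProcessFractions:
    def _result(self, processes):
        frame = pd.DataFrame(
            {
                "sample_a": [f"a{i}" for i in range(len(processes))],
                "sample_b": [f"b{i}" for i in range(len(processes))],
                "group": "g",
                "betaMNTD": 1.0,
                "betaNTI": 0.0,
                "RC": 0.0,
                "process": processes,
            }
        )
        return AssemblyResult(pairs=frame, n_null=99, seed=0)

    def test_all_undominated(self):
        frac = self._result(["undominated"] * 4).fractions()
        assert frac.loc["g", "undominated"] == pytest.approx(1.0)
        assert frac.loc["g"].drop("undominated").sum() == pytest.approx(0.0)

    def test_fifteen_pair_arithmetic(self):
        procs = ["dispersal_limitation"] * 9 + ["undominated"] * 6
        frac = self._result(procs).fractions()
        assert frac.loc["g", "dispersal_limitation"] == pytest.approx(0.6)
        assert frac.loc["g"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_end_to_end_fractions_sum_to_one(self, tiny_gradient, tiny_tree_traits):
        table, meta = tiny_gradient
        tree, _ = tiny_tree_traits
        sub = table.select(sample_ids=table.sample_ids[:6])
        res = assembly_processes(sub, tree, meta, n_null=99, seed=3)
        frac = res.fractions()
        assert np.allclose(frac.sum(axis=1), 1.0, atol=1e-12)
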