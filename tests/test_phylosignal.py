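"""Phylogeny utilities and Blomberg's K, with dense-algebra and R oracles."""

import subprocess

import dendropy
import numpy as np
import pandas as pd
import pytest

from pollenflow import (
    add_tip_to_genus,
    blombergs_k,
    exclude_genera,
    k_randomization_test,
    phylo_vcv,
    prune,
    random_ultrametric_tree,
    read_newick,
    rename_tips,
    simulate_bm_trait,
    write_newick,
)
from pollenflow.errors import TreeError
from pollenflow.phylosignal import tip_labels


def patristic(tree):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    return {(a.label, b.label): pdm.distance(a, b)
            for a in taxa for b in taxa if a.label < b.label}


class TestTreeIO:
    def test_parse_two_tips(self):
        tree = read_newick("(A:1,B:1):0;")
        assert sorted(tip_labels(tree)) == ["A", "B"]
        V = phylo_vcv(tree)
        assert V.loc["A", "A"] == 1.0

    def test_round_trip_preserves_lengths(self):
        text = "((A:1.5,B:1.5):0.5,C:2.0);"
        tree = read_newick(text)
        again = read_newick(write_newick(tree))
        assert patristic(tree) == patristic(again)

    def test_missing_branch_length_rejected(self):
        with pytest.raises(TreeError):
            read_newick("((A:1,B):1,C:2);")

    def test_duplicate_tips_rejected(self):
        with pytest.raises(TreeError):
            read_newick("((A:1,A:1):1,C:2);")

    def test_prune_preserves_patristic_distances(self):
        tree = random_ultrametric_tree(12, seed=2)
        keep = tip_labels(tree)[:6]
        sub = prune(tree, keep)
        assert sorted(tip_labels(sub)) == sorted(keep)
        full = patristic(tree)
        small = patristic(sub)
        for pair, d in small.items():
            assert d == pytest.approx(full[pair], rel=1e-9)

    def test_prune_unknown_tip_rejected(self):
        tree = read_newick("(A:1,B:1);")
        with pytest.raises(TreeError, match="not in tree"):
            prune(tree, ["A", "Z"])

    def test_rename_tips(self):
        tree = read_newick("(Elytrigia_repens:1,Carex_ovalis:1);")
        out = rename_tips(tree, {"Elytrigia_repens": "Elymus_repens",
                                 "Carex_ovalis": "Carex_leporina"})
        assert sorted(tip_labels(out)) == ["Carex_leporina", "Elymus_repens"]


class TestGenusAddition:
    def test_attach_at_genus_mrca_stays_ultrametric(self):
        tree = read_newick("((Pinus_sylvestris:2,Pinus_nigra:2):1,Quercus_robur:3);")
        out = add_tip_to_genus(tree, "Pinus_bungeana")
        V = phylo_vcv(out)
        assert set(V.index) == {"Pinus_sylvestris", "Pinus_nigra",
                                "Pinus_bungeana", "Quercus_robur"}
        assert np.allclose(np.diag(V), 3.0)  # all depths equal

    def test_single_congener_midpoint_attachment(self):
        tree = read_newick("((Pinus_sylvestris:2,Quercus_ilex:2):1,Quercus_robur:3);")
        out = add_tip_to_genus(tree, "Pinus_bungeana")
        V = phylo_vcv(out)
        assert np.allclose(np.diag(V), 3.0)
        # the new pair shares half the old terminal branch
        assert V.loc["Pinus_sylvestris", "Pinus_bungeana"] == pytest.approx(2.0)

    def test_species_already_present_unchanged(self):
        tree = read_newick("((Pinus_sylvestris:2,Pinus_nigra:2):1,Quercus_robur:3);")
        out = add_tip_to_genus(tree, "Pinus_nigra")
        assert patristic(out) == patristic(tree)

    def test_no_congener_raises(self):
        tree = read_newick("(A_x:1,B_y:1);")
        with pytest.raises(TreeError, match="congeneric"):
            add_tip_to_genus(tree, "Ginkgo_biloba")

    def test_exclude_genera(self):
        tree = read_newick(
            "(((Pinus_sylvestris:1,Picea_abies:1):1,Betula_pendula:2):1,Quercus_robur:3);")
        out = exclude_genera(tree, ["Pinus", "Picea"])
        assert sorted(tip_labels(out)) == ["Betula_pendula", "Quercus_robur"]


class TestVCV:
    def test_hand_computed_three_tip(self):
        V = phylo_vcv(read_newick("((A:1,B:1):1,C:2);"))
        assert V.loc["A", "B"] == 1.0
        assert V.loc["A", "C"] == 0.0
        assert np.allclose(np.diag(V), 2.0)

    def test_star_tree_diagonal(self):
        V = phylo_vcv(read_newick("(A:3,B:3,C:3,D:3);"))
        assert np.allclose(V.to_numpy(), 3.0 * np.eye(4))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_symmetric_positive_semidefinite(self, seed):
        V = phylo_vcv(random_ultrametric_tree(15, seed=seed)).to_numpy()
        assert np.allclose(V, V.T)
        assert np.linalg.eigvalsh(V).min() > -1e-9

    @pytest.mark.parametrize("seed", [3, 4])
    def test_prune_commutes_with_vcv(self, seed):
        tree = random_ultrametric_tree(10, seed=seed)
        keep = tip_labels(tree)[:5]
        V_full = phylo_vcv(tree).loc[keep, keep]
        V_sub = phylo_vcv(prune(tree, keep)).loc[keep, keep]
        np.testing.assert_allclose(V_full.to_numpy(), V_sub.to_numpy(),
                                   atol=1e-9)


def brute_force_k(tree, trait):
    """Independent scalar evaluation of the K formula via explicit solves."""
    V = phylo_vcv(tree)
    x = np.array([trait[lb] for lb in V.index])
    Vm = V.to_numpy()
    n = len(x)
    ones = np.ones(n)
    a = (ones @ np.linalg.solve(Vm, x)) / (ones @ np.linalg.solve(Vm, ones))
    d = x - a
    mse0 = d @ d / (n - 1)
    mse = d @ np.linalg.solve(Vm, d) / (n - 1)
    expected = (np.trace(Vm) - n / (ones @ np.linalg.solve(Vm, ones))) / (n - 1)
    return (mse0 / mse) / expected


class TestBlombergsK:
    def test_star_tree_k_is_exactly_one(self):
        star = read_newick("(A:1,B:1,C:1,D:1,E:1,F:1);")
        rng = np.random.default_rng(0)
        for _ in range(5):
            trait = pd.Series(rng.normal(0, 1, 6), index=list("ABCDEF"))
            assert abs(blombergs_k(star, trait) - 1.0) < 1e-10

    def test_four_tip_matches_brute_force(self):
        tree = read_newick("((A:1,B:1):1.5,(C:2,D:0.5):0.5);")
        trait = pd.Series({"A": 1.2, "B": 0.7, "C": -0.4, "D": 2.2})
        assert blombergs_k(tree, trait) == pytest.approx(
            brute_force_k(tree, trait), abs=1e-10)

    def test_matches_phytools_phylosig(self, tmp_path):
        """Independent oracle: R phytools::phylosig on a 10-tip tree."""
        tree = random_ultrametric_tree(10, seed=7)
        trait = simulate_bm_trait(tree, 2.0, seed=4)
        nwk = tmp_path / "t.nwk"
        csv = tmp_path / "trait.csv"
        nwk.write_text(write_newick(tree))
        trait.rename_axis("species").rename("value").to_csv(csv)
        script = (
            'suppressMessages(library(phytools));'
            f'tr <- ape::read.tree("{nwk}");'
            f'x <- read.csv("{csv}");'
            'v <- setNames(x$value, x$species);'
            'cat(sprintf("%.12f", phylosig(tr, v, method="K")))'
        )
        proc = subprocess.run(["Rscript", "-e", script],
                              capture_output=True, text=True, check=True)
        assert blombergs_k(tree, trait) == pytest.approx(
            float(proc.stdout.strip()), abs=1e-8)

    def test_affine_invariance(self):
        tree = random_ultrametric_tree(12, seed=9)
        trait = simulate_bm_trait(tree, 1.0, seed=1)
        k = blombergs_k(tree, trait)
        assert blombergs_k(tree, 5.0 * trait + 3.0) == pytest.approx(k, abs=1e-9)

    def test_constant_trait_rejected(self):
        tree = random_ultrametric_tree(5, seed=0)
        trait = pd.Series(1.0, index=tip_labels(tree))
        with pytest.raises(ValueError):
            blombergs_k(tree, trait)

    def test_missing_tip_rejected(self):
        tree = read_newick("(A:1,B:1,C:1);")
        with pytest.raises(TreeError, match="missing"):
            blombergs_k(tree, pd.Series({"A": 1.0, "B": 2.0}))


class TestRandomizationTest:
    def test_fixed_seed_reproduces_p_exactly(self):
        tree = random_ultrametric_tree(20, seed=3)
        trait = simulate_bm_trait(tree, 1.0, seed=5)
        a = k_randomization_test(tree, trait, n_perm=99, seed=11)
        b = k_randomization_test(tree, trait, n_perm=99, seed=11)
        assert a.p_value == b.p_value
        assert a.k_observed == b.k_observed
        assert 0 < a.p_value <= 1.0
        assert a.n_permutations == 99

    def test_strong_bm_signal_detected(self):
        """BM traits on a 50-tip tree are flagged significant in nearly
        every replicate."""
        tree = random_ultrametric_tree(50, seed=13)
        hits = 0
        reps = 40
        for i in range(reps):
            trait = simulate_bm_trait(tree, 1.0, seed=100 + i)
            res = k_randomization_test(tree, trait, n_perm=200, seed=i)
            hits += res.p_value <= 0.01
        assert hits / reps >= 0.95

    def test_signal_destroyed_by_shuffling(self):
        """K decreases monotonically as the trait is progressively
        shuffled across tips."""
        tree = random_ultrametric_tree(40, seed=21)
        labels = tip_labels(tree)
        rng = np.random.default_rng(0)
        med = {}
        for frac in (0.0, 0.5, 1.0):
            ks = []
            for i in range(25):
                trait = simulate_bm_trait(tree, 1.0, seed=500 + i)
                x = trait.to_numpy().copy()
                k = int(frac * len(x))
                if k > 1:
                    idx = rng.choice(len(x), size=k, replace=False)
                    x[idx] = x[rng.permutation(idx)]
                ks.append(blombergs_k(tree, pd.Series(x, index=labels)))
            med[frac] = np.median(ks)
        assert med[0.0] > med[0.5] > med[1.0]
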