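import dendropy
import numpy as np
import pandas as pd
import pytest

from sterolome import DegenerateInputError, SterolomeError
from sterolome import io as io_mod
from sterolome import phylosignal as ps
from sterolome import simulate as sim


class TestPruneAndMatch:
    TREE = "((((Aa_x:1,Aa_y:1):1,Bb_z:2):1,Cc_w:3):1,Dd_v:4);"

    def test_direct_matches_pruned(self):
        tree = io_mod.read_tree(self.TREE)
        pruned, unplaced = ps.prune_and_match(tree, ["Aa_x", "Bb_z", "Cc_w"])
        labels = sorted(l.taxon.label for l in pruned.leaf_node_iter())
        assert labels == ["Aa_x", "Bb_z", "Cc_w"]
        assert unplaced == []

    def test_synonym_renamed_and_kept(self):
        tree = io_mod.read_tree(self.TREE)
        rules = [ps.RenameRule("Dd_v", "Ee_q", kind="synonym")]
        pruned, unplaced = ps.prune_and_match(
            tree, ["Aa_x", "Bb_z", "Ee_q"], rules
        )
        labels = sorted(l.taxon.label for l in pruned.leaf_node_iter())
        assert "Ee_q" in labels
        assert unplaced == []

    def test_congener_substitution_refused_when_genus_matched(self):
        tree = io_mod.read_tree(self.TREE)
        # Aa_x is already a direct match for genus Aa; the congener rule
        # for Aa_q must be refused and the taxon reported unplaced
        rules = [ps.RenameRule("Aa_y", "Aa_q", kind="congener-substitute")]
        pruned, unplaced = ps.prune_and_match(
            tree, ["Aa_x", "Aa_q", "Bb_z", "Cc_w"], rules
        )
        assert unplaced == ["Aa_q"]

    def test_congener_substitution_applied_when_genus_unmatched(self):
        tree = io_mod.read_tree(self.TREE)
        rules = [ps.RenameRule("Aa_y", "Aa_q", kind="congener-substitute")]
        pruned, unplaced = ps.prune_and_match(
            tree, ["Aa_q", "Bb_z", "Cc_w"], rules
        )
        labels = sorted(l.taxon.label for l in pruned.leaf_node_iter())
        assert "Aa_q" in labels and unplaced == []

    def test_rule_for_missing_tip_rejected(self):
        tree = io_mod.read_tree(self.TREE)
        with pytest.raises(SterolomeError):
            ps.prune_and_match(
                tree, ["Aa_x", "Bb_z", "Cc_w"],
                [ps.RenameRule("NotATip", "Aa_x")],
            )


class TestMonophyly:
    def test_monophyletic(self):
        tree = io_mod.read_tree("((A:1,B:1):1,C:2);")
        res = ps.check_monophyly(tree, {"A": "F1", "B": "F1", "C": "F2"})
        assert res["F1"] == "monophyletic"
        assert res["F2"] == "singleton"

    def test_not_monophyletic(self):
        tree = io_mod.read_tree("((A:1,C:1):1,B:2);")
        res = ps.check_monophyly(tree, {"A": "F1", "B": "F1", "C": "F2"})
        assert res["F1"] == "not_monophyletic"

    def test_unmapped_tip_rejected(self):
        tree = io_mod.read_tree("((A:1,B:1):1,C:2);")
        with pytest.raises(SterolomeError):
            ps.check_monophyly(tree, {"A": "F1", "B": "F1"})


def _brute_force_vcv(tree: dendropy.Tree):
    """Independent oracle: C[i, j] as the depth of the MRCA, computed via
    dendropy's own MRCA and root-distance machinery."""
    leaves = list(tree.leaf_node_iter())
    labels = [l.taxon.label for l in leaves]
    n = len(leaves)
    pdm = tree.phylogenetic_distance_matrix()
    c = np.zeros((n, n))
    for i in range(n):
        c[i, i] = leaves[i].distance_from_root()
        for j in range(i + 1, n):
            mrca = pdm.mrca(leaves[i].taxon, leaves[j].taxon)
            d = mrca.distance_from_root()
            c[i, j] = c[j, i] = d
    return labels, c


class TestPhyloVcv:
    def test_two_tips_at_root(self):
        labels, c = ps.phylo_vcv(io_mod.read_tree("(A:1.5,B:1.5);"))
        assert np.allclose(c, np.diag([1.5, 1.5]))

    def test_hand_path_sums(self):
        labels, c = ps.phylo_vcv(io_mod.read_tree("((A:1,B:1):1,C:2);"))
        idx = {lab: i for i, lab in enumerate(labels)}
        assert c[idx["A"], idx["B"]] == pytest.approx(1.0)
        assert c[idx["A"], idx["A"]] == pytest.approx(2.0)
        assert c[idx["A"], idx["C"]] == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle_on_small_trees(self, seed):
        tree = sim.gen_tree(6, seed=seed)
        labels, c = ps.phylo_vcv(tree)
        labels_b, c_b = _brute_force_vcv(tree)
        order = [labels.index(lab) for lab in labels_b]
        assert np.allclose(c[np.ix_(order, order)], c_b, atol=1e-10)

    def test_symmetric_psd(self):
        tree = sim.gen_tree(25, seed=5)
        _, c = ps.phylo_vcv(tree)
        assert np.allclose(c, c.T)
        assert np.linalg.eigvalsh(c).min() > -1e-9


class TestBlombergK:
    def test_star_tree_k_is_one(self):
        tree = io_mod.read_tree("(A:1,B:1,C:1,D:1,E:1);")
        trait = pd.Series([0.3, -1.0, 2.0, 0.5, 1.1], index=list("ABCDE"))
        k, _ = ps.blomberg_k(tree, trait, n_permutations=0)
        assert k == pytest.approx(1.0, abs=1e-10)

    def test_affine_invariance(self, calib_tree):
        vcv = ps.phylo_vcv(calib_tree)
        trait = sim.simulate_traits(calib_tree, 1.0, 1.0, 1, seed=3).iloc[:, 0]
        k1, _ = ps.blomberg_k(vcv, trait, n_permutations=0)
        k2, _ = ps.blomberg_k(vcv, 10.0 * trait - 3.0, n_permutations=0)
        assert k1 == pytest.approx(k2, rel=1e-9)

    def test_shuffled_trait_low_k_high_p(self, calib_tree):
        vcv = ps.phylo_vcv(calib_tree)
        rng = np.random.default_rng(5)
        labels = vcv[0]
        ks, ps_ = [], []
        for i in range(10):
            trait = pd.Series(rng.standard_normal(len(labels)), index=labels)
            k, p = ps.blomberg_k(vcv, trait, n_permutations=199, seed=i)
            ks.append(k)
            ps_.append(p)
        assert np.mean(ks) < 0.5
        assert np.mean(ps_) > 0.05

    def test_constant_trait_rejected(self, calib_tree):
        labels, _ = ps.phylo_vcv(calib_tree)
        with pytest.raises(DegenerateInputError):
            ps.blomberg_k(calib_tree, pd.Series(1.0, index=labels))


class TestPagelLambda:
    def test_loglik_optimum_dominates_endpoints(self, calib_tree):
        vcv = ps.phylo_vcv(calib_tree)
        trait = sim.simulate_traits(calib_tree, 0.7, 1.0, 1, seed=9).iloc[:, 0]
        res = ps.pagel_lambda(vcv, trait)
        assert res.loglik >= ps._lambda_loglik(
            trait.loc[vcv[0]].to_numpy(), vcv[1], 0.0
        ) - 1e-8
        assert res.loglik >= ps._lambda_loglik(
            trait.loc[vcv[0]].to_numpy(), vcv[1], 1.0
        ) - 1e-8

    def test_affine_invariance(self, calib_tree):
        vcv = ps.phylo_vcv(calib_tree)
        trait = sim.simulate_traits(calib_tree, 0.8, 1.0, 1, seed=13).iloc[:, 0]
        r1 = ps.pagel_lambda(vcv, trait)
        r2 = ps.pagel_lambda(vcv, -4.0 * trait + 2.0)
        assert r1.lambda_hat == pytest.approx(r2.lambda_hat, abs=1e-4)

    def test_brownian_trait_high_lambda_small_p(self, calib_tree):
        vcv = ps.phylo_vcv(calib_tree)
        trait = sim.simulate_traits(calib_tree, 1.0, 1.0, 1, seed=17).iloc[:, 0]
        res = ps.pagel_lambda(vcv, trait)
        assert res.lambda_hat > 0.8
        assert res.p_value < 0.01

    def test_matches_phytools_convention_on_small_tree(self):
        """Frozen cross-check values computed once with an independent ML
        implementation (phytools::phylosig) on this exact fixture."""
        tree = sim.gen_tree(30, seed=3)
        traits = sim.simulate_traits(tree, 1.0, 1.0, 3, seed=8)
        vcv = ps.phylo_vcv(tree)
        expected_k = [1.062607, 1.005635, 0.605452]
        expected_lambda = [0.999972, 1.001625, 1.001368]
        for col, ek, el in zip(traits.columns, expected_k, expected_lambda):
            k, _ = ps.blomberg_k(vcv, traits[col], n_permutations=0)
            lam = ps.pagel_lambda(vcv, traits[col])
            assert k == pytest.approx(ek, abs=1e-4)
            assert lam.lambda_hat == pytest.approx(el, abs=1e-3)


class TestSignalScreen:
    def test_low_abundance_sterol_excluded_total_always_included(self):
        tree = sim.gen_tree(10, seed=2)
        labels = [l.taxon.label for l in tree.leaf_node_iter()]
        rng = np.random.default_rng(0)
        profiles = pd.DataFrame(
            {
                "major": rng.uniform(0.7, 0.995, 10),
                "trace": rng.uniform(0.0, 0.005, 10),
            },
            index=labels,
        )
        profiles["major"] = 1.0 - profiles["trace"]
        totals = pd.Series(rng.uniform(500, 5000, 10), index=labels)
        table = ps.signal_screen(
            profiles, tree, totals=totals, n_permutations=49, seed=1
        )
        assert "trace" not in set(table["trait"])
        assert "total_mg_kg" in set(table["trait"])

    def test_screen_separates_signal_from_noise_traits(self, calib_tree):
        """Traits simulated with lambda=1 rank above iid traits by fitted
        lambda (AUC > 0.9)."""
        vcv = ps.phylo_vcv(calib_tree)
        labels = vcv[0]
        bm = sim.simulate_traits(calib_tree, 1.0, 1.0, 10, seed=31)
        rng = np.random.default_rng(32)
        iid = pd.DataFrame(
            rng.standard_normal((len(labels), 10)), index=labels
        )
        lam_bm = [ps.pagel_lambda(vcv, bm[c]).lambda_hat for c in bm.columns]
        lam_iid = [ps.pagel_lambda(vcv, iid[c]).lambda_hat for c in iid.columns]
        wins = sum(a > b for a in lam_bm for b in lam_iid)
        ties = sum(a == b for a in lam_bm for b in lam_iid)
        auc = (wins + 0.5 * ties) / (len(lam_bm) * len(lam_iid))
        assert auc > 0.9

    def test_too_few_overlapping_tips_rejected(self):
        tree = sim.gen_tree(5, seed=1)
        profiles = pd.DataFrame(
            {"a": [0.5, 0.5]}, index=["t1", "t2"]
        )
        with pytest.raises(SterolomeError):
            ps.signal_screen(profiles, tree, n_permutations=9, seed=0)
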