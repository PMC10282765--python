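"""Module detection, eigengenes, merging, and module-trait statistics."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from n4 import coexpression as cx
from n4 import modules as mod
from n4.synthio import SynthConfig, make_expression
from oracles import first_pc_eigh


def fixture_assignment(seed=1, noise=0.1, sizes=(50, 40, 30), beta=6, min_size=20,
                       n_genes=200):
    cfg = SynthConfig(seed=seed, n_genes=n_genes, module_sizes=sizes,
                      module_noise_sd=noise)
    expr, traits, gt = make_expression(cfg)
    net = cx.adjacency_matrix(expr, beta=beta)
    cx.tom_matrix(net)
    asg = mod.detect_modules(net.dissimilarity(), net.gene_ids, min_module_size=min_size)
    return expr, traits, gt, asg


class TestDetectModules:
    def test_planted_modules_recovered_with_sizes_and_high_ari(self):
        # pure three-module fixture (no background genes): sizes are exact
        expr, _, gt, asg = fixture_assignment(noise=0.1, n_genes=120)
        sizes = asg.module_sizes()
        non_grey = {m: n for m, n in sizes.items() if m != mod.GREY}
        assert sorted(non_grey.values(), reverse=True) == [50, 40, 30]
        planted_genes = [g for g, m in gt["module_of_gene"].items() if m >= 0]
        ari = adjusted_rand_score(
            [gt["module_of_gene"][g] for g in planted_genes],
            [asg.labels[g] for g in planted_genes],
        )
        assert ari >= 0.95

    def test_largest_module_is_turquoise(self):
        _, _, _, asg = fixture_assignment()
        sizes = asg.module_sizes()
        largest = max((m for m in sizes if m != mod.GREY), key=lambda m: sizes[m])
        assert largest == "turquoise"
        assert asg.non_grey()[0] == "turquoise"

    def test_oversized_min_module_size_greys_everything(self):
        _, _, _, asg = fixture_assignment(min_size=10_000)
        assert set(asg.labels.values()) == {mod.GREY}

    def test_size_order_follows_color_list(self):
        _, _, _, asg = fixture_assignment()
        sizes = asg.module_sizes()
        ordered = [sizes[m] for m in asg.non_grey()]
        assert ordered == sorted(ordered, reverse=True)

    def test_bad_cut_height_rejected(self):
        _, _, _, asg = fixture_assignment()  # warm-up for data only
        d = np.array([[0, 0.5], [0.5, 0]])
        with pytest.raises(ValueError, match="cut_height"):
            mod.detect_modules(d, ["a", "b"], min_module_size=1, cut_height=99.0)


class TestEigengene:
    def test_identical_profiles_are_rank_one(self):
        base = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        expr = pd.DataFrame([base, 2 * base + 1, 0.5 * base - 2], index=list("abc"))
        profile, ve = mod.eigengene(expr)
        assert ve == pytest.approx(1.0)
        z = (base - base.mean()) / base.std()
        assert abs(np.corrcoef(profile, z)[0, 1]) == pytest.approx(1.0)

    def test_zero_noise_module_recovers_latent_factor(self):
        cfg = SynthConfig(seed=6, module_noise_sd=0.0)
        expr, _, gt = make_expression(cfg)
        members = [g for g, m in gt["module_of_gene"].items() if m == 0]
        profile, ve = mod.eigengene(expr.loc[members])
        f = np.array(gt["latent_factors"][0])
        assert abs(np.corrcoef(profile, f)[0, 1]) == pytest.approx(1.0, abs=1e-10)
        assert ve == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_independent_eigendecomposition(self, seed):
        rng = np.random.default_rng(seed)
        expr = pd.DataFrame(rng.standard_normal((10, 8)))
        profile, ve = mod.eigengene(expr)
        x = expr.to_numpy()
        z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
        oracle_profile, oracle_ve = first_pc_eigh(z)
        assert ve == pytest.approx(oracle_ve, abs=1e-10)
        dot = abs(float(profile @ oracle_profile))
        assert dot == pytest.approx(1.0, abs=1e-10)

    def test_sign_oriented_towards_mean_profile(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(rng.standard_normal((6, 9)) + 2)
        profile, _ = mod.eigengene(expr)
        x = expr.to_numpy()
        z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
        assert profile @ z.mean(axis=0) >= 0

    def test_too_small_module_rejected(self):
        with pytest.raises(ValueError, match="2 genes"):
            mod.eigengene(pd.DataFrame([[1.0, 2.0, 3.0]]))


class TestMerge:
    def test_same_factor_modules_merge(self):
        rng = np.random.default_rng(0)
        f = rng.standard_normal(30)
        expr = pd.DataFrame(
            np.vstack(
                [
                    np.outer(rng.uniform(0.6, 1, 25), f) + 0.05 * rng.standard_normal((25, 30)),
                    np.outer(rng.uniform(0.6, 1, 20), f) + 0.05 * rng.standard_normal((20, 30)),
                ]
            ),
            index=[f"g{i}" for i in range(45)],
        )
        labels = {f"g{i}": ("m1" if i < 25 else "m2") for i in range(45)}
        asg = mod.ModuleAssignment(labels, 5, 0.9)
        merged, _ = mod.merge_modules(expr, asg, merge_threshold=0.25)
        assert len(merged.non_grey()) == 1
        assert merged.non_grey() == ["m1"]  # larger constituent keeps its label

    def test_orthogonal_factors_do_not_merge(self, expression_fixture):
        expr, _, gt = expression_fixture
        labels = {
            g: (f"m{m}" if m >= 0 else mod.GREY) for g, m in gt["module_of_gene"].items()
        }
        asg = mod.ModuleAssignment(labels, 5, 0.9)
        merged, _ = mod.merge_modules(expr, asg, merge_threshold=0.25)
        assert len(merged.non_grey()) == 3

    def test_zero_threshold_is_identity(self, expression_fixture):
        expr, _, gt = expression_fixture
        labels = {
            g: (f"m{m}" if m >= 0 else mod.GREY) for g, m in gt["module_of_gene"].items()
        }
        asg = mod.ModuleAssignment(labels, 5, 0.9)
        merged, _ = mod.merge_modules(expr, asg, merge_threshold=0.0)
        assert merged.labels == labels

    def test_merge_is_idempotent(self):
        rng = np.random.default_rng(5)
        f1, f2 = rng.standard_normal((2, 30))
        blocks = [
            np.outer(rng.uniform(0.6, 1, 20), f1),
            np.outer(rng.uniform(0.6, 1, 15), 0.9 * f1 + 0.4 * f2),
            np.outer(rng.uniform(0.6, 1, 10), f2),
        ]
        expr = pd.DataFrame(
            np.vstack(blocks) + 0.05 * rng.standard_normal((45, 30)),
            index=[f"g{i}" for i in range(45)],
        )
        labels = {}
        for i in range(45):
            labels[f"g{i}"] = "a" if i < 20 else ("b" if i < 35 else "c")
        asg = mod.ModuleAssignment(labels, 5, 0.9)
        once, _ = mod.merge_modules(expr, asg, 0.25)
        twice, _ = mod.merge_modules(expr, once, 0.25)
        assert once.labels == twice.labels


class TestModuleTraitRelationships:
    def _eg(self, expression_fixture):
        expr, traits, gt = expression_fixture
        labels = {
            g: (f"m{m}" if m >= 0 else mod.GREY) for g, m in gt["module_of_gene"].items()
        }
        asg = mod.ModuleAssignment(labels, 5, 0.9)
        return expr, traits, gt, asg, mod.module_eigengenes(expr, asg)

    def test_trait_equal_to_eigengene_is_perfectly_correlated(self, expression_fixture):
        expr, traits, gt, asg, eg = self._eg(expression_fixture)
        t2 = traits.copy()
        t2["self"] = eg.profiles["m0"]
        mtr = mod.module_trait_relationships(eg, t2)
        row = mtr[(mtr["module"] == "m0") & (mtr["trait"] == "self")].iloc[0]
        assert row["r"] == pytest.approx(1.0)
        assert row["p"] < 1e-15

    def test_planted_trait_correlation_recovered(self):
        # target |r| = 0.8 at n = 50; 20 seeds, recovery within +/- 0.15
        errs = []
        for seed in range(20):
            cfg = SynthConfig(
                seed=seed, n_samples=50, trait_module_map={"t": (0, 0.8)}
            )
            expr, traits, gt = make_expression(cfg)
            members = [g for g, m in gt["module_of_gene"].items() if m == 0]
            profile, _ = mod.eigengene(expr.loc[members])
            r = abs(np.corrcoef(profile, traits["t"])[0, 1])
            errs.append(abs(r - 0.8))
        assert max(errs) <= 0.15

    def test_bh_q_monotone_and_not_below_p(self, expression_fixture):
        expr, traits, gt, asg, eg = self._eg(expression_fixture)
        mtr = mod.module_trait_relationships(eg, traits).dropna(subset=["p"])
        s = mtr.sort_values("p")
        assert (s["q"].to_numpy() >= s["p"].to_numpy() - 1e-12).all()
        assert (np.diff(s["q"].to_numpy()) >= -1e-12).all()

    def test_zero_variance_trait_flagged_na(self, expression_fixture):
        expr, traits, gt, asg, eg = self._eg(expression_fixture)
        t2 = traits.copy()
        t2["flat"] = 1.0
        mtr = mod.module_trait_relationships(eg, t2)
        assert mtr.loc[mtr["trait"] == "flat", "r"].isna().all()
        assert mtr.loc[mtr["trait"] == "flat", "q"].isna().all()


class TestSignificantModules:
    def test_coherent_planted_module_qualifies(self):
        cfg = SynthConfig(seed=4, trait_module_map={"t": (0, 0.9)})
        expr, traits, gt = make_expression(cfg)
        labels = {
            g: (f"m{m}" if m >= 0 else mod.GREY) for g, m in gt["module_of_gene"].items()
        }
        asg = mod.ModuleAssignment(labels, 5, 0.9)
        eg = mod.module_eigengenes(expr, asg)
        mtr = mod.module_trait_relationships(eg, traits)
        stats = mod.gene_module_stats(expr, asg, eg, traits)
        sig = mod.significant_modules(mtr, stats)
        assert "m0" in set(sig["module"])

    def test_pure_noise_modules_rarely_qualify(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            expr = pd.DataFrame(
                rng.standard_normal((30, 40)), index=[f"g{i}" for i in range(30)]
            )
            traits = pd.DataFrame({"t": rng.standard_normal(40)})
            asg = mod.ModuleAssignment({f"g{i}": "noise" for i in range(30)}, 5, 0.9)
            eg = mod.module_eigengenes(expr, asg)
            mtr = mod.module_trait_relationships(eg, traits)
            stats = mod.gene_module_stats(expr, asg, eg, traits)
            if len(mod.significant_modules(mtr, stats)):
                hits += 1
        assert hits <= 1  # >= 19/20 seeds reject

    def test_unattainable_r2_cut_gives_empty_result(self, expression_fixture):
        expr, traits, gt = expression_fixture
        labels = {
            g: (f"m{m}" if m >= 0 else mod.GREY) for g, m in gt["module_of_gene"].items()
        }
        asg = mod.ModuleAssignment(labels, 5, 0.9)
        eg = mod.module_eigengenes(expr, asg)
        mtr = mod.module_trait_relationships(eg, traits)
        stats = mod.gene_module_stats(expr, asg, eg, traits)
        assert len(mod.significant_modules(mtr, stats, r2_cut=1.0)) == 0
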