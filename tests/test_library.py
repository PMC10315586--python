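import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hibed import (
    BetaMatrix,
    ComputeError,
    DEFAULT_HIERARCHY,
    ValidationError,
    build_hibed_library,
    compute_dsc,
    moderated_one_vs_rest,
    select_top_cpgs,
)
from hibed.hierarchy import LAYER1
from hibed.library import build_sub_library


def _ann(sample_ids, labels):
    return pd.DataFrame({"sample_id": sample_ids, "cell_type": labels})


def _planted_scenario(seed=7, n_probes=200, n_classes=3, n_per=5, n_signal=10, delta=0.6):
    """Three classes, planted hypermethylation blocks, Gaussian noise."""
    rng = np.random.default_rng(seed)
    classes = [f"C{k}" for k in range(n_classes)]
    samples = [f"{c}_{i}" for c in classes for i in range(n_per)]
    labels = [c for c in classes for _ in range(n_per)]
    base = np.full((n_probes, len(samples)), 0.3)
    planted = {}
    for k, cls in enumerate(classes):
        rows = np.arange(k * n_signal, (k + 1) * n_signal)
        cols = np.arange(k * n_per, (k + 1) * n_per)
        base[np.ix_(rows, cols)] += delta
        planted[cls] = [f"cg{r:04d}" for r in rows]
    base += rng.normal(0, 0.02, size=base.shape)
    beta = BetaMatrix([f"cg{i:04d}" for i in range(n_probes)], samples, np.clip(base, 0, 1))
    return beta, _ann(samples, labels), planted, classes


class TestModeratedOneVsRest:
    def test_flat_probe_has_zero_effect_and_t(self):
        beta = BetaMatrix(["cg1"], ["a1", "a2", "b1", "b2"], np.full((1, 4), 0.4))
        res = moderated_one_vs_rest(beta, _ann(beta.sample_ids, ["A", "A", "B", "B"]))
        assert res.effects.tolist() == [[0.0, 0.0]]
        assert res.t.tolist() == [[0.0, 0.0]]

    def test_two_class_effect_antisymmetry(self):
        beta = BetaMatrix(
            ["cg1"], ["a1", "a2", "b1", "b2"], np.array([[0.9, 0.9, 0.1, 0.1]])
        )
        res = moderated_one_vs_rest(beta, _ann(beta.sample_ids, ["A", "A", "B", "B"]))
        eff = res.effect_frame()
        assert eff.loc["cg1", "A"] == pytest.approx(0.8)
        assert eff.loc["cg1", "B"] == pytest.approx(-0.8)
        assert res.direction().loc["cg1", "A"] == "hyper"
        assert res.direction().loc["cg1", "B"] == "hypo"

    def test_small_class_raises(self):
        beta = BetaMatrix(["cg1"], ["a1", "b1", "b2"], np.array([[0.2, 0.3, 0.4]]))
        with pytest.raises(ValidationError, match=">=2 samples"):
            moderated_one_vs_rest(beta, _ann(beta.sample_ids, ["A", "B", "B"]))

    def test_planted_probes_dominate_top_ranks_vs_plain_t_oracle(self):
        """Moderated ranking recovers planted blocks at least as often as the
        plain two-sample t computed independently on the same data."""
        beta, ann, planted, classes = _planted_scenario()
        res = moderated_one_vs_rest(beta, ann, classes)
        labels = np.asarray(ann["cell_type"])
        hits_mod = 0
        hits_plain = 0
        for ci, cls in enumerate(classes):
            order = np.argsort(-np.abs(res.t[:, ci]), kind="stable")
            top = {beta.probe_ids[i] for i in order[:10]}
            hits_mod += len(top & set(planted[cls]))
            # independent oracle: plain Welch-free pooled two-sample t
            t_plain = stats.ttest_ind(
                beta.values[:, labels == cls].T, beta.values[:, labels != cls].T
            ).statistic
            order_p = np.argsort(-np.abs(t_plain), kind="stable")
            top_p = {beta.probe_ids[i] for i in order_p[:10]}
            hits_plain += len(top_p & set(planted[cls]))
        assert hits_mod >= 28
        assert hits_mod >= hits_plain - 2


class TestSelectTopCpgs:
    def test_hyper_takes_exactly_the_largest(self):
        beta, ann, planted, classes = _planted_scenario()
        res = moderated_one_vs_rest(beta, ann, classes)
        per_class, _ = select_top_cpgs(res, 3, mode="hyper")
        for ci, cls in enumerate(classes):
            expected = [
                res.probe_ids[i] for i in np.argsort(-res.t[:, ci], kind="stable")[:3]
            ]
            assert set(per_class[cls]["hyper"]) == set(expected)

    def test_two_class_mirror_symmetry(self):
        rng = np.random.default_rng(3)
        beta = BetaMatrix(
            [f"cg{i}" for i in range(50)],
            [f"s{j}" for j in range(8)],
            rng.uniform(0.1, 0.9, size=(50, 8)),
        )
        res = moderated_one_vs_rest(beta, _ann(beta.sample_ids, ["A"] * 4 + ["B"] * 4))
        per_class, pooled = select_top_cpgs(res, 1, mode="hybrid")
        assert per_class["A"]["hyper"] == per_class["B"]["hypo"]
        assert per_class["A"]["hypo"] == per_class["B"]["hyper"]
        assert len(pooled) <= 4

    def test_planted_scenario_hybrid_recovers_planted_probes(self):
        beta, ann, planted, classes = _planted_scenario()
        res = moderated_one_vs_rest(beta, ann, classes)
        _, pooled = select_top_cpgs(res, 10, mode="hybrid")
        planted_all = {p for ps in planted.values() for p in ps}
        assert len(planted_all & set(pooled)) >= 0.9 * len(planted_all)

    def test_hybrid_pools_both_directions(self):
        beta, ann, _, classes = _planted_scenario()
        res = moderated_one_vs_rest(beta, ann, classes)
        per_hyb, pooled_hyb = select_top_cpgs(res, 5, mode="hybrid")
        _, pooled_hyper = select_top_cpgs(res, 5, mode="hyper")
        _, pooled_hypo = select_top_cpgs(res, 5, mode="hypo")
        assert set(pooled_hyb) >= set(pooled_hyper)
        assert set(pooled_hyb) >= set(pooled_hypo)

    def test_excess_n_raises(self):
        beta, ann, _, classes = _planted_scenario()
        res = moderated_one_vs_rest(beta, ann, classes)
        with pytest.raises(ValidationError, match="exceeds"):
            select_top_cpgs(res, len(beta.probe_ids) + 1)


class TestBuildSubLibrary:
    def test_single_class_mean(self):
        beta = BetaMatrix(["cg1"], ["s1", "s2"], np.array([[0.2, 0.4]]))
        labels = pd.Series(["A", "A"], index=beta.sample_ids)
        sub = build_sub_library(beta, labels, ["A"], ["cg1"], "node")
        assert sub.means[0, 0] == pytest.approx(0.3)

    def test_layer1_pooled_mean_differs_from_mean_of_leaf_means(self):
        # 2 GABA samples at 0.2, 4 GLU samples at 0.8: pooled neuronal mean
        # is (2*0.2 + 4*0.8)/6, not (0.2+0.8)/2
        samples = ["g1", "g2", "u1", "u2", "u3", "u4"]
        beta = BetaMatrix(["cg1"], samples, np.array([[0.2, 0.2, 0.8, 0.8, 0.8, 0.8]]))
        groups = pd.Series(["Neuronal"] * 6, index=samples)
        sub = build_sub_library(beta, groups, ["Neuronal"], ["cg1"], LAYER1)
        pooled = (2 * 0.2 + 4 * 0.8) / 6
        assert sub.means[0, 0] == pytest.approx(pooled)
        assert sub.means[0, 0] != pytest.approx((0.2 + 0.8) / 2)

    def test_constant_matrix_gives_constant_means(self):
        beta = BetaMatrix(["cg1", "cg2"], ["s1", "s2"], np.full((2, 2), 0.7))
        labels = pd.Series(["A", "B"], index=beta.sample_ids)
        sub = build_sub_library(beta, labels, ["A", "B"], ["cg1", "cg2"], "node")
        assert (sub.means == 0.7).all()

    def test_empty_class_raises(self):
        beta = BetaMatrix(["cg1", "cg2"], ["s1", "s2"], np.full((2, 2), 0.5))
        labels = pd.Series(["A", "A"], index=beta.sample_ids)
        with pytest.raises(ValidationError, match="zero samples"):
            build_sub_library(beta, labels, ["A", "B"], ["cg1", "cg2"], "node")


class TestBuildHibedLibrary:
    def test_four_sub_libraries_with_expected_labels(self, library):
        assert set(library.sub_libraries) == {"Layer1", "Layer2A", "Layer2B", "Layer2C"}
        assert library.sub_libraries["Layer1"].cell_types == [
            "Neuronal", "Glial", "EndoStromal",
        ]
        assert library.sub_libraries["Layer2C"].cell_types == ["GABA", "GLU"]

    def test_identifiability_invariant(self, library):
        for sub in library.sub_libraries.values():
            assert len(sub.probe_ids) >= len(sub.cell_types)

    def test_layer1_probes_mostly_disjoint_from_layer2(self, ref_panel):
        # group and leaf signals occupy distinct planted blocks, so when the
        # selection size matches the planted marker count per direction the
        # Layer-1 library should barely overlap the Layer-2 libraries
        beta, ann, _ = ref_panel
        lib = build_hibed_library(beta, ann, n_per_type=10)
        l1 = set(lib.sub_libraries["Layer1"].probe_ids)
        l2 = set().union(
            *(set(lib.sub_libraries[n].probe_ids) for n in ("Layer2A", "Layer2B", "Layer2C"))
        )
        assert len(l1 & l2) < 0.5 * len(l1)

    def test_layer2_nodes_carry_complement_profiles(self, library):
        assert library.sub_libraries["Layer1"].complement_mean is None
        for node in ("Layer2A", "Layer2B", "Layer2C"):
            sub = library.sub_libraries[node]
            assert sub.complement_mean is not None
            assert sub.complement_mean.shape == (len(sub.probe_ids),)

    def test_deterministic_rebuild(self, ref_panel, library):
        beta, ann, _ = ref_panel
        again = build_hibed_library(beta, ann)
        for node, sub in library.sub_libraries.items():
            assert again.sub_libraries[node].probe_ids == sub.probe_ids
            np.testing.assert_array_equal(again.sub_libraries[node].means, sub.means)


class TestDSC:
    def test_hand_computed_example(self):
        beta = BetaMatrix(["cg1"], ["a1", "a2", "b1", "b2"],
                          np.array([[0.1, 0.3, 0.7, 0.9]]))
        ann = _ann(beta.sample_ids, ["A", "A", "B", "B"])
        d = compute_dsc(beta, ann, ["cg1"])
        assert d.between_dispersion == pytest.approx(0.3)
        assert d.within_dispersion == pytest.approx(0.1)
        assert d.value == pytest.approx(3.0)

    def test_within_class_duplicates_give_infinity(self):
        beta = BetaMatrix(["cg1"], ["a1", "a2", "b1", "b2"],
                          np.array([[0.2, 0.2, 0.8, 0.8]]))
        d = compute_dsc(beta, _ann(beta.sample_ids, ["A", "A", "B", "B"]), ["cg1"])
        assert math.isinf(d.value)

    def test_invariant_under_sample_permutation(self):
        rng = np.random.default_rng(5)
        beta = BetaMatrix(
            [f"cg{i}" for i in range(10)],
            [f"s{j}" for j in range(8)],
            rng.uniform(0, 1, size=(10, 8)),
        )
        labels = ["A", "B", "A", "B", "A", "B", "A", "B"]
        d1 = compute_dsc(beta, _ann(beta.sample_ids, labels), beta.probe_ids)
        perm = [3, 0, 7, 1, 5, 2, 6, 4]
        beta2 = beta.select_samples([beta.sample_ids[i] for i in perm])
        labels2 = [labels[i] for i in perm]
        d2 = compute_dsc(beta2, _ann(beta2.sample_ids, labels2), beta.probe_ids)
        assert d2.value == pytest.approx(d1.value, rel=1e-12)

    def test_degenerate_and_single_class_raise(self):
        beta = BetaMatrix(["cg1"], ["a", "b"], np.array([[0.5, 0.5]]))
        with pytest.raises(ComputeError, match="degenerate"):
            compute_dsc(beta, _ann(["a", "b"], ["A", "B"]), ["cg1"])
        with pytest.raises(ValidationError, match=">=2 classes"):
            compute_dsc(beta, _ann(["a", "b"], ["A", "A"]), ["cg1"])

    def test_library_probes_separate_better_than_random(self, ref_panel, library):
        """Cell-type-specific probes should beat random probe sets of equal
        size in most draws."""
        beta, ann, _ = ref_panel
        probes = library.sub_libraries["Layer2B"].probe_ids
        glial = ann[ann["cell_type"].isin(["Astrocyte", "Microglia", "Oligodendrocyte"])]
        sub_beta = beta.select_samples(list(glial["sample_id"]))
        d_lib = compute_dsc(sub_beta, glial, probes).value
        rng = np.random.default_rng(0)
        wins = 0
        for _ in range(10):
            rand = list(rng.choice(beta.probe_ids, size=len(probes), replace=False))
            if d_lib > compute_dsc(sub_beta, glial, rand).value:
                wins += 1
        assert wins >= 9
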