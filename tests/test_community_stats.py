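"""Unit tests for distances, ordination, PERMANOVA and OTU-level summaries."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist, squareform

from seaflood import (
    DistanceMatrix, InputError, bray_curtis, hierarchical_cluster, nmds,
    permanova, fit_env_vectors, sharing_counts, detect_modules,
)
from seaflood.trflp_pipeline import OtuTable


def table_from(matrix, samples=None, otus=None) -> OtuTable:
    m = np.asarray(matrix, float)
    samples = samples or [f"s{i}" for i in range(m.shape[0])]
    otus = otus or [f"o{j}" for j in range(m.shape[1])]
    df = pd.DataFrame(m, index=samples, columns=otus)
    centroids = pd.Series(np.arange(len(otus), dtype=float) * 10 + 100,
                          index=otus)
    ranges = pd.DataFrame({"size_min": centroids - 0.1,
                           "size_max": centroids + 0.1})
    return OtuTable(data=df, centroids=centroids, size_ranges=ranges,
                    state="relative")


def naive_bray_curtis(a, b):
    return 1.0 - 2.0 * np.minimum(a, b).sum() / (a.sum() + b.sum())


class TestBrayCurtis:
    @pytest.mark.parametrize("a,b,expected", [
        ((1, 0), (0, 1), 1.0),
        ((2, 1, 3), (2, 1, 3), 0.0),
        ((2, 1, 0), (1, 1, 1), 1.0 / 3.0),
    ])
    def test_closed_forms(self, a, b, expected):
        d = bray_curtis(table_from([a, b]))
        assert d.values[0, 1] == pytest.approx(expected, abs=1e-12)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(2, 12), st.integers(1, 8), st.integers(0, 10 ** 6))
    def test_matches_double_loop_oracle(self, n, m, seed):
        rng = np.random.default_rng(seed)
        mat = rng.random((n, m)) + 1e-6
        d = bray_curtis(table_from(mat))
        for i, j in itertools.combinations(range(n), 2):
            assert d.values[i, j] == pytest.approx(
                naive_bray_curtis(mat[i], mat[j]), abs=1e-12)

    def test_zero_sum_row_named_in_error(self):
        with pytest.raises(InputError, match="s1"):
            bray_curtis(table_from([[1, 2], [0, 0]]))

    def test_otu_axis(self):
        d = bray_curtis(table_from([[1, 0], [0, 1]]), axis="otus")
        assert d.labels == ("o0", "o1")
        assert d.values[0, 1] == pytest.approx(1.0)


class TestHierarchicalCluster:
    def test_closest_pair_merges_first(self):
        vals = np.array([[0.0, 0.1, 0.9], [0.1, 0.0, 0.8], [0.9, 0.8, 0.0]])
        tree = hierarchical_cluster(DistanceMatrix(("a", "b", "c"), vals))
        assert set(tree.linkage[0, :2].astype(int)) == {0, 1}

    def test_ultrametric_input_reproduced_cophenetically(self):
        # a valid ultrametric: d(a,b)=0.2, all others 0.6
        vals = np.full((4, 4), 0.6)
        np.fill_diagonal(vals, 0.0)
        vals[0, 1] = vals[1, 0] = 0.2
        vals[2, 3] = vals[3, 2] = 0.4
        tree = hierarchical_cluster(DistanceMatrix(tuple("abcd"), vals))
        assert np.allclose(tree.cophenetic(), vals, atol=1e-12)

    def test_label_permutation_preserves_topology(self):
        rng = np.random.default_rng(3)
        pts = rng.random((6, 3))
        vals = squareform(pdist(pts))
        labels = tuple("abcdef")
        t1 = hierarchical_cluster(DistanceMatrix(labels, vals))
        perm = np.array([3, 1, 5, 0, 2, 4])
        t2 = hierarchical_cluster(DistanceMatrix(
            tuple(labels[i] for i in perm), vals[np.ix_(perm, perm)]))
        c1 = pd.DataFrame(t1.cophenetic(), index=labels, columns=labels)
        c2 = pd.DataFrame(t2.cophenetic(), index=[labels[i] for i in perm],
                          columns=[labels[i] for i in perm])
        assert np.allclose(c1, c2.loc[list(labels), list(labels)], atol=1e-12)

    def test_single_item_rejected(self):
        with pytest.raises(InputError):
            hierarchical_cluster(DistanceMatrix(("a",), np.zeros((1, 1))))


class TestNmds:
    def test_planar_configuration_has_negligible_stress(self):
        pts = np.array([[0, 0], [1, 0], [0, 1], [1, 1.0]])
        d = DistanceMatrix(tuple("abcd"), squareform(pdist(pts)))
        assert nmds(d, n_restarts=10, seed=0).stress < 0.01

    def test_identical_samples_coincide(self):
        vals = np.array([[0, 0, 0.6, 0.5], [0, 0, 0.6, 0.5],
                         [0.6, 0.6, 0, 0.4], [0.5, 0.5, 0.4, 0.0]])
        o = nmds(DistanceMatrix(tuple("pqrs"), vals), n_restarts=10, seed=1)
        scale = np.abs(o.scores).max()
        assert np.linalg.norm(o.scores[0] - o.scores[1]) < 0.05 * scale

    def test_seed_determinism_and_best_of_restarts(self):
        rng = np.random.default_rng(7)
        vals = squareform(pdist(rng.random((8, 4)), "braycurtis"))
        d = DistanceMatrix(tuple(f"s{i}" for i in range(8)), vals)
        o1 = nmds(d, n_restarts=6, seed=42)
        o2 = nmds(d, n_restarts=6, seed=42)
        assert np.array_equal(o1.scores, o2.scores)
        assert o1.stress == min(o1.restart_stresses)
        assert np.allclose(o1.scores.mean(axis=0), 0.0, atol=1e-9)


def oracle_one_factor(dist: np.ndarray, groups: list) -> tuple[float, float]:
    """Brute-force one-factor SS partition straight from the distances."""
    n = len(groups)
    ss_total = (dist[np.triu_indices(n, 1)] ** 2).sum() / n
    ss_within = 0.0
    for g in set(groups):
        idx = [i for i, x in enumerate(groups) if x == g]
        sub = dist[np.ix_(idx, idx)]
        ss_within += (sub[np.triu_indices(len(idx), 1)] ** 2).sum() / len(idx)
    return ss_total, ss_total - ss_within


class TestPermanova:
    def labels(self, n):
        return tuple(f"s{i}" for i in range(n))

    def test_r2_partition_sums_to_one(self):
        rng = np.random.default_rng(0)
        vals = squareform(pdist(rng.random((9, 4)), "braycurtis"))
        meta = pd.DataFrame({"a": list("xxxyyyzzz"), "b": list("uvuvuvuvu")},
                            index=self.labels(9))
        res = permanova(DistanceMatrix(self.labels(9), vals), meta,
                        terms=["a", "b"], n_perm=99, exhaustive_cap=1, seed=0)
        assert sum(res.r2) + res.residual_r2 == pytest.approx(1.0, abs=1e-9)

    def test_one_factor_matches_bruteforce_partition(self):
        rng = np.random.default_rng(1)
        for trial in range(10):
            n = int(rng.integers(6, 11))
            groups = [("A", "B")[i % 2] for i in range(n)]
            vals = squareform(pdist(rng.random((n, 5)), "braycurtis"))
            meta = pd.DataFrame({"g": groups}, index=self.labels(n))
            res = permanova(DistanceMatrix(self.labels(n), vals), meta,
                            terms=["g"], n_perm=99, exhaustive_cap=1, seed=0)
            ss_total, ss_g = oracle_one_factor(vals, groups)
            assert res.total_ss == pytest.approx(ss_total, abs=1e-12)
            assert res.ss[0] == pytest.approx(ss_g, abs=1e-12)

    def test_perfectly_separated_exhaustive_p(self):
        vals = np.ones((6, 6))
        vals[:3, :3] = 0
        vals[3:, 3:] = 0
        np.fill_diagonal(vals, 0)
        meta = pd.DataFrame({"g": ["a"] * 3 + ["b"] * 3}, index=self.labels(6))
        res = permanova(DistanceMatrix(self.labels(6), vals), meta, terms=["g"])
        assert res.exhaustive
        # 10 distinct 3+3 splits; only the true one separates perfectly
        assert res.p[0] == pytest.approx(0.1)
        assert res.r2[0] == pytest.approx(1.0)

    def test_matches_skbio_pseudo_f(self):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(5)
        vals = squareform(pdist(rng.random((10, 6)), "braycurtis"))
        groups = list("aaabbbcccc")
        meta = pd.DataFrame({"g": groups}, index=self.labels(10))
        res = permanova(DistanceMatrix(self.labels(10), vals), meta,
                        terms=["g"], n_perm=99, exhaustive_cap=1, seed=0)
        sk = skbio_stats.permanova(
            skbio_stats.DistanceMatrix(vals, ids=self.labels(10)),
            meta, column="g", permutations=99)
        assert res.f[0] == pytest.approx(sk["test statistic"], rel=1e-10)

    def test_exhaustive_p_invariant_to_sample_order(self):
        rng = np.random.default_rng(9)
        vals = squareform(pdist(rng.random((6, 4)), "braycurtis"))
        groups = ["a", "a", "a", "b", "b", "b"]
        meta = pd.DataFrame({"g": groups}, index=self.labels(6))
        res1 = permanova(DistanceMatrix(self.labels(6), vals), meta, terms=["g"])
        perm = np.array([4, 0, 5, 2, 1, 3])
        labels2 = tuple(f"s{i}" for i in perm)
        res2 = permanova(DistanceMatrix(labels2, vals[np.ix_(perm, perm)]),
                         meta, terms=["g"])
        assert res1.p[0] == pytest.approx(res2.p[0])
        assert res1.f[0] == pytest.approx(res2.f[0], rel=1e-10)

    def test_constant_factor_rejected_and_singletons_flagged(self):
        rng = np.random.default_rng(2)
        vals = squareform(pdist(rng.random((6, 4)), "braycurtis"))
        meta = pd.DataFrame({"g": ["x"] * 6, "h": list("aabbbc")},
                            index=self.labels(6))
        with pytest.raises(InputError, match="constant"):
            permanova(DistanceMatrix(self.labels(6), vals), meta, terms=["g"])
        res = permanova(DistanceMatrix(self.labels(6), vals), meta, terms=["h"])
        assert "h" in res.singleton_groups


class TestVectorFit:
    def make_ordination(self):
        rng = np.random.default_rng(0)
        vals = squareform(pdist(rng.random((12, 5)), "braycurtis"))
        labels = tuple(f"s{i}" for i in range(12))
        return nmds(DistanceMatrix(labels, vals), n_restarts=4, seed=0)

    def test_axis_aligned_variables(self):
        o = self.make_ordination()
        env = pd.DataFrame({"v1": o.scores[:, 0], "v2": -o.scores[:, 1]},
                           index=o.labels)
        fit = fit_env_vectors(o, env, n_perm=99, seed=0)
        assert fit.r2[0] == pytest.approx(1.0, abs=1e-9)
        assert fit.directions[0] == pytest.approx([1.0, 0.0], abs=1e-6)
        assert fit.directions[1] == pytest.approx([0.0, -1.0], abs=1e-6)
        assert np.allclose(np.linalg.norm(fit.directions, axis=1), 1.0)

    def test_zero_variance_variable_skipped(self):
        o = self.make_ordination()
        env = pd.DataFrame({"flat": np.ones(12)}, index=o.labels)
        fit = fit_env_vectors(o, env, n_perm=99, seed=0)
        assert fit.skipped == ("flat",) and fit.variables == ()


class TestSharingCounts:
    def test_enumerable_example(self):
        counts = sharing_counts({"UC": {"A", "B", "C"}, "C": {"B", "C", "D"},
                                 "SW": {"C"}})
        as_dict = dict(zip(counts["groups"], counts["n_otus"]))
        assert as_dict["UC+C+SW"] == 1
        assert as_dict["UC+C"] == 1
        assert as_dict["UC"] == 1 and as_dict["C"] == 1
        assert counts["n_otus"].sum() == 4

    def test_identical_and_disjoint_sets(self):
        same = sharing_counts({"a": {"x", "y"}, "b": {"x", "y"}})
        assert dict(zip(same["groups"], same["n_otus"]))["a+b"] == 2
        disjoint = sharing_counts({"a": {"x"}, "b": {"y"}})
        d = dict(zip(disjoint["groups"], disjoint["n_otus"]))
        assert d["a"] == 1 and d["b"] == 1 and d["a+b"] == 0


class TestDetectModules:
    def test_disjoint_blocks_recovered(self):
        mat = np.zeros((6, 8))
        mat[:3, :4] = 0.25   # block 1 occupies first three samples
        mat[3:, 4:] = 0.25   # block 2 the rest
        modules = detect_modules(table_from(mat), k=2)
        assert modules.iloc[:4].nunique() == 1
        assert modules.iloc[4:].nunique() == 1
        assert modules.iloc[0] != modules.iloc[7]
        assert modules.iloc[0] == 1  # earliest-appearing block is module 1

    def test_k_equals_n_otus(self):
        rng = np.random.default_rng(4)
        mat = rng.random((5, 6)) + 0.01
        modules = detect_modules(table_from(mat), k=6)
        assert modules.nunique() == 6

    def test_duplicated_profiles_share_a_module(self):
        rng = np.random.default_rng(8)
        mat = rng.random((5, 5)) + 0.01
        mat[:, 1] = mat[:, 0]   # duplicate profile
        for k in range(2, 5):
            modules = detect_modules(table_from(mat), k=k)
            assert modules.iloc[0] == modules.iloc[1]

    def test_k_too_large_rejected(self):
        with pytest.raises(InputError):
            detect_modules(table_from(np.ones((3, 3))), k=4)


def test_flooding_scenario_time_effect_detected(default_scenario):
    """On a scenario with module turnover the time-point term dominates."""
    from seaflood import run_pipeline
    truth, bundle = default_scenario
    table = run_pipeline(bundle.peaks)["log"]
    d = bray_curtis(table)
    meta = bundle.metadata.set_index("sample_id")
    res = permanova(d, meta, terms=["time_point", "station"], n_perm=199,
                    seed=0, exhaustive_cap=1)
    assert res.p[0] <= 0.05
    assert res.r2[0] > res.residual_r2 * 0.1
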