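"""Jaccard distances, bootstrap intervals, PCoA and PERMDISP."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from acupanel.core_data import ValidationError
from acupanel.variability import (
    DistanceMatrix,
    bootstrap_difference_ci,
    jaccard_dissimilarity,
    mean_pairwise_dissimilarity,
    pairwise_distance_matrix,
    pcoa_embedding,
    permdisp,
)
from acupanel.variability import _anova_f, _centroid_distances
from conftest import make_dataset

sets_strategy = st.sets(st.sampled_from(list("ABCDEFGH")), max_size=6)


class TestJaccard:
    def test_identical_sets(self):
        assert jaccard_dissimilarity({"LI4", "LR3", "SP6"}, {"LI4", "LR3", "SP6"}) == 0.0

    def test_disjoint_sets(self):
        assert jaccard_dissimilarity({"LI4", "LR3"}, {"BL23", "GB30"}) == 1.0

    def test_half_overlap(self):
        assert jaccard_dissimilarity({"LI4", "LR3", "SP6"}, {"SP6", "LR3", "BL23"}) == 0.5

    def test_both_empty_convention(self):
        assert jaccard_dissimilarity(set(), set()) == 0.0

    @given(s1=sets_strategy, s2=sets_strategy, s3=sets_strategy)
    def test_metric_properties(self, s1, s2, s3):
        d12 = jaccard_dissimilarity(s1, s2)
        d21 = jaccard_dissimilarity(s2, s1)
        assert d12 == d21
        assert 0.0 <= d12 <= 1.0
        assert (d12 == 0.0) == (s1 == s2)
        d13 = jaccard_dissimilarity(s1, s3)
        d23 = jaccard_dissimilarity(s2, s3)
        assert d12 <= d13 + d23 + 1e-12


class TestPairwiseMatrix:
    def test_identical_responses(self, vocab):
        ds = make_dataset(vocab, {"case1": {"GPT": [{"ST36", "LI4"}] * 3}})
        m = pairwise_distance_matrix(ds, "case1")
        assert np.allclose(m.d, 0.0)

    def test_two_disjoint_responses(self, vocab):
        ds = make_dataset(vocab, {"case1": {"GPT": [{"ST36"}, {"LI4"}]}})
        m = pairwise_distance_matrix(ds, "case1")
        assert m.d[0, 1] == 1.0

    def test_matches_double_loop_oracle(self, vocab):
        rng = np.random.default_rng(42)
        codes = list(vocab.codes)
        sets = [
            set(rng.choice(codes, size=rng.integers(3, 6), replace=False))
            for _ in range(10)
        ]
        ds = make_dataset(vocab, {"case1": {"KMD": sets[:6], "GPT": sets[6:]}})
        m = pairwise_distance_matrix(ds, "case1")
        ordered = [r.acupoints for r in ds.case_responses("case1")]
        for i in range(10):
            for j in range(10):
                assert m.d[i, j] == pytest.approx(
                    jaccard_dissimilarity(ordered[i], ordered[j])
                )

    def test_single_response_rejected(self, vocab):
        ds = make_dataset(vocab, {"case1": {"GPT": [{"ST36"}]}})
        with pytest.raises(ValidationError):
            pairwise_distance_matrix(ds, "case1")


class TestMeanPairwise:
    def test_group_of_two(self, vocab):
        ds = make_dataset(vocab, {"case1": {"GPT": [{"ST36", "LI4"}, {"ST36", "SP6"}]}})
        m = pairwise_distance_matrix(ds, "case1")
        expected = jaccard_dissimilarity({"ST36", "LI4"}, {"ST36", "SP6"})
        assert mean_pairwise_dissimilarity(m, "GPT") == pytest.approx(expected)

    def test_enumerated_pairs_oracle(self, vocab):
        rng = np.random.default_rng(7)
        codes = list(vocab.codes)
        sets = [
            frozenset(rng.choice(codes, size=rng.integers(3, 6), replace=False))
            for _ in range(5)
        ]
        ds = make_dataset(vocab, {"case1": {"KMD": [set(s) for s in sets]}})
        m = pairwise_distance_matrix(ds, "case1")
        pairs = [
            jaccard_dissimilarity(a, b) for a, b in itertools.combinations(sets, 2)
        ]
        assert len(pairs) == 10
        assert mean_pairwise_dissimilarity(m, "KMD") == pytest.approx(np.mean(pairs))

    def test_small_group_rejected(self, vocab):
        ds = make_dataset(
            vocab, {"case1": {"KMD": [{"ST36"}], "GPT": [{"LI4"}, {"SP6"}]}}
        )
        m = pairwise_distance_matrix(ds, "case1")
        with pytest.raises(ValidationError):
            mean_pairwise_dissimilarity(m, "KMD")


class TestBootstrapCI:
    def test_degenerate_groups_give_zero_interval(self, vocab):
        ds = make_dataset(
            vocab,
            {
                "case1": {
                    "KMD": [{"ST36", "LI4", "SP6"}] * 4,
                    "GPT": [{"LR3", "CV12", "KI3"}] * 4,
                }
            },
        )
        ci = bootstrap_difference_ci(ds, "case1", "KMD", "GPT", n_boot=200, seed=1)
        assert ci.point == 0.0
        assert (ci.lower, ci.upper) == (0.0, 0.0)

    def test_constructed_heterogeneity_gap_excludes_zero(self, vocab):
        spread = [
            {"ST36", "LI4", "SP6"},
            {"LR3", "CV12", "BL23"},
            {"GB30", "KI3", "PC6"},
            {"HT7", "ST36", "CV12"},
            {"LI4", "BL23", "KI3"},
            {"SP6", "GB30", "HT7"},
        ]
        ds = make_dataset(
            vocab,
            {"case1": {"KMD": spread, "GPT": [{"ST36", "LI4", "SP6"}] * 6}},
        )
        ci = bootstrap_difference_ci(ds, "case1", "KMD", "GPT", n_boot=500, seed=2)
        assert ci.point > 0
        assert ci.lower > 0

    def test_seed_determinism(self, two_group_dataset):
        a = bootstrap_difference_ci(
            two_group_dataset, "case1", "KMD", "GPT", n_boot=300, seed=11
        )
        b = bootstrap_difference_ci(
            two_group_dataset, "case1", "KMD", "GPT", n_boot=300, seed=11
        )
        assert (a.lower, a.upper, a.point) == (b.lower, b.upper, b.point)

    def test_low_n_boot_rejected(self, two_group_dataset):
        with pytest.raises(ValueError):
            bootstrap_difference_ci(
                two_group_dataset, "case1", "KMD", "GPT", n_boot=50
            )


class TestPCoA:
    def test_equilateral_simplex(self):
        # 3 points pairwise at distance delta embed exactly in 2 positive axes
        delta = 0.8
        d = np.full((3, 3), delta)
        np.fill_diagonal(d, 0.0)
        emb = pcoa_embedding(d)
        assert emb.coords_pos.shape[1] == 2
        assert emb.coords_neg.shape[1] == 0
        for i in range(3):
            for j in range(i + 1, 3):
                got = np.linalg.norm(emb.coords_pos[i] - emb.coords_pos[j])
                assert got == pytest.approx(delta)

    def test_collinear_points_recovered(self):
        # classical MDS on points on a line: one dominant axis, distances exact
        x = np.array([0.0, 1.0, 2.0, 5.0])
        d = np.abs(x[:, None] - x[None, :])
        emb = pcoa_embedding(d)
        assert emb.coords_pos.shape[1] == 1
        rec = emb.coords_pos[:, 0]
        assert np.allclose(
            np.abs(rec[:, None] - rec[None, :]), d, atol=1e-9
        )

    def test_zero_matrix(self):
        emb = pcoa_embedding(np.zeros((4, 4)))
        assert emb.eigvals_pos.size == 0 and emb.eigvals_neg.size == 0

    def test_asymmetric_rejected(self):
        d = np.array([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ValidationError):
            pcoa_embedding(d)

    def test_jaccard_matrix_can_have_negative_eigenvalues(self, vocab):
        rng = np.random.default_rng(3)
        codes = list(vocab.codes)
        sets = [
            set(rng.choice(codes, size=rng.integers(3, 6), replace=False))
            for _ in range(12)
        ]
        ds = make_dataset(vocab, {"case1": {"KMD": sets}})
        emb = pcoa_embedding(pairwise_distance_matrix(ds, "case1"))
        assert emb.eigvals_neg.size > 0  # Jaccard is generally non-Euclidean


def _matrix_from_sets(sets_by_group):
    ids, labels, all_sets = [], {}, []
    for g, sets in sets_by_group.items():
        for i, s in enumerate(sets):
            rid = f"{g}{i}"
            ids.append(rid)
            labels[rid] = g
            all_sets.append(frozenset(s))
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d[i, j] = jaccard_dissimilarity(all_sets[i], all_sets[j])
    return DistanceMatrix(ids=tuple(ids), d=d, labels=labels)


class TestPermdisp:
    def test_constructed_separation(self, vocab):
        spread = [
            {"ST36", "LI4", "SP6"},
            {"LR3", "CV12", "BL23"},
            {"GB30", "KI3", "PC6"},
            {"HT7", "ST36", "CV12"},
            {"LI4", "BL23", "KI3"},
            {"SP6", "GB30", "HT7"},
            {"ST36", "KI3", "HT7"},
            {"LR3", "GB30", "LI4"},
        ]
        m = _matrix_from_sets({"KMD": spread, "GPT": [{"ST36", "LI4", "SP6"}] * 8})
        res = permdisp(m, n_perm=999, seed=5)
        assert res.group_mean_dist["KMD"] > res.group_mean_dist["GPT"]
        assert res.p_value < 0.05

    def test_p_value_convention(self, two_group_dataset):
        m = pairwise_distance_matrix(two_group_dataset, "case1")
        res = permdisp(m, n_perm=99, seed=0)
        assert res.p_value >= 1 / 100
        assert res.p_value * 100 == pytest.approx(round(res.p_value * 100))

    def test_f_invariant_to_relabeling_and_permutation(self, vocab):
        rng = np.random.default_rng(9)
        codes = list(vocab.codes)
        sets = [
            set(rng.choice(codes, size=rng.integers(3, 6), replace=False))
            for _ in range(10)
        ]
        m = _matrix_from_sets({"A": sets[:5], "B": sets[5:]})
        base = permdisp(m, n_perm=49, seed=1).F_stat
        # swap group names
        m_swapped = DistanceMatrix(
            ids=m.ids,
            d=m.d,
            labels={k: ("B" if v == "A" else "A") for k, v in m.labels.items()},
        )
        assert permdisp(m_swapped, n_perm=49, seed=2).F_stat == pytest.approx(base)
        # permute rows/columns jointly
        perm = rng.permutation(len(m.ids))
        m_perm = DistanceMatrix(
            ids=tuple(m.ids[i] for i in perm),
            d=m.d[np.ix_(perm, perm)],
            labels=m.labels,
        )
        assert permdisp(m_perm, n_perm=49, seed=3).F_stat == pytest.approx(base)

    def test_group_of_one_rejected(self):
        m = _matrix_from_sets({"A": [{"X"}], "B": [{"Y"}, {"Z"}]})
        with pytest.raises(ValidationError):
            permdisp(m, n_perm=9, seed=0)

    def test_seed_determinism(self, two_group_dataset):
        m = pairwise_distance_matrix(two_group_dataset, "case1")
        a = permdisp(m, n_perm=199, seed=8)
        b = permdisp(m, n_perm=199, seed=8)
        assert a.p_value == b.p_value and a.F_stat == b.F_stat
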