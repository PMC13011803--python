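"""Distance-based ecology: Bray-Curtis, PCoA, PERMANOVA, envfit, Procrustes, dbRDA."""

import numpy as np
import pandas as pd
import pytest
import scipy.spatial
from scipy.spatial.distance import pdist, squareform

from domlink.ecology import (
    DistanceMatrix,
    bray_curtis,
    dbrda,
    envfit_vectors,
    pcoa,
    permanova,
    procrustes_protest,
)


def frame(arr, labels=None):
    arr = np.asarray(arr, dtype=float)
    labels = labels or [f"s{i}" for i in range(arr.shape[1])]
    return pd.DataFrame(arr, columns=labels)


class TestBrayCurtis:
    def test_hand_examples(self):
        df = frame(np.array([[1, 3, 1], [2, 2, 2], [3, 1, 3]]))
        d = bray_curtis(df)
        assert d.d[0, 1] == pytest.approx(1 / 3)  # (1,2,3) vs (3,2,1)
        assert d.d[0, 2] == pytest.approx(0.0)  # identical columns
        # disjoint supports
        dd = bray_curtis(frame(np.array([[1, 0], [0, 2]])))
        assert dd.d[0, 1] == pytest.approx(1.0)

    def test_matches_scipy_oracle_and_bounds(self):
        rng = np.random.default_rng(0)
        x = rng.random((15, 10))
        d = bray_curtis(frame(x))
        oracle = squareform(pdist(x.T, metric="braycurtis"))
        np.testing.assert_allclose(d.d, oracle, atol=1e-12)
        assert (d.d >= 0).all() and (d.d <= 1).all()
        np.testing.assert_allclose(d.d, d.d.T)
        np.testing.assert_allclose(np.diag(d.d), 0)

    def test_all_zero_pair_is_undefined(self):
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis(frame(np.array([[0.0, 0.0], [0.0, 0.0]])))


class TestPcoa:
    def test_three_collinear_points(self):
        labels = ["a", "b", "c"]
        d = DistanceMatrix(labels, np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], float))
        ordn = pcoa(d)
        tol = 1e-10
        assert (ordn.eigenvalues > tol).sum() == 1
        coords = ordn.coords.to_numpy()[:, 0]
        got = np.abs(coords[:, None] - coords[None, :])
        np.testing.assert_allclose(got, d.d, atol=1e-9)

    def test_zero_distances_give_zero_coordinates(self):
        d = DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)))
        ordn = pcoa(d)
        assert np.allclose(ordn.coords.to_numpy(), 0.0)

    def test_euclidean_configuration_reconstructed(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(12, 2))
        d = DistanceMatrix(
            [f"s{i}" for i in range(12)], squareform(pdist(pts))
        )
        ordn = pcoa(d)
        got = squareform(pdist(ordn.coords.to_numpy()))
        np.testing.assert_allclose(got, d.d, atol=1e-9)

    def test_matches_scikit_bio_on_bray_curtis(self):
        skbio_pcoa = pytest.importorskip("skbio.stats.ordination").pcoa
        import skbio

        rng = np.random.default_rng(2)
        x = rng.random((30, 10))
        d = bray_curtis(frame(x))
        ours = pcoa(d)
        theirs = skbio_pcoa(skbio.DistanceMatrix(d.d, ids=d.labels))
        n = ours.coords.shape[1]
        np.testing.assert_allclose(
            ours.eigenvalues[:n],
            theirs.eigvals.to_numpy()[:n],
            atol=1e-9,
        )
        np.testing.assert_allclose(
            np.abs(ours.coords.to_numpy()),
            np.abs(theirs.samples.to_numpy()[:, :n]),
            atol=1e-6,
        )

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="at least 3"):
            pcoa(DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0]], float)))


def anderson_group_sum_f(d: np.ndarray, groups: np.ndarray) -> float:
    """Independent one-factor pseudo-F oracle from within-group distance sums."""
    n = len(groups)
    ss_total = (d[np.triu_indices(n, 1)] ** 2).sum() / n
    ss_within = 0.0
    for g in np.unique(groups):
        idx = np.nonzero(groups == g)[0]
        sub = d[np.ix_(idx, idx)]
        ss_within += (sub[np.triu_indices(len(idx), 1)] ** 2).sum() / len(idx)
    a = len(np.unique(groups))
    ss_among = ss_total - ss_within
    return (ss_among / (a - 1)) / (ss_within / (n - a))


class TestPermanova:
    def random_case(self, seed, n_per=5, groups=3):
        rng = np.random.default_rng(seed)
        x = rng.random((20, n_per * groups))
        labels = [f"s{i}" for i in range(n_per * groups)]
        d = bray_curtis(frame(x, labels))
        design = pd.Series(
            np.repeat([f"g{k}" for k in range(groups)], n_per), index=labels,
            name="group",
        )
        return d, design

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_group_sum_oracle(self, seed):
        d, design = self.random_case(seed)
        res = permanova(d, design, n_perm=9, seed=0)
        oracle = anderson_group_sum_f(d.d, design.to_numpy())
        assert res.pseudo_f == pytest.approx(oracle, abs=1e-9)

    def test_identical_compositions_are_uninformative(self):
        x = np.tile(np.array([[0.2], [0.8]]), (1, 6))
        labels = [f"s{i}" for i in range(6)]
        d = bray_curtis(frame(x, labels))
        design = pd.Series(["a"] * 3 + ["b"] * 3, index=labels, name="g")
        res = permanova(d, design, n_perm=99, seed=0)
        assert res.p_value == 1.0

    def test_perfectly_separated_groups_reach_small_p(self):
        x = np.zeros((2, 6))
        x[0, :3] = 1.0
        x[1, 3:] = 1.0
        labels = [f"s{i}" for i in range(6)]
        d = bray_curtis(frame(x, labels))
        design = pd.Series(["a"] * 3 + ["b"] * 3, index=labels, name="g")
        res = permanova(d, design, n_perm=999, seed=1)
        # only 20 distinct assignments of 3+3; identity-equivalent ones tie
        assert res.p_value <= 0.12
        assert res.p_value >= 1 / 1000
        assert res.r2 == pytest.approx(1.0, abs=1e-9)

    def test_seeded_p_values_reproduce(self):
        d, design = self.random_case(7)
        p1 = permanova(d, design, n_perm=99, seed=3).p_value
        p2 = permanova(d, design, n_perm=99, seed=3).p_value
        assert p1 == p2

    def test_matches_scikit_bio_statistic(self):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        import skbio

        d, design = self.random_case(11)
        ours = permanova(d, design, n_perm=9, seed=0)
        theirs = skbio_stats.permanova(
            skbio.DistanceMatrix(d.d, ids=d.labels),
            grouping=design.to_numpy(),
            permutations=9,
        )
        assert ours.pseudo_f == pytest.approx(theirs["test statistic"], abs=1e-9)

    def test_rank_deficient_design_names_aliased_columns(self):
        d, design = self.random_case(5)
        df = design.to_frame()
        df["copy"] = df["group"]
        with pytest.raises(ValueError, match="aliased.*copy"):
            permanova(d, df, n_perm=9, seed=0)


class TestEnvfit:
    def ordination(self, seed=0, n=30):
        rng = np.random.default_rng(seed)
        x = rng.random((12, n))
        return pcoa(bray_curtis(frame(x)))

    def test_variable_equal_to_axis_score(self):
        ordn = self.ordination()
        v = pd.DataFrame({"a1": ordn.coords.iloc[:, 0]}, index=ordn.labels)
        fit = envfit_vectors(ordn, v, n_perm=99, seed=0)
        assert abs(fit.loc["a1", "axis1"]) == pytest.approx(1.0, abs=1e-9)
        assert fit.loc["a1", "axis2"] == pytest.approx(0.0, abs=1e-9)
        assert fit.loc["a1", "r2"] == pytest.approx(1.0, abs=1e-9)

    def test_equal_mix_of_two_axes(self):
        ordn = self.ordination(3)
        scores = ordn.coords.to_numpy()
        # equalize scale so the coefficient vector is (1, 1) before norming
        v = scores[:, 0] / scores[:, 0].std() + scores[:, 1] / scores[:, 1].std()
        fit = envfit_vectors(
            ordn,
            pd.DataFrame({"mix": v}, index=ordn.labels),
            n_perm=19,
            seed=0,
        )
        d1 = abs(fit.loc["mix", "axis1"]) * scores[:, 0].std()
        d2 = abs(fit.loc["mix", "axis2"]) * scores[:, 1].std()
        assert d1 / d2 == pytest.approx(1.0, rel=1e-6)

    def test_noise_variable_rarely_significant(self):
        ordn = self.ordination(4)
        rng = np.random.default_rng(0)
        hits = 0
        for i in range(10):
            v = pd.DataFrame(
                {"noise": rng.normal(size=len(ordn.labels))}, index=ordn.labels
            )
            fit = envfit_vectors(ordn, v, n_perm=199, seed=i)
            hits += fit.loc["noise", "p_value"] <= 0.05
        assert hits <= 1

    def test_zero_variance_flagged(self):
        ordn = self.ordination(5)
        v = pd.DataFrame({"const": np.ones(len(ordn.labels))}, index=ordn.labels)
        fit = envfit_vectors(ordn, v, n_perm=9, seed=0)
        assert fit.loc["const", "zero_variance"]
        assert fit.loc["const", "r2"] == 0.0
        assert fit.loc["const", "p_value"] == 1.0


class TestProcrustes:
    def pair(self, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.random((15, 20))
        y = x + 0.05 * rng.random((15, 20))
        return (
            pcoa(bray_curtis(frame(x))),
            pcoa(bray_curtis(frame(y))),
        )

    def test_rotated_scaled_copy_has_zero_residual(self):
        a, _ = self.pair()
        theta = 0.7
        rot = np.eye(a.coords.shape[1])
        rot[:2, :2] = [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        b_coords = 3.0 * a.coords.to_numpy() @ rot
        b = pcoa(
            DistanceMatrix(
                a.labels, squareform(pdist(b_coords))
            )
        )
        res = procrustes_protest(a, b, n_perm=99, seed=0)
        assert res.m2 == pytest.approx(0.0, abs=1e-9)

    def test_statistic_is_symmetric_and_consistent_with_protest_r(self):
        a, b = self.pair(1)
        r1 = procrustes_protest(a, b, n_perm=9, seed=0)
        r2 = procrustes_protest(b, a, n_perm=9, seed=0)
        assert r1.m2 == pytest.approx(r2.m2, abs=1e-9)
        assert r1.protest_r**2 + r1.m2 == pytest.approx(1.0, abs=1e-12)

    def test_matches_scipy_disparity(self):
        a, b = self.pair(2)
        k = min(a.coords.shape[1], b.coords.shape[1])
        _, _, disparity = scipy.spatial.procrustes(
            a.coords.to_numpy()[:, :k], b.coords.to_numpy()[:, :k]
        )
        from domlink.ecology import _center_scale, _procrustes_m2

        ours = _procrustes_m2(
            _center_scale(a.coords.to_numpy()[:, :k], k),
            _center_scale(b.coords.to_numpy()[:, :k], k),
        )
        assert ours == pytest.approx(disparity, abs=1e-9)

    def test_independent_configurations_not_significant(self):
        rng = np.random.default_rng(3)
        hits = 0
        for i in range(10):
            a = pcoa(bray_curtis(frame(rng.random((30, 15)))))
            b = pcoa(bray_curtis(frame(rng.random((30, 15)))))
            res = procrustes_protest(a, b, n_perm=199, seed=i)
            hits += res.p_value <= 0.05
        assert hits <= 1

    def test_mismatched_samples_reported(self):
        a, b = self.pair(4)
        b.labels = [f"x{i}" for i in range(len(b.labels))]
        with pytest.raises(ValueError, match="only in"):
            procrustes_protest(a, b, n_perm=9, seed=0)


class TestDbrda:
    def test_own_axes_explain_everything(self):
        # Euclidean distances: no negative eigenvalues, so the PCoA axes
        # reproduce the full inertia exactly
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(12, 4))
        labels = [f"s{i}" for i in range(12)]
        d = DistanceMatrix(labels, squareform(pdist(pts)))
        ordn = pcoa(d)
        res = dbrda(d, ordn.coords, n_perm=9, seed=0)
        assert res.r2 == pytest.approx(1.0, abs=1e-9)

    def test_binary_predictor_equals_two_group_permanova(self):
        rng = np.random.default_rng(1)
        labels = [f"s{i}" for i in range(12)]
        d = bray_curtis(frame(rng.random((10, 12)), labels))
        g = pd.Series(["a"] * 6 + ["b"] * 6, index=labels, name="g")
        binary = pd.DataFrame({"x": (g == "b").astype(float)})
        f1 = permanova(d, g, n_perm=9, seed=0).pseudo_f
        f2 = dbrda(d, binary, n_perm=9, seed=0).pseudo_f
        assert f1 == pytest.approx(f2, abs=1e-9)

    def test_noise_predictors_explain_q_over_n_minus_1(self):
        rng = np.random.default_rng(2)
        r2s = []
        q, n = 2, 14
        for _ in range(200):
            labels = [f"s{i}" for i in range(n)]
            d = bray_curtis(frame(rng.random((8, n)), labels))
            preds = pd.DataFrame(
                rng.normal(size=(n, q)), index=labels, columns=["p1", "p2"]
            )
            r2s.append(dbrda(d, preds, n_perm=0, seed=0).r2)
        assert np.mean(r2s) == pytest.approx(q / (n - 1), abs=0.02)
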