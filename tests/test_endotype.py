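import numpy as np
import pandas as pd
import pytest

from npxpred.endotype import (
    PcaResult,
    assign_endotypes,
    compare_endotypes,
    loocv_press,
    pca,
)

from conftest import make_clinical


def frame(X):
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(
        X,
        index=[f"s{i + 1}" for i in range(X.shape[0])],
        columns=[f"p{j}" for j in range(X.shape[1])],
    )


class TestPca:
    def test_rank_one_explains_everything(self, rng):
        u = rng.normal(size=10)
        v = rng.normal(size=4)
        res = pca(frame(np.outer(u, v)))
        assert res.explained_variance_ratio[0] > 0.999999

    def test_full_reconstruction(self, rng):
        X = rng.normal(size=(12, 5))
        res = pca(frame(X))
        recon = res.scores @ res.loadings.T + res.mean
        np.testing.assert_allclose(recon, X, atol=1e-8)

    def test_score_covariance_diagonal(self, rng):
        X = rng.normal(size=(30, 6))
        res = pca(frame(X))
        cov = res.scores.T @ res.scores / (30 - 1)
        eigvals = np.diag(cov).copy()
        np.testing.assert_allclose(cov, np.diag(eigvals), atol=1e-8)
        # eigenvalues match those of the sample covariance matrix
        Xc = X - X.mean(0)
        ref = np.sort(np.linalg.eigvalsh(Xc.T @ Xc / (30 - 1)))[::-1]
        np.testing.assert_allclose(eigvals, ref[: len(eigvals)], atol=1e-8)

    def test_row_permutation_invariance_up_to_sign(self, rng):
        X = rng.normal(size=(15, 4))
        res1 = pca(frame(X))
        perm = rng.permutation(15)
        res2 = pca(frame(X[perm]))
        for c in range(4):
            s1 = res1.scores[perm, c]
            s2 = res2.scores[:, c]
            agree = np.allclose(s1, s2, atol=1e-8) or np.allclose(
                s1, -s2, atol=1e-8
            )
            assert agree

    def test_clamps_components(self, rng):
        X = rng.normal(size=(5, 3))
        res = pca(frame(X), n_components=10)
        assert res.n_components == 3

    def test_incomplete_errors(self):
        X = np.array([[1.0, np.nan], [2.0, 3.0], [0.0, 1.0]])
        with pytest.raises(ValueError, match="complete"):
            pca(frame(X))


class TestLoocvPress:
    def rank2_fixture(self, rng, n=24, p=8, noise=0.02):
        t = rng.normal(size=(n, 2))
        load = rng.normal(size=(2, p))
        return t @ load + noise * rng.normal(size=(n, p))

    def test_pseudoinverse_recovers_rank(self, rng):
        X = self.rank2_fixture(rng)
        press, argmin = loocv_press(X, max_pcs=6, method="pseudoinverse")
        assert argmin == 2

    def test_baseline_is_loo_centered_ss(self, rng):
        X = rng.normal(size=(10, 4))
        press, _ = loocv_press(X, max_pcs=3, method="naive")
        expected = sum(
            ((X[i] - np.delete(X, i, axis=0).mean(0)) ** 2).sum()
            for i in range(10)
        )
        assert press[0] == pytest.approx(expected)

    def test_noise_gives_small_argmin(self, rng):
        argmins = []
        for seed in range(3):
            X = np.random.default_rng(seed).normal(size=(15, 6))
            press, argmin = loocv_press(X, max_pcs=5, method="pseudoinverse")
            argmins.append(argmin)
            assert (np.diff(press[1:]) >= -0.15 * press[0]).all()
        assert min(argmins) <= 1

    def test_naive_self_prediction_optimism(self, rng):
        # the naive projection reconstructs the held-out row from itself,
        # so its PRESS is optimistically low past the true rank and its
        # argmin drifts to the largest q; the pseudoinverse variant is
        # honest and recovers the rank
        X = self.rank2_fixture(rng, noise=0.05)
        press_n, argmin_n = loocv_press(X, max_pcs=5, method="naive")
        press_p, argmin_p = loocv_press(X, max_pcs=5, method="pseudoinverse")
        assert argmin_p == 2
        assert argmin_n > 2
        for q in range(2, 6):
            assert press_n[q] < press_p[q]

    def test_too_few_samples_errors(self):
        with pytest.raises(ValueError, match="at least 3"):
            loocv_press(np.zeros((2, 4)))

    def test_unknown_method_errors(self, rng):
        with pytest.raises(ValueError, match="method"):
            loocv_press(rng.normal(size=(6, 3)), method="approximate")


def planted_pca(rng, n=60, p=10, strength=3.0):
    """Bimodal latent factor on the first protein block."""
    group = rng.choice([-1.0, 1.0], size=n)
    X = rng.normal(size=(n, p))
    X[:, :4] += strength * group[:, None]
    return frame(X), group


class TestAssignEndotypes:
    def test_recovers_planted_grouping(self, rng):
        X, group = planted_pca(rng)
        res = pca(X)
        assignment = assign_endotypes(res, component=1)
        labels = assignment.labels.to_numpy()
        truth = np.where(group > 0, 1, 2)
        agreement = max(
            (labels == truth).mean(), (labels == (3 - truth)).mean()
        )
        assert agreement >= 0.95

    def test_sign_flip_invariance(self, rng):
        X, _ = planted_pca(rng)
        res = pca(X)
        flipped = PcaResult(
            loadings=-res.loadings,
            scores=-res.scores,
            explained_variance_ratio=res.explained_variance_ratio,
            mean=res.mean,
            sample_ids=res.sample_ids,
        )
        a1 = assign_endotypes(res, component=1)
        a2 = assign_endotypes(flipped, component=1)
        pd.testing.assert_series_equal(a1.labels, a2.labels)

    def test_all_positive_scores_single_group(self):
        loadings = np.eye(3)[:, :2]
        scores = np.array([[1.0, 2.0], [2.0, 1.0], [3.0, 0.5]])
        res = PcaResult(
            loadings=loadings,
            scores=scores,
            explained_variance_ratio=np.array([0.6, 0.3]),
            mean=np.zeros(3),
            sample_ids=["s1", "s2", "s3"],
        )
        a = assign_endotypes(res, component=1)
        assert (a.labels == 1).all()

    def test_clinical_orientation(self, rng):
        X, group = planted_pca(rng)
        res = pca(X)
        das = np.where(group > 0, 6.5, 4.5) + rng.normal(0, 0.2, len(group))
        clin = make_clinical(len(group), baseline_das=np.clip(das, 0, 10).round(2))
        a = assign_endotypes(res, component=1, clinical=clin)
        das_1 = das[(a.labels == 1).to_numpy()].mean()
        das_2 = das[(a.labels == 2).to_numpy()].mean()
        assert das_1 > das_2

    def test_bad_component_errors(self, rng):
        res = pca(frame(rng.normal(size=(6, 3))))
        with pytest.raises(ValueError, match="component"):
            assign_endotypes(res, component=9)


class TestCompareEndotypes:
    def test_identical_groups_p_near_one(self, rng):
        X, _ = planted_pca(rng, n=40)
        res = pca(X)
        a = assign_endotypes(res, component=1)
        clin = make_clinical(40, rng=rng)
        # duplicate ages across endotypes: continuous p-values ~ 1
        clin.frame["age"] = 60.0
        clin.frame["disease_duration"] = 9.0
        table = compare_endotypes(a, clin)
        assert np.isnan(table.loc["age", "p_value"]) or table.loc["age", "p_value"] > 0.99

    def test_planted_das_shift_detected(self, rng):
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            X, group = planted_pca(r, n=89, strength=3.0)
            das = np.clip(np.where(group > 0, 5.9, 4.9) + r.normal(0, 1.0, 89), 0, 10)
            clin = make_clinical(89, rng=r, baseline_das=das.round(2))
            res = pca(X)
            a = assign_endotypes(res, component=1, clinical=clin)
            table = compare_endotypes(a, clin)
            if table.loc["baseline_das", "p_value"] < 0.05:
                hits += 1
        assert hits >= 8

    def test_null_false_positive_rate(self, rng):
        pvals = []
        for seed in range(20):
            r = np.random.default_rng(seed + 1000)
            X, _ = planted_pca(r, n=50)
            res = pca(X)
            a = assign_endotypes(res, component=1)
            clin = make_clinical(50, rng=r)
            table = compare_endotypes(a, clin)
            pvals.append(table.loc["age", "p_value"])
        assert np.mean(np.asarray(pvals) < 0.05) <= 0.25
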