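import numpy as np
import pandas as pd
import pytest

from afidreg.covariance import (
    afre_correlation_matrix,
    attribute_variance,
    center_targets,
    covariate_screen,
    multivariate_regression,
    pca,
    r2_map,
    simple_regression,
    stacked_pca,
)
from afidreg.errors import DegenerateStatisticsError, InputError


def make_afre_table(values: dict[int, np.ndarray], subjects=None) -> pd.DataFrame:
    """AFRE table from {afid: (n_subjects, 3) array}."""
    rows = []
    for afid, arr in values.items():
        arr = np.asarray(arr, dtype=float)
        subs = subjects or [f"sub-{k:03d}" for k in range(len(arr))]
        for s, v in zip(subs, arr):
            rows.append(
                dict(subject=s, rater="t", afid=afid, label=f"AFID{afid:02d}",
                     dx_mm=v[0], dy_mm=v[1], dz_mm=v[2],
                     euclidean_mm=float(np.linalg.norm(v)), kind="AFRE")
            )
    return pd.DataFrame(rows)


def make_tips(disp: np.ndarray, subjects=None, side="R") -> pd.DataFrame:
    """Centered tip table from an (n, 3) displacement array."""
    disp = np.asarray(disp, dtype=float)
    subs = subjects or [f"sub-{k:03d}" for k in range(len(disp))]
    return pd.DataFrame(
        dict(subject=subs, side=side,
             x_mm=disp[:, 0], y_mm=disp[:, 1], z_mm=disp[:, 2],
             dx_mm=disp[:, 0] - disp[:, 0].mean(),
             dy_mm=disp[:, 1] - disp[:, 1].mean(),
             dz_mm=disp[:, 2] - disp[:, 2].mean(),
             euclidean_mm=np.linalg.norm(disp - disp.mean(axis=0), axis=1))
    )


class TestCenterTargets:
    def test_two_tips(self):
        tips = pd.DataFrame(
            dict(subject=["a", "b"], side="R",
                 x_mm=[0.0, 2.0], y_mm=0.0, z_mm=0.0)
        )
        out = center_targets(tips)
        np.testing.assert_allclose(out["dx_mm"], [-1.0, 1.0])
        np.testing.assert_allclose(out["euclidean_mm"], [1.0, 1.0])

    def test_identical_tips_zero(self):
        tips = pd.DataFrame(
            dict(subject=list("abc"), side="L", x_mm=1.0, y_mm=2.0, z_mm=3.0)
        )
        out = center_targets(tips)
        assert (out[["dx_mm", "dy_mm", "dz_mm", "euclidean_mm"]] == 0).all().all()

    def test_column_means_zero_per_side(self, rng):
        tips = pd.DataFrame(
            dict(
                subject=[f"s{i}" for i in range(20)],
                side=["R"] * 10 + ["L"] * 10,
                x_mm=rng.normal(12, 2, 20),
                y_mm=rng.normal(-13, 2, 20),
                z_mm=rng.normal(-7, 2, 20),
            )
        )
        out = center_targets(tips)
        for _, grp in out.groupby("side"):
            np.testing.assert_allclose(
                grp[["dx_mm", "dy_mm", "dz_mm"]].mean(), 0.0, atol=1e-9
            )
        # brute-force check
        r = tips[tips.side == "R"]
        np.testing.assert_allclose(
            out.loc[out.side == "R", "dx_mm"].to_numpy(),
            r["x_mm"].to_numpy() - r["x_mm"].mean(),
            atol=1e-12,
        )

    def test_singleton_cell_errors(self):
        tips = pd.DataFrame(
            dict(subject=["a", "b"], side=["R", "L"], x_mm=0.0, y_mm=0.0, z_mm=0.0)
        )
        with pytest.raises(InputError, match="single"):
            center_targets(tips)

    def test_unknown_grouping(self):
        with pytest.raises(InputError, match="grouping"):
            center_targets(pd.DataFrame(), grouping="everything")


class TestSimpleRegression:
    def test_exact_line(self):
        x = np.arange(10.0)
        fit = simple_regression(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_y(self):
        fit = simple_regression(np.arange(5.0), np.full(5, 3.0))
        assert fit.slope == 0.0
        assert fit.r_squared == 0.0

    def test_constant_x_errors(self):
        with pytest.raises(DegenerateStatisticsError):
            simple_regression(np.ones(5), np.arange(5.0))

    def test_matches_normal_equations(self, rng):
        x = rng.normal(size=50)
        y = 1.3 * x + rng.normal(size=50)
        fit = simple_regression(x, y)
        X = np.column_stack([np.ones(50), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.intercept == pytest.approx(beta[0], abs=1e-9)
        assert fit.slope == pytest.approx(beta[1], abs=1e-9)
        r = np.corrcoef(x, y)[0, 1]
        assert fit.r_squared == pytest.approx(r**2, abs=1e-9)


class TestR2Map:
    def test_planted_identity(self, rng):
        afre2 = rng.normal(size=(30, 3))
        afre = make_afre_table({2: afre2, 3: rng.normal(size=(30, 3))})
        tips = make_tips(afre2)
        grid = r2_map(afre, tips)
        cell = grid[(grid.afid == 2)]
        np.testing.assert_allclose(cell["r_squared"], 1.0, atol=1e-9)

    def test_null_r2_small(self):
        rng = np.random.default_rng(7)
        afre = make_afre_table({i: rng.normal(size=(200, 3)) for i in (1, 2, 3)})
        tips = make_tips(rng.normal(size=(200, 3)))
        grid = r2_map(afre, tips)
        assert (grid["r_squared"] < 0.06).all()

    def test_planted_single_axis_coupling(self):
        rng = np.random.default_rng(11)
        afre2 = rng.normal(size=(100, 3))
        disp = rng.normal(size=(100, 3)) * 0.1
        disp[:, 1] = afre2[:, 1]  # y only
        afre = make_afre_table({2: afre2})
        grid = r2_map(afre, make_tips(disp)).set_index("axis")
        assert grid.loc["y", "r_squared"] > 0.99
        assert grid.loc["x", "r_squared"] < 0.1
        assert grid.loc["z", "r_squared"] < 0.1
        assert bool(grid.loc["y", "significant_corrected"])

    def test_too_few_subjects_marked_missing(self):
        afre = make_afre_table({2: np.zeros((2, 3))})
        tips = make_tips(np.zeros((2, 3)))
        grid = r2_map(afre, tips)
        assert grid["r_squared"].isna().all()


class TestCovariateScreen:
    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(3)
        disp = rng.normal(size=(40, 3))
        tips = make_tips(disp)
        cov = pd.DataFrame(dict(subject=tips["subject"], sex=[0, 1] * 20))
        # make groups literally identical in displacement distribution
        tips.loc[:, ["dx_mm", "dy_mm", "dz_mm"]] = np.tile(
            disp[:20] - disp[:20].mean(axis=0), (2, 1)
        )
        tips["euclidean_mm"] = np.linalg.norm(
            tips[["dx_mm", "dy_mm", "dz_mm"]], axis=1
        )
        out = covariate_screen(tips, cov, {"sex": "binary"})
        assert not out["significant_corrected"].any()

    def test_continuous_self_correlation(self):
        rng = np.random.default_rng(4)
        disp = rng.normal(size=(30, 3))
        tips = make_tips(disp)
        cov = pd.DataFrame(dict(subject=tips["subject"], age=tips["dy_mm"]))
        out = covariate_screen(tips, cov, {"age": "continuous"})
        row = out[(out.covariate == "age") & (out.axis == "dy")]
        assert row["statistic"].iloc[0] == pytest.approx(1.0)

    def test_single_level_skipped_with_warning(self):
        tips = make_tips(np.random.default_rng(0).normal(size=(10, 3)))
        cov = pd.DataFrame(dict(subject=tips["subject"], site=1))
        with pytest.warns(UserWarning, match="one level"):
            out = covariate_screen(tips, cov, {"site": "binary"})
        assert len(out) == 0

    def test_null_false_positive_rate(self):
        rng = np.random.default_rng(5)
        hits = total = 0
        for _ in range(40):
            tips = make_tips(rng.normal(size=(200, 3)))
            cov = pd.DataFrame(
                dict(subject=tips["subject"], age=rng.normal(size=200),
                     sex=rng.integers(0, 2, 200))
            )
            out = covariate_screen(
                tips, cov, {"age": "continuous", "sex": "binary"}
            )
            hits += int(out["significant_nominal"].sum())
            total += len(out)
        assert hits / total < 0.10  # ~5% expected under the null


class TestMultivariateRegression:
    def test_single_column_nests_simple(self, rng):
        x = rng.normal(size=30)
        y = 2.0 * x + rng.normal(size=30)
        simple = simple_regression(x, y)
        multi = multivariate_regression(pd.DataFrame({"x": x}), y)
        coef = multi["coefficients"].set_index("term")
        assert coef.loc["x", "estimate"] == pytest.approx(simple.slope, abs=1e-9)
        assert coef.loc["x", "p_value"] == pytest.approx(simple.p_value, abs=1e-9)
        assert multi["r_squared"] == pytest.approx(simple.r_squared, abs=1e-9)

    def test_exact_two_column_fit(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=20), "b": rng.normal(size=20)})
        y = 3.0 * X["a"] - 2.0 * X["b"] + 1.0
        out = multivariate_regression(X, y)
        assert out["r_squared"] == pytest.approx(1.0)

    def test_matches_normal_equations(self, rng):
        X = pd.DataFrame(rng.normal(size=(100, 4)), columns=list("abcd"))
        y = rng.normal(size=100)
        out = multivariate_regression(X, y)
        Xd = np.column_stack([np.ones(100), X.to_numpy()])
        beta = np.linalg.solve(Xd.T @ Xd, Xd.T @ y)
        np.testing.assert_allclose(
            out["coefficients"]["estimate"], beta, atol=1e-9
        )

    def test_rank_deficient_names_columns(self, rng):
        a = rng.normal(size=30)
        X = pd.DataFrame({"a": a, "b": 2 * a})
        with pytest.raises(InputError, match="collinear"):
            multivariate_regression(X, rng.normal(size=30))

    def test_too_few_rows(self, rng):
        X = pd.DataFrame(rng.normal(size=(4, 3)), columns=list("abc"))
        with pytest.raises(InputError, match="n > p"):
            multivariate_regression(X, rng.normal(size=4))


class TestPca:
    def test_rank_one_diagonal(self):
        t = np.linspace(-1, 1, 20)
        X = np.stack([t, t], axis=1)
        axes = pca(X)
        np.testing.assert_allclose(
            axes.components[:, 0], [1 / np.sqrt(2), 1 / np.sqrt(2)], atol=1e-12
        )
        np.testing.assert_allclose(axes.explained_fraction, [1.0, 0.0], atol=1e-12)

    def test_isotropic_square(self):
        X = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        axes = pca(X)
        np.testing.assert_allclose(axes.explained_fraction, [0.5, 0.5], atol=1e-12)

    def test_matches_eigendecomposition_oracle(self, rng):
        X = rng.normal(size=(50, 12))
        axes = pca(X)
        Xc = X - X.mean(axis=0)
        eigvals, eigvecs = np.linalg.eigh(Xc.T @ Xc / 49)
        order = np.argsort(eigvals)[::-1]
        np.testing.assert_allclose(
            axes.explained_fraction * eigvals.sum(), eigvals[order], atol=1e-9
        )
        for j in range(12):
            v = eigvecs[:, order[j]]
            got = axes.components[:, j]
            # eigenvectors defined up to sign
            assert min(np.abs(got - v).max(), np.abs(got + v).max()) < 1e-9

    def test_orthonormal_and_reconstructs(self, rng):
        X = rng.normal(size=(30, 6))
        axes = pca(X)
        np.testing.assert_allclose(
            axes.components.T @ axes.components, np.eye(6), atol=1e-9
        )
        recon = axes.scores @ axes.components.T + axes.column_means
        np.testing.assert_allclose(recon, X, atol=1e-9)
        assert axes.explained_fraction.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(axes.scores.mean(axis=0), 0.0, atol=1e-9)

    def test_sign_convention(self, rng):
        X = rng.normal(size=(40, 5))
        axes = pca(X)
        for j in range(5):
            pivot = np.argmax(np.abs(axes.components[:, j]))
            assert axes.components[pivot, j] > 0

    def test_single_sample_rejected(self):
        with pytest.raises(InputError, match=">= 2"):
            pca(np.zeros((1, 3)))


class TestCorrelationMatrix:
    def test_identical_tables_unit_diagonal_blocks(self, rng):
        arr = rng.normal(size=(25, 3))
        afre = make_afre_table({2: arr, 3: arr})
        corr = afre_correlation_matrix(afre, [2, 3])
        for ax in ("x", "y", "z"):
            assert corr.loc[f"AFID02.{ax}", f"AFID03.{ax}"] == pytest.approx(1.0)

    def test_independent_near_zero(self):
        rng = np.random.default_rng(21)
        afre = make_afre_table(
            {2: rng.normal(size=(200, 3)), 3: rng.normal(size=(200, 3))}
        )
        corr = afre_correlation_matrix(afre, [2, 3])
        off = corr.loc[[f"AFID02.{a}" for a in "xyz"],
                       [f"AFID03.{a}" for a in "xyz"]]
        assert (off.to_numpy() < 0.06).all()

    def test_planted_shared_component_prc_basis(self):
        rng = np.random.default_rng(22)
        n = 400
        s = rng.normal(size=n)
        u2 = np.array([0.0, 1.0, 0.3])
        u3 = np.array([0.1, 0.9, 0.2])
        noise_sd = 0.3
        afre = make_afre_table(
            {
                2: np.outer(s, u2) + rng.normal(scale=noise_sd, size=(n, 3)),
                3: np.outer(s, u3) + rng.normal(scale=noise_sd, size=(n, 3)),
            }
        )
        corr = afre_correlation_matrix(afre, [2, 3], basis="per_afid_prc")
        # expected PrC1-PrC1 share: product of each landmark's signal fractions
        exp2 = (u2 @ u2) / (u2 @ u2 + noise_sd**2)
        exp3 = (u3 @ u3) / (u3 @ u3 + noise_sd**2)
        got = corr.loc["AFID02.PrC1", "AFID03.PrC1"]
        assert got == pytest.approx(exp2 * exp3, abs=0.08)

    def test_bad_basis(self, rng):
        afre = make_afre_table({2: rng.normal(size=(5, 3))})
        with pytest.raises(InputError, match="basis"):
            afre_correlation_matrix(afre, [2], basis="polar")


class TestStackedPca:
    def test_rank_one_no_noise(self, rng):
        s = rng.normal(size=30)
        pattern = rng.normal(size=(4, 3))
        afre = make_afre_table({a: np.outer(s, pattern[i])
                                for i, a in enumerate((2, 3, 4, 14))})
        axes = stacked_pca(afre, [2, 3, 4, 14])
        assert axes.explained_fraction[0] == pytest.approx(1.0)
        assert axes.components.shape == (12, 12)
        assert axes.feature_labels[0] == "AFID02.x"

    def test_planted_top4_share(self):
        # four orthogonal planted directions + iid noise sized so the top-4
        # eigenvalue share is 0.89:  (sum_p + 4 s2) / (sum_p + 12 s2) = 0.89
        rng = np.random.default_rng(33)
        n = 500
        q, _ = np.linalg.qr(rng.normal(size=(12, 4)))
        planted_sd = np.array([np.sqrt(5.0), np.sqrt(2.0), 1.0, np.sqrt(0.9)])
        sum_p = float((planted_sd**2).sum())
        share = 0.89
        s2 = sum_p * (1 - share) / (12 * share - 4)
        scores = rng.normal(size=(n, 4)) * planted_sd
        X = scores @ q.T + rng.normal(scale=np.sqrt(s2), size=(n, 12))
        afre = make_afre_table(
            {a: X[:, 3 * i : 3 * i + 3] for i, a in enumerate((2, 3, 4, 14))}
        )
        axes = stacked_pca(afre, [2, 3, 4, 14])
        assert axes.explained_fraction[:4].sum() == pytest.approx(share, abs=0.03)

    def test_feature_permutation_equivariance(self, rng):
        arr = {a: rng.normal(size=(20, 3)) for a in (2, 3, 14)}
        afre = make_afre_table(arr)
        a1 = stacked_pca(afre, [2, 3, 14])
        a2 = stacked_pca(afre, [14, 2, 3])
        np.testing.assert_allclose(
            a1.explained_fraction, a2.explained_fraction, atol=1e-9
        )

    def test_needs_two_landmarks(self, rng):
        afre = make_afre_table({2: rng.normal(size=(5, 3))})
        with pytest.raises(InputError, match="two"):
            stacked_pca(afre, [2])


class TestAttributeVariance:
    def _axes_pair(self, afre_arrs, tip_disp, subjects=None):
        afre = make_afre_table(afre_arrs, subjects=subjects)
        axes = stacked_pca(afre, sorted(afre_arrs))
        tips = make_tips(tip_disp, subjects=subjects)
        tip_mat = tips.set_index(["subject", "side"])[["dx_mm", "dy_mm", "dz_mm"]]
        tip_axes = pca(tip_mat, sample_ids=list(tip_mat.index))
        return axes, tip_axes

    def test_planted_identity(self, rng):
        s = rng.normal(size=40)
        pattern = rng.normal(size=(2, 3))
        tip_dir = rng.normal(size=3)
        afre_arrs = {2: np.outer(s, pattern[0]), 3: np.outer(s, pattern[1])}
        axes, tip_axes = self._axes_pair(afre_arrs, np.outer(s, tip_dir))
        res = attribute_variance(axes, tip_axes)
        assert res.summary["r2_prc1"] == pytest.approx(1.0)
        np.testing.assert_allclose(
            res.explained_mm.to_numpy(), np.abs(tip_axes.scores[:, 0]), atol=1e-9
        )

    def test_null_r2_small(self):
        rng = np.random.default_rng(44)
        afre_arrs = {2: rng.normal(size=(200, 3)), 3: rng.normal(size=(200, 3))}
        axes, tip_axes = self._axes_pair(afre_arrs, rng.normal(size=(200, 3)))
        res = attribute_variance(axes, tip_axes)
        assert res.summary["r2_prc1"] < 0.06

    def test_scale_equivariance(self):
        rng = np.random.default_rng(45)
        s = rng.normal(size=50)
        afre_arrs = {
            2: np.outer(s, [0, 1, 0.5]) + rng.normal(scale=0.2, size=(50, 3)),
            3: np.outer(s, [0.2, 0.8, 0.1]) + rng.normal(scale=0.2, size=(50, 3)),
        }
        disp = np.outer(s, [0.1, 0.9, 0.3]) + rng.normal(scale=0.5, size=(50, 3))
        axes, tip_axes = self._axes_pair(afre_arrs, disp)
        res1 = attribute_variance(axes, tip_axes)
        scaled = {k: 3.0 * v for k, v in afre_arrs.items()}
        axes2, _ = self._axes_pair(scaled, disp)
        res2 = attribute_variance(axes2, tip_axes)
        assert res2.summary["r2_prc1"] == pytest.approx(
            res1.summary["r2_prc1"], abs=1e-9
        )
        np.testing.assert_allclose(
            res2.explained_mm.to_numpy(), res1.explained_mm.to_numpy(), atol=1e-9
        )

    def test_degenerate_component_raises(self):
        rng = np.random.default_rng(46)
        afre_arrs = {2: np.zeros((10, 3)), 3: np.zeros((10, 3))}
        axes, tip_axes = self._axes_pair(afre_arrs, rng.normal(size=(10, 3)))
        with pytest.raises(DegenerateStatisticsError):
            attribute_variance(axes, tip_axes)

    def test_missing_subject_errors(self, rng):
        s = rng.normal(size=10)
        afre_arrs = {2: np.outer(s, [0, 1, 0]), 3: np.outer(s, [1, 0, 0])}
        afre = make_afre_table(afre_arrs)
        axes = stacked_pca(afre, [2, 3])
        tips = make_tips(rng.normal(size=(10, 3)),
                         subjects=[f"other-{i}" for i in range(10)])
        tip_mat = tips.set_index(["subject", "side"])[["dx_mm", "dy_mm", "dz_mm"]]
        tip_axes = pca(tip_mat, sample_ids=list(tip_mat.index))
        with pytest.raises(InputError, match="missing"):
            attribute_variance(axes, tip_axes)
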