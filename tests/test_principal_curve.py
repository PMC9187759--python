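import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr
from sklearn.decomposition import PCA

from tnbcstrat import ExpressionMatrix, GeneSet, compute_pds, fit_principal_curve
from tnbcstrat.principal_curve import project_to_polyline


def _arc_points(seed, n=200, noise=0.1):
    rng = np.random.default_rng(seed)
    t = np.sort(rng.uniform(-1.0, 1.0, n))
    pts = np.c_[t, t**2] + rng.normal(0.0, noise, (n, 2))
    return pts, t


class TestFitPrincipalCurve:
    def test_collinear_points_recover_the_pca_line(self):
        direction = np.array([1.0, 2.0, 3.0])
        line = np.outer(np.linspace(0, 1, 50), direction)
        pc = fit_principal_curve(line)
        assert pc.converged
        assert pc.residuals.max() < 1e-6
        # projections equal orthogonal projections onto the PCA line
        pca = PCA(n_components=1).fit(line)
        proj = pca.transform(line).ravel()
        proj = proj - proj.min()
        lam = pc.lambdas - pc.lambdas.min()
        if np.corrcoef(lam, proj)[0, 1] < 0:
            proj = proj.max() - proj
        assert np.allclose(lam, proj, atol=1e-6)

    def test_noisy_arc_parameter_recovery(self):
        # oracle: brute-force projection of the noisy points onto a densely
        # sampled polyline of the TRUE quadratic arc
        pts, t = _arc_points(seed=0)
        dense_t = np.linspace(-1.1, 1.1, 2000)
        true_curve = np.c_[dense_t, dense_t**2]
        lam_true, _ = project_to_polyline(pts, true_curve)
        pc = fit_principal_curve(pts)
        rho = abs(spearmanr(pc.lambdas, lam_true).statistic)
        assert pc.converged
        assert rho >= 0.9

    def test_duplicating_every_point_leaves_curve_unchanged(self):
        pts, _ = _arc_points(seed=3)
        pc1 = fit_principal_curve(pts)
        pc2 = fit_principal_curve(np.vstack([pts, pts]))
        assert np.allclose(pc1.lambdas, pc2.lambdas[:200], atol=1e-9)
        assert np.allclose(pc2.lambdas[:200], pc2.lambdas[200:], atol=1e-12)

    def test_arc_lengths_non_decreasing_and_lambdas_in_range(self):
        pts, _ = _arc_points(seed=5)
        pc = fit_principal_curve(pts)
        assert np.all(np.diff(pc.arc_lengths) >= 0)
        assert pc.lambdas.min() >= 0
        assert pc.lambdas.max() <= pc.total_length + 1e-12

    def test_residuals_shrink_with_smaller_span_on_noiseless_curve(self):
        rng = np.random.default_rng(11)
        t = np.sort(rng.uniform(-1, 1, 150))
        pts = np.c_[t, t**2]
        res = [
            fit_principal_curve(pts, span=s).residuals.sum() for s in (0.5, 0.3, 0.1)
        ]
        assert res[0] >= res[1] >= res[2]

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            fit_principal_curve(np.zeros((4, 2)))

    def test_one_dimension_rejected(self):
        with pytest.raises(ValueError, match="2 dimensions"):
            fit_principal_curve(np.zeros((10, 1)))

    def test_non_convergence_is_flagged_not_silent(self):
        pts, _ = _arc_points(seed=2)
        pc = fit_principal_curve(pts, tol=1e-300, max_iter=3)
        assert not pc.converged
        assert pc.n_iter == 3


def _matrix_from_points(points, stage="normalized"):
    # points: samples x genes -> matrix genes x samples
    n, d = points.shape
    return ExpressionMatrix(
        pd.DataFrame(
            points.T,
            index=[f"g{i}" for i in range(d)],
            columns=[f"s{j:03d}" for j in range(n)],
        ),
        stage=stage,
    )


class TestComputePDS:
    def test_collinear_data_pds_is_signed_distance_from_reference_centroid(self):
        # closed-form oracle: on a straight line the arc-length parameter
        # equals the Euclidean coordinate along the line
        rng = np.random.default_rng(1)
        t = np.sort(rng.uniform(-2, 2, 40))
        direction = np.array([1.0, 1.0, 0.5])
        points = np.outer(t, direction)
        m = _matrix_from_points(points)
        refs = [f"s{j:03d}" for j in range(5)]  # lowest-t end
        gs = GeneSet(name="path", genes=("g0", "g1", "g2"))
        res = compute_pds(m, gs, reference_ids=refs)
        # after per-gene standardization the line has a known scale
        z = (points - points.mean(0)) / points.std(0)
        dist = np.linalg.norm(z - z[:5].mean(0), axis=1)
        signed = np.sign(t - t[:5].mean()) * dist
        assert np.allclose(res.scores.values.to_numpy(), signed, atol=1e-6)

    def test_reference_group_mean_pds_is_zero(self, norm100, gene_sets):
        refs = [f"S{i:04d}" for i in range(10)]
        res = compute_pds(norm100, gene_sets["immune"], reference_ids=refs)
        assert abs(res.reference_mean()) < 1e-8

    def test_sample_at_reference_centroid_scores_zero(self):
        # on collinear data every reference projects onto the line, so a
        # sample sitting at the reference centroid scores exactly zero
        rng = np.random.default_rng(4)
        t = np.sort(rng.uniform(-2, 2, 30))
        pts = np.outer(t, np.array([1.0, -0.5, 2.0]))
        pts[0] = pts[1:6].mean(0)
        m = _matrix_from_points(pts)
        gs = GeneSet(name="p", genes=("g0", "g1", "g2"))
        res = compute_pds(m, gs, reference_ids=[f"s{j:03d}" for j in range(1, 6)])
        assert abs(res.scores.values.iloc[0]) < 1e-8

    def test_translation_invariance(self):
        # shifting all points by a constant vector leaves PDS unchanged
        # because genes are standardized before the fit
        rng = np.random.default_rng(15)
        t = np.sort(rng.uniform(-1, 1, 60))
        pts = np.c_[t, t**2, 0.5 * t, -t] + rng.normal(0, 0.1, (60, 4))
        gs = GeneSet(name="p", genes=tuple(f"g{i}" for i in range(4)))
        refs = [f"s{j:03d}" for j in range(8)]
        r1 = compute_pds(_matrix_from_points(pts), gs, reference_ids=refs)
        r2 = compute_pds(_matrix_from_points(pts + 17.5), gs, reference_ids=refs)
        assert np.allclose(
            r1.scores.values.to_numpy(), r2.scores.values.to_numpy(), atol=1e-6
        )

    def test_pds_differences_invariant_to_anchor_choice(self, norm100, gene_sets):
        refs = [f"S{i:04d}" for i in range(10)]
        res = compute_pds(norm100, gene_sets["fibrosis"], reference_ids=refs)
        # re-anchor at the curve extremum (parameter 0): differences match
        lam = res.curve.lambdas
        sign = res.scores.provenance["sign"]
        extremum_scores = sign * (lam - 0.0)
        pds = res.scores.values.to_numpy()
        d1 = pds[:, None] - pds[None, :]
        d2 = extremum_scores[:, None] - extremum_scores[None, :]
        assert np.allclose(d1, d2, atol=1e-10)

    def test_zero_variance_gene_dropped_with_warning(self, rng):
        pts = rng.standard_normal((30, 3))
        pts[:, 2] = 4.2
        m = _matrix_from_points(pts)
        gs = GeneSet(name="p", genes=("g0", "g1", "g2"))
        with pytest.warns(UserWarning, match="zero-variance"):
            res = compute_pds(m, gs, reference_ids=[f"s{j:03d}" for j in range(5)])
        assert res.genes_dropped == ("g2",)

    def test_missing_genes_rejected(self, norm100):
        gs = GeneSet(name="absent", genes=("NOPE1", "NOPE2"))
        with pytest.raises(ValueError, match="absent"):
            compute_pds(norm100, gs)

    def test_no_reference_warns_and_anchors_at_cohort_mean(self, rng):
        pts = rng.standard_normal((25, 3))
        m = _matrix_from_points(pts)
        gs = GeneSet(name="p", genes=("g0", "g1", "g2"))
        with pytest.warns(UserWarning, match="cohort mean"):
            res = compute_pds(m, gs, reference_ids=None)
        assert abs(res.scores.values.mean()) < 1e-8
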