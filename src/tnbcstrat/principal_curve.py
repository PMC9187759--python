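"""Hastie-Stuetzle principal curves for pathway deregulation scoring.

A principal curve is a smooth one-dimensional curve through the "middle"
of a point cloud. The fit alternates two steps starting from the first
principal-component line: (i) project every point onto the current
polyline, giving each point an arc-length parameter; (ii) re-estimate
each coordinate as a smoothed function of that parameter (local
averaging over a span-sized window). The polyline is reparameterized by
arc length after each pass, and iteration stops when the mean squared
vertex shift drops below a tolerance.

The fitted object is a results container in the statsmodels spirit: it
carries the polyline, per-sample projections, residuals and convergence
diagnostics, and can project new points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PrincipalCurve", "fit_principal_curve", "project_to_polyline"]


def project_to_polyline(
    points: np.ndarray, vertices: np.ndarray, extend: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Project points onto a polyline given by ordered vertices.

    Returns (arc-length parameter of the closest polyline point,
    squared Euclidean residual) for each point. With ``extend=True`` the
    first and last segments continue to infinity, which removes the
    endpoint bias of a truncated polyline; the parameter may then fall
    outside [0, total length].
    """
    points = np.asarray(points, dtype=float)
    vertices = np.asarray(vertices, dtype=float)
    # drop zero-length segments (duplicate consecutive vertices)
    seg = np.diff(vertices, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    keep = np.concatenate([[True], seglen > 0])
    vertices = vertices[keep]
    if len(vertices) == 1:
        lam = np.zeros(len(points))
        res = np.sum((points - vertices[0]) ** 2, axis=1)
        return lam, res
    seg = np.diff(vertices, axis=0)  # (m, d)
    seglen = np.linalg.norm(seg, axis=1)  # (m,)
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    a = vertices[:-1]  # (m, d)
    # t_{ij}: position of point i along segment j, clipped to [0, 1]
    diff = points[:, None, :] - a[None, :, :]  # (n, m, d)
    t_raw = np.einsum("nmd,md->nm", diff, seg) / (seglen**2)[None, :]
    t = np.clip(t_raw, 0.0, 1.0)
    if extend:
        t[:, 0] = np.minimum(t_raw[:, 0], 1.0)
        t[:, -1] = np.maximum(t_raw[:, -1], 0.0)
    closest = a[None, :, :] + t[:, :, None] * seg[None, :, :]
    d2 = np.sum((points[:, None, :] - closest) ** 2, axis=2)  # (n, m)
    jbest = np.argmin(d2, axis=1)
    n = np.arange(len(points))
    lam = cum[jbest] + t[n, jbest] * seglen[jbest]
    return lam, d2[n, jbest]


def _smooth(points: np.ndarray, lam: np.ndarray, span: float, kind: str) -> np.ndarray:
    """Local-average each coordinate as a function of the parameter.

    ``window``: average over points whose parameter lies within
    span/2 * (parameter range) of the target point — exactly invariant
    under duplicating the data. ``rank``: average over the span*n
    nearest parameter-ranked neighbors.
    """
    n = len(points)
    if kind == "window":
        # tri-cube kernel over a span-sized bandwidth: weights depend only
        # on parameter distances, so the smoother is exactly invariant
        # under duplicating the data, and weighted averages of collinear
        # points stay on the line
        width = lam.max() - lam.min()
        h = max(span * width / 2.0, 1e-300)
        d = np.abs(lam[:, None] - lam[None, :]) / h
        w = np.clip(1.0 - d**3, 0.0, None) ** 3
        return (w @ points) / w.sum(axis=1)[:, None]
    if kind == "rank":
        half = max(1, int(round(span * n / 2.0)))
        order = np.argsort(lam, kind="stable")
        pts_s = points[order]
        csum = np.vstack([np.zeros(points.shape[1]), np.cumsum(pts_s, axis=0)])
        rank = np.empty(n, dtype=int)
        rank[order] = np.arange(n)
        lo = np.maximum(rank - half, 0)
        hi = np.minimum(rank + half + 1, n)
        return (csum[hi] - csum[lo]) / (hi - lo)[:, None]
    raise ValueError(f"unknown smoother {kind!r}")


@dataclass
class PrincipalCurve:
    """Fitted principal curve with projections and diagnostics.

    Attributes
    ----------
    vertices : ordered polyline vertices in the data space.
    arc_lengths : cumulative arc length at each vertex (non-decreasing).
    lambdas : per-sample projection parameter (arc length of the closest
        polyline point), each in [0, total_length].
    residuals : per-sample squared distance to the curve.
    converged, n_iter, final_shift : convergence diagnostics.
    """

    vertices: np.ndarray
    arc_lengths: np.ndarray
    lambdas: np.ndarray
    residuals: np.ndarray
    converged: bool
    n_iter: int
    final_shift: float
    params: dict = field(default_factory=dict)

    @property
    def total_length(self) -> float:
        return float(self.arc_lengths[-1])

    def project(self, points: np.ndarray) -> np.ndarray:
        """Arc-length parameters of new points projected onto the curve."""
        lam, _ = project_to_polyline(np.atleast_2d(points), self.vertices)
        return lam


def fit_principal_curve(
    points: np.ndarray,
    span: float = 0.3,
    tol: float = 1e-4,
    max_iter: int = 50,
    smoother: str = "window",
) -> PrincipalCurve:
    """Fit a principal curve to an n x d point cloud.

    Initialized at the first principal-component line; alternates
    projection and per-coordinate smoothing until the mean squared
    vertex shift falls below `tol` or `max_iter` is reached (the result
    then carries ``converged=False``, never failing silently). Points
    are expected to be standardized upstream.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2:
        raise ValueError("points must be a 2-D array")
    n, d = points.shape
    if n < 5:
        raise ValueError(f"need at least 5 points, got {n}")
    if d < 2:
        raise ValueError(f"need at least 2 dimensions, got {d}")
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")

    center = points.mean(axis=0)
    x = points - center
    # first PC direction via SVD; lambda = signed position along the line
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    lam = x @ vt[0]
    smoothed = center + np.outer(lam, vt[0])

    def _order(lam_: np.ndarray, sm: np.ndarray) -> np.ndarray:
        # sort by lambda, break ties by the smoothed coordinates so
        # duplicated points stay adjacent (no spurious zigzag segments)
        keys = tuple(sm[:, j] for j in reversed(range(sm.shape[1]))) + (lam_,)
        return np.lexsort(keys)

    converged = False
    shift = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        new_smoothed = _smooth(points, lam, span, smoother)
        shift = float(np.mean((new_smoothed - smoothed) ** 2))
        smoothed = new_smoothed
        vertices = smoothed[_order(lam, smoothed)]
        lam, _ = project_to_polyline(points, vertices)
        if shift < tol:
            converged = True
            break

    vertices = smoothed[_order(lam, smoothed)]
    # drop float-noise-short segments before the final pass: their
    # directions are meaningless and would corrupt the end extension
    diag = float(np.linalg.norm(points.max(axis=0) - points.min(axis=0)))
    seglen = np.linalg.norm(np.diff(vertices, axis=0), axis=1)
    keep = np.concatenate([[True], seglen > 1e-9 * max(diag, 1.0)])
    vertices = vertices[keep]
    lam, res = project_to_polyline(points, vertices, extend=True)
    # grow the polyline to cover projections beyond its ends, so every
    # stored parameter lies within [0, total length]
    if len(vertices) > 1:
        length = float(
            np.sum(np.linalg.norm(np.diff(vertices, axis=0), axis=1))
        )

        def _end_direction(anchor: np.ndarray, inward: np.ndarray) -> np.ndarray:
            # skip float-noise-short segments when estimating the tangent
            min_len = 1e-8 * max(length, 1.0)
            for v in inward:
                delta = anchor - v
                nrm = np.linalg.norm(delta)
                if nrm > min_len:
                    return delta / nrm
            delta = anchor - inward[-1]
            return delta / np.linalg.norm(delta)

        lo, hi = float(lam.min()), float(lam.max())
        if lo < 0:
            u0 = -_end_direction(vertices[0], vertices[1:])
            vertices = np.vstack([vertices[0] + lo * u0, vertices])
            lam = lam - lo
        if hi > length:
            u1 = _end_direction(vertices[-1], vertices[-2::-1])
            vertices = np.vstack([vertices, vertices[-1] + (hi - length) * u1])
    arc = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(vertices, axis=0), axis=1))]
    )
    lam = np.clip(lam, 0.0, arc[-1])
    return PrincipalCurve(
        vertices=vertices,
        arc_lengths=arc,
        lambdas=lam,
        residuals=res,
        converged=converged,
        n_iter=it,
        final_shift=shift,
        params={"span": span, "tol": tol, "max_iter": max_iter, "smoother": smoother},
    )
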