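"""Landmark-based polynomial registration between SLO and fundus frames.

The scanning-laser-ophthalmoscope (SLO) image that anchors the OCT thickness
map and the color fundus photograph view the same retina through different
optics, so comparing thickness with fundus texture requires a spatial
transform between the two frames.  Following standard practice for
wide-field retinal registration on a curved retina, the transform is a
12-parameter second-order polynomial

    x' = a11 x² + a12 xy + a13 y² + a14 x + a15 y + a16
    y' = a21 x² + a22 xy + a23 y² + a24 x + a25 y + a26

fitted to manually picked landmark pairs (vessel bifurcations) by minimizing
the sum of squared coordinate residuals (the energy ℰ).  Both coordinate
rows share one monomial design matrix [x², xy, y², x, y, 1], so the fit is an
ordinary linear least-squares problem; it is solved here by QR/SVD
(numerically equivalent to solving the normal equations by Gauss
elimination, but better conditioned).

Coordinates are 0-based with pixel centers at integers, stored in (x, y) =
(col, row) order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator

__all__ = [
    "LandmarkSet",
    "QuadraticTransform",
    "SingularLandmarkError",
    "QuadraticLandmarkTransform",
    "fit_transform",
    "residual_energy",
    "apply_transform",
    "invert_points",
    "warp_image",
    "chessboard",
]

#: index of each monomial in the design matrix / coefficient rows
MONOMIALS = ("x^2", "xy", "y^2", "x", "y", "1")
_QUAD_COLS = (0, 1, 2)  # x², xy, y²


class SingularLandmarkError(ValueError):
    """Landmark configuration leaves the design matrix rank-deficient."""


@dataclass
class LandmarkSet:
    """Paired landmark coordinates, floating (x, y) ↔ reference (X, Y)."""

    floating: np.ndarray
    reference: np.ndarray

    def __post_init__(self) -> None:
        self.floating = np.atleast_2d(np.asarray(self.floating, dtype=float))
        self.reference = np.atleast_2d(np.asarray(self.reference, dtype=float))
        if self.floating.shape != self.reference.shape or self.floating.shape[1] != 2:
            raise ValueError("floating and reference must both be (N, 2) arrays")

    def __len__(self) -> int:
        return len(self.floating)


def _design(pts: np.ndarray) -> np.ndarray:
    x, y = pts[:, 0], pts[:, 1]
    return np.column_stack([x * x, x * y, y * y, x, y, np.ones_like(x)])


@dataclass
class QuadraticTransform:
    """2×6 coefficient matrix of the second-order polynomial transform."""

    a: np.ndarray
    kind: str = "quadratic"

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        if self.a.shape != (2, 6):
            raise ValueError("coefficient matrix must have shape (2, 6)")
        if self.kind not in ("affine", "quadratic"):
            raise ValueError("kind must be 'affine' or 'quadratic'")
        if self.kind == "affine" and np.any(self.a[:, _QUAD_COLS] != 0):
            raise ValueError("affine transform must have zero quadratic coefficients")

    @classmethod
    def identity(cls, kind: str = "quadratic") -> "QuadraticTransform":
        a = np.zeros((2, 6))
        a[0, 3] = 1.0  # a14: x
        a[1, 4] = 1.0  # a25: y
        return cls(a, kind=kind)

    def __call__(self, pts) -> np.ndarray:
        return apply_transform(self, pts)

    def jacobian(self, pts: np.ndarray) -> np.ndarray:
        """Per-point 2×2 Jacobian d(x', y')/d(x, y); shape (N, 2, 2)."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        x, y = pts[:, 0], pts[:, 1]
        a = self.a
        J = np.empty((len(pts), 2, 2))
        for i in range(2):
            J[:, i, 0] = 2 * a[i, 0] * x + a[i, 1] * y + a[i, 3]
            J[:, i, 1] = a[i, 1] * x + 2 * a[i, 2] * y + a[i, 4]
        return J

    # -- serialization: 12 numbers, row-major (a11..a16, a21..a26) -----------
    def to_json(self) -> str:
        return json.dumps({"kind": self.kind, "a": self.a.ravel().tolist()})

    @classmethod
    def from_json(cls, text: str) -> "QuadraticTransform":
        d = json.loads(text)
        return cls(np.asarray(d["a"], dtype=float).reshape(2, 6), kind=d["kind"])


def apply_transform(t: QuadraticTransform, pts) -> np.ndarray:
    """Map points through the polynomial; exact arithmetic, no resampling."""
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    return _design(pts) @ t.a.T


def fit_transform(lm: LandmarkSet, kind: str = "quadratic") -> QuadraticTransform:
    """Least-squares estimate of the transform from landmark pairs.

    Minimizes ℰ = Σ_i ‖t(x_i, y_i) − (X_i, Y_i)‖² over the 12 (quadratic) or
    6 (affine) free coefficients.  The x' and y' rows decouple and share the
    same design matrix, so each is an independent linear solve.

    Raises
    ------
    SingularLandmarkError
        Fewer landmarks than unknowns per row (6 quadratic / 3 affine) or a
        degenerate configuration (e.g. collinear points).
    """
    n_min = 6 if kind == "quadratic" else 3
    if len(lm) < n_min:
        raise SingularLandmarkError(
            f"{kind} fit needs at least {n_min} landmarks, got {len(lm)}"
        )
    A_full = _design(lm.floating)
    A = A_full if kind == "quadratic" else A_full[:, 3:]
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        raise SingularLandmarkError(
            f"landmark design matrix is rank-deficient (rank {rank} < "
            f"{A.shape[1]}); landmarks are degenerate (e.g. collinear)"
        )
    coef, *_ = np.linalg.lstsq(A, lm.reference, rcond=None)
    a = np.zeros((2, 6))
    if kind == "quadratic":
        a[:] = coef.T
    else:
        a[:, 3:] = coef.T
    return QuadraticTransform(a, kind=kind)


def residual_energy(t: QuadraticTransform, lm: LandmarkSet) -> float:
    """ℰ — sum of squared landmark residuals under ``t``."""
    r = apply_transform(t, lm.floating) - lm.reference
    return float(np.sum(r * r))


def invert_points(
    t: QuadraticTransform,
    pts,
    tol: float = 1e-6,
    max_iter: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """Numerically invert the transform at given *reference* points.

    A quadratic warp has no closed-form inverse; each point is refined by
    Newton iteration on t(p) − target = 0, seeded with the inverse of the
    affine part.  Returns ``(points, converged)`` where non-converged entries
    (outside the warp's invertible domain) are flagged False.
    """
    targets = np.atleast_2d(np.asarray(pts, dtype=float))
    # affine seed: solve [a14 a15; a24 a25] p = target - translation
    M = t.a[:, 3:5]
    b = t.a[:, 5]
    try:
        p = np.linalg.solve(M, (targets - b).T).T
    except np.linalg.LinAlgError:
        p = targets.copy()

    converged = np.zeros(len(targets), dtype=bool)
    active = np.ones(len(targets), dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        f = apply_transform(t, p[active]) - targets[active]
        err = np.abs(f).max(axis=1)
        done = err < tol
        idx_active = np.flatnonzero(active)
        converged[idx_active[done]] = True
        active[idx_active[done]] = False
        still = idx_active[~done]
        if len(still) == 0:
            break
        J = t.jacobian(p[still])
        det = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
        bad = np.abs(det) < 1e-12
        # singular Jacobian: mark unrecoverable
        if bad.any():
            active[still[bad]] = False
            still = still[~bad]
            if len(still) == 0:
                continue
            J = t.jacobian(p[still])
            det = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
        f = apply_transform(t, p[still]) - targets[still]
        dx = (J[:, 1, 1] * f[:, 0] - J[:, 0, 1] * f[:, 1]) / det
        dy = (-J[:, 1, 0] * f[:, 0] + J[:, 0, 0] * f[:, 1]) / det
        p[still, 0] -= dx
        p[still, 1] -= dy
    return p, converged


def warp_image(
    img: np.ndarray,
    t: QuadraticTransform,
    out_shape: tuple[int, int],
    interp: str = "bilinear",
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Resample a floating image onto the reference grid through ``t``.

    For every reference pixel (X, Y) the floating-frame location t⁻¹(X, Y) is
    found by Newton iteration and the floating image sampled there.  Pixels
    whose inverse does not converge or falls outside the floating raster are
    flagged invalid (mask False), never silently zero-filled.

    Returns ``(warped, valid_mask)``.
    """
    if interp not in ("nearest", "bilinear"):
        raise ValueError("interp must be 'nearest' or 'bilinear'")
    img = np.asarray(img, dtype=float)
    H, W = out_shape
    X, Y = np.meshgrid(np.arange(W, dtype=float), np.arange(H, dtype=float))
    targets = np.column_stack([X.ravel(), Y.ravel()])
    src, ok = invert_points(t, targets, tol=tol)
    if not ok.any():
        raise ValueError("warp is not invertible anywhere over the requested domain")

    xs, ys = src[:, 0], src[:, 1]
    inside = ok & (xs >= 0) & (xs <= img.shape[1] - 1) & (ys >= 0) & (ys <= img.shape[0] - 1)
    order = 0 if interp == "nearest" else 1
    sampled = ndimage.map_coordinates(
        img, [np.clip(ys, 0, img.shape[0] - 1), np.clip(xs, 0, img.shape[1] - 1)],
        order=order, mode="nearest",
    )
    warped = np.where(inside, sampled, np.nan).reshape(H, W)
    return warped, inside.reshape(H, W)


def chessboard(img_a: np.ndarray, img_b: np.ndarray, tile_px: int = 32) -> np.ndarray:
    """Diagnostic composite alternating tiles from two registered images."""
    if img_a.shape != img_b.shape:
        raise ValueError("chessboard inputs must share a shape")
    rr, cc = np.indices(img_a.shape[:2])
    take_a = ((rr // tile_px) + (cc // tile_px)) % 2 == 0
    return np.where(take_a, img_a, img_b)


class QuadraticLandmarkTransform(BaseEstimator):
    """Sklearn-style estimator for the landmark-fitted polynomial transform.

    ``fit(X, y)`` takes floating coordinates ``X`` (N, 2) and reference
    coordinates ``y`` (N, 2); ``transform`` maps floating → reference and
    ``inverse_transform`` goes the other way (Newton iteration).

    Attributes
    ----------
    coef_ : ndarray (2, 6)
        Fitted coefficient matrix (rows x', y'; columns x², xy, y², x, y, 1).
    energy_ : float
        Residual sum of squares ℰ at the fit.
    n_landmarks_ : int
    """

    def __init__(self, kind: str = "quadratic", refine_from_affine: bool = False):
        self.kind = kind
        self.refine_from_affine = refine_from_affine

    def fit(self, X, y):
        lm = LandmarkSet(X, y)
        if self.refine_from_affine and self.kind == "quadratic":
            # affine first for robustness diagnostics, then the full model;
            # the quadratic optimum itself is unchanged (nested linear models)
            self.affine_ = fit_transform(lm, kind="affine")
        t = fit_transform(lm, kind=self.kind)
        self.transform_ = t
        self.coef_ = t.a
        self.energy_ = residual_energy(t, lm)
        self.n_landmarks_ = len(lm)
        return self

    def transform(self, X):
        self._check_fitted()
        return apply_transform(self.transform_, X)

    def inverse_transform(self, X):
        self._check_fitted()
        pts, ok = invert_points(self.transform_, X)
        if not ok.all():
            raise ValueError("inverse did not converge for some points")
        return pts

    def _check_fitted(self):
        if not hasattr(self, "transform_"):
            raise AttributeError("estimator is not fitted; call fit(X, y) first")
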