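"""Landmark-based LM-to-EM registration.

Two transform families:

* :class:`AffineTransform` — rotation (unit quaternion) composed with a
  per-axis anisotropic scale of the source frame and a translation:
  ``y = R @ diag(s) @ x + t``.  Fitted from control-point pairs by Horn's
  closed-form absolute-orientation solution, with the scale vector optimized
  by block coordinate descent (the per-axis least-squares scale update is
  itself closed form, so the alternation is derivative-free and monotone in
  mean squared residual).  Anisotropic scale matters because EM processing
  shrinks tissue differently along the cutting axis.

* :class:`FreeformTransform` — the affine base plus a multi-level cubic
  B-spline displacement field.  Level 0 fits the residual displacements on a
  coarse knot lattice; each refinement bisects the knot spacing and fits what
  remains.  A small Tikhonov (ridge) weight keeps under-determined lattice
  cells stable.  Defaults: 32 µm initial knot spacing, four refinement
  levels.

All fitting is done in physical nanometres, so the initial scale guess is
the unit vector (any nominal voxel-size ratio is absorbed by the I/O
conversion).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import lsqr

from .io_formats import ControlPointTable
from .skeletons import Skeleton


class FitError(ValueError):
    pass


# ---------------------------------------------------------------------------
# quaternion helpers
# ---------------------------------------------------------------------------

def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    w, x, y, z = q / np.linalg.norm(q)
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)]])


def matrix_to_quat(R: np.ndarray) -> np.ndarray:
    # Shepperd's method
    t = np.trace(R)
    if t > 0:
        w = np.sqrt(1 + t) / 2
        x = (R[2, 1] - R[1, 2]) / (4 * w)
        y = (R[0, 2] - R[2, 0]) / (4 * w)
        z = (R[1, 0] - R[0, 1]) / (4 * w)
    else:
        i = int(np.argmax(np.diag(R)))
        j, k = (i + 1) % 3, (i + 2) % 3
        s = np.sqrt(1 + R[i, i] - R[j, j] - R[k, k]) * 2
        q = np.empty(4)
        q[0] = (R[k, j] - R[j, k]) / s
        q[i + 1] = s / 4
        q[j + 1] = (R[j, i] + R[i, j]) / s
        q[k + 1] = (R[k, i] + R[i, k]) / s
        w, x, y, z = q
    q = np.array([w, x, y, z])
    if q[0] < 0:
        q = -q
    return q / np.linalg.norm(q)


def rotation_about_axis(axis, angle_rad: float) -> np.ndarray:
    """Unit quaternion for a rotation about an axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    return np.concatenate([[np.cos(angle_rad / 2)],
                           np.sin(angle_rad / 2) * axis])


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

@dataclass
class AffineTransform:
    """y = R @ diag(scale) @ x + translation, all in nm."""

    quaternion: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 0, 0, 0]))
    scale: np.ndarray = field(default_factory=lambda: np.ones(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.quaternion = np.asarray(self.quaternion, dtype=float)
        self.quaternion = self.quaternion / np.linalg.norm(self.quaternion)
        self.scale = np.asarray(self.scale, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if np.any(self.scale <= 0):
            raise ValueError("scale components must be > 0")

    @property
    def matrix(self) -> np.ndarray:
        return quat_to_matrix(self.quaternion) @ np.diag(self.scale)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        out = np.atleast_2d(pts) @ self.matrix.T + self.translation
        return out[0] if single else out

    def apply_inverse(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        R = quat_to_matrix(self.quaternion)
        out = ((pts - self.translation) @ R) / self.scale
        return out[0] if np.asarray(points).ndim == 1 else out

    def translated(self, offset) -> "AffineTransform":
        return AffineTransform(self.quaternion.copy(), self.scale.copy(),
                               self.translation + np.asarray(offset, float))

    def to_dict(self) -> dict:
        return {"type": "affine", "quaternion": self.quaternion.tolist(),
                "scale": self.scale.tolist(),
                "translation": self.translation.tolist()}

    @classmethod
    def from_dict(cls, d) -> "AffineTransform":
        return cls(np.array(d["quaternion"]), np.array(d["scale"]),
                   np.array(d["translation"]))

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls()


def _bspline_weights(t: np.ndarray) -> np.ndarray:
    """Uniform cubic B-spline basis values for fractional offsets t in [0,1).

    Returns shape (len(t), 4): weights for lattice points i-1, i, i+1, i+2.
    """
    t2, t3 = t * t, t * t * t
    return np.stack([
        (1 - t) ** 3 / 6.0,
        (3 * t3 - 6 * t2 + 4) / 6.0,
        (-3 * t3 + 3 * t2 + 3 * t + 1) / 6.0,
        t3 / 6.0], axis=1)


@dataclass
class BSplineLevel:
    """One cubic B-spline displacement lattice."""

    origin: np.ndarray       # nm, lattice index 0 position
    spacing: np.ndarray      # nm per knot cell, (3,)
    shape: tuple             # knots per axis (K1, K2, K3)
    coeffs: np.ndarray       # (K1*K2*K3, 3) displacement coefficients, nm

    def design(self, points: np.ndarray):
        """Sparse design matrix rows for the given points.

        Points outside the lattice support contribute zero rows (their
        displacement from this level is 0).
        """
        pts = np.atleast_2d(points)
        n = len(pts)
        u = (pts - self.origin) / self.spacing
        cell = np.floor(u).astype(int)
        frac = u - cell
        K = np.array(self.shape)
        valid = np.all((cell >= 1) & (cell <= K - 3), axis=1)
        w = [_bspline_weights(frac[:, d]) for d in range(3)]
        rows, cols, vals = [], [], []
        idx_valid = np.nonzero(valid)[0]
        if len(idx_valid):
            offs = np.arange(-1, 3)
            # tensor-product weights, vectorized over points
            wx = w[0][idx_valid][:, :, None, None]
            wy = w[1][idx_valid][:, None, :, None]
            wz = w[2][idx_valid][:, None, None, :]
            wt = (wx * wy * wz).reshape(len(idx_valid), -1)
            ci = cell[idx_valid]
            gx = ci[:, 0, None, None, None] + offs[None, :, None, None]
            gy = ci[:, 1, None, None, None] + offs[None, None, :, None]
            gz = ci[:, 2, None, None, None] + offs[None, None, None, :]
            flat = ((gx * K[1] + gy) * K[2] + gz).reshape(len(idx_valid), -1)
            rows = np.repeat(idx_valid, 64)
            cols = flat.ravel()
            vals = wt.ravel()
        A = coo_matrix((vals, (rows, cols)),
                       shape=(n, int(np.prod(self.shape)))).tocsr()
        return A

    def displacement(self, points: np.ndarray) -> np.ndarray:
        return self.design(points) @ self.coeffs

    def to_dict(self) -> dict:
        return {"origin": self.origin.tolist(),
                "spacing": self.spacing.tolist(),
                "shape": list(self.shape), "coeffs": self.coeffs.tolist()}

    @classmethod
    def from_dict(cls, d) -> "BSplineLevel":
        return cls(np.array(d["origin"]), np.array(d["spacing"]),
                   tuple(d["shape"]), np.array(d["coeffs"]))


@dataclass
class FreeformTransform:
    """Affine base followed by summed multi-level B-spline displacements."""

    base: AffineTransform
    levels: list = field(default_factory=list)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        out = np.atleast_2d(self.base.apply(pts))
        x = out.copy()
        for lev in self.levels:
            out = out + lev.displacement(x)
        return out[0] if single else out

    def displacement_field(self, affine_frame_points: np.ndarray) -> np.ndarray:
        """Summed displacement evaluated at affine-frame positions."""
        pts = np.atleast_2d(affine_frame_points)
        d = np.zeros_like(pts)
        for lev in self.levels:
            d = d + lev.displacement(pts)
        return d

    def to_dict(self) -> dict:
        return {"type": "freeform", "base": self.base.to_dict(),
                "levels": [lev.to_dict() for lev in self.levels]}

    @classmethod
    def from_dict(cls, d) -> "FreeformTransform":
        return cls(AffineTransform.from_dict(d["base"]),
                   [BSplineLevel.from_dict(x) for x in d["levels"]])


def transform_from_dict(d):
    return (AffineTransform.from_dict(d) if d.get("type") == "affine"
            else FreeformTransform.from_dict(d))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _horn_rigid(src: np.ndarray, dst: np.ndarray):
    """Closed-form least-squares rotation + translation (no scale)."""
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    a, b = src - cs, dst - cd
    M = a.T @ b
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    N = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz]])
    w, v = np.linalg.eigh(N)
    q = v[:, -1]
    if q[0] < 0:
        q = -q
    R = quat_to_matrix(q)
    t = cd - R @ cs
    return q, R, t


def fit_affine(cps: ControlPointTable, tol: float = 1e-12,
               max_iter: int = 500) -> AffineTransform:
    """Fit rotation, anisotropic scale and translation from landmark pairs.

    Requires >= 3 non-collinear pairs.  Starts from Horn's isotropic-scale
    solution and alternates (i) closed-form rigid refit on the scaled source
    and (ii) closed-form per-axis scale update, until the relative MSE
    improvement falls below ``tol``.
    """
    if len(cps) < 3:
        raise FitError("need at least 3 control point pairs")
    lm, em = cps.lm, cps.em
    centered = lm - lm.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[1] <= 1e-9 * max(sv[0], 1.0):
        raise FitError("control points are collinear; affine fit is "
                       "degenerate")

    # Horn isotropic initialization
    q, R, t = _horn_rigid(lm, em)
    a = lm - lm.mean(axis=0)
    b = em - em.mean(axis=0)
    denom = (a * a).sum()
    s_iso = float((b * (a @ R.T)).sum() / denom) if denom > 0 else 1.0
    s = np.full(3, max(s_iso, 1e-12))

    def mse(q, s, t):
        r = em - (lm * s) @ quat_to_matrix(q).T - t
        return float((r * r).sum() / len(lm))

    q, R, t = _horn_rigid(lm * s, em)
    prev = mse(q, s, t)
    for _ in range(max_iter):
        # exact per-axis scale given (R, t): minimize ||R^T(em - t) - s*lm||
        z = (em - t) @ R
        num = (lm * z).sum(axis=0)
        den = (lm * lm).sum(axis=0)
        s_new = np.where(den > 0, num / den, s)
        s = np.where(s_new > 0, s_new, s)
        q, R, t = _horn_rigid(lm * s, em)
        cur = mse(q, s, t)
        if prev - cur <= tol * max(prev, 1e-300):
            prev = cur
            break
        prev = cur
    return AffineTransform(q, s, t)


def apply_transform(transform, obj):
    """Apply an affine or free-form transform to points or a Skeleton."""
    if isinstance(obj, Skeleton):
        return obj.transformed(transform.apply)
    return transform.apply(np.asarray(obj, dtype=float))


def local_offset_correction(t: AffineTransform, anchor_lm,
                            anchor_em) -> AffineTransform:
    """Compose ``t`` with the translation mapping t(anchor_lm) onto anchor_em.

    Rotation and scale are unchanged; useful to cancel the local residual of
    a coarse fit near a known corresponding landmark.
    """
    anchor_lm = np.asarray(anchor_lm, dtype=float)
    anchor_em = np.asarray(anchor_em, dtype=float)
    return t.translated(anchor_em - t.apply(anchor_lm))


def fit_freeform(cps: ControlPointTable, base: AffineTransform | None = None,
                 initial_spacing: float = 32_000.0, refinements: int = 4,
                 ridge: float = 1e-3) -> FreeformTransform:
    """Fit a multi-level cubic B-spline displacement field on top of an affine.

    Level 0 fits the residuals ``em - base(lm)`` (as a function of the
    affine-frame position) on a lattice with ``initial_spacing`` nm knots;
    each of the ``refinements`` further levels halves the knot spacing and
    fits the remaining residual.  Each level solves a damped least-squares
    problem (LSQR with damp = sqrt(ridge)), so the training residual never
    increases across levels.
    """
    if initial_spacing <= 0:
        raise ValueError("initial_spacing must be > 0")
    if refinements < 0:
        raise ValueError("refinements must be >= 0")
    if base is None:
        base = fit_affine(cps)
    x = base.apply(cps.lm)          # affine-frame positions
    resid = cps.em - x
    lo, hi = x.min(axis=0), x.max(axis=0)
    levels = []
    for k in range(refinements + 1):
        spacing = np.full(3, initial_spacing / (2 ** k))
        origin = lo - spacing
        # lattice covers [lo, hi] with one full knot margin on each side
        n_cells = np.ceil((hi - origin) / spacing).astype(int)
        shape = tuple(int(c) + 3 for c in n_cells)
        lev = BSplineLevel(origin=origin, spacing=spacing, shape=shape,
                           coeffs=np.zeros((int(np.prod(shape)), 3)))
        A = lev.design(x)
        damp = np.sqrt(ridge)
        coeffs = np.zeros((A.shape[1], 3))
        for d in range(3):
            coeffs[:, d] = lsqr(A, resid[:, d], damp=damp, atol=1e-12,
                                btol=1e-12, iter_lim=2000)[0]
        lev.coeffs = coeffs
        pred = A @ coeffs
        resid = resid - pred
        levels.append(lev)
    return FreeformTransform(base=base, levels=levels)


# ---------------------------------------------------------------------------
# residuals and bootstrap
# ---------------------------------------------------------------------------

@dataclass
class ResidualReport:
    residuals_nm: np.ndarray
    mean_nm: float
    sd_nm: float
    median_nm: float
    n: int

    def to_dict(self) -> dict:
        return {"residuals_nm": self.residuals_nm.tolist(),
                "mean_nm": self.mean_nm, "sd_nm": self.sd_nm,
                "median_nm": self.median_nm, "n": self.n}


def residual_error(transform, heldout: ControlPointTable) -> ResidualReport:
    """Per-pair Euclidean residual ||em - T(lm)|| on held-out pairs."""
    if len(heldout) == 0:
        raise ValueError("held-out table is empty")
    pred = transform.apply(heldout.lm)
    r = np.linalg.norm(heldout.em - pred, axis=1)
    return ResidualReport(residuals_nm=r, mean_nm=float(r.mean()),
                          sd_nm=float(r.std(ddof=1)) if len(r) > 1 else 0.0,
                          median_nm=float(np.median(r)), n=len(r))


@dataclass
class BootstrapCurve:
    cp_counts: list
    mean_residual_nm: np.ndarray
    sd_residual_nm: np.ndarray
    n_reps: int
    seed: int
    mode: str

    def to_dict(self) -> dict:
        return {"cp_counts": list(self.cp_counts),
                "mean_residual_nm": self.mean_residual_nm.tolist(),
                "sd_residual_nm": self.sd_residual_nm.tolist(),
                "n_reps": self.n_reps, "seed": self.seed, "mode": self.mode}


def bootstrap_cp_curve(cps: ControlPointTable,
                       counts=(5, 10, 25, 50, 75, 100, 150, 200, 250),
                       n_reps: int = 10, n_holdout: int = 30,
                       seed: int = 0, mode: str = "affine",
                       freeform_kwargs: dict | None = None) -> BootstrapCurve:
    """Held-out residual vs number of constraining control points.

    For each count: sample that many constraint pairs without replacement,
    fit (affine or free-form), sample a disjoint holdout of ``n_holdout``
    pairs, and record the mean residual; repeated ``n_reps`` times.
    """
    counts = sorted(counts)
    if counts[-1] + n_holdout > len(cps):
        raise ValueError(f"need at least {counts[-1] + n_holdout} control "
                         f"points, have {len(cps)}")
    rng = np.random.default_rng(seed)
    means, sds = [], []
    for c in counts:
        reps = []
        for _ in range(n_reps):
            perm = rng.permutation(len(cps))
            fit_idx, hold_idx = perm[:c], perm[c:c + n_holdout]
            fit_set, hold_set = cps.subset(fit_idx), cps.subset(hold_idx)
            if mode == "affine":
                t = fit_affine(fit_set)
            elif mode == "freeform":
                t = fit_freeform(fit_set, **(freeform_kwargs or {}))
            else:
                raise ValueError(f"unknown mode {mode!r}")
            reps.append(residual_error(t, hold_set).mean_nm)
        reps = np.array(reps)
        means.append(reps.mean())
        sds.append(reps.std(ddof=1) if len(reps) > 1 else 0.0)
    return BootstrapCurve(cp_counts=list(counts),
                          mean_residual_nm=np.array(means),
                          sd_residual_nm=np.array(sds),
                          n_reps=n_reps, seed=seed, mode=mode)
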