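"""Subset-based incremental digital image correlation and strain profiles.

Each point of a regular grid (step 4 px) inside a user ROI carries a
square subset (31 px) that is matched between consecutive analysed
frames by minimising the normalised sum of squared differences (NSSD)

    C(p) = sum_i ( f_i / ||f||  -  g_i(p) / ||g|| )^2

over first-order (affine) subset shape functions
``p = (u, v, du/dx, du/dy, dv/dx, dv/dy)``, with an integer-pixel coarse
search followed by Gauss-Newton subpixel refinement on cubic-spline
interpolated intensities.  Displacements accumulate across increments by
advecting each point with its cumulative displacement; points whose
match fails to converge, or whose final update exceeds the matchability
threshold (0.1 px), are invalidated and never revived.

Strain is a post-processing step: a local least-squares affine fit of
the cumulative displacement over a square window of grid points yields
the deformation gradient F and the Lagrangian strain
``E = (F^T F - I)/2``, rotated into polar components about the reference
pupil centre.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.distance import directed_hausdorff

logger = logging.getLogger(__name__)

__all__ = [
    "DisplacementField",
    "StrainField",
    "StrainProfile",
    "TrackingLostError",
    "correlate_incremental",
    "compute_strain_field",
    "extract_profile",
    "hausdorff_outlier",
    "virtual_tensometer",
]


class TrackingLostError(RuntimeError):
    def __init__(self, message, increment=None):
        super().__init__(message)
        self.increment = increment


@dataclass
class DisplacementField:
    """Cumulative subpixel displacements of a reference grid."""

    points: np.ndarray        # (N, 2) reference grid positions, px (x, y)
    displacement: np.ndarray  # (N, 2) cumulative (u, v), px
    valid: np.ndarray         # (N,) bool
    residual: np.ndarray      # (N,) final-update norm of last increment, px
    grid_shape: tuple         # (ny, nx) of the rectangular grid
    subset: int = 31
    step: int = 4

    def as_grids(self):
        """(X, Y, U, V, valid) reshaped to the rectangular grid with NaN
        at invalid points."""
        ny, nx = self.grid_shape
        X = self.points[:, 0].reshape(ny, nx)
        Y = self.points[:, 1].reshape(ny, nx)
        U = np.where(self.valid, self.displacement[:, 0], np.nan).reshape(ny, nx)
        V = np.where(self.valid, self.displacement[:, 1], np.nan).reshape(ny, nx)
        return X, Y, U, V, self.valid.reshape(ny, nx)


@dataclass
class StrainField:
    """Lagrangian strain tensors on the DIC grid (NaN where invalid)."""

    x: np.ndarray             # (ny, nx) reference grid positions
    y: np.ndarray
    E_xx: np.ndarray
    E_yy: np.ndarray
    E_xy: np.ndarray
    E_rr: np.ndarray          # polar components about `center`
    E_tt: np.ndarray
    E_rt: np.ndarray
    valid: np.ndarray
    center: tuple             # reference pupil centre (x, y), px


@dataclass
class StrainProfile:
    """Median/IQR of each strain component versus normalised radius.

    ``x_bar`` runs from 0 at the pupillary margin to 1 at the limbus.
    ``data`` has columns x_bar, then <comp>_median, <comp>_q1, <comp>_q3
    for each of E_rr, E_tt, E_rt.
    """

    data: pd.DataFrame

    @property
    def x_bar(self):
        return self.data["x_bar"].to_numpy()

    def component(self, name):
        return self.data[f"{name}_median"].to_numpy()

    def to_csv(self, path):
        self.data.to_csv(path, index=False)


def _prefilter(img):
    return ndimage.spline_filter(np.asarray(img, dtype=float), order=3)


def _sample(coeffs, ys, xs):
    return ndimage.map_coordinates(coeffs, [ys, xs], order=3,
                                   prefilter=False, mode="nearest")


def _nssd(f, g):
    fn = f / np.maximum(np.linalg.norm(f, axis=-1, keepdims=True), 1e-12)
    gn = g / np.maximum(np.linalg.norm(g, axis=-1, keepdims=True), 1e-12)
    return np.sum((fn - gn) ** 2, axis=-1)


def _integer_search(ref_sub, cur_img, centers, search: int, decim: int = 4):
    """Coarse integer-pixel translation per point by decimated NSSD scan."""
    n, m2 = ref_sub.shape
    m = int(np.sqrt(m2))
    half = (m - 1) // 2
    off = np.arange(-half, half + 1)
    oy, ox = np.meshgrid(off[::decim], off[::decim], indexing="ij")
    sel = (np.ravel_multi_index(
        (oy.ravel() + half, ox.ravel() + half), (m, m)))
    f = ref_sub[:, sel]
    best = np.zeros((n, 2))
    best_c = np.full(n, np.inf)
    # visit offsets outward from zero so featureless (tied) subsets keep
    # the zero-displacement hypothesis
    offsets = sorted(((dx, dy)
                      for dy in range(-search, search + 1)
                      for dx in range(-search, search + 1)),
                     key=lambda d: d[0] ** 2 + d[1] ** 2)
    for dx, dy in offsets:
        ys = (centers[:, 1, None] + dy + oy.ravel())
        xs = (centers[:, 0, None] + dx + ox.ravel())
        g = ndimage.map_coordinates(cur_img, [ys.ravel(), xs.ravel()],
                                    order=1, prefilter=False,
                                    mode="nearest").reshape(n, -1)
        c = _nssd(f, g)
        upd = c < best_c * (1.0 - 1e-9)
        best_c = np.where(upd, c, best_c)
        best[upd] = (dx, dy)
    return best


def _gauss_newton(ref_sub, cur_coeffs, gx_coeffs, gy_coeffs, centers, p0,
                  offsets, max_iter=20, tol=1e-4):
    """Batched forward-additive Gauss-Newton NSSD refinement.

    Returns (params, last_update_norm, converged, final_cost) per point.
    """
    n = len(centers)
    p = p0.copy()                     # (n, 6): u, v, ux, uy, vx, vy
    ox, oy = offsets                  # each (m,)
    fn = ref_sub / np.maximum(np.linalg.norm(ref_sub, axis=1, keepdims=True),
                              1e-12)
    last = np.full(n, np.inf)
    cost = np.full(n, np.inf)
    active = np.ones(n, dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        idx = np.where(active)[0]
        pa = p[idx]
        xs = centers[idx, 0, None] + ox + pa[:, 0, None] \
            + pa[:, 2, None] * ox + pa[:, 3, None] * oy
        ys = centers[idx, 1, None] + oy + pa[:, 1, None] \
            + pa[:, 4, None] * ox + pa[:, 5, None] * oy
        g = _sample(cur_coeffs, ys.ravel(), xs.ravel()).reshape(len(idx), -1)
        gx = _sample(gx_coeffs, ys.ravel(), xs.ravel()).reshape(len(idx), -1)
        gy = _sample(gy_coeffs, ys.ravel(), xs.ravel()).reshape(len(idx), -1)
        gnorm = np.maximum(np.linalg.norm(g, axis=1, keepdims=True), 1e-12)
        r = fn[idx] - g / gnorm
        cost[idx] = np.sum(r ** 2, axis=1)
        # Jacobian of g/||g|| approximated by grad(g)/||g||
        J = np.stack([gx, gy, gx * ox, gx * oy, gy * ox, gy * oy],
                     axis=2) / gnorm[:, :, None]
        A = np.einsum("nmi,nmj->nij", J, J)
        b = np.einsum("nmi,nm->ni", J, r)
        try:
            dp = np.linalg.solve(A + 1e-12 * np.eye(6), b[..., None])[..., 0]
        except np.linalg.LinAlgError:
            dp = np.zeros_like(b)
        p[idx] += dp
        upd = np.linalg.norm(dp[:, :2], axis=1)
        last[idx] = upd
        active[idx] = upd > tol
    return p, last, ~active, cost


def _grid_points(roi_mask, subset, step):
    h, w = roi_mask.shape
    half = subset // 2
    xs = np.arange(half, w - half, step)
    ys = np.arange(half, h - half, step)
    X, Y = np.meshgrid(xs, ys)
    inside = roi_mask[Y, X]
    return np.column_stack([X.ravel(), Y.ravel()]).astype(float), \
        inside.ravel(), (len(ys), len(xs))


def correlate_incremental(frames, roi_mask, subset: int = 31, step: int = 4,
                          threshold: float = 0.1, search: int = 8,
                          max_nssd: float = 0.05,
                          exclude=()) -> DisplacementField:
    """Incremental NSSD correlation through a frame list.

    Parameters
    ----------
    frames : sequence of 2D arrays
        Analysed frames in time order (the first is the reference).
    roi_mask : 2D bool array
        Region of interest in the reference frame; must exclude the
        pupil and eyelids.
    threshold : float
        Matchability threshold (px) on the final Gauss-Newton update;
        points above it are invalidated permanently.
    exclude : collection of int
        Frame indices (e.g. blinks) skipped while keeping time order.
    """
    frames = [np.asarray(f, dtype=float) for f in frames]
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    points, inside, grid_shape = _grid_points(np.asarray(roi_mask, bool),
                                              subset, step)
    n = len(points)
    disp = np.zeros((n, 2))
    valid = inside.copy()
    residual = np.zeros(n)
    half = subset // 2
    off = np.arange(-half, half + 1)
    OX, OY = np.meshgrid(off, off)
    ox, oy = OX.ravel().astype(float), OY.ravel().astype(float)

    keep = [i for i in range(len(frames)) if i not in set(exclude)]
    for inc, (i0, i1) in enumerate(zip(keep[:-1], keep[1:])):
        ref_c = _prefilter(frames[i0])
        cur = frames[i1]
        cur_c = _prefilter(cur)
        gyi, gxi = np.gradient(cur)
        gx_c, gy_c = _prefilter(gxi), _prefilter(gyi)
        idx = np.where(valid)[0]
        if len(idx) == 0:
            raise TrackingLostError("tracking lost: all points invalid",
                                    increment=inc)
        centers = points[idx] + disp[idx]
        xs = centers[:, 0, None] + ox
        ys = centers[:, 1, None] + oy
        ref_sub = _sample(ref_c, ys.ravel(), xs.ravel()).reshape(len(idx), -1)
        p0 = np.zeros((len(idx), 6))
        p0[:, :2] = _integer_search(ref_sub, cur, centers, search)
        p, last, conv, cost = _gauss_newton(ref_sub, cur_c, gx_c, gy_c,
                                            centers, p0, (ox, oy))
        ok = (last <= threshold) & (cost <= max_nssd)
        # reject matches that drifted out of the image
        newc = centers + p[:, :2]
        h, w = cur.shape
        ok &= (newc[:, 0] > half) & (newc[:, 0] < w - half) \
            & (newc[:, 1] > half) & (newc[:, 1] < h - half)
        disp[idx[ok]] += p[ok, :2]
        residual[idx] = last
        valid[idx] = ok
        if not valid.any():
            raise TrackingLostError("tracking lost: all points invalid",
                                    increment=inc)
    return DisplacementField(points=points, displacement=disp, valid=valid,
                             residual=residual, grid_shape=grid_shape,
                             subset=subset, step=step)


def compute_strain_field(field: DisplacementField, filter_size: int = 15,
                         center=None, min_points: int = 9) -> StrainField:
    """Lagrangian strain from a local affine fit of the displacement.

    At each grid point the displacement over a ``filter_size`` x
    ``filter_size`` window of grid points (grid units, matching common
    commercial-DIC convention) is fitted with u = a + b x + c y by least
    squares; F = I + grad(u) and E = (F^T F - I)/2.  Points with fewer
    than ``min_points`` valid neighbours are marked invalid.
    """
    X, Y, U, V, valid = field.as_grids()
    ny, nx = X.shape
    half = filter_size // 2
    s = float(field.step)
    # windowed moment sums via correlation with offset kernels
    dx_k = np.tile(np.arange(-half, half + 1, dtype=float), (filter_size, 1))
    dy_k = dx_k.T
    one_k = np.ones((filter_size, filter_size))

    m = valid.astype(float)
    Uz = np.where(valid, U, 0.0)
    Vz = np.where(valid, V, 0.0)

    def corr(a, k):
        return ndimage.correlate(a, k, mode="constant", cval=0.0)

    # correlate applies the kernel unflipped, so the weight at neighbour
    # (i+dy, j+dx) is exactly (dx, dy) in grid units
    def moments(k):
        return corr(m, k)

    S1 = moments(one_k)
    Sx = moments(dx_k)
    Sy = moments(dy_k)
    Sxx = moments(dx_k * dx_k)
    Sxy = moments(dx_k * dy_k)
    Syy = moments(dy_k * dy_k)

    def rhs(f):
        fz = np.where(valid, f, 0.0)
        return corr(fz, one_k), corr(fz, dx_k), corr(fz, dy_k)

    Su, Sxu, Syu = rhs(Uz)
    Sv, Sxv, Syv = rhs(Vz)

    A = np.stack([
        np.stack([S1, Sx, Sy], -1),
        np.stack([Sx, Sxx, Sxy], -1),
        np.stack([Sy, Sxy, Syy], -1),
    ], -2)                                      # (ny, nx, 3, 3)
    bu = np.stack([Su, Sxu, Syu], -1)
    bv = np.stack([Sv, Sxv, Syv], -1)
    good = valid & (S1 >= min_points)
    det_ok = np.abs(np.linalg.det(A)) > 1e-9
    good &= det_ok
    Ai = np.linalg.pinv(A)
    cu = np.einsum("...ij,...j->...i", Ai, bu)
    cv = np.einsum("...ij,...j->...i", Ai, bv)
    # gradients w.r.t. pixels: window offsets were in grid units
    ux, uy = cu[..., 1] / s, cu[..., 2] / s
    vx, vy = cv[..., 1] / s, cv[..., 2] / s

    Fxx, Fxy, Fyx, Fyy = 1.0 + ux, uy, vx, 1.0 + vy
    Exx = 0.5 * (Fxx ** 2 + Fyx ** 2 - 1.0)
    Eyy = 0.5 * (Fxy ** 2 + Fyy ** 2 - 1.0)
    Exy = 0.5 * (Fxx * Fxy + Fyx * Fyy)
    for arr in (Exx, Eyy, Exy):
        arr[~good] = np.nan

    if center is None:
        center = (float(np.nanmean(X)), float(np.nanmean(Y)))
    th = np.arctan2(Y - center[1], X - center[0])
    c, sn = np.cos(th), np.sin(th)
    Err = Exx * c ** 2 + 2 * Exy * sn * c + Eyy * sn ** 2
    Ett = Exx * sn ** 2 - 2 * Exy * sn * c + Eyy * c ** 2
    Ert = (Eyy - Exx) * sn * c + Exy * (c ** 2 - sn ** 2)
    return StrainField(x=X, y=Y, E_xx=Exx, E_yy=Eyy, E_xy=Exy,
                       E_rr=Err, E_tt=Ett, E_rt=Ert, valid=good,
                       center=center)


def extract_profile(strain: StrainField, pupil_center, pupil_radius_px,
                    limbus_radius_px, n_bins: int = 25) -> StrainProfile:
    """Strain profile along the nasal-temporal axis.

    Uses a rectangular box through the pupil centre of total height half
    the reference pupil radius and width twice the limbus radius; per
    x-bar bin, the median and quartiles over the box are computed with
    the nasal and temporal arms pooled.  ``x_bar = (|x - x_c| - r_p0) /
    (r_l - r_p0)``.
    """
    xc, yc = pupil_center
    rp, rl = float(pupil_radius_px), float(limbus_radius_px)
    box = (np.abs(strain.y - yc) <= rp / 4.0) & \
        (np.abs(strain.x - xc) <= rl)
    if not box.any():
        raise ValueError("profile box does not intersect the strain grid")
    xbar = (np.abs(strain.x - xc) - rp) / (rl - rp)
    sel = box & strain.valid & (xbar >= 0.0) & (xbar <= 1.0)
    if not sel.any():
        raise ValueError("no valid strain points inside the profile box")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    rows = {"x_bar": mids}
    for name, comp in [("E_rr", strain.E_rr), ("E_tt", strain.E_tt),
                       ("E_rt", strain.E_rt)]:
        med = np.full(n_bins, np.nan)
        q1 = np.full(n_bins, np.nan)
        q3 = np.full(n_bins, np.nan)
        for k in range(n_bins):
            inbin = sel & (xbar >= edges[k]) & (xbar < edges[k + 1])
            vals = comp[inbin]
            vals = vals[np.isfinite(vals)]
            if len(vals):
                med[k] = np.median(vals)
                q1[k], q3[k] = np.percentile(vals, [25, 75])
        rows[f"{name}_median"] = med
        rows[f"{name}_q1"] = q1
        rows[f"{name}_q3"] = q3
    return StrainProfile(data=pd.DataFrame(rows).dropna(
        subset=["E_rr_median"]).reset_index(drop=True))


def hausdorff_outlier(profiles, component: str = "E_rr", n_sd: float = 2.0):
    """Screen profile curves by Hausdorff distance to the median curve.

    Each curve is the point set {(x_bar, eps)}; curves whose symmetric
    Hausdorff distance to the pointwise-median curve exceeds
    ``mean + n_sd * sd`` of all distances are excluded.  Returns
    (kept, excluded) index arrays; with fewer than 3 curves nothing is
    excluded.
    """
    import warnings as _w

    idx = np.arange(len(profiles))
    if len(profiles) < 3:
        _w.warn("fewer than 3 profiles: outlier screen skipped")
        return idx, np.array([], dtype=int)
    grid = np.linspace(0.0, 1.0, 50)
    curves = []
    for p in profiles:
        curves.append(np.interp(grid, p.x_bar, p.component(component)))
    curves = np.array(curves)
    median_curve = np.median(curves, axis=0)
    ref = np.column_stack([grid, median_curve])
    dists = np.array([
        max(directed_hausdorff(np.column_stack([grid, c]), ref)[0],
            directed_hausdorff(ref, np.column_stack([grid, c]))[0])
        for c in curves])
    cut = dists.mean() + n_sd * dists.std(ddof=0)
    bad = dists > max(cut, 1e-12)
    return idx[~bad], idx[bad]


def virtual_tensometer(field: DisplacementField, pupil_center,
                       pupil_radius_px, band_px: float = 12.0) -> float:
    """Pupil-margin strain from a tracked chord across the pupil.

    Picks the valid DIC points nearest the nasal-temporal axis inside an
    annular band just outside the reference pupil margin, one on each
    side, and evaluates the Lagrangian strain of the chord between them.
    """
    xc, yc = pupil_center
    rel = field.points - np.array([xc, yc])
    rad = np.hypot(rel[:, 0], rel[:, 1])
    band = field.valid & (rad >= pupil_radius_px) & \
        (rad <= pupil_radius_px + band_px)
    left = band & (rel[:, 0] < 0)
    right = band & (rel[:, 0] > 0)
    if not left.any() or not right.any():
        raise TrackingLostError("tensometer failed: no valid margin points")

    def pick(mask):
        cand = np.where(mask)[0]
        return cand[np.argmin(np.abs(rel[cand, 1]))]

    i, j = pick(left), pick(right)
    p0 = field.points[i], field.points[j]
    p1 = p0[0] + field.displacement[i], p0[1] + field.displacement[j]
    L0 = np.linalg.norm(p0[1] - p0[0])
    L1 = np.linalg.norm(p1[1] - p1[0])
    return float(0.5 * ((L1 / L0) ** 2 - 1.0))
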