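"""Per-frame pupil segmentation and limbus localisation.

The pupil is the dark disc: median filter, fixed-threshold binarisation
of dark pixels (0.1 on normalised intensity, with an optional Otsu
fallback), a 2-px square erosion/dilation pass, hole filling, and the
largest connected component; the radius is ``sqrt(area / pi)``.

The limbus (iris outer boundary) shows only a weak gradient, so it is
localised with Daugman's integro-differential operator: the centre and
radius maximising the Gaussian-smoothed radial derivative of the mean
image intensity on a circle, with the contour integral restricted to
lateral (nasal/temporal) sectors to avoid the eyelids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "PupilNotFoundError",
    "LimbusNotFoundError",
    "PupilLimbusTrace",
    "segment_pupil",
    "detect_limbus",
    "trace_sequence",
]


class PupilNotFoundError(RuntimeError):
    pass


class LimbusNotFoundError(RuntimeError):
    pass


def segment_pupil(frame: np.ndarray, threshold=0.1):
    """Locate the pupil; returns ``((cx, cy), radius)`` in pixels.

    Parameters
    ----------
    frame : ndarray
        Grayscale image with intensities normalised to [0, 1].
    threshold : float or 'otsu'
        Binarisation threshold on the median-filtered image; pixels
        darker than it are pupil candidates.

    Raises
    ------
    PupilNotFoundError
        If no dark component exists or the largest one hugs the image
        border (more than half of the border pixels dark).
    """
    frame = np.asarray(frame, dtype=float)
    med = ndimage.median_filter(frame, size=3)
    if threshold == "otsu":
        from skimage.filters import threshold_otsu

        threshold = threshold_otsu(med)
    mask = med < float(threshold)
    se = np.ones((2, 2), dtype=bool)
    mask = ndimage.binary_dilation(ndimage.binary_erosion(mask, se), se)
    mask = ndimage.binary_fill_holes(mask)
    labels, n = ndimage.label(mask)
    if n == 0:
        raise PupilNotFoundError("no pupil found: no dark component")
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    lab = int(np.argmax(sizes)) + 1
    comp = labels == lab
    border = np.concatenate([comp[0], comp[-1], comp[:, 0], comp[:, -1]])
    if border.mean() > 0.5:
        raise PupilNotFoundError("no pupil found: component touches border")
    area = float(sizes[lab - 1])
    cy, cx = ndimage.center_of_mass(comp)
    radius = float(np.sqrt(area / np.pi))
    return (float(cx), float(cy)), radius


def _daugman_response(frame, centers, radii, sigma=2.0, n_angles=96,
                      sector_half_deg=45.0, saturation=0.97):
    """|Gaussian-smoothed d/dr of circular mean intensity| for a batch of
    candidate centres.

    The contour integral is restricted to lateral (nasal/temporal)
    angular sectors to avoid the eyelids, and saturated pixels (corneal
    glints) are excluded from the arc means.  ``sigma`` is in pixels of
    radius.
    """
    half = np.deg2rad(sector_half_deg)
    ang = np.concatenate([np.linspace(-half, half, n_angles // 2),
                          np.linspace(np.pi - half, np.pi + half,
                                      n_angles // 2)])
    ca, sa = np.cos(ang), np.sin(ang)
    dr = radii[1] - radii[0]
    out = np.empty((len(centers), len(radii)))
    for k, (cx, cy) in enumerate(centers):
        xs = cx + np.outer(radii, ca)
        ys = cy + np.outer(radii, sa)
        vals = ndimage.map_coordinates(frame, [ys.ravel(), xs.ravel()],
                                       order=1, mode="nearest")
        vals = vals.reshape(len(radii), -1)
        ok = vals < saturation
        cnt = np.maximum(ok.sum(axis=1), 1)
        mean_i = np.where(ok, vals, 0.0).sum(axis=1) / cnt
        deriv = np.gradient(mean_i, radii)
        out[k] = np.abs(ndimage.gaussian_filter1d(deriv, sigma=sigma / dr))
    return out


def detect_limbus(frame: np.ndarray, center_hint, r_range, sigma: float = 2.0,
                  flatness_threshold: float = 1.5):
    """Daugman integro-differential limbus fit.

    Searches a coarse grid of centres around ``center_hint`` and radii in
    ``r_range = (r_min, r_max)``, then refines locally on a 1-px grid.
    Returns ``((cx, cy), radius)`` in pixels.

    Raises
    ------
    LimbusNotFoundError
        If the response landscape is flat (max/median < 1.5), as on a
        featureless image.
    """
    frame = np.asarray(frame, dtype=float)
    cx0, cy0 = center_hint
    r_min, r_max = r_range
    if r_max <= r_min:
        raise ValueError("empty radius range")

    def search(cx, cy, offs, radii):
        """Best (center, radius, response); candidate centres are visited
        outward from the hint, ties keeping the nearer centre."""
        cand = sorted(((dx, dy) for dy in offs for dx in offs),
                      key=lambda d: d[0] ** 2 + d[1] ** 2)
        centers = [(cx + dx, cy + dy) for dx, dy in cand]
        resp = _daugman_response(frame, centers, radii, sigma)
        best = np.max(resp, axis=1)
        k = int(np.argmax(best > (1.0 - 1e-9) * best.max()))
        j = int(np.argmax(resp[k]))
        return centers[k], float(radii[j]), resp

    # stage 0: radius scan at the hint centre (rules out the degenerate
    # off-centre/small-radius valley of lateral-arc-only integration)
    radii = np.arange(float(r_min), float(r_max) + 0.5, 1.0)
    _, r0, resp = search(cx0, cy0, [0.0], radii)
    if resp.max() < flatness_threshold * max(np.median(resp), 1e-12):
        raise LimbusNotFoundError("limbus not found: flat response")
    # stage 1: coarse joint centre/radius search near the hint
    radii = np.arange(max(r_min, r0 - 8.0), min(r_max, r0 + 8.0) + 0.5, 1.0)
    (cx, cy), r_best, _ = search(cx0, cy0, np.arange(-12, 13, 4), radii)
    # stage 2: local refinement
    radii = np.arange(max(r_min, r_best - 5.0),
                      min(r_max, r_best + 5.0) + 0.25, 0.5)
    (cx, cy), r_best, _ = search(cx, cy, np.arange(-3.0, 3.5, 1.0), radii)
    return (float(cx), float(cy)), float(r_best)


@dataclass
class PupilLimbusTrace:
    """Per-analysed-frame pupil/limbus geometry and the beta series.

    ``data`` columns: frame, t_s, xp, yp, rp_px, xl, yl, rl_px, beta,
    plus rp_mm / rl_mm when a pixel scale is known.  beta is the
    pupil-to-limbus radius ratio.
    """

    data: pd.DataFrame
    stride: int
    pixel_scale_um: float | None = None

    @property
    def beta(self) -> pd.Series:
        return self.data["beta"]

    @property
    def valid(self) -> pd.DataFrame:
        return self.data.dropna(subset=["rp_px", "rl_px"])

    def to_csv(self, path):
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, stride: int = 10, pixel_scale_um=None):
        return cls(pd.read_csv(path), stride=stride,
                   pixel_scale_um=pixel_scale_um)


def trace_sequence(seq, stride: int = 10, threshold=0.1,
                   limbus_margin_px: float = 25.0) -> PupilLimbusTrace:
    """Track pupil and limbus through every ``stride``-th frame.

    The limbus search for each frame is seeded by the previous analysed
    frame (and by the pupil centre for the first).  Per-frame failures
    are recorded as missing values and logged with their frame index.
    """
    if len(seq) == 0:
        raise ValueError("empty sequence")
    rows = []
    prev_limbus = None
    mm = getattr(seq, "pixel_scale_um", None)
    for i in range(0, len(seq), stride):
        frame = seq[i]
        row = {"frame": i, "t_s": float(seq.times[i]),
               "xp": np.nan, "yp": np.nan, "rp_px": np.nan,
               "xl": np.nan, "yl": np.nan, "rl_px": np.nan, "beta": np.nan}
        try:
            (xp, yp), rp = segment_pupil(frame, threshold)
            row.update(xp=xp, yp=yp, rp_px=rp)
            if prev_limbus is None:
                hint = (xp, yp)
                r_range = (rp + limbus_margin_px,
                           min(frame.shape) / 2.0 - 2.0)
            else:
                (hx, hy), hr = prev_limbus
                hint = (hx, hy)
                r_range = (max(hr - 6.0, rp + 5.0), hr + 6.0)
            (xl, yl), rl = detect_limbus(frame, hint, r_range)
            prev_limbus = ((xl, yl), rl)
            row.update(xl=xl, yl=yl, rl_px=rl, beta=rp / rl)
        except (PupilNotFoundError, LimbusNotFoundError) as exc:
            logger.warning("frame %d: %s", i, exc)
        rows.append(row)
    df = pd.DataFrame(rows)
    if mm is not None:
        df["rp_mm"] = df["rp_px"] * mm / 1000.0
        df["rl_mm"] = df["rl_px"] * mm / 1000.0
    return PupilLimbusTrace(data=df, stride=stride, pixel_scale_um=mm)
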