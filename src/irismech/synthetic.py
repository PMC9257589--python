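"""Synthetic NIR pupillary-light-reflex frame sequences with known kinematics.

Emulates the acquisition protocol of near-infrared pupillometry video:
a dark-adapted eye (15 s acclimation), a 5 s light stimulus driving pupil
constriction, and 10 s of darkness with partial recovery.  Frames show a
dark pupil disc inside a textured iris annulus (multiscale speckle with
radially elongated features, mimicking crypts and furrows) and a bright
sclera, optionally corrupted by sensor noise, fixed corneal glints and
eyelid occlusion.

The iris texture is advected by a closed-form kinematic map that is
*linear in the reference radius*, so the radial stretch is spatially
uniform and every Lagrangian strain component has a closed form — the
ground truth against which the tracking and DIC stages are validated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "ProtocolConfig",
    "GroundTruth",
    "FrameSequence",
    "generate_plr_timecourse",
    "kinematic_map",
    "render_sequence",
]


@dataclass(frozen=True)
class ProtocolConfig:
    """Acquisition protocol and rendering parameters.

    Defaults emulate a 30 s, 25 Hz NIR recording at 768x576 px and
    ~39 um/px: dark acclimation to 15 s, light from 15-20 s, darkness to
    30 s.  The pupil-to-limbus radius ratio beta falls from 0.566
    (dark-adapted cohort mean) to 0.262 at maximum constriction.
    """

    duration_s: float = 30.0
    frame_rate_hz: float = 25.0
    acclim_end_s: float = 15.0
    light_end_s: float = 20.0
    pixel_scale_um: float = 39.0
    image_width_px: int = 768
    image_height_px: int = 576
    limbus_radius_mm: float = 6.0
    beta_acclim: float = 0.566
    beta_min: float = 0.262
    constriction_tau_s: float = 0.5
    recovery_tau_s: float = 4.0
    noise_sd: float = 0.01
    glint_count: int = 2
    eyelid_coverage_fraction: float = 0.0
    rng_seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.beta_min < self.beta_acclim < 1.0):
            raise ValueError("require 0 < beta_min < beta_acclim < 1")
        if not (0.0 < self.acclim_end_s < self.light_end_s < self.duration_s):
            raise ValueError("require 0 < acclim_end < light_end < duration")
        limbus_px = self.limbus_radius_mm * 1000.0 / self.pixel_scale_um
        if 2.0 * limbus_px >= min(self.image_width_px, self.image_height_px):
            raise ValueError("image too small for limbus radius at this "
                             "pixel scale")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate_hz))

    @property
    def pupil_radius_acclim_mm(self) -> float:
        return self.beta_acclim * self.limbus_radius_mm

    @property
    def limbus_radius_px(self) -> float:
        return self.limbus_radius_mm * 1000.0 / self.pixel_scale_um

    @property
    def mm_per_px(self) -> float:
        return self.pixel_scale_um / 1000.0

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz

    def phase(self, t) -> np.ndarray:
        """Protocol phase label per time: 'acclim', 'light' or 'recovery'."""
        t = np.asarray(t, dtype=float)
        out = np.where(t < self.acclim_end_s, "acclim",
                       np.where(t < self.light_end_s, "light", "recovery"))
        return out if out.ndim else out.item()


def generate_plr_timecourse(cfg: ProtocolConfig, t=None) -> np.ndarray:
    """Pupil radius (mm) over the protocol.

    Constant dark-adapted radius during acclimation; exponential decay
    toward the maximum-constriction radius during the light stimulus;
    exponential recovery toward the dark-adapted radius afterwards
    (asymptotic, hence never complete within the recording).
    """
    t = cfg.times() if t is None else np.asarray(t, dtype=float)
    r0 = cfg.beta_acclim * cfg.limbus_radius_mm
    rmin = cfg.beta_min * cfg.limbus_radius_mm
    tau_c = max(cfg.constriction_tau_s, 1e-9)
    tau_r = max(cfg.recovery_tau_s, 1e-9)
    r = np.full_like(t, r0, dtype=float)
    light = t >= cfg.acclim_end_s
    r[light] = rmin + (r0 - rmin) * np.exp(-(t[light] - cfg.acclim_end_s) / tau_c)
    rec = t >= cfg.light_end_s
    r_end = rmin + (r0 - rmin) * np.exp(-(cfg.light_end_s - cfg.acclim_end_s) / tau_c)
    r[rec] = r0 - (r0 - r_end) * np.exp(-(t[rec] - cfg.light_end_s) / tau_r)
    # recovery is driven back toward r0 but cannot overshoot it
    return np.minimum(r, r0)


def kinematic_map(R, t, cfg: ProtocolConfig):
    """Deformed radius r(R, t) of the material circle at reference R (mm).

    Linear interpolation between the moving pupil margin and the fixed
    limbus:  r = r_p(t) + (R - r_p0) (r_l - r_p(t)) / (r_l - r_p0),
    which makes the radial stretch lambda_r = (r_l - r_p)/(r_l - r_p0)
    spatially uniform.
    """
    R = np.asarray(R, dtype=float)
    r_p0 = cfg.pupil_radius_acclim_mm
    r_l = cfg.limbus_radius_mm
    if np.any(R < r_p0 - 1e-9) or np.any(R > r_l + 1e-9):
        raise ValueError("reference radius outside the iris annulus")
    r_p = generate_plr_timecourse(cfg, np.atleast_1d(np.asarray(t, dtype=float)))
    r = r_p + (R - r_p0) * (r_l - r_p) / (r_l - r_p0)
    return r if np.ndim(t) or np.ndim(R) else float(r[0])


@dataclass
class GroundTruth:
    """Closed-form kinematics underlying a rendered sequence."""

    config: ProtocolConfig
    times: np.ndarray
    pupil_radius_mm: np.ndarray
    radial_map: object = None      # optional custom map r(R_mm, t)

    def radial_stretch(self, t) -> np.ndarray:
        cfg = self.config
        r_p = generate_plr_timecourse(cfg, np.asarray(t, dtype=float))
        return (cfg.limbus_radius_mm - r_p) / \
            (cfg.limbus_radius_mm - cfg.pupil_radius_acclim_mm)

    def map(self, R, t):
        if self.radial_map is not None:
            return self.radial_map(np.asarray(R, dtype=float), t)
        return kinematic_map(R, t, self.config)

    def strain_rr(self, R, t):
        """Lagrangian E_rr — spatially uniform: 0.5 (lambda_r**2 - 1)."""
        lam = self.radial_stretch(t)
        return np.broadcast_to(0.5 * (lam ** 2 - 1.0),
                               np.broadcast(np.asarray(R), lam).shape).copy()

    def strain_tt(self, R, t):
        """Lagrangian E_thth = 0.5 ((r/R)**2 - 1)."""
        r = kinematic_map(R, t, self.config)
        return 0.5 * ((r / np.asarray(R, dtype=float)) ** 2 - 1.0)

    def strain_rt(self, R, t):
        return np.zeros(np.broadcast(np.asarray(R),
                                     np.asarray(t, dtype=float)).shape)

    def displacement_px(self, x, y, t):
        """Ground-truth image-plane displacement (px) of the material point
        at reference pixel position (x, y) relative to the iris centre."""
        cfg = self.config
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        R_px = np.hypot(x, y)
        R_mm = R_px * cfg.mm_per_px
        r_mm = self.map(np.clip(R_mm, cfg.pupil_radius_acclim_mm,
                                cfg.limbus_radius_mm), t)
        scale = np.where(R_px > 0, r_mm / cfg.mm_per_px / np.maximum(R_px, 1e-12), 1.0)
        return x * (scale - 1.0), y * (scale - 1.0)


class FrameSequence:
    """Time-stamped grayscale frames with pixel scale and phase labels.

    Frames are float32 in [0, 1].  Rendered sequences are generated
    lazily per frame (deterministic in the seed) and cached; sequences
    loaded from disk hold their frames directly.
    """

    def __init__(self, times, pixel_scale_um, render=None, frames=None,
                 phases=None, metadata=None):
        self.times = np.asarray(times, dtype=float)
        self.pixel_scale_um = float(pixel_scale_um)
        self._render = render
        self._frames = list(frames) if frames is not None else None
        self._cache: dict[int, np.ndarray] = {}
        self.phases = phases
        self.metadata = metadata or {}

    def __len__(self) -> int:
        return len(self.times)

    def __getitem__(self, i: int) -> np.ndarray:
        if self._frames is not None:
            return self._frames[i]
        if i not in self._cache:
            self._cache[i] = self._render(i)
        return self._cache[i]

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]

    @property
    def frame_shape(self):
        return self[0].shape

    def save(self, directory, bit_depth: int = 8):
        """Write zero-padded numbered PNGs plus a JSON sidecar."""
        import imageio.v3 as iio

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        width = len(str(len(self) - 1))
        for i, frame in enumerate(self):
            arr = np.clip(frame, 0.0, 1.0)
            if bit_depth == 8:
                arr = (arr * 255.0 + 0.5).astype(np.uint8)
            else:
                arr = (arr * 65535.0 + 0.5).astype(np.uint16)
            iio.imwrite(directory / f"frame_{i:0{width}d}.png", arr)
        sidecar = {
            "times_s": self.times.tolist(),
            "pixel_scale_um": self.pixel_scale_um,
            "phases": list(self.phases) if self.phases is not None else None,
            **self.metadata,
        }
        (directory / "sequence.json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_directory(cls, directory, pixel_scale_um=None):
        """Load a frame directory (PNG/TIFF) with optional JSON sidecar."""
        import imageio.v3 as iio

        directory = Path(directory)
        paths = sorted(p for p in directory.iterdir()
                       if p.suffix.lower() in {".png", ".tif", ".tiff"})
        if not paths:
            raise FileNotFoundError(f"no frames in {directory}")
        frames = []
        for p in paths:
            arr = np.asarray(iio.imread(p), dtype=np.float32)
            if arr.ndim == 3:
                arr = arr.mean(axis=2)
            peak = 255.0 if arr.max() <= 255 else 65535.0
            frames.append(arr / peak)
        sidecar_path = directory / "sequence.json"
        times = np.arange(len(frames), dtype=float)
        phases = None
        meta = {}
        if sidecar_path.exists():
            meta = json.loads(sidecar_path.read_text())
            times = np.asarray(meta.pop("times_s", times), dtype=float)
            phases = meta.pop("phases", None)
            pixel_scale_um = pixel_scale_um or meta.get("pixel_scale_um")
        return cls(times=times, pixel_scale_um=pixel_scale_um or 39.0,
                   frames=frames, phases=phases, metadata=meta)


def _polar_texture(cfg: ProtocolConfig, rng: np.random.Generator,
                   n_r: int = 384, n_theta: int = 1024):
    """Speckle texture on a polar (R, theta) lookup grid.

    Sum of band-passed seeded noise octaves with feature sizes fixed in
    physical units (mm radially, mm of arc circumferentially at the iris
    mid-radius) and elongated along R, mimicking the radial crypts and
    furrows that make the iris matchable for subset correlation.
    """
    r_p0 = cfg.pupil_radius_acclim_mm
    r_l = cfg.limbus_radius_mm
    d_r = (r_l - r_p0) / n_r                       # mm per radial bin
    d_arc = np.pi * (r_p0 + r_l) / n_theta         # mm of arc per theta bin
    tex = np.zeros((n_r, n_theta))
    # (radial size mm, circumferential size mm, amplitude); mild radial
    # elongation mimicking crypts/furrows without starving the subsets of
    # circumferential gradient content
    for sig_r, sig_arc, amp in [(0.12, 0.08, 1.0), (0.3, 0.2, 0.8),
                                (0.7, 0.45, 0.6)]:
        layer = rng.standard_normal((n_r, n_theta))
        layer = ndimage.gaussian_filter(layer, (sig_r / d_r, sig_arc / d_arc),
                                        mode="wrap")
        tex += amp * layer / max(layer.std(), 1e-12)
    tex /= tex.std()
    return np.clip(0.5 + 0.18 * tex, 0.02, 0.98)


def render_sequence(cfg: ProtocolConfig, radial_map=None):
    """Render the full protocol; returns (FrameSequence, GroundTruth).

    Deterministic in ``cfg.rng_seed``: the texture and glint geometry use
    one seeded stream, per-frame sensor noise uses a stream derived from
    (seed, frame index), so any frame can be rendered independently.

    ``radial_map(R_mm, t) -> r_mm`` optionally replaces the built-in
    linear kinematic map with an arbitrary monotone radial deformation
    (e.g. the equilibrium field of the annulus model), letting the
    tracking stages be validated against externally supplied kinematics.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    tex = _polar_texture(cfg, rng)
    tex_coeffs = ndimage.spline_filter(tex, order=3, mode="wrap")
    n_r, n_theta = tex.shape
    h, w = cfg.image_height_px, cfg.image_width_px
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    rho_px = np.hypot(xx - cx, yy - cy)
    theta = np.arctan2(yy - cy, xx - cx)
    rho_mm = rho_px * cfg.mm_per_px

    r_l = cfg.limbus_radius_mm
    r_p0 = cfg.pupil_radius_acclim_mm
    times = cfg.times()
    if radial_map is None:
        r_p_series = generate_plr_timecourse(cfg)
    else:
        r_p_series = np.array([float(radial_map(np.array([r_p0]), t)[0])
                               for t in times])
    R_grid = np.linspace(r_p0, r_l, 512)

    # glints: saturated discs fixed in image coordinates over the iris
    glints = []
    for _ in range(cfg.glint_count):
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0.55, 0.8) * r_l / cfg.mm_per_px
        glints.append((cx + rad * np.cos(ang), cy + rad * np.sin(ang),
                       rng.uniform(2.5, 4.5)))

    edge_px = 1.0  # smoothing width of intensity transitions, px

    def smoothstep(x):
        x = np.clip(x, 0.0, 1.0)
        return x * x * (3.0 - 2.0 * x)

    def render(i: int) -> np.ndarray:
        r_p = r_p_series[i]
        # inverse map: reference radius of the material point now at
        # deformed radius rho (linear map -> linear inverse; custom maps
        # are inverted by monotone interpolation on a radial grid)
        if radial_map is None:
            lam = (r_l - r_p) / (r_l - r_p0)
            R_mm = r_p0 + (rho_mm - r_p) / lam
        else:
            r_grid = np.asarray(radial_map(R_grid, times[i]), dtype=float)
            R_mm = np.interp(rho_mm, r_grid, R_grid,
                             left=r_p0 - 1.0, right=r_l)
        R_clip = np.clip(R_mm, r_p0, r_l)
        ri = (R_clip - r_p0) / (r_l - r_p0) * (n_r - 1)
        ti = (theta % (2 * np.pi)) / (2 * np.pi) * n_theta
        iris = ndimage.map_coordinates(tex_coeffs, [ri.ravel(), ti.ravel()],
                                       order=3, prefilter=False,
                                       mode="wrap").reshape(h, w)
        w_pupil = smoothstep((rho_mm - r_p) / (edge_px * cfg.mm_per_px) + 0.5)
        w_sclera = smoothstep((rho_mm - r_l) / (edge_px * cfg.mm_per_px) + 0.5)
        img = 0.05 * (1 - w_pupil) + iris * w_pupil * (1 - w_sclera) \
            + 0.85 * w_sclera
        for gx, gy, gr in glints:
            d = np.hypot(xx - gx, yy - gy)
            img = np.maximum(img, smoothstep((gr - d) / 1.0 + 0.5))
        if cfg.eyelid_coverage_fraction > 0:
            band = cfg.eyelid_coverage_fraction * h
            wlid = smoothstep((band - yy) / 2.0 + 0.5)
            img = img * (1 - wlid) + 0.6 * wlid
        if cfg.noise_sd > 0:
            frame_rng = np.random.default_rng([cfg.rng_seed, 1000 + i])
            img = img + frame_rng.normal(0.0, cfg.noise_sd, img.shape)
        return np.clip(img, 0.0, 1.0).astype(np.float32)

    seq = FrameSequence(times=times, pixel_scale_um=cfg.pixel_scale_um,
                        render=render, phases=cfg.phase(times),
                        metadata={"rng_seed": cfg.rng_seed,
                                  "config": asdict(cfg),
                                  "pupil_radius_mm": r_p_series.tolist()})
    gt = GroundTruth(config=cfg, times=times, pupil_radius_mm=r_p_series,
                     radial_map=radial_map)
    return seq, gt
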