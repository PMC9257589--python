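"""Shared fixtures: scaled-down synthetic sequences and cached fits.

Rendering and correlation fixtures use half-resolution geometry
(384x288 px at 78 um/px) so the whole suite runs in minutes; the
physics (protocol phases, beta series, kinematic map) is unchanged.
"""

import numpy as np
import pytest

from irismech.synthetic import ProtocolConfig, render_sequence


def half_scale_config(**overrides) -> ProtocolConfig:
    base = dict(image_width_px=384, image_height_px=288,
                pixel_scale_um=78.0, duration_s=21.0,
                noise_sd=0.0, glint_count=0, constriction_tau_s=1.5)
    base.update(overrides)
    return ProtocolConfig(**base)


@pytest.fixture(scope="session")
def contraction():
    """Clean moderate-contraction sequence with ground truth.

    beta falls 0.566 -> 0.40: large enough to exercise finite strain
    (E_rr ~ 0.4) while every DIC increment stays well inside the search
    range.
    """
    cfg = half_scale_config(beta_min=0.40)
    seq, gt = render_sequence(cfg)
    c = {"cx": (cfg.image_width_px - 1) / 2.0,
         "cy": (cfg.image_height_px - 1) / 2.0,
         "rl_px": cfg.limbus_radius_px,
         "rp0_px": cfg.pupil_radius_acclim_mm / cfg.mm_per_px}
    return cfg, seq, gt, c


@pytest.fixture(scope="session")
def dic_run(contraction):
    """Incremental DIC through the constriction phase of `contraction`."""
    from irismech.dic import correlate_incremental

    cfg, seq, gt, geo = contraction
    subset = 17
    yy, xx = np.mgrid[0:cfg.image_height_px, 0:cfg.image_width_px]
    rad = np.hypot(xx - geo["cx"], yy - geo["cy"])
    roi = (rad > geo["rp0_px"] + subset // 2) & \
        (rad < geo["rl_px"] - subset // 2)
    start = int(np.searchsorted(seq.times, cfg.acclim_end_s))
    idxs = [i for i in range(start, len(seq), 10) if seq.times[i] <= 20.4]
    frames = [seq[i] for i in idxs]
    field = correlate_incremental(frames, roi, subset=subset, step=4,
                                  search=10)
    return field, idxs, roi


@pytest.fixture(scope="session")
def traced():
    """Noisy full-constriction sequence and its pupil/limbus trace."""
    from irismech.segmentation import trace_sequence

    cfg = half_scale_config(noise_sd=0.01, glint_count=2,
                            constriction_tau_s=0.5, rng_seed=7)
    seq, gt = render_sequence(cfg)
    trace = trace_sequence(seq, stride=10)
    return cfg, seq, gt, trace


@pytest.fixture(scope="session")
def clean_trace(contraction):
    """Pupil/limbus trace of the noise-free contraction sequence."""
    from irismech.segmentation import trace_sequence

    _, seq, _, _ = contraction
    return trace_sequence(seq, stride=10)


@pytest.fixture(scope="session")
def fit_1mm():
    """Multi-start identification at the baseline 1 mm sphincter width."""
    from irismech.inverse import fit_single

    return fit_single(-0.386, sphincter_width=1.0, n_starts=25)


@pytest.fixture(scope="session")
def sweep_result():
    """Full multi-start width sweep against the cohort target strain."""
    import time

    from irismech.inverse import width_sweep

    t0 = time.time()
    df = width_sweep(-0.386, widths=(0.4, 0.7, 1.0, 1.3),
                     method="multistart", n_starts=25)
    return df, time.time() - t0
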