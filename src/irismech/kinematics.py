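"""Margin strains, quality control and cohort summary statistics.

The Lagrangian strain of a circular margin (pupil or limbus) follows
from its radius relative to the dark-adapted reference:

    eps_i = 0.5 [ (r_i / rbar_i0)^2 - 1 ],

where ``rbar_i0`` averages ``r_i`` over the acclimation phase.  The
maximum-constriction pupil strain is the mean of ``eps_p`` over the
17-20 s window of the protocol.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StrainTrace",
    "margin_strain",
    "lagrangian_strain",
    "radius_ratio",
    "qc_outliers",
    "summarize",
]


def lagrangian_strain(r, r0):
    """eps = 0.5 [(r/r0)^2 - 1]."""
    return 0.5 * ((np.asarray(r, dtype=float) / r0) ** 2 - 1.0)


def radius_ratio(eps):
    """Inverse of :func:`lagrangian_strain`: r/r0 = sqrt(1 + 2 eps)."""
    return np.sqrt(1.0 + 2.0 * np.asarray(eps, dtype=float))


@dataclass
class StrainTrace:
    """Pupil- and limbus-margin strain series for one scan."""

    data: pd.DataFrame               # t_s, eps_p, eps_l
    pupil_radius_ref: float          # rbar_p0 (same units as the trace)
    limbus_radius_ref: float         # rbar_l0
    max_constriction_strain: float   # mean eps_p over the 17-20 s window
    qc_pass: bool = True

    @property
    def eps_p(self) -> pd.Series:
        return self.data["eps_p"]

    @property
    def eps_l(self) -> pd.Series:
        return self.data["eps_l"]

    def to_csv(self, path):
        self.data.to_csv(path, index=False)


def margin_strain(trace, acclim_window=(0.0, 15.0),
                  constriction_window=(17.0, 20.0)) -> StrainTrace:
    """Strain series from a :class:`~irismech.segmentation.PupilLimbusTrace`.

    Reference radii are the means over the acclimation window; the
    maximum-constriction strain averages the pupil strain over the
    constriction window (NaN if no analysed frame falls inside it).
    """
    df = trace.data
    acc = df[(df["t_s"] >= acclim_window[0]) & (df["t_s"] < acclim_window[1])]
    acc = acc.dropna(subset=["rp_px", "rl_px"])
    if len(acc) < 2:
        raise ValueError("no reference state: fewer than 2 valid frames "
                         "in the acclimation window")
    rp0 = float(acc["rp_px"].mean())
    rl0 = float(acc["rl_px"].mean())
    out = pd.DataFrame({
        "t_s": df["t_s"],
        "eps_p": lagrangian_strain(df["rp_px"], rp0),
        "eps_l": lagrangian_strain(df["rl_px"], rl0),
    })
    win = out[(out["t_s"] >= constriction_window[0])
              & (out["t_s"] <= constriction_window[1])]
    eps_max = float(win["eps_p"].mean())
    return StrainTrace(data=out, pupil_radius_ref=rp0, limbus_radius_ref=rl0,
                       max_constriction_strain=eps_max)


def qc_outliers(values, n_sd: float = 3.0):
    """Single-pass mean +/- ``n_sd``-sd screen; returns (kept, excluded)
    integer index arrays.  With fewer than 3 values nothing is excluded."""
    values = np.asarray(values, dtype=float)
    idx = np.arange(len(values))
    if len(values) < 3:
        warnings.warn("fewer than 3 values: outlier screen skipped")
        return idx, np.array([], dtype=int)
    mean = values.mean()
    sd = values.std(ddof=0)
    bad = np.abs(values - mean) > n_sd * sd if sd > 0 \
        else np.zeros(len(values), dtype=bool)
    return idx[~bad], idx[bad]


def summarize(values, eye=None, scan=None, z: float = 1.96) -> pd.DataFrame:
    """Cohort statistics with test-retest averaging per eye.

    ``values`` are per-scan maximum-constriction strains; ``eye`` labels
    group test-retest scans of the same eye, which are averaged before
    cohort statistics.  Returns a one-row DataFrame with mean, sd, n and
    the normal-theory 95% CI (``mean +/- z sd / sqrt(n)``).
    """
    df = pd.DataFrame({"value": np.asarray(values, dtype=float)})
    df["eye"] = eye if eye is not None else np.arange(len(df))
    df["scan"] = scan if scan is not None else 0
    empty = df.groupby("eye")["value"].count() == 0
    if empty.any():
        warnings.warn("empty groups omitted")
    per_eye = df.groupby("eye")["value"].mean().dropna()
    n = len(per_eye)
    mean = float(per_eye.mean())
    sd = float(per_eye.std(ddof=1)) if n > 1 else 0.0
    half = z * sd / np.sqrt(n) if n > 0 else np.nan
    return pd.DataFrame([{
        "mean": mean, "sd": sd, "n_eyes": n,
        "ci_low": mean - half, "ci_high": mean + half,
    }])
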