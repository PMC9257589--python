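"""Finite-strain mechanical model of the iris annulus.

The iris is idealised as a thin annular disc of compressible neo-Hookean
stroma under plane stress, loaded by an active circumferential (hoop)
Cauchy stress of magnitude ``T_s`` carried by the sphincter muscle, a ring
of width ``a_s`` adjacent to the pupillary margin.  With axisymmetric
geometry, loading and boundary conditions the problem reduces to a 1D
two-point boundary-value problem for the deformed radius ``r(R)`` of each
material circle of reference radius ``R``:

    d(sigma_rr)/dr + (sigma_rr - sigma_tt)/r = 0,   R_in <= R <= R_out,

with a traction-free inner edge (``sigma_rr = 0`` at the pupil margin) and
a fixed outer edge (``r(R_out) = R_out``; the limbus is observed not to
move).  The through-thickness stretch ``lambda_z`` is eliminated pointwise
by the plane-stress condition ``sigma_zz = 0``.  Equilibrium is enforced
in the membrane (thin-limit) form, i.e. on the thickness-weighted stress
resultants ``N = lambda_z * sigma``, which is the consistent reduction of
a thin three-dimensional disc whose thickness changes with deformation.

The active muscle stress is the push-forward of a referential fiber
stress ``T_s M ⊗ M`` along the circumferential direction, giving a Cauchy
contribution ``(T_s/J) * lambda_theta**p * e_theta ⊗ e_theta`` with
``p = 2`` (the convention of standard active-contraction implementations
in soft-tissue FE codes).  ``p`` is configurable via
``active_stretch_power``; ``p = 0`` corresponds to prescribing the Cauchy
stress magnitude directly.

The solver is a 1D Galerkin finite-element scheme (linear elements, 2-point
Gauss quadrature) with Newton iteration and incremental load stepping in
the active traction.  Because the passive stress scales with the stromal
modulus ``E`` and the active stress with ``T_s``, the equilibrium
deformation depends on the two only through the ratio ``T_s/E`` — the
property that makes the ratio identifiable from pupil strain alone.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import solve_banded

__all__ = [
    "IrisModelConfig",
    "FESolution",
    "SolverError",
    "cauchy_stress",
    "plane_stress_lambda_z",
    "solve_iris",
    "strain_profiles",
]


class SolverError(RuntimeError):
    """Raised when the Newton/load-stepping scheme fails to converge."""

    def __init__(self, message: str, load_fraction: float = 0.0):
        super().__init__(message)
        self.load_fraction = load_fraction


@dataclass(frozen=True)
class IrisModelConfig:
    """Geometry, material and discretisation parameters of the iris model.

    Parameters
    ----------
    R_in, R_out : float
        Reference pupillary and limbal radii in mm.  Defaults follow the
        dark-adapted human iris: pupil 3.4 mm, limbus 6 mm.
    thickness : float
        Disc thickness in mm (informational; it cancels from the
        plane-stress equilibrium).
    sphincter_width : float
        Width ``a_s`` (mm) of the active muscle ring, fixed in the
        reference configuration: ``R in [R_in, R_in + a_s]``.
    youngs_modulus, poisson_ratio : float
        Stromal neo-Hookean parameters ``E`` (kPa) and ``nu``.
    traction : float
        Active sphincter traction magnitude ``T_s`` (kPa); enters the
        Cauchy stress as ``T_s/J`` on the hoop component.
    n_elements : int
        Number of linear elements across the annulus.
    load_steps : int
        Number of equal increments used to ramp ``T_s`` from zero.
    newton_tol : float
        Convergence tolerance on the residual norm (scaled by ``E``).
    """

    R_in: float = 3.4
    R_out: float = 6.0
    thickness: float = 0.17
    sphincter_width: float = 1.0
    youngs_modulus: float = 1.0
    poisson_ratio: float = 0.49
    traction: float = 0.0
    n_elements: int = 100
    load_steps: int = 10
    newton_tol: float = 1e-9
    max_newton_iter: int = 40
    active_stretch_power: float = 2.0

    def __post_init__(self):
        if not (0 < self.R_in < self.R_out):
            raise ValueError("require 0 < R_in < R_out")
        if not (0 < self.sphincter_width <= self.R_out - self.R_in):
            raise ValueError("sphincter_width must lie in (0, R_out - R_in]")
        if not (0 < self.poisson_ratio < 0.5):
            raise ValueError("poisson_ratio must lie in (0, 0.5)")
        if self.youngs_modulus <= 0:
            raise ValueError("youngs_modulus must be positive")
        if self.traction < 0:
            raise ValueError("traction must be non-negative")
        if self.n_elements < 4:
            raise ValueError("need at least 4 elements")

    @property
    def mu(self) -> float:
        """Shear modulus E / (2 (1 + nu))."""
        return self.youngs_modulus / (2.0 * (1.0 + self.poisson_ratio))

    @property
    def lame_lambda(self) -> float:
        """First Lame parameter E nu / ((1 + nu)(1 - 2 nu))."""
        nu = self.poisson_ratio
        return self.youngs_modulus * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))


def plane_stress_lambda_z(lam_r, lam_t, mu: float, lame_lambda: float,
                          lam_z0=None, tol: float = 1e-12,
                          max_iter: int = 60):
    """Through-thickness stretch enforcing ``sigma_zz = 0`` pointwise.

    Solves ``mu (lam_z**2 - 1) + lame_lambda * ln(lam_r lam_t lam_z) = 0``
    by Newton iteration (the left side is strictly increasing in lam_z, so
    the root is unique).  Vectorised over arrays of stretches.
    """
    lam_r = np.asarray(lam_r, dtype=float)
    lam_t = np.asarray(lam_t, dtype=float)
    if np.any(lam_r <= 0) or np.any(lam_t <= 0):
        raise ValueError("stretches must be positive")
    lz = np.full(np.broadcast(lam_r, lam_t).shape, 1.0) if lam_z0 is None \
        else np.array(lam_z0, dtype=float, copy=True)
    lnA = np.log(lam_r * lam_t)
    for _ in range(max_iter):
        f = mu * (lz ** 2 - 1.0) + lame_lambda * (lnA + np.log(lz))
        fp = 2.0 * mu * lz + lame_lambda / lz
        step = f / fp
        # keep lam_z positive
        lz = np.maximum(lz - step, 0.2 * lz)
        if np.all(np.abs(step) < tol * np.maximum(lz, 1.0)):
            break
    return lz


def cauchy_stress(lam_r, lam_t, lam_z, E: float, nu: float, active=0.0):
    """Principal Cauchy stresses of the compressible neo-Hookean stroma.

    Passive part ``sigma_i = (mu/J)(lam_i**2 - 1) + (lame_lambda/J) ln J``
    derived from the energy
    ``Psi = mu [ (I1 - 3)/2 - ln J ] + (lame_lambda/2) (ln J)^2``;
    the active sphincter traction adds ``active / J`` to the hoop
    component only.

    Returns ``(sigma_rr, sigma_tt, sigma_zz)`` in the units of ``E``.
    """
    lam_r, lam_t, lam_z = (np.asarray(a, dtype=float) for a in (lam_r, lam_t, lam_z))
    if np.any(lam_r <= 0) or np.any(lam_t <= 0) or np.any(lam_z <= 0):
        raise ValueError("stretches must be positive")
    mu = E / (2.0 * (1.0 + nu))
    lam_L = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    J = lam_r * lam_t * lam_z
    lnJ = np.log(J)
    srr = (mu * (lam_r ** 2 - 1.0) + lam_L * lnJ) / J
    stt = (mu * (lam_t ** 2 - 1.0) + lam_L * lnJ + np.asarray(active)) / J
    szz = (mu * (lam_z ** 2 - 1.0) + lam_L * lnJ) / J
    return srr, stt, szz


@dataclass
class FESolution:
    """Converged equilibrium state of the iris annulus.

    Attributes
    ----------
    R, r : ndarray
        Nodal reference and deformed radii (mm).
    lam_r, lam_t, lam_z, J : ndarray
        Nodal stretches and volume ratio (lam_r is the element value
        averaged to nodes — linear elements carry a piecewise-constant
        radial stretch).
    strain_energy : ndarray
        Nodal Helmholtz free-energy density (kPa).
    pupil_strain : float
        Lagrangian hoop strain of the pupillary margin,
        ``0.5 (lam_t(R_in)**2 - 1)``.
    """

    config: IrisModelConfig
    R: np.ndarray
    r: np.ndarray
    lam_r: np.ndarray
    lam_t: np.ndarray
    lam_z: np.ndarray
    J: np.ndarray
    strain_energy: np.ndarray
    pupil_strain: float
    newton_iterations: int = 0
    load_fraction: float = 1.0

    @property
    def x_bar(self) -> np.ndarray:
        """Normalised radial coordinate: 0 at pupil margin, 1 at limbus."""
        cfg = self.config
        return (self.R - cfg.R_in) / (cfg.R_out - cfg.R_in)

    @property
    def E_rr(self) -> np.ndarray:
        return 0.5 * (self.lam_r ** 2 - 1.0)

    @property
    def E_tt(self) -> np.ndarray:
        return 0.5 * (self.lam_t ** 2 - 1.0)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "R_mm": self.R, "r_mm": self.r, "x_bar": self.x_bar,
            "lam_r": self.lam_r, "lam_t": self.lam_t, "lam_z": self.lam_z,
            "J": self.J, "E_rr": self.E_rr, "E_tt": self.E_tt,
        })


_GAUSS_XI = np.array([-1.0, 1.0]) / np.sqrt(3.0)
_GAUSS_W = np.array([1.0, 1.0])


def _element_residual(r1, r2, R1, R2, cfg: IrisModelConfig, traction: float):
    """Galerkin residual contributions (per element) of the weak form

    ``int [ sigma_rr * r * dN/dR + sigma_tt * lam_r * N ] dR``.

    Vectorised over elements; returns (F1, F2) or None when the trial
    deformation is inadmissible (non-positive stretch).
    """
    h = R2 - R1
    lam_r = (r2 - r1) / h
    if np.any(lam_r <= 0):
        return None
    mu, lam_L = cfg.mu, cfg.lame_lambda
    F1 = np.zeros_like(r1)
    F2 = np.zeros_like(r1)
    for xi, w in zip(_GAUSS_XI, _GAUSS_W):
        N1 = 0.5 * (1.0 - xi)
        N2 = 0.5 * (1.0 + xi)
        Rg = N1 * R1 + N2 * R2
        rg = N1 * r1 + N2 * r2
        if np.any(rg <= 0):
            return None
        lam_t = rg / Rg
        lam_z = plane_stress_lambda_z(lam_r, lam_t, mu, lam_L)
        active = np.where(Rg <= cfg.R_in + cfg.sphincter_width, traction, 0.0)
        if cfg.active_stretch_power:
            active = active * lam_t ** cfg.active_stretch_power
        srr, stt, _ = cauchy_stress(lam_r, lam_t, lam_z,
                                    cfg.youngs_modulus, cfg.poisson_ratio,
                                    active=active)
        # membrane (thin-limit) equilibrium: stress resultants carry the
        # deformed thickness factor lam_z
        Nrr = lam_z * srr
        Ntt = lam_z * stt
        wh = w * 0.5 * h
        F1 += wh * (Nrr * rg * (-1.0 / h) + Ntt * lam_r * N1)
        F2 += wh * (Nrr * rg * (+1.0 / h) + Ntt * lam_r * N2)
    return F1, F2


def _assemble(r, R, cfg, traction):
    """Global residual and tridiagonal Jacobian (FD at element level).

    The last node is constrained (r = R_out) and excluded from the system.
    Returns (residual, banded_jacobian) or None if inadmissible.
    """
    n = len(R)
    r1, r2 = r[:-1], r[1:]
    R1, R2 = R[:-1], R[1:]
    base = _element_residual(r1, r2, R1, R2, cfg, traction)
    if base is None:
        return None
    eps = 1e-7 * cfg.R_out
    p1 = _element_residual(r1 + eps, r2, R1, R2, cfg, traction)
    p2 = _element_residual(r1, r2 + eps, R1, R2, cfg, traction)
    if p1 is None or p2 is None:
        return None
    F1, F2 = base
    d11 = (p1[0] - F1) / eps
    d21 = (p1[1] - F2) / eps
    d12 = (p2[0] - F1) / eps
    d22 = (p2[1] - F2) / eps

    free = n - 1  # nodes 0 .. n-2 are unknowns
    res = np.zeros(free)
    np.add.at(res, np.arange(n - 1), F1)
    np.add.at(res, np.arange(1, n)[:-1], F2[:-1])  # last element's F2 -> fixed node
    # banded (1 super, 1 sub) Jacobian in solve_banded layout
    ab = np.zeros((3, free))
    diag = np.zeros(free)
    np.add.at(diag, np.arange(n - 1), d11)
    np.add.at(diag, np.arange(1, n)[:-1], d22[:-1])
    ab[1, :] = diag
    ab[0, 1:] = d12[: free - 1]   # super-diagonal J[i, i+1]
    ab[2, : free - 1] = d21[: free - 1]  # sub-diagonal J[i+1, i]
    return res, ab


def _newton_solve(r, R, cfg, traction):
    """Newton iteration at fixed traction; returns (r, iterations) or None."""
    scale = cfg.youngs_modulus * cfg.R_out
    for it in range(cfg.max_newton_iter):
        out = _assemble(r, R, cfg, traction)
        if out is None:
            return None
        res, ab = out
        norm = np.linalg.norm(res) / scale
        if norm < cfg.newton_tol:
            return r, it
        try:
            step = solve_banded((1, 1), ab, -res)
        except np.linalg.LinAlgError:
            return None
        # damped update with positivity guard on the trial state
        alpha = 1.0
        for _ in range(25):
            trial = r.copy()
            trial[:-1] += alpha * step
            if np.all(np.diff(trial) > 0) and trial[0] > 0:
                break
            alpha *= 0.5
        else:
            return None
        r = trial
    return None


def _mesh(cfg: IrisModelConfig) -> np.ndarray:
    """Nodal reference radii with a node placed exactly at the sphincter
    outer edge (removes the discretisation wobble of the active-region
    boundary cutting through an element)."""
    edge = cfg.R_in + cfg.sphincter_width
    if edge >= cfg.R_out - 1e-12:
        return np.linspace(cfg.R_in, cfg.R_out, cfg.n_elements + 1)
    frac = cfg.sphincter_width / (cfg.R_out - cfg.R_in)
    n_ring = min(max(int(round(cfg.n_elements * frac)), 4), cfg.n_elements - 4)
    n_out = cfg.n_elements - n_ring
    return np.concatenate([
        np.linspace(cfg.R_in, edge, n_ring + 1),
        np.linspace(edge, cfg.R_out, n_out + 1)[1:],
    ])


def solve_iris(cfg: IrisModelConfig, warm_start=None) -> FESolution:
    """Solve the axisymmetric plane-stress equilibrium of the iris annulus.

    Ramps the active traction in ``cfg.load_steps`` increments with
    adaptive step halving on Newton divergence.  ``warm_start`` may be a
    previous :class:`FESolution` on the same mesh (e.g. from a nearby
    parameter set); Newton is then attempted directly at full load and
    the ramp is used only as a fallback.  Raises :class:`SolverError`
    (carrying the last converged load fraction) if the full load cannot
    be reached.
    """
    R = _mesh(cfg)
    r = R.copy()
    total_iters = 0
    loaded = 0.0
    if warm_start is not None and warm_start.r.shape == R.shape \
            and np.allclose(warm_start.R, R):
        out = _newton_solve(warm_start.r.copy(), R, cfg, cfg.traction)
        if out is not None:
            r, total_iters = out
            return _finalize(cfg, R, r, total_iters)
    if cfg.traction > 0:
        dstep = 1.0 / cfg.load_steps
        min_step = dstep / 1024.0
        while loaded < 1.0 - 1e-12:
            target = min(1.0, loaded + dstep)
            out = _newton_solve(r.copy(), R, cfg, target * cfg.traction)
            if out is None:
                dstep *= 0.5
                if dstep < min_step:
                    raise SolverError(
                        f"solver failed at load fraction {loaded:.4f}",
                        load_fraction=loaded)
                continue
            r, it = out
            total_iters += it
            loaded = target
    else:
        out = _newton_solve(r, R, cfg, 0.0)
        if out is None:
            raise SolverError("solver failed at zero load")
        r, total_iters = out
        loaded = 1.0
    return _finalize(cfg, R, r, total_iters, loaded)


def _finalize(cfg, R, r, total_iters, loaded=1.0):
    lam_r_elem = np.diff(r) / np.diff(R)
    lam_r = np.empty_like(R)
    lam_r[1:-1] = 0.5 * (lam_r_elem[:-1] + lam_r_elem[1:])
    lam_r[0] = lam_r_elem[0]
    lam_r[-1] = lam_r_elem[-1]
    lam_t = r / R
    lam_z = plane_stress_lambda_z(lam_r, lam_t, cfg.mu, cfg.lame_lambda)
    J = lam_r * lam_t * lam_z
    I1 = lam_r ** 2 + lam_t ** 2 + lam_z ** 2
    lnJ = np.log(J)
    psi = cfg.mu * (0.5 * (I1 - 3.0) - lnJ) + 0.5 * cfg.lame_lambda * lnJ ** 2
    pupil_strain = 0.5 * (lam_t[0] ** 2 - 1.0)
    return FESolution(config=cfg, R=R, r=r, lam_r=lam_r, lam_t=lam_t,
                      lam_z=lam_z, J=J, strain_energy=psi,
                      pupil_strain=pupil_strain,
                      newton_iterations=total_iters, load_fraction=loaded)


def strain_profiles(sol: FESolution):
    """Model Lagrangian strain profiles versus normalised position.

    Returns a DataFrame with columns ``x_bar, E_rr, E_tt, E_rt`` (the
    shear component is identically zero by axisymmetry) plus the location
    of peak radial strain, which sits at the outer edge of the sphincter
    ring.
    """
    import pandas as pd

    df = pd.DataFrame({
        "x_bar": sol.x_bar,
        "E_rr": sol.E_rr,
        "E_tt": sol.E_tt,
        "E_rt": np.zeros_like(sol.R),
    })
    df.attrs["peak_E_rr_x_bar"] = float(df["x_bar"][int(np.argmax(df["E_rr"]))])
    return df


def pupil_strain_for_ratio(ratio: float, cfg: IrisModelConfig | None = None,
                           **overrides) -> float:
    """Pupil-margin strain at traction-to-stiffness ratio ``T_s/E``.

    Convenience wrapper exploiting scale invariance: solves with E = 1 kPa
    and T_s = ratio.
    """
    cfg = cfg or IrisModelConfig()
    cfg = replace(cfg, youngs_modulus=1.0, traction=float(ratio), **overrides)
    return solve_iris(cfg).pupil_strain
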