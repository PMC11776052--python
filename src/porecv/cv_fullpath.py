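"""The Full-Path collective variable for membrane pore formation.

The joint CV blends two regimes of pore formation with a complementary pair of
switching functions:

    CV = s1(x) * CV_cyl + s2(x) * CV_radius,        s1 + s2 = 1

* ``CV_cyl = 1 - d / CV_eq`` measures the hydrophilic membrane *defect*: d is a
  smooth count of lipid-tail beads inside a virtual cylinder of radius R_cyl
  spanning the box along the membrane normal, and CV_eq is the same count in an
  equilibrated intact bilayer.  CV_cyl is 0 for the intact membrane and
  approaches 1 (its upper limit) as the cylinder empties.
* ``CV_radius = r_min / r_unit`` measures pore *expansion*: r_min is a smooth
  underestimating minimum (a converging exponential sum) of the xy distances
  from the pore centre to the lipid-tail beads, made dimensionless with
  r_unit = 1 nm.

The switching pair is a logistic sigmoid in CV_radius: below the threshold CV0
the defect term dominates, above it the CV equals the dimensionless pore
radius.  All pieces are continuously differentiable and the exact analytic
per-particle gradient is returned alongside the value; the gradient is zero
for head and water particles by construction (only tail beads enter either
component).

The pore centre is the geometric box xy-centre.  Configurations in which the
membrane has drifted should be passed through
:func:`porecv.membranes.recenter_lipids` first.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
from scipy.special import expit, logsumexp

from .membranes import ParticleConfiguration

__all__ = [
    "CVParams",
    "CVValue",
    "CalibrationResult",
    "switching_pair",
    "rational_switch",
    "cylinder_soft_count",
    "cv_cyl",
    "calibrate_cv_eq",
    "soft_min_radius",
    "fullpath_cv",
]


@dataclass
class CVParams:
    """Parameters of the Full-Path CV.

    r_cyl          virtual cylinder radius, nm
    cv_eq          equilibrium soft count inside the cylinder (set by
                   :func:`calibrate_cv_eq`)
    cv0            switching threshold; must lie in (0.5, 1) so that the
                   defect can fully develop before the radius takes over
    alpha          switching rate
    r_unit         radius scale making CV_radius dimensionless, nm
    softmin_beta   sharpness of the converging-sum soft minimum
    boundary_exponents  (n, m) of the rational membership function
                   (1 - (rho/R)^n) / (1 - (rho/R)^m)
    softmin_floor  smallest distance fed to the soft minimum, nm
    """

    r_cyl: float = 1.2
    cv_eq: Optional[float] = None
    cv0: float = 0.95
    alpha: float = 20.0
    r_unit: float = 1.0
    softmin_beta: float = 200.0
    boundary_exponents: Tuple[int, int] = (6, 12)
    softmin_floor: float = 1e-3

    def __post_init__(self) -> None:
        if not (0.5 < self.cv0 < 1.0):
            raise ValueError("cv0 must lie strictly between 0.5 and 1")
        if self.alpha <= 0 or self.r_cyl <= 0 or self.r_unit <= 0:
            raise ValueError("alpha, r_cyl and r_unit must be positive")
        if self.softmin_beta <= 0 or self.softmin_floor <= 0:
            raise ValueError("softmin_beta and softmin_floor must be positive")
        n, m = self.boundary_exponents
        if n <= 0 or m <= n:
            raise ValueError("boundary exponents require 0 < n < m")
        if self.cv_eq is not None and self.cv_eq <= 0:
            raise ValueError("cv_eq must be positive")


@dataclass
class CVValue:
    """Joint CV with components and the exact per-particle gradient (1/nm)."""

    value: float
    cv_cyl: float
    cv_radius: float
    s1: float
    s2: float
    gradient: np.ndarray  # (N, 3)


@dataclass
class CalibrationResult:
    """CV_eq calibration summary over intact-bilayer frames."""

    cv_eq: float
    n_frames: int
    std: float


def switching_pair(x, cv0: float, alpha: float):
    """Complementary logistic switching functions (s1, s2).

    s1 = 1 / (1 + exp(alpha * (x - cv0))) decreases from 1 to 0, s2 = 1 - s1
    increases; they intersect at x = cv0 where both equal 1/2, and alpha sets
    the transition rate.  Vectorised and overflow-safe.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    s1 = expit(-alpha * (np.asarray(x, dtype=float) - cv0))
    return s1, 1.0 - s1


def rational_switch(x, n: int, m: int):
    """Smoothly decaying rational membership w(x) = (1 - x^n) / (1 - x^m).

    Returns (w, dw/dx).  The removable singularity at x = 1 (limit n/m) is
    handled exactly for the m = 2n case via w = 1 / (1 + x^n) and by a local
    Taylor expansion otherwise.
    """
    x = np.asarray(x, dtype=float)
    if m == 2 * n:
        xn = x ** n
        w = 1.0 / (1.0 + xn)
        with np.errstate(divide="ignore", invalid="ignore"):
            dw = np.where(x > 0, -n * x ** (n - 1) * w * w, 0.0)
        return w, dw
    num = 1.0 - x ** n
    den = 1.0 - x ** m
    near = np.abs(x - 1.0) < 1e-4
    safe_den = np.where(near, 1.0, den)
    w = np.where(near, 0.0, num / safe_den)
    with np.errstate(divide="ignore", invalid="ignore"):
        dw_gen = np.where(
            near, 0.0,
            (-n * x ** (n - 1) * safe_den + m * x ** (m - 1) * num) / safe_den ** 2)
    u = x - 1.0
    # (1 - x^n)/(1 - x^m) = (n/m) (1 + (n - m) u / 2 + O(u^2)) around x = 1
    w_taylor = (n / m) * (1.0 + (n - m) * u / 2.0)
    dw_taylor = np.full_like(x, n * (n - m) / (2.0 * m))
    w = np.where(near, w_taylor, w)
    dw = np.where(near, dw_taylor, dw_gen)
    return w, dw


def _xy_displacements(config: ParticleConfiguration, mask: np.ndarray) -> np.ndarray:
    """Minimum-image xy displacement of masked particles from the box centre."""
    delta = config.positions[mask][:, :2] - config.box[:2] / 2.0
    for ax in range(2):
        if config.periodic[ax]:
            L = config.box[ax]
            delta[:, ax] -= L * np.round(delta[:, ax] / L)
    return delta


def cylinder_soft_count(config: ParticleConfiguration, params: CVParams,
                        return_gradient: bool = False):
    """Smooth count d of lipid-tail beads inside the virtual cylinder.

    d = sum_i w(rho_i / R_cyl) over tail and terminal-tail beads, where rho_i
    is the minimum-image xy distance to the box centre and w is the rational
    membership function (w(0) = 1, w -> 0 beyond R_cyl).  The cylinder spans
    the whole box along z.  With ``return_gradient`` also returns the (N, 3)
    array of dd/dposition (zero for non-tail particles).
    """
    mask = config.tail_mask
    if not mask.any():
        raise ValueError("configuration has no tail-role particles")
    delta = _xy_displacements(config, mask)
    rho = np.linalg.norm(delta, axis=1)
    n, m = params.boundary_exponents
    w, dw = rational_switch(rho / params.r_cyl, n, m)
    d = float(w.sum())
    if not return_gradient:
        return d
    grad = np.zeros_like(config.positions)
    ok = rho > 1e-10
    coeff = np.zeros_like(rho)
    coeff[ok] = dw[ok] / (params.r_cyl * rho[ok])
    grad[np.where(mask)[0], :2] = coeff[:, None] * delta
    return d, grad


def cv_cyl(d: float, cv_eq: float) -> float:
    """Membrane-defect coordinate: CV_cyl = 1 - d / CV_eq.

    0 for the equilibrated intact bilayer, 1 for an empty cylinder (its upper
    limit), negative for an over-filled cylinder; linear and smooth in d.
    """
    if cv_eq <= 0:
        raise ValueError("cv_eq must be positive")
    return 1.0 - d / cv_eq


def calibrate_cv_eq(frames: Iterable[ParticleConfiguration],
                    params: CVParams) -> CalibrationResult:
    """CV_eq = time-averaged cylinder soft count over intact-bilayer frames.

    The caller is responsible for supplying pore-free frames.
    """
    counts = [cylinder_soft_count(f, params) for f in frames]
    if not counts:
        raise ValueError("calibration requires at least one frame")
    arr = np.asarray(counts, dtype=float)
    return CalibrationResult(cv_eq=float(arr.mean()), n_frames=len(arr),
                             std=float(arr.std(ddof=0)))


def soft_min_radius(config: ParticleConfiguration, params: CVParams,
                    return_gradient: bool = False):
    """Smooth underestimating minimum xy distance from the pore centre to any
    lipid-tail bead: r_soft = beta / ln sum_i exp(beta / d_i).

    r_soft <= min(d_i) always, converging to the exact minimum as beta grows.
    Distances are floored at ``params.softmin_floor`` to avoid overflow; the
    sum is evaluated with log-sum-exp.
    """
    mask = config.tail_mask
    if not mask.any():
        raise ValueError("configuration has no tail-role particles")
    delta = _xy_displacements(config, mask)
    rho = np.linalg.norm(delta, axis=1)
    clamped = rho < params.softmin_floor
    d = np.maximum(rho, params.softmin_floor)
    beta = params.softmin_beta
    a = beta / d
    L = float(logsumexp(a))
    r_soft = beta / L
    if not return_gradient:
        return r_soft
    p = np.exp(a - a.max())
    p /= p.sum()  # softmax weights: dL/da_i
    # dr/dd_i = beta^2 p_i / (L^2 d_i^2); dd_i/dpos = delta/rho (xy)
    dr_dd = beta ** 2 * p / (L ** 2 * d ** 2)
    grad = np.zeros_like(config.positions)
    ok = (~clamped) & (rho > 1e-10)
    coeff = np.where(ok, dr_dd / np.maximum(rho, 1e-300), 0.0)
    grad[np.where(mask)[0], :2] = coeff[:, None] * delta
    return r_soft, grad


def fullpath_cv(config: ParticleConfiguration, params: CVParams) -> CVValue:
    """Evaluate the joint Full-Path CV and its exact analytic gradient.

    Requires a calibrated ``params.cv_eq``.  The switching argument is
    CV_radius: below CV0 the defect term dominates, above it the joint CV is
    the dimensionless pore radius.
    """
    if params.cv_eq is None:
        raise ValueError("params.cv_eq is not calibrated; run calibrate_cv_eq first")
    d, grad_d = cylinder_soft_count(config, params, return_gradient=True)
    cvc = cv_cyl(d, params.cv_eq)
    grad_cvc = -grad_d / params.cv_eq
    r_soft, grad_r = soft_min_radius(config, params, return_gradient=True)
    cvr = r_soft / params.r_unit
    grad_cvr = grad_r / params.r_unit

    s1, s2 = switching_pair(cvr, params.cv0, params.alpha)
    s1 = float(s1)
    s2 = float(s2)
    ds1 = -params.alpha * s1 * s2  # ds1/dx at x = cv_radius
    value = s1 * cvc + s2 * cvr
    gradient = s1 * grad_cvc + (s2 + ds1 * (cvc - cvr)) * grad_cvr
    return CVValue(value=float(value), cv_cyl=float(cvc), cv_radius=float(cvr),
                   s1=s1, s2=s2, gradient=gradient)
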