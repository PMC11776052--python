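"""The Rapid line-tension CV: box edge along the pore rim, its restraints, and
conversion of a free-energy slope into a line tension.

A lipid stripe (bilayer ribbon periodic along one axis) models a pore of
infinite radius with two rims.  Biasing the box edge along the rim axis
changes the total rim length; the free energy is linear in that edge with
slope m = n_rims * gamma, so the line tension is gamma = m / (n_rims * N_A)
per molecule — reported here both in kJ mol^-1 nm^-1 (the per-mole form,
m / n_rims) and in pN (1 kJ mol^-1 nm^-1 = 1.66054 pN).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Tuple, Union

import numpy as np
from scipy import constants

from .membranes import ParticleConfiguration

__all__ = [
    "KJ_PER_MOL_NM_AS_PN",
    "BiasSpec",
    "LineTensionResult",
    "rim_length_cv",
    "harmonic_bias",
    "flat_bottom_bias",
    "line_tension_from_slope",
    "pn_to_kjmolnm",
    "kjmolnm_to_pn",
]

# 1 kJ mol^-1 nm^-1 expressed as a force in pN (= 1e24 / N_A).
KJ_PER_MOL_NM_AS_PN = 1e24 / constants.N_A


def kjmolnm_to_pn(x: float) -> float:
    return x * KJ_PER_MOL_NM_AS_PN


def pn_to_kjmolnm(x: float) -> float:
    return x / KJ_PER_MOL_NM_AS_PN


@dataclass
class BiasSpec:
    """A bias potential on a CV or coordinate.

    kind        one of {"harmonic", "moving_harmonic", "flat_bottom"}
    center      bias centre in CV units (harmonic), or ignored when a
                schedule is given
    kappa       harmonic force constant, kJ mol^-1 per squared CV unit
    schedule    moving_harmonic only: callable t -> centre, or a tuple
                (c_start, c_end, t_total) for a linear ramp
    k_fb        flat-bottom force constant, kJ mol^-1 nm^-2
    half_width  flat-bottom half width, nm
    """

    kind: str = "harmonic"
    center: float = 0.0
    kappa: float = 5000.0
    schedule: Optional[Union[Callable[[float], float], Tuple[float, float, float]]] = None
    k_fb: float = 1000.0
    half_width: float = 2.5

    def __post_init__(self) -> None:
        if self.kind not in ("harmonic", "moving_harmonic", "flat_bottom"):
            raise ValueError(f"unknown bias kind {self.kind!r}")
        if self.kappa < 0 or self.k_fb < 0:
            raise ValueError("force constants must be >= 0")
        if self.half_width <= 0:
            raise ValueError("half_width must be positive")

    def center_at(self, time: Optional[float] = None) -> float:
        """Bias centre, evaluating the schedule for a moving restraint."""
        if self.kind == "moving_harmonic":
            if self.schedule is None:
                raise ValueError("moving_harmonic requires a schedule")
            if callable(self.schedule):
                return float(self.schedule(0.0 if time is None else time))
            c0, c1, t_total = self.schedule
            if time is None:
                return c0
            frac = np.clip(time / t_total, 0.0, 1.0)
            return float(c0 + (c1 - c0) * frac)
        return self.center


@dataclass
class LineTensionResult:
    """Line tension from a free-energy slope.

    slope_m         fitted slope, kJ mol^-1 nm^-1
    gamma_kjmolnm   per-mole line tension m / n_rims, kJ mol^-1 nm^-1
    gamma_pN        the same as a force, pN
    error           uncertainty on gamma_pN (same estimator as the fit), pN
    n_rims          rims sharing the slope (2 for a stripe, 1 for one edge)
    """

    slope_m: float
    gamma_kjmolnm: float
    gamma_pN: float
    error: float = 0.0
    n_rims: int = 2


def rim_length_cv(config: ParticleConfiguration, rim_axis: int = 1) -> float:
    """Box edge length along the rim axis (default y), the Rapid CV.

    Depends only on the box, never on particle positions.  Raises if the rim
    axis is not periodic (the rim must be continuous through the boundary).
    """
    if not config.periodic[rim_axis]:
        raise ValueError("rim axis must be periodic")
    return float(config.box[rim_axis])


def harmonic_bias(cv: float, spec: BiasSpec,
                  time: Optional[float] = None) -> Tuple[float, float]:
    """Harmonic umbrella bias: U = 1/2 kappa (cv - c)^2, returns (U, dU/dcv).

    For a moving restraint the centre is evaluated from the schedule at
    ``time``.
    """
    if spec.kind not in ("harmonic", "moving_harmonic"):
        raise ValueError("harmonic_bias requires a (moving_)harmonic BiasSpec")
    c = spec.center_at(time)
    delta = cv - c
    return 0.5 * spec.kappa * delta * delta, spec.kappa * delta


def flat_bottom_bias(x: float, x_ref: float, spec: BiasSpec) -> Tuple[float, float]:
    """Flat-bottom restraint on a coordinate, returns (U, force = -dU/dx).

    Zero inside |x - x_ref| <= half_width and harmonic with constant k_fb
    outside; C1-continuous at the boundary.  In the toy dynamics this acts on
    head beads along the membrane normal relative to the stripe centre of
    mass, preventing the stripe from rotating or self-interacting through the
    periodic boundary.
    """
    if spec.kind != "flat_bottom":
        raise ValueError("flat_bottom_bias requires a flat_bottom BiasSpec")
    delta = x - x_ref
    excess = abs(delta) - spec.half_width
    if excess <= 0:
        return 0.0, 0.0
    u = 0.5 * spec.k_fb * excess * excess
    force = -spec.k_fb * excess * np.sign(delta)
    return float(u), float(force)


def line_tension_from_slope(slope_m: float, n_rims: int = 2,
                            error_slope: float = 0.0) -> LineTensionResult:
    """Convert a free-energy slope (kJ mol^-1 nm^-1) into a line tension.

    gamma = m / (n_rims * N_A): per-mole value m / n_rims in kJ mol^-1 nm^-1
    and the equivalent force in pN.  ``error_slope`` is propagated with the
    same factors.
    """
    if n_rims not in (1, 2):
        raise ValueError("n_rims must be 1 or 2")
    if not np.isfinite(slope_m):
        raise ValueError("slope must be finite")
    gamma_kj = slope_m / n_rims
    return LineTensionResult(
        slope_m=float(slope_m),
        gamma_kjmolnm=float(gamma_kj),
        gamma_pN=float(kjmolnm_to_pn(gamma_kj)),
        error=float(kjmolnm_to_pn(abs(error_slope) / n_rims)),
        n_rims=n_rims,
    )
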