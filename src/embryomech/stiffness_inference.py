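"""Stiffness inference for the DV epidermis from paired seam / HYP7 openings.

Three quantities of the fiber-reinforced picture of the dorso-ventral
epidermal cell (HYP7) are identifiable from cut openings alone:

* the matrix modulus ratio E0_HYP7 / E_H1 — the H1 seam cell and HYP7 sit
  side by side along the circumference and share the DV stress (tension
  continuity across the junction), so at equal stress openings vary
  inversely with moduli and the ratio is the reciprocal slope of a
  through-origin regression of HYP7 DV openings on H1 DV openings;
* the fiber reinforcement factor K — the AP cut severs the circumferential
  fibers and opens isotropically with the bare matrix modulus, fixing
  sigma_DV/E0; transferring the seam-cell stress anisotropy fixes
  sigma_AP/E0; the DV cut, whose fibers stay intact, then determines K
  through the monotone anisotropic crack-opening factor H(K);
* the stiffness anisotropy omega = E_DV/E_AP = 1 + K(1 - nu0^2), monotone
  in K.

Only ratios are identifiable; absolute moduli in Pa are not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .plane_elasticity import build_fiber_reinforced, crack_opening_factor

__all__ = [
    "PairedOpenings",
    "StiffnessEstimate",
    "matrix_modulus_ratio",
    "infer_K",
    "stiffness_anisotropy",
    "opening_ratio_report",
    "fiber_factor_opening_factor",
]

K_MAX = 1e3


@dataclass(frozen=True)
class PairedOpenings:
    """One stage's four openings (mean ± SE): H1 and HYP7, AP cut and DV cut."""

    stage: str
    h1_ap_cut: float
    h1_ap_cut_se: float
    h1_dv_cut: float
    h1_dv_cut_se: float
    hyp7_ap_cut: float
    hyp7_ap_cut_se: float
    hyp7_dv_cut: float
    hyp7_dv_cut_se: float

    def __post_init__(self) -> None:
        for name in ("h1_ap_cut", "h1_dv_cut", "hyp7_ap_cut", "hyp7_dv_cut"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class StiffnessEstimate:
    value: float
    se: float


def fiber_factor_opening_factor(K: float, nu0: float) -> float:
    """Dimensionless opening factor E0*H(K) for a DV cut (fibers intact).

    Strictly decreasing in K from 1 at K = 0: stiffer fiber reinforcement
    closes down the parallel-cut opening.
    """
    sheet = build_fiber_reinforced(1.0, nu0, K)
    return crack_opening_factor(sheet.compliance, cut_axis="DV")


def matrix_modulus_ratio(
    h1_dv_openings: np.ndarray, hyp7_dv_openings: np.ndarray
) -> StiffnessEstimate:
    """E0_HYP7 / E_H1 from paired per-embryo DV-direction openings.

    The DV-direction opening is that of the *AP cut*, which severs the
    circumferential fibers in HYP7, so both cells respond isotropically
    with their matrix moduli under the shared DV stress and openings are
    inversely proportional to moduli.  Regression through the origin of
    HYP7 openings on H1 openings (zero stress must give zero opening in
    both cells) gives slope s = sum(xy)/sum(x^2) with the usual
    through-origin slope SE; the modulus ratio is 1/s.
    """
    x = np.asarray(h1_dv_openings, dtype=float)
    y = np.asarray(hyp7_dv_openings, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need >= 2 paired openings of equal length")
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise ValueError("all H1 openings are zero: slope undefined")
    slope = float(np.sum(x * y)) / sxx
    resid = y - slope * x
    dof = max(x.size - 1, 1)
    slope_se = math.sqrt(float(np.sum(resid**2)) / dof / sxx)
    if slope <= 0:
        raise ValueError("non-positive regression slope: openings inconsistent")
    ratio = 1.0 / slope
    return StiffnessEstimate(value=ratio, se=slope_se / slope**2)


def _solve_K(hyp7_ap_cut: float, hyp7_dv_cut: float, AS: float, nu0: float) -> float:
    """Invert the fiber-reinforced forward model for K (noise-free core)."""
    if hyp7_dv_cut <= 0:
        raise ValueError("DV-cut opening must be positive to constrain K")
    if AS <= 0:
        raise ValueError("AS must be positive")
    sigma_dv_over_e0 = hyp7_ap_cut / 2.0  # AP cut: fibers severed, isotropic law
    sigma_ap_over_e0 = sigma_dv_over_e0 / AS
    if sigma_ap_over_e0 <= 0:
        raise ValueError("zero AP stress: DV-cut opening cannot be matched")

    def residual(K: float) -> float:
        return 2.0 * sigma_ap_over_e0 * fiber_factor_opening_factor(K, nu0) - hyp7_dv_cut

    r0 = residual(0.0)
    if r0 < 0:
        # DV-cut opening exceeds even the unreinforced prediction
        raise ValueError(
            "openings inconsistent with fiber-reinforced model (would need K < 0)"
        )
    if abs(r0) < 1e-15:
        return 0.0
    if residual(K_MAX) > 0:
        raise ValueError(
            f"openings inconsistent with fiber-reinforced model (no root in [0, {K_MAX:g}])"
        )
    return float(brentq(residual, 0.0, K_MAX, xtol=1e-12, rtol=1e-9))


def infer_K(
    hyp7_ap_cut: float,
    hyp7_dv_cut: float,
    AS: float,
    nu0: float = 0.5,
    *,
    se_ap_cut: float = 0.0,
    se_dv_cut: float = 0.0,
    se_AS: float = 0.0,
) -> StiffnessEstimate:
    """Fiber reinforcement factor K of HYP7 from its two cut openings.

    ``hyp7_ap_cut`` and ``hyp7_dv_cut`` are b/l means; ``AS`` is the stress
    anisotropy transferred from the adjacent H1 seam cell (stress
    continuity — the strongest modelling assumption of this inference).
    Monotonicity of the opening factor in K makes the root unique; the SE
    propagates the input SEs through the inverse by finite differences.
    """
    K = _solve_K(hyp7_ap_cut, hyp7_dv_cut, AS, nu0)
    var = 0.0
    for value, se, name in (
        (hyp7_ap_cut, se_ap_cut, "ap"),
        (hyp7_dv_cut, se_dv_cut, "dv"),
        (AS, se_AS, "as"),
    ):
        if se <= 0:
            continue
        h = 1e-4 * max(abs(value), 1e-6)
        args = {"ap": hyp7_ap_cut, "dv": hyp7_dv_cut, "as": AS}
        hi = dict(args, **{name: value + h})
        lo = dict(args, **{name: max(value - h, 1e-12)})
        try:
            dK = (_solve_K(hi["ap"], hi["dv"], hi["as"], nu0)
                  - _solve_K(lo["ap"], lo["dv"], lo["as"], nu0)) / (hi[name] - lo[name])
        except ValueError:
            dK = 0.0
        var += (dK * se) ** 2
    return StiffnessEstimate(value=K, se=math.sqrt(var))


def stiffness_anisotropy(K: float, nu0: float = 0.5, se_K: float = 0.0) -> StiffnessEstimate:
    """omega = E_DV/E_AP of the fiber-reinforced sheet; monotone in K.

    Closed form omega = 1 + K (1 - nu0^2); SE by the delta method.
    """
    if K < 0:
        raise ValueError("K must be non-negative")
    sheet = build_fiber_reinforced(1.0, nu0, K)
    domega_dK = 1.0 - nu0**2
    return StiffnessEstimate(value=sheet.omega, se=abs(domega_dK) * se_K)


def opening_ratio_report(paired: PairedOpenings) -> dict:
    """DV/AP opening ratio (AP-cut over DV-cut opening) per cell, with flags.

    For an isotropic cortex this ratio equals the stress anisotropy and
    must match between adjacent cells sharing the stresses; a HYP7 ratio
    exceeding the H1 ratio is the signature that rejects cortical isotropy
    of HYP7 and motivates the fiber-reinforced model.
    """
    from .stress_inference import anisotropy_from_values

    if paired.h1_dv_cut <= 0 or paired.hyp7_dv_cut <= 0:
        raise ValueError("DV-cut openings must be positive (ratio denominator)")
    h1_ratio, h1_se = anisotropy_from_values(
        paired.h1_ap_cut, paired.h1_ap_cut_se, paired.h1_dv_cut, paired.h1_dv_cut_se
    )
    hyp7_ratio, hyp7_se = anisotropy_from_values(
        paired.hyp7_ap_cut, paired.hyp7_ap_cut_se, paired.hyp7_dv_cut, paired.hyp7_dv_cut_se
    )
    return {
        "stage": paired.stage,
        "h1_ratio": h1_ratio,
        "h1_ratio_se": h1_se,
        "hyp7_ratio": hyp7_ratio,
        "hyp7_ratio_se": hyp7_se,
        "hyp7_exceeds_h1": hyp7_ratio > h1_ratio,
    }
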