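"""Plane-stress elasticity of a thin cortical sheet with a line cut.

A laser line cut through a pre-stressed elastic sheet relaxes into an
elliptical hole.  For an isotropic sheet under remote tension ``sigma``
perpendicular to a cut of length ``l``, the equilibrium minor axis is

    b = 2 * (sigma / E) * l

so the dimensionless opening ``b / l`` measures the stress-to-stiffness
ratio directly and is independent of the cut length.  This module provides
that relation, its generalisation to anisotropic sheets through the
classical orthotropic crack-opening factor, a fiber-reinforced constitutive
model for the dorso-ventral (DV) epidermis of the elongating C. elegans
embryo, and the Hooke's-law strain predictions used to interpret seam- and
DV-cell deformation.

Axes convention: index 1 = AP (antero-posterior), index 2 = DV
(dorso-ventral, the circumferential fiber direction).  Stresses are
expressed as dimensionless ratios over a reference modulus unless noted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

Axis = Literal["AP", "DV"]

__all__ = [
    "IsotropicSheet",
    "FiberReinforcedSheet",
    "ComplianceMatrix",
    "BiaxialLoad",
    "CrackOpening",
    "opening_isotropic",
    "build_fiber_reinforced",
    "crack_opening_factor",
    "opening_anisotropic",
    "opening_pair_fiber_reinforced",
    "opening_orthotropic_comparison",
    "orthotropic_compliance",
    "hooke_isotropic_strains",
    "hooke_fiber_reinforced_strains",
]


@dataclass(frozen=True)
class IsotropicSheet:
    """Isotropic plane-stress sheet: Young modulus ``E`` and 2-D Poisson ratio ``nu``.

    ``nu = 1`` (incompressible 2-D sheet) is permitted only in Hooke's-law
    strain formulas; stiffness-matrix construction rejects it as singular.
    """

    E: float
    nu: float = 0.0

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValueError(f"Young modulus must be positive, got {self.E}")
        if not 0.0 <= self.nu <= 1.0:
            raise ValueError(f"2-D Poisson ratio must lie in [0, 1], got {self.nu}")

    def compliance(self) -> "ComplianceMatrix":
        if self.nu >= 1.0:
            raise ValueError("nu = 1 gives a singular stiffness; valid only in Hooke's-law strain formulas")
        E, nu = self.E, self.nu
        return ComplianceMatrix(s11=1 / E, s12=-nu / E, s22=1 / E, s66=2 * (1 + nu) / E)


@dataclass(frozen=True)
class ComplianceMatrix:
    """Plane-stress compliance in the AP (1) / DV (2) material frame.

    Engineering-shear convention: eps = [eps_11, eps_22, gamma_12] = S sigma
    with S = [[s11, s12, 0], [s12, s22, 0], [0, 0, s66]] for an orthotropic
    sheet whose principal axes are AP and DV.
    """

    s11: float
    s12: float
    s22: float
    s66: float

    def __post_init__(self) -> None:
        if self.s11 <= 0 or self.s22 <= 0 or self.s66 <= 0:
            raise ValueError("diagonal compliances must be positive")
        if self.s11 * self.s22 - self.s12**2 <= 0:
            raise ValueError("compliance matrix is not positive definite")

    def as_matrix(self) -> np.ndarray:
        return np.array(
            [[self.s11, self.s12, 0.0], [self.s12, self.s22, 0.0], [0.0, 0.0, self.s66]]
        )

    def stiffness(self) -> np.ndarray:
        return np.linalg.inv(self.as_matrix())

    def swap_axes(self) -> "ComplianceMatrix":
        """Compliance seen from the frame with axes 1 and 2 interchanged."""
        return ComplianceMatrix(s11=self.s22, s12=self.s12, s22=self.s11, s66=self.s66)


@dataclass(frozen=True)
class BiaxialLoad:
    """Remote biaxial stress, tensile-positive, in units of a reference modulus."""

    sigma_AP: float
    sigma_DV: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.sigma_AP) and np.isfinite(self.sigma_DV)):
            raise ValueError("stress magnitudes must be finite")

    def perpendicular_to(self, cut_axis: Axis) -> float:
        """Stress component opening a cut laid along ``cut_axis``."""
        return self.sigma_DV if cut_axis == "AP" else self.sigma_AP


@dataclass(frozen=True)
class CrackOpening:
    """Equilibrium ellipse of a relaxed line cut, scaled by the cut length."""

    b_over_l: float
    a_over_l: float = 1.0
    direction_of_opening: Axis = "DV"
    l_um: float | None = None

    def __post_init__(self) -> None:
        if self.b_over_l < 0:
            raise ValueError("opening ratio b/l must be non-negative")

    @property
    def b_um(self) -> float | None:
        return None if self.l_um is None else self.b_over_l * self.l_um

    @property
    def a_um(self) -> float | None:
        return None if self.l_um is None else self.a_over_l * self.l_um


@dataclass(frozen=True)
class FiberReinforcedSheet:
    """Isotropic matrix (E0, nu0) reinforced by fibers along DV with factor K.

    The plane-stress stiffness is the isotropic matrix stiffness plus K*E0
    added to the DV normal entry.  Derived directional moduli:

        E_DV = E0 * (1 + K)                      (exactly linear in K)
        E_AP = E0 * (1 + K) / (1 + K*(1 - nu0^2))  (plateau E0/(1-nu0^2))
        omega = E_DV / E_AP = 1 + K*(1 - nu0^2)  (stiffness anisotropy)

    ``nu1`` and ``nu2`` are the composite Poisson ratios entering the
    fiber-reinforced Hooke's law (nu1/E_DV = nu2/E_AP by symmetry).
    """

    E0: float
    nu0: float
    K: float
    fiber_axis: Axis = "DV"
    compliance: ComplianceMatrix = field(init=False)
    E_AP: float = field(init=False)
    E_DV: float = field(init=False)
    omega: float = field(init=False)
    nu1: float = field(init=False)
    nu2: float = field(init=False)

    def __post_init__(self) -> None:
        if self.E0 <= 0:
            raise ValueError("matrix modulus E0 must be positive")
        if not 0.0 <= self.nu0 < 1.0:
            raise ValueError("matrix Poisson ratio must lie in [0, 1); nu0 = 1 is singular")
        if self.K < 0:
            raise ValueError("fiber reinforcement factor K must be non-negative")
        if self.fiber_axis != "DV":
            raise ValueError("fibers are circumferential: fiber_axis must be 'DV'")
        E0, nu0, K = self.E0, self.nu0, self.K
        c = E0 / (1 - nu0**2)
        # stiffness in AP/DV frame; rank-one fiber term on the DV normal entry
        Q = np.array(
            [
                [c, nu0 * c, 0.0],
                [nu0 * c, c + K * E0, 0.0],
                [0.0, 0.0, E0 / (2 * (1 + nu0))],
            ]
        )
        S = np.linalg.inv(Q)
        comp = ComplianceMatrix(s11=S[0, 0], s12=S[0, 1], s22=S[1, 1], s66=S[2, 2])
        object.__setattr__(self, "compliance", comp)
        object.__setattr__(self, "E_AP", 1.0 / comp.s11)
        object.__setattr__(self, "E_DV", 1.0 / comp.s22)
        object.__setattr__(self, "omega", self.E_DV / self.E_AP)
        object.__setattr__(self, "nu1", -comp.s12 / comp.s22)
        object.__setattr__(self, "nu2", -comp.s12 / comp.s11)


def build_fiber_reinforced(E0: float, nu0: float, K: float) -> FiberReinforcedSheet:
    """Assemble the fiber-reinforced sheet and its inverted compliance.

    Parameters
    ----------
    E0 : matrix Young modulus (> 0, any consistent stress unit).
    nu0 : matrix 2-D Poisson ratio in [0, 1).
    K : dimensionless fiber reinforcement factor (>= 0); K = 0 recovers the
        isotropic matrix.
    """
    return FiberReinforcedSheet(E0=E0, nu0=nu0, K=K)


def opening_isotropic(
    load_perp: float,
    l: float = 1.0,
    *,
    nu: float = 0.0,
    load_parallel: float = 0.0,
    direction_of_opening: Axis = "DV",
) -> CrackOpening:
    """Equilibrium opening of a line cut in an isotropic pre-stressed sheet.

    ``load_perp`` is the tensile stress perpendicular to the cut in units of
    the sheet modulus (sigma/E); the minor axis obeys b/l = 2 * sigma/E,
    independent of the cut length.  The major axis carries the small
    correction from the remote strain parallel to the cut,
    a/l = 1 + (sigma_par - nu*sigma_perp)/E; it is reported but plays no
    role in stress inference.
    """
    if l <= 0:
        raise ValueError("cut length must be positive")
    if load_perp < 0:
        raise ValueError(
            "compressive perpendicular load would close the cut; linear crack model invalid"
        )
    eps_parallel = load_parallel - nu * load_perp
    return CrackOpening(
        b_over_l=2.0 * load_perp,
        a_over_l=1.0 + eps_parallel,
        direction_of_opening=direction_of_opening,
        l_um=l,
    )


def crack_opening_factor(compliance: ComplianceMatrix, cut_axis: Axis = "AP") -> float:
    """Anisotropic crack-opening factor H (units 1/stress).

    Classical orthotropic crack result in the crack-aligned frame (crack
    along local axis 1, opening load along local axis 2):

        H = sqrt(s11' s22' / 2) * sqrt( sqrt(s22'/s11') + (2 s12' + s66') / (2 s11') )

    so the equilibrium minor axis of the relaxed cut is b/l = 2 sigma_perp H.
    Reduces to 1/E for an isotropic sheet, any Poisson ratio.
    """
    s = compliance if cut_axis == "AP" else compliance.swap_axes()
    inner = np.sqrt(s.s22 / s.s11) + (2 * s.s12 + s.s66) / (2 * s.s11)
    if inner <= 0:
        raise ValueError("compliance yields no real crack-opening factor")
    return float(np.sqrt(s.s11 * s.s22 / 2.0) * np.sqrt(inner))


def opening_anisotropic(
    compliance: ComplianceMatrix,
    load_perp: float,
    cut_axis: Axis = "AP",
    l: float = 1.0,
) -> CrackOpening:
    """Opening of a cut along ``cut_axis`` in an anisotropic sheet.

    ``load_perp`` is the remote tensile stress perpendicular to the cut in
    the same (reference-modulus) units as the compliance entries' inverse.
    """
    if load_perp < 0:
        raise ValueError("compressive perpendicular load: crack closes, model invalid")
    if l <= 0:
        raise ValueError("cut length must be positive")
    H = crack_opening_factor(compliance, cut_axis)
    return CrackOpening(
        b_over_l=2.0 * load_perp * H,
        a_over_l=1.0,
        direction_of_opening="DV" if cut_axis == "AP" else "AP",
        l_um=l,
    )


def opening_pair_fiber_reinforced(
    sheet: FiberReinforcedSheet, load: BiaxialLoad, l: float = 1.0
) -> tuple[CrackOpening, CrackOpening]:
    """Openings of an AP-direction cut and a DV-direction cut in a fiber sheet.

    The AP-direction cut runs perpendicular to the DV fibers and severs
    them locally, so its DV opening follows the isotropic law with the bare
    matrix modulus E0 and does not depend on K.  The DV-direction cut runs
    parallel to the fibers, which stay intact, so its AP opening uses the
    full reinforced compliance and shrinks as K grows.

    Loads are in units of E0.  Returns ``(ap_cut_opening, dv_cut_opening)``.
    """
    if load.sigma_AP < 0 or load.sigma_DV < 0:
        raise ValueError("tensile-positive loads required")
    ap_cut = opening_isotropic(load.sigma_DV, l, nu=sheet.nu0, direction_of_opening="DV")
    # compliance entries are in 1/E0 units when evaluated with E0 = sheet.E0
    comp_unit = build_fiber_reinforced(1.0, sheet.nu0, sheet.K).compliance
    dv_cut = opening_anisotropic(comp_unit, load.sigma_AP, cut_axis="DV", l=l)
    return ap_cut, dv_cut


def orthotropic_compliance(E_AP: float, E_DV: float, nu: float) -> ComplianceMatrix:
    """Orthotropic compliance from directional moduli and a mean Poisson ratio.

    The cross terms are tied to the geometric-mean modulus,
    s12 = -nu / sqrt(E_AP E_DV) and s66 = 2(1+nu)/sqrt(E_AP E_DV), so that
    E_AP = E_DV = E recovers the isotropic sheet exactly.
    """
    if E_AP <= 0 or E_DV <= 0:
        raise ValueError("moduli must be positive")
    Em = np.sqrt(E_AP * E_DV)
    return ComplianceMatrix(s11=1 / E_AP, s12=-nu / Em, s22=1 / E_DV, s66=2 * (1 + nu) / Em)


def opening_orthotropic_comparison(
    E_AP: float,
    E_DV: float,
    nu: float,
    load_perp: float,
    cut_axis: Axis,
    l: float = 1.0,
) -> CrackOpening:
    """Opening under the plain orthotropic model, for model comparison.

    Both cut directions use the full orthotropic compliance — there is no
    fiber-destruction asymmetry, which is what distinguishes this model from
    the fiber-reinforced one when confronted with paired-cut data.
    """
    comp = orthotropic_compliance(E_AP, E_DV, nu)
    return opening_anisotropic(comp, load_perp, cut_axis=cut_axis, l=l)


def hooke_isotropic_strains(
    sigma_AP_over_E: float, AS: float, nu: float
) -> tuple[float, float]:
    """Hooke's-law strains of an isotropic seam cell under contractile stress.

    Stresses are contractile; ``sigma_AP_over_E`` is the (positive)
    magnitude of the AP stress over the cell modulus and ``AS`` the
    DV-to-AP stress anisotropy.  Then

        eps_AP = (sigma_AP/E) * (nu*AS - 1)
        eps_DV = (sigma_AP/E) * (nu - AS)

    so AP extension (eps_AP > 0) requires AS > 1/nu: stress anisotropy
    drives seam-cell elongation along AP while shrinking it along DV.
    """
    if sigma_AP_over_E < 0:
        raise ValueError("sigma_AP_over_E is a contractile magnitude, must be >= 0")
    if AS <= 0:
        raise ValueError("anisotropy of stress must be positive")
    if not 0.0 <= nu <= 1.0:
        raise ValueError("nu must lie in [0, 1]")
    eps_AP = sigma_AP_over_E * (nu * AS - 1.0)
    eps_DV = sigma_AP_over_E * (nu - AS)
    return eps_AP, eps_DV


def hooke_fiber_reinforced_strains(
    sigma_AP_over_EAP: float,
    AS: float,
    omega: float,
    nu1: float = 1.0,
    nu2: float = 1.0,
) -> tuple[float, float]:
    """Hooke's-law strains of a fiber-reinforced DV cell under tensile stress.

    With omega = E_DV/E_AP and sigma_DV/E_DV = (sigma_AP/E_AP) * AS / omega:

        eps_AP = (sigma_AP/E_AP) * (1 - nu1 * AS / omega)
        eps_DV = (sigma_DV/E_DV) * (1 - nu2 * omega / AS)

    Stiffness anisotropy omega > nu1*AS lets the cell extend along AP while
    shrinking along DV, even though the DV stress is the larger one.
    """
    if sigma_AP_over_EAP < 0 or nu1 < 0 or nu2 < 0:
        raise ValueError("inputs must be non-negative")
    if AS <= 0 or omega <= 0:
        raise ValueError("AS and omega must be positive")
    if omega < 1:
        raise ValueError("omega = E_DV/E_AP must be >= 1 for DV-reinforced sheets")
    eps_AP = sigma_AP_over_EAP * (1.0 - nu1 * AS / omega)
    sigma_DV_over_EDV = sigma_AP_over_EAP * AS / omega
    eps_DV = sigma_DV_over_EDV * (1.0 - nu2 * omega / AS)
    return eps_AP, eps_DV
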