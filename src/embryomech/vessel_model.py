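"""Thin-wall axisymmetric pressure-vessel model of the elongating embryo.

The embryo is idealised as a pressurised thin-wall vessel: a head that is a
sphere (early stages) or a prolate spheroid (later), attached to a
cylindrical body.  Membrane equilibrium on an axisymmetric wall gives

    sigma_AP = (p / t) * r_circ / 2          (meridional)
    sigma_DV = sigma_AP * (2 - r_circ / r_merid)   (circumferential / hoop)

where ``r_circ`` is the normal (parallel-circle) radius and ``r_merid`` the
meridional curvature radius.  The anisotropy of stress AS = sigma_DV /
sigma_AP is therefore a pure function of geometry: 1 for a sphere, 2 for a
cylinder, and 2 - (a2/a1)^2 at the equator of a prolate head with AP
semi-axis a1 and transverse semi-axis a2.  Under the approximation that the
AP stress is constant across the epidermis at a given stage, the body AS is
2 * R2 / r_circ(head), so embryo diameters alone predict the stress
anisotropy measured by laser ablation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import pandas as pd

__all__ = [
    "SphereHead",
    "ProlateHead",
    "AxisymmetricVessel",
    "MembraneStressState",
    "membrane_stresses",
    "predict_AS_head",
    "predict_AS_body",
    "compare_predicted_vs_measured",
]


@dataclass(frozen=True)
class SphereHead:
    R1: float  # radius, µm

    def __post_init__(self) -> None:
        if self.R1 <= 0:
            raise ValueError("sphere radius must be positive")

    @property
    def r_circ_equator(self) -> float:
        return self.R1


@dataclass(frozen=True)
class ProlateHead:
    """Prolate spheroid head: a1 = AP (symmetry-axis) semi-axis, a2 transverse."""

    a1: float
    a2: float

    def __post_init__(self) -> None:
        if self.a1 <= 0 or self.a2 <= 0:
            raise ValueError("semi-axes must be positive")
        if self.a1 < self.a2:
            raise ValueError("prolate head requires a1 >= a2")

    @property
    def r_circ_equator(self) -> float:
        return self.a2


Head = Union[SphereHead, ProlateHead]


@dataclass(frozen=True)
class AxisymmetricVessel:
    """Head (sphere or prolate) plus cylindrical body of radius R2, thin wall."""

    head: Head
    R2: float
    p_over_t: float = 1.0  # pressure / wall thickness, arbitrary units

    def __post_init__(self) -> None:
        if self.R2 <= 0:
            raise ValueError("body radius must be positive")
        if self.p_over_t <= 0:
            raise ValueError("pressure-to-thickness scale must be positive")


@dataclass(frozen=True)
class MembraneStressState:
    sigma_AP: float  # meridional
    sigma_DV: float  # circumferential (hoop)

    @property
    def AS(self) -> float:
        return self.sigma_DV / self.sigma_AP


def membrane_stresses(
    r_circumferential: float, r_meridional: float, p_over_t: float = 1.0
) -> MembraneStressState:
    """Membrane stresses of an axisymmetric thin wall at one point.

    ``r_meridional`` may be ``math.inf`` for a cylinder, where AS = 2;
    a sphere (equal radii) has AS = 1.  The pressure scale cancels in AS.
    """
    if r_circumferential <= 0 or r_meridional <= 0:
        raise ValueError("radii must be positive")
    if p_over_t <= 0:
        raise ValueError("p_over_t must be positive")
    sigma_AP = p_over_t * r_circumferential / 2.0
    ratio = 0.0 if math.isinf(r_meridional) else r_circumferential / r_meridional
    sigma_DV = sigma_AP * (2.0 - ratio)
    return MembraneStressState(sigma_AP=sigma_AP, sigma_DV=sigma_DV)


def predict_AS_head(vessel: AxisymmetricVessel) -> float:
    """Stress anisotropy of the head wall, evaluated at the equator.

    Sphere: 1 exactly.  Prolate spheroid: at the equator r_circ = a2 and
    r_merid = a1^2 / a2, giving AS = 2 - (a2/a1)^2, strictly between 1 and
    2 for any finite elongation a1 > a2.
    """
    head = vessel.head
    if isinstance(head, SphereHead):
        return 1.0
    state = membrane_stresses(head.a2, head.a1**2 / head.a2, vessel.p_over_t)
    return state.AS


def predict_AS_body(vessel: AxisymmetricVessel) -> float:
    """Stress anisotropy in the cylindrical body.

    Approximating the AP (meridional) stress as constant at a given stage
    and anchoring it to the head equator, the body hoop stress (p/t)*R2
    over the head meridional stress (p/t)*r_circ(head)/2 gives
    AS_body = 2 * R2 / r_circ(head); for a spherical head this is 2*R2/R1.
    """
    return 2.0 * vessel.R2 / vessel.head.r_circ_equator


def _vessel_from_row(row: pd.Series) -> AxisymmetricVessel:
    a1, a2 = row.get("a1_um"), row.get("a2_um")
    if pd.notna(a1) and pd.notna(a2) and a1 > a2:
        head: Head = ProlateHead(a1=float(a1), a2=float(a2))
    else:
        head = SphereHead(R1=float(row["R1_um"]))
    return AxisymmetricVessel(head=head, R2=float(row["R2_um"]))


def compare_predicted_vs_measured(
    geometry: Union[pd.DataFrame, str, Path],
    measured: Union[pd.DataFrame, str, Path],
    out_json: Union[str, Path, None] = None,
) -> pd.DataFrame:
    """Per-stage comparison of geometry-predicted AS with ablation-measured AS.

    ``geometry`` has columns stage, R1_um, R2_um and optionally a1_um,
    a2_um; ``measured`` has stage, cell, AS_measured, AS_se.  Cells named
    'H1' (or any head seam cell label containing 'H') are compared to the
    head prediction, others to the body prediction.  Missing stage keys on
    either side raise with an explicit listing.
    """
    geo = pd.read_csv(geometry) if not isinstance(geometry, pd.DataFrame) else geometry.copy()
    mea = pd.read_csv(measured) if not isinstance(measured, pd.DataFrame) else measured.copy()
    missing = sorted(set(mea["stage"]) - set(geo["stage"]))
    if missing or mea.empty:
        raise KeyError(
            f"stages present in measurements but absent from geometry: {missing or 'all (empty input)'}"
        )
    rows = []
    for _, m in mea.iterrows():
        g = geo.loc[geo["stage"] == m["stage"]].iloc[0]
        vessel = _vessel_from_row(g)
        head_cell = str(m.get("cell", "H1")).upper().startswith("H")
        predicted = predict_AS_head(vessel) if head_cell else predict_AS_body(vessel)
        se = float(m.get("AS_se", float("nan")))
        rows.append(
            {
                "stage": m["stage"],
                "cell": m.get("cell", "H1"),
                "AS_predicted": predicted,
                "AS_measured": float(m["AS_measured"]),
                "AS_se": se,
                "difference": float(m["AS_measured"]) - predicted,
                "ratio": float(m["AS_measured"]) / predicted,
                "within_2se": abs(float(m["AS_measured"]) - predicted) <= 2 * se
                if se == se
                else None,
            }
        )
    report = pd.DataFrame(rows)
    if out_json is not None:
        Path(out_json).write_text(json.dumps(report.to_dict(orient="records"), indent=2))
    return report
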