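"""From equilibrium cut openings to cortical stress ratios and their anisotropy.

Inverting the isotropic crack relation b/l = 2 sigma/E gives the
stress-to-stiffness ratio sigma/E = (b/l)/2 for each cut direction.  Because
the modulus of an isotropic cortex cancels in the ratio, the anisotropy of
stress AS = sigma_DV/sigma_AP equals the ratio of the DV-direction opening
(AP cut) to the AP-direction opening (DV cut).  Uncertainties use
first-order (delta-method) propagation; group comparisons follow the
field's conventions: Welch two-tailed t-tests on per-embryo equilibrium
openings and two-sided Z-tests on derived AS values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CellOpeningRecord",
    "StressEstimate",
    "AnisotropyOfStress",
    "stress_from_opening",
    "anisotropy_of_stress",
    "anisotropy_from_values",
    "compare_openings_ttest",
    "compare_AS_ztest",
]

Cell = Literal["H1", "V3", "V6", "HYP7_dorsal", "HYP7_ventral", "HYP7"]
Stage = Literal["1.3F", "1.5F", "1.7F"]


@dataclass(frozen=True)
class CellOpeningRecord:
    """Cohort-level equilibrium opening for one cell/stage/cut-direction."""

    cell: str
    stage: str
    cut_direction: Literal["AP", "DV"]
    b_over_l: float
    se: float = 0.0
    n_embryos: int = 1

    def __post_init__(self) -> None:
        if self.b_over_l < 0:
            raise ValueError("opening must be non-negative")
        if self.se < 0:
            raise ValueError("SE must be non-negative")
        if self.n_embryos < 1:
            raise ValueError("need at least one embryo")

    @property
    def direction_of_opening(self) -> str:
        """An AP cut opens along DV and vice versa."""
        return "DV" if self.cut_direction == "AP" else "AP"


@dataclass(frozen=True)
class StressEstimate:
    direction: Literal["AP", "DV"]
    sigma_over_E: float
    se: float


@dataclass(frozen=True)
class AnisotropyOfStress:
    AS: float
    se: float
    cell: str
    stage: str


def stress_from_opening(record: CellOpeningRecord) -> StressEstimate:
    """sigma/E in the opening direction: half the scaled opening, SE scaled too."""
    return StressEstimate(
        direction=record.direction_of_opening,  # type: ignore[arg-type]
        sigma_over_E=record.b_over_l / 2.0,
        se=record.se / 2.0,
    )


def anisotropy_from_values(
    b_ap_cut: float, se_ap_cut: float, b_dv_cut: float, se_dv_cut: float
) -> tuple[float, float]:
    """AS and its delta-method SE from the two openings of one cell/stage.

    The AP cut opens along DV (numerator); the DV cut opens along AP
    (denominator).  For the ratio r = x/y the first-order variance is
    r^2 * (se_x^2/x^2 + se_y^2/y^2).
    """
    if b_dv_cut <= 0:
        raise ValueError("AP-direction opening (DV cut) is zero: AS undefined")
    AS = b_ap_cut / b_dv_cut
    se = AS * math.sqrt(
        (se_ap_cut / b_ap_cut) ** 2 + (se_dv_cut / b_dv_cut) ** 2
    ) if b_ap_cut > 0 else se_ap_cut / b_dv_cut
    return AS, se


def anisotropy_of_stress(
    ap_cut: CellOpeningRecord, dv_cut: CellOpeningRecord
) -> AnisotropyOfStress:
    """Anisotropy of stress AS = sigma_DV/sigma_AP for one cell and stage.

    Requires the AP-cut record (which measures the DV opening) and the
    DV-cut record (AP opening) of the same cell and stage; the shared
    cortical modulus cancels in the ratio.
    """
    if (ap_cut.cell, ap_cut.stage) != (dv_cut.cell, dv_cut.stage):
        raise ValueError(
            f"records refer to different cell/stage: "
            f"{(ap_cut.cell, ap_cut.stage)} vs {(dv_cut.cell, dv_cut.stage)}"
        )
    if ap_cut.cut_direction != "AP" or dv_cut.cut_direction != "DV":
        raise ValueError("pass the AP-cut record first and the DV-cut record second")
    AS, se = anisotropy_from_values(ap_cut.b_over_l, ap_cut.se, dv_cut.b_over_l, dv_cut.se)
    return AnisotropyOfStress(AS=AS, se=se, cell=ap_cut.cell, stage=ap_cut.stage)


def compare_openings_ttest(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Welch two-tailed t-test on per-embryo equilibrium openings.

    Returns ``(statistic, p_value)``.  The sampling unit is the embryo
    (each value is one embryo's mean equilibrium opening), not the frame.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two embryos per group")
    if np.array_equal(a, b) or (np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]):
        return 0.0, 1.0  # degenerate zero-variance, identical groups
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def compare_AS_ztest(
    as_1: float, se_1: float, as_2: float, se_2: float
) -> tuple[float, float]:
    """Two-sided Z-test on the difference of two AS estimates, pooled SE.

    Returns ``(z, p_value)``.
    """
    if se_1 <= 0 or se_2 <= 0:
        raise ValueError("standard errors must be positive for a Z-test")
    z = (as_1 - as_2) / math.hypot(se_1, se_2)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)
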