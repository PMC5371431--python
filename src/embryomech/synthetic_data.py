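"""Seeded generators for every input of the pipeline, with ground truth.

Real inputs are lab microscopy of ablated C. elegans embryos; none are
deposited.  These generators emulate their structure so every analysis
stage can be exercised against known truth:

* ablation movies — a fibrous bright cortex with a dark elliptical hole
  whose minor axis follows one-phase-association kinetics toward the
  equilibrium 2*(sigma/E)*l, imaged with Poisson-Gaussian noise;
* texture patches — anti-aliased filament segments with von Mises
  orientations of controlled concentration, PSF-blurred;
* paired cohorts — per-embryo equilibrium openings for the H1 seam cell
  (isotropic forward model) and the HYP7 DV cell (fiber-reinforced
  forward model, shared stresses by tension continuity), under
  multiplicative lognormal measurement noise;
* embryo geometry tables — per-stage head/body radii on the 25-µm embryo
  scale, with the vessel-model AS attached as the 'measured' value.

Every generator is a pure function of (settings, seed): reruns are
bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .opening_quantification import AblationMovie, CutROI
from .actin_texture import TexturePatch
from .stiffness_inference import PairedOpenings, fiber_factor_opening_factor
from .vessel_model import (
    AxisymmetricVessel,
    ProlateHead,
    SphereHead,
    predict_AS_body,
    predict_AS_head,
)

__all__ = [
    "GroundTruth",
    "SyntheticCohort",
    "default_stage_truths",
    "gen_ablation_movie",
    "gen_texture_patch",
    "gen_paired_cohort",
    "gen_embryo_geometry",
    "DEFAULT_GEOMETRY",
]


@dataclass(frozen=True)
class GroundTruth:
    """Per-scenario ground truth carried by every generated artifact.

    Stresses are in units of the H1 seam-cell modulus E_H1; ``matrix_ratio``
    is E0_HYP7 / E_H1; ``K`` the fiber reinforcement factor of HYP7.
    """

    stage: str = "1.7F"
    sigma_dv_over_e: float = 0.10
    AS: float = 1.8
    matrix_ratio: float = 1.5
    K: float = 4.0
    nu0: float = 0.5
    gamma_per_s: float = 0.4
    y0_um: float = 0.6
    texture_mean_deg: float = 90.0
    texture_kappa: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_dv_over_e < 0 or self.AS <= 0 or self.matrix_ratio <= 0:
            raise ValueError("stresses, AS and matrix ratio must be positive")
        if self.K < 0 or not 0 <= self.nu0 < 1:
            raise ValueError("need K >= 0 and nu0 in [0, 1)")
        if self.gamma_per_s <= 0 or self.y0_um < 0:
            raise ValueError("relaxation parameters out of range")

    @property
    def sigma_ap_over_e(self) -> float:
        return self.sigma_dv_over_e / self.AS

    @property
    def omega(self) -> float:
        return 1.0 + self.K * (1.0 - self.nu0**2)

    def forward_openings(self) -> dict[str, float]:
        """Noise-free equilibrium b/l of all four cuts of this scenario.

        H1 is isotropic with modulus E_H1; HYP7 has matrix modulus
        matrix_ratio * E_H1 and intact fibers only for the DV cut.
        Both cells share the stresses (tension continuity).
        """
        s_dv, s_ap = self.sigma_dv_over_e, self.sigma_ap_over_e
        mr = self.matrix_ratio
        h_factor = fiber_factor_opening_factor(self.K, self.nu0)
        return {
            "h1_ap_cut": 2.0 * s_dv,
            "h1_dv_cut": 2.0 * s_ap,
            "hyp7_ap_cut": 2.0 * s_dv / mr,
            "hyp7_dv_cut": 2.0 * (s_ap / mr) * h_factor,
        }


def default_stage_truths(seed: int = 0) -> list[GroundTruth]:
    """The three-stage scenario the cohort generator emulates by default.

    Stress anisotropy grows from isotropic at 1.3F to 1.8 at 1.7F, the DV
    stress rises as elongation proceeds, the HYP7 matrix stays 1.5x
    stiffer than H1, and the fiber factor K climbs from 0.6 to 4 so the
    stiffness anisotropy omega = 1 + K(1 - nu0^2) always exceeds the AS.
    """
    return [
        GroundTruth(stage="1.3F", sigma_dv_over_e=0.055, AS=1.0, K=0.6, seed=seed),
        GroundTruth(stage="1.5F", sigma_dv_over_e=0.075, AS=1.5, K=2.0, seed=seed),
        GroundTruth(stage="1.7F", sigma_dv_over_e=0.100, AS=1.8, K=4.0, seed=seed),
    ]


# ---------------------------------------------------------------------------
# ablation movies


def _render_filaments(
    rng: np.random.Generator,
    shape: tuple[int, int],
    pixel_size_um: float,
    mean_angle_deg: float,
    kappa: float,
    n_filaments: int,
    length_range_um: tuple[float, float] = (1.0, 3.0),
    width_px: float = 1.0,
) -> np.ndarray:
    """Accumulate anti-aliased bright filament segments on a dark canvas."""
    h, w = shape
    img = np.zeros(shape)
    if kappa > 0:
        thetas = rng.vonmises(np.deg2rad(mean_angle_deg), kappa, size=n_filaments) % np.pi
    else:
        thetas = rng.uniform(0.0, np.pi, size=n_filaments)
    margin = 4.0 * width_px
    for theta in thetas:
        cx, cy = rng.uniform(0, w), rng.uniform(0, h)
        half = rng.uniform(*length_range_um) / 2.0 / pixel_size_um
        ux, uy = np.cos(theta), -np.sin(theta)  # y-down image frame
        # render only inside the segment's bounding box
        x0 = max(int(cx - half * abs(ux) - margin), 0)
        x1 = min(int(cx + half * abs(ux) + margin) + 1, w)
        y0 = max(int(cy - half * abs(uy) - margin), 0)
        y1 = min(int(cy + half * abs(uy) + margin) + 1, h)
        if x0 >= x1 or y0 >= y1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dx, dy = xx - cx, yy - cy
        along = dx * ux + dy * uy
        t = np.clip(along, -half, half)
        dist2 = (dx - t * ux) ** 2 + (dy - t * uy) ** 2
        img[y0:y1, x0:x1] += np.exp(-dist2 / (2.0 * width_px**2))
    return img


def _ellipse_coverage(
    shape: tuple[int, int],
    cx: float,
    cy: float,
    semi_a_px: float,
    semi_b_px: float,
    angle_deg: float,
    supersample: int = 4,
) -> np.ndarray:
    """Per-pixel fraction covered by the ellipse, by supersampling."""
    h, w = shape
    s = supersample
    off = (np.arange(s) + 0.5) / s - 0.5
    cov = np.zeros((h, w))
    ca, sa = np.cos(np.deg2rad(angle_deg)), np.sin(np.deg2rad(angle_deg))
    # evaluate only inside the ellipse's bounding box
    r = max(semi_a_px, semi_b_px) + 2.0
    x0, x1 = max(int(cx - r), 0), min(int(cx + r) + 1, w)
    y0, y1 = max(int(cy - r), 0), min(int(cy + r) + 1, h)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    for oy in off:
        for ox in off:
            dx = xx + ox - cx
            dy = yy + oy - cy
            u = dx * ca - dy * sa  # image y-down: -angle rotation
            v = dx * sa + dy * ca
            cov[y0:y1, x0:x1] += (
                (u / semi_a_px) ** 2 + (v / max(semi_b_px, 1e-9)) ** 2 <= 1.0
            )
    return cov / s**2


def gen_ablation_movie(
    truth: GroundTruth,
    l_um: float = 5.0,
    direction: str = "AP",
    n_frames: int = 20,
    frame_interval_s: float = 0.5,
    snr: float = 10.0,
    seed: int | None = None,
    *,
    pixel_size_um: float = 0.1,
    fov_um: float = 12.0,
    hole_floor: float = 0.05,
    reseal_at_s: float | None = None,
    t0_offset_s: float = 1.44,
) -> tuple[AblationMovie, GroundTruth]:
    """Synthetic ablation time-lapse with one-phase-association opening.

    The stress opening the cut is sigma_DV for an AP cut and sigma_AP for
    a DV cut (in units of the cortex modulus), so the rendered equilibrium
    minor axis is b_eq = 2*(sigma_perp/E)*l and the per-frame minor axis
    follows b(t) = b_eq - (b_eq - y0) * exp(-gamma*t) from the 0.6-µm
    initial width.  With ``reseal_at_s`` set, a scripted repair phase
    shrinks the hole linearly after that time.  ``snr = inf`` disables the
    Poisson-Gaussian noise.
    """
    if n_frames < 6:
        raise ValueError("need at least 6 frames")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    n_px = int(round(fov_um / pixel_size_um))
    sigma_perp = truth.sigma_dv_over_e if direction == "AP" else truth.sigma_ap_over_e
    b_eq_um = 2.0 * sigma_perp * l_um
    if b_eq_um >= fov_um / 2.0 or l_um >= fov_um:
        raise ValueError("equilibrium opening or cut exceeds the field of view")

    # the cortex is a filled meshwork, not sticks on black: a diffuse base
    # plus a blurred filament field keeps inter-fiber dips well above the
    # hole level, as the soluble actin pool does in real movies
    from scipy.ndimage import gaussian_filter

    filaments = _render_filaments(
        rng, (n_px, n_px), pixel_size_um,
        mean_angle_deg=truth.texture_mean_deg, kappa=1.0,
        n_filaments=int(40 * (fov_um / 4.0) ** 2),
        width_px=max(0.05 / pixel_size_um, 0.5),
    )
    background = 0.8 + gaussian_filter(filaments, 0.3 / pixel_size_um)
    cut = CutROI(
        x_px=(n_px - 1) / 2.0, y_px=(n_px - 1) / 2.0,
        direction=direction, length_um=l_um,
    )
    times = t0_offset_s + np.arange(n_frames) * frame_interval_s
    frames = np.empty((n_frames, n_px, n_px))
    bg_mean = float(background.mean())
    for i, t in enumerate(times):
        b_um = b_eq_um - (b_eq_um - truth.y0_um) * np.exp(-truth.gamma_per_s * t)
        if reseal_at_s is not None and t > reseal_at_s:
            b_um = max(b_um * (1.0 - 0.15 * (t - reseal_at_s)), 0.0)
        cov = _ellipse_coverage(
            (n_px, n_px), cut.x_px, cut.y_px,
            semi_a_px=l_um / 2.0 / pixel_size_um,
            semi_b_px=b_um / 2.0 / pixel_size_um,
            angle_deg=cut.angle_deg,
        )
        frame = background * (1.0 - (1.0 - hole_floor) * cov)
        if np.isfinite(snr):
            gain = snr**2 / bg_mean
            frame = rng.poisson(np.clip(frame, 0, None) * gain) / gain
            frame = frame + rng.normal(0.0, 0.1 * bg_mean / snr, frame.shape)
        frames[i] = frame
    movie = AblationMovie(
        stack=frames, pixel_size_um=pixel_size_um,
        frame_interval_s=frame_interval_s, cut=cut, t0_offset_s=t0_offset_s,
    )
    return movie, truth


# ---------------------------------------------------------------------------
# texture patches


def gen_texture_patch(
    mean_angle_deg: float = 90.0,
    kappa: float = 4.0,
    n_filaments: int = 160,
    snr: float = 10.0,
    seed: int = 0,
    *,
    size_um: float = 4.0,
    pixel_size_um: float = 0.05,
    psf_sigma_um: float = 0.05,
) -> tuple[TexturePatch, GroundTruth]:
    """Square actin-texture patch of oriented filaments.

    Orientations are von Mises around ``mean_angle_deg`` with concentration
    ``kappa`` (kappa = 0 gives a uniform angular distribution); segments
    are anti-aliased with ~0.1 µm width, blurred by a Gaussian PSF, and
    degraded with Poisson-Gaussian noise at the stated SNR.  The default
    PSF width emulates deconvolved high-NA confocal stacks, which is what
    real texture analyses run on; a wider PSF leaves too thin a usable
    frequency annulus and the angular spectrum of a single 4-µm patch
    degenerates into speckle.
    """
    from scipy.ndimage import gaussian_filter

    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    rng = np.random.default_rng(seed)
    n_px = int(round(size_um / pixel_size_um))
    img = 0.1 + _render_filaments(
        rng, (n_px, n_px), pixel_size_um, mean_angle_deg, kappa, n_filaments,
        length_range_um=(1.0, 3.0), width_px=max(0.1 / pixel_size_um / 2.0, 0.8),
    )
    img = gaussian_filter(img, sigma=psf_sigma_um / pixel_size_um)
    if np.isfinite(snr):
        gain = snr**2 / float(img.mean())
        img = rng.poisson(np.clip(img, 0, None) * gain) / gain
        img = img + rng.normal(0.0, 0.1 * img.mean() / snr, img.shape)
    truth = GroundTruth(texture_mean_deg=mean_angle_deg, texture_kappa=kappa, seed=seed)
    return TexturePatch(image=img, pixel_size_um=pixel_size_um), truth


# ---------------------------------------------------------------------------
# paired cohorts


@dataclass
class SyntheticCohort:
    """Per-embryo noisy equilibrium openings with their generating truth."""

    openings: pd.DataFrame  # embryo, stage, cell, cut_direction, b_over_l
    truths: list[GroundTruth]
    n_embryos: int
    noise_cv: float
    seed: int

    def stage_truth(self, stage: str) -> GroundTruth:
        for t in self.truths:
            if t.stage == stage:
                return t
        raise KeyError(stage)

    def summarize(self) -> pd.DataFrame:
        """Cohort mean, SE and N per stage/cell/cut-direction."""
        g = self.openings.groupby(["stage", "cell", "cut_direction"])["b_over_l"]
        out = g.agg(["mean", "sem", "count"]).reset_index()
        return out.rename(columns={"mean": "b_over_l", "sem": "se", "count": "n_embryos"})

    def paired(self, stage: str) -> PairedOpenings:
        """Stage summary in the shape the stiffness inference consumes."""
        s = self.summarize()
        s = s[s["stage"] == stage]

        def pick(cell: str, cut: str) -> tuple[float, float]:
            row = s[(s["cell"] == cell) & (s["cut_direction"] == cut)]
            if row.empty:
                raise KeyError(f"no {cell} {cut}-cut openings at stage {stage}")
            return float(row["b_over_l"].iloc[0]), float(row["se"].iloc[0])

        h1_ap, h1_ap_se = pick("H1", "AP")
        h1_dv, h1_dv_se = pick("H1", "DV")
        hy_ap, hy_ap_se = pick("HYP7", "AP")
        hy_dv, hy_dv_se = pick("HYP7", "DV")
        return PairedOpenings(
            stage=stage,
            h1_ap_cut=h1_ap, h1_ap_cut_se=h1_ap_se,
            h1_dv_cut=h1_dv, h1_dv_cut_se=h1_dv_se,
            hyp7_ap_cut=hy_ap, hyp7_ap_cut_se=hy_ap_se,
            hyp7_dv_cut=hy_dv, hyp7_dv_cut_se=hy_dv_se,
        )


def gen_paired_cohort(
    stage_truths: list[GroundTruth] | None = None,
    n_embryos: int = 15,
    noise_cv: float = 0.10,
    seed: int = 0,
) -> SyntheticCohort:
    """Cohort of paired H1/HYP7 equilibrium openings across stages.

    Each embryo's four openings per stage come from the forward models
    (isotropic H1, fiber-reinforced HYP7, shared stresses) multiplied by
    independent mean-one lognormal noise of coefficient of variation
    ``noise_cv`` — openings are positive ratios, so the noise is
    multiplicative.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    if n_embryos < 1:
        raise ValueError("need at least one embryo")
    truths = default_stage_truths(seed) if stage_truths is None else stage_truths
    rng = np.random.default_rng(seed)
    sigma_ln = np.sqrt(np.log1p(noise_cv**2))
    rows = []
    for truth in truths:
        fwd = truth.forward_openings()
        cell_cut = [("H1", "AP", fwd["h1_ap_cut"]), ("H1", "DV", fwd["h1_dv_cut"]),
                    ("HYP7", "AP", fwd["hyp7_ap_cut"]), ("HYP7", "DV", fwd["hyp7_dv_cut"])]
        for embryo in range(n_embryos):
            for cell, cut, value in cell_cut:
                noise = (
                    rng.lognormal(-0.5 * sigma_ln**2, sigma_ln) if noise_cv > 0 else 1.0
                )
                rows.append(
                    dict(embryo=embryo, stage=truth.stage, cell=cell,
                         cut_direction=cut, b_over_l=value * noise)
                )
    return SyntheticCohort(
        openings=pd.DataFrame(rows), truths=truths,
        n_embryos=n_embryos, noise_cv=noise_cv, seed=seed,
    )


# ---------------------------------------------------------------------------
# embryo geometry

# Per-stage vessel geometry on the 25-µm embryo scale: spherical head early,
# prolate head at 1.7F, body narrowing as elongation proceeds.
DEFAULT_GEOMETRY: dict[str, dict[str, float]] = {
    "1.3F": {"R1_um": 12.5, "R2_um": 10.0, "a1_um": 12.5, "a2_um": 12.5},
    "1.5F": {"R1_um": 12.0, "R2_um": 9.0, "a1_um": 12.0, "a2_um": 12.0},
    "1.7F": {"R1_um": 11.0, "R2_um": 8.0, "a1_um": 14.0, "a2_um": 10.0},
}


def gen_embryo_geometry(
    stage_params: dict[str, dict[str, float]] | None = None,
    seed: int = 0,
    noise_cv: float = 0.0,
    measurement_se: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-stage geometry table plus the vessel-model 'measured' AS table.

    Returns ``(geometry, measured)``: geometry has stage, R1_um, R2_um,
    a1_um, a2_um; measured carries the head (H1) and body (V3) AS computed
    from that geometry by the vessel model, perturbed by mean-one lognormal
    noise of CV ``noise_cv``, with ``measurement_se`` attached — a
    closed-loop fixture for the predicted-vs-measured comparison.
    """
    params = DEFAULT_GEOMETRY if stage_params is None else stage_params
    rng = np.random.default_rng(seed)
    sigma_ln = np.sqrt(np.log1p(noise_cv**2)) if noise_cv > 0 else 0.0
    geo_rows, mea_rows = [], []
    for stage, g in params.items():
        for k in ("R1_um", "R2_um"):
            if g[k] <= 0:
                raise ValueError(f"{k} must be positive at stage {stage}")
        geo_rows.append(dict(stage=stage, **g))
        if g["a1_um"] > g["a2_um"]:
            vessel = AxisymmetricVessel(
                head=ProlateHead(a1=g["a1_um"], a2=g["a2_um"]), R2=g["R2_um"]
            )
        else:
            vessel = AxisymmetricVessel(head=SphereHead(R1=g["R1_um"]), R2=g["R2_um"])
        for cell, as_true in (
            ("H1", predict_AS_head(vessel)),
            ("V3", predict_AS_body(vessel)),
        ):
            noise = rng.lognormal(-0.5 * sigma_ln**2, sigma_ln) if sigma_ln else 1.0
            mea_rows.append(
                dict(stage=stage, cell=cell, AS_measured=as_true * noise,
                     AS_se=measurement_se)
            )
    return pd.DataFrame(geo_rows), pd.DataFrame(mea_rows)
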