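"""Quantification of ablation time-lapse movies: hole contour -> ellipse -> fit.

A laser line cut through the fluorescent actin cortex leaves a dark,
roughly elliptical hole that relaxes open over a few seconds and may later
reseal.  This module segments the hole in each frame, fits an ellipse,
builds the dimensionless opening series b(t)/l, finds the pre-repair
equilibrium opening (the mean of the last five time points before repair
begins), and fits the one-phase association law

    y(t) = y0 + (plateau - y0) * (1 - exp(-gamma * t))

whose plateau is the equilibrium minor axis and whose half-time is
ln(2)/gamma.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from matplotlib.path import Path as MplPath
from scipy.optimize import curve_fit
from scipy import ndimage
from skimage import measure, morphology
from skimage.filters import gaussian

__all__ = [
    "CutROI",
    "AblationMovie",
    "EllipseParams",
    "OpeningSeries",
    "RelaxationFit",
    "UnmeasurableFrame",
    "segment_opening",
    "fit_ellipse",
    "track_opening",
    "equilibrium_opening",
    "fit_relaxation",
]

VALIDATED_CUT_RANGE_UM = (3.0, 6.0)
DEFAULT_T0_OFFSET_S = 1.44  # first frame recorded this long after the cut


class UnmeasurableFrame(RuntimeError):
    """Raised when no dark opening can be segmented in a frame."""


@dataclass(frozen=True)
class CutROI:
    """Line-cut region: centre (pixel coords), direction, and length in µm."""

    x_px: float
    y_px: float
    direction: str  # "AP" | "DV"
    length_um: float

    def __post_init__(self) -> None:
        if self.direction not in ("AP", "DV"):
            raise ValueError("cut direction must be 'AP' or 'DV'")
        if self.length_um <= 0:
            raise ValueError("cut length must be positive")
        lo, hi = VALIDATED_CUT_RANGE_UM
        if not lo <= self.length_um <= hi:
            warnings.warn(
                f"cut length {self.length_um} µm outside the validated {lo}-{hi} µm range",
                stacklevel=2,
            )

    @property
    def angle_deg(self) -> float:
        """Cut direction vs the image x axis (AP horizontal by convention)."""
        return 0.0 if self.direction == "AP" else 90.0


@dataclass
class AblationMovie:
    """Time-lapse stack of an ablated cortex plus acquisition metadata."""

    stack: np.ndarray  # (T, H, W)
    pixel_size_um: float
    frame_interval_s: float
    cut: CutROI
    t0_offset_s: float = DEFAULT_T0_OFFSET_S

    def __post_init__(self) -> None:
        self.stack = np.asarray(self.stack, dtype=float)
        if self.stack.ndim != 3 or self.stack.shape[0] < 2:
            raise ValueError("stack must be (T, H, W) with at least two frames")
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ValueError("pixel size and frame interval must be positive")

    @property
    def times_s(self) -> np.ndarray:
        """Time of each frame after the cut (cut at t = 0)."""
        return self.t0_offset_s + np.arange(self.stack.shape[0]) * self.frame_interval_s


@dataclass(frozen=True)
class EllipseParams:
    """Fitted opening ellipse; axes are full axes in pixels.

    ``angle_deg`` is the major-axis orientation vs the image x axis in
    (-90, 90]; a circle reports 0 by convention.
    """

    xc: float
    yc: float
    a_px: float  # full major axis
    b_px: float  # full minor axis
    angle_deg: float

    def __post_init__(self) -> None:
        if not self.a_px >= self.b_px >= 0:
            raise ValueError("ellipse axes must satisfy a >= b >= 0")


@dataclass
class OpeningSeries:
    """Per-frame ellipse series of one movie, in µm-converted opening units."""

    frame: pd.DataFrame  # columns: time_s, a_px, b_px, angle_vs_cut_deg, measured
    cut: CutROI
    pixel_size_um: float

    @property
    def times_s(self) -> np.ndarray:
        return self.frame.loc[self.frame["measured"], "time_s"].to_numpy()

    @property
    def b_um(self) -> np.ndarray:
        return (
            self.frame.loc[self.frame["measured"], "b_px"].to_numpy() * self.pixel_size_um
        )

    @property
    def b_over_l(self) -> np.ndarray:
        return self.b_um / self.cut.length_um

    @property
    def a_over_l(self) -> np.ndarray:
        return (
            self.frame.loc[self.frame["measured"], "a_px"].to_numpy()
            * self.pixel_size_um
            / self.cut.length_um
        )


@dataclass(frozen=True)
class RelaxationFit:
    y0_um: float
    plateau_um: float
    gamma_per_s: float
    y0_se: float
    plateau_se: float
    gamma_se: float

    @property
    def t_half_s(self) -> float:
        return math.log(2.0) / self.gamma_per_s


def segment_opening(
    frame: np.ndarray,
    init_region: np.ndarray,
    *,
    smooth_sigma: float = 1.0,
    bg_window_px: int = 31,
    bridge_radius_px: int = 2,
    min_contrast: float = 0.5,
) -> np.ndarray:
    """Sub-pixel closed contour of the dark opening inside ``init_region``.

    The frame is smoothed and flat-fielded: a running median over a
    ``bg_window_px`` square (wider than any plausible opening, so hole
    pixels stay a minority in every window) estimates the local cortex
    background; the frame/background ratio is then contoured at the level
    halfway between the hole floor and the typical background ratio, the
    unbiased crossing of the blurred hole edge.  The largest closed
    iso-contour enclosing the init-region centroid is returned as an
    (N, 2) array of (row, col) points.  Deterministic given the frame,
    the init region and the settings.

    Raises
    ------
    UnmeasurableFrame
        if the region shows no dark hole (floor of the ratio image above
        1 - ``min_contrast``) or no closed contour encloses the centre.
    """
    frame = np.asarray(frame, dtype=float)
    init = np.asarray(init_region, dtype=bool)
    if frame.shape != init.shape or not init.any():
        raise ValueError("init_region must be a non-empty boolean mask of the frame")
    smoothed = gaussian(frame, sigma=smooth_sigma, preserve_range=True)

    def running_median(img: np.ndarray) -> np.ndarray:
        # the background is smooth: for wide windows estimate the running
        # median on a decimated grid and interpolate back
        ds = max(1, bg_window_px // 32)
        if ds > 1:
            from skimage.transform import resize

            bg_small = ndimage.median_filter(
                img[::ds, ::ds], size=max(bg_window_px // ds, 3)
            )
            return resize(bg_small, img.shape, order=1, mode="edge")
        return ndimage.median_filter(img, size=bg_window_px)

    def floor_and_level(ratio: np.ndarray) -> tuple[float, float]:
        hole_floor = float(np.percentile(ratio[init], 5))
        bg_typical = float(
            np.median(ratio[~ndimage.binary_dilation(init, iterations=3)])
        )
        # midway between hole floor and typical cortex ratio: the unbiased
        # crossing level of the blurred hole edge
        return hole_floor, 0.5 * (bg_typical + hole_floor)

    background = running_median(smoothed)
    ratio = smoothed / np.maximum(background, 1e-12)
    hole_floor, level = floor_and_level(ratio)
    # second pass: the hole itself drags the running median down near its
    # flanks, so re-estimate with hole pixels replaced by the first guess
    filled = np.where(ratio < level, background, smoothed)
    background = running_median(filled)
    ratio = smoothed / np.maximum(background, 1e-12)
    hole_floor, level = floor_and_level(ratio)
    bg_typical = 2.0 * level - hole_floor
    if bg_typical - hole_floor < min_contrast:
        raise UnmeasurableFrame("no dark opening: contrast below threshold")
    rows, cols = np.nonzero(init)
    cy, cx = float(rows.mean()), float(cols.mean())
    # keep only the dark component under the cut: a binary opening severs
    # thin dark bridges into the fibrous texture, then everything outside
    # the (slightly dilated) component is flattened to background so the
    # sub-pixel iso-contour wraps the hole alone
    dark_raw = ratio < level
    # a hole thinner than the opening disk would vanish: fall back to
    # smaller radii so early, narrow openings stay measurable
    for radius in range(bridge_radius_px, -1, -1):
        dark = (
            morphology.opening(dark_raw, morphology.disk(radius)) if radius else dark_raw
        )
        labels, _ = ndimage.label(dark)
        seed_labels = np.unique(labels[init & dark])
        seed_labels = seed_labels[seed_labels > 0]
        if len(seed_labels) > 0:
            break
    else:
        raise UnmeasurableFrame("no dark component under the cut after cleanup")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, seed_labels)
    component = labels == seed_labels[int(np.argmax(sizes))]
    zone = ndimage.binary_dilation(component, iterations=1 + bridge_radius_px)
    cleaned = np.where(zone, ratio, 1.0)
    best = None
    best_area = 0.0
    for contour in measure.find_contours(cleaned, level):
        if not np.allclose(contour[0], contour[-1]):
            continue
        path = MplPath(contour[:, ::-1])  # (x, y) order
        if not path.contains_point((cx, cy)):
            continue
        x, y = contour[:, 1], contour[:, 0]
        area = 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))
        if area > best_area:
            best, best_area = contour, area
    if best is None:
        raise UnmeasurableFrame("no closed contour encloses the cut centre")
    return best


def fit_ellipse(contour: np.ndarray, trim_fraction: float = 0.0) -> EllipseParams:
    """Least-squares ellipse fit of an (N, 2) (row, col) contour.

    Uses the algebraic conic fit constrained to an ellipse; exact on
    noiseless elliptical input.  With ``trim_fraction`` > 0 the fit is
    repeated twice after discarding that fraction of worst-residual points,
    which ignores small non-elliptical lobes (e.g. dark cortex pockets
    attached to the segmented hole).  A circle (a = b within 1e-9
    relative) reports angle 0 by convention.
    """
    contour = np.asarray(contour, dtype=float)
    if contour.ndim != 2 or len(contour) < 5:
        raise ValueError("need at least 5 contour points")
    xy = contour[:, ::-1]  # EllipseModel works in (x, y)
    model = measure.EllipseModel.from_estimate(xy)
    if not model:
        raise ValueError(f"degenerate contour: ellipse fit failed ({model})")
    if trim_fraction > 0:
        for _ in range(2):
            keep = int(np.ceil(len(xy) * (1.0 - trim_fraction)))
            if keep < 5:
                break
            residuals = np.abs(model.residuals(xy))
            xy = xy[np.argsort(residuals)[:keep]]
            refit = measure.EllipseModel.from_estimate(xy)
            if not refit:
                break
            model = refit
    (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    if not (np.isfinite(a) and np.isfinite(b)) or a <= 0 or b <= 0:
        raise ValueError("degenerate ellipse parameters")
    if b > a:
        a, b = b, a
        theta += math.pi / 2.0
    angle = math.degrees(theta) % 180.0
    if angle > 90.0:
        angle -= 180.0
    if abs(a - b) <= 1e-9 * a:
        angle = 0.0
    return EllipseParams(xc=xc, yc=yc, a_px=2 * a, b_px=2 * b, angle_deg=angle)


def _initial_region(movie: AblationMovie) -> np.ndarray:
    """Rectangular init mask around the cut segment, ~1 µm across."""
    h, w = movie.stack.shape[1:]
    yy, xx = np.mgrid[0:h, 0:w]
    half_l = movie.cut.length_um / 2.0 / movie.pixel_size_um
    half_w = max(0.25 / movie.pixel_size_um, 2.0)
    dx, dy = xx - movie.cut.x_px, yy - movie.cut.y_px
    ang = math.radians(movie.cut.angle_deg)
    along = dx * math.cos(ang) + dy * math.sin(ang)
    across = -dx * math.sin(ang) + dy * math.cos(ang)
    return (np.abs(along) <= half_l) & (np.abs(across) <= half_w)


def track_opening(
    movie: AblationMovie, *, max_unmeasured_fraction: float = 0.5
) -> OpeningSeries:
    """Segment and fit every frame, propagating the contour as the next seed.

    Unmeasured frames are carried as gaps (no interpolation); the series is
    rejected if more than half the frames are unmeasurable.
    """
    times = movie.times_s
    init = _initial_region(movie)
    records = []
    h, w = movie.stack.shape[1:]
    # one-pixel smoothing (noise control without widening the hole edge);
    # background window fixed in physical units, wider than any opening
    px = movie.pixel_size_um
    smooth_sigma = 1.0
    bg_window = int(round(3.2 / px)) | 1
    for t, frame in zip(times, movie.stack):
        try:
            contour = segment_opening(
                frame, init, smooth_sigma=smooth_sigma, bg_window_px=bg_window
            )
            ell = fit_ellipse(contour, trim_fraction=0.2)
            angle_vs_cut = (ell.angle_deg - movie.cut.angle_deg + 90.0) % 180.0 - 90.0
            records.append(
                dict(time_s=t, a_px=ell.a_px, b_px=ell.b_px,
                     angle_vs_cut_deg=angle_vs_cut, measured=True)
            )
            mask = np.zeros((h, w), dtype=bool)
            rr = np.clip(np.round(contour[:, 0]).astype(int), 0, h - 1)
            cc = np.clip(np.round(contour[:, 1]).astype(int), 0, w - 1)
            mask[rr, cc] = True
            from scipy.ndimage import binary_fill_holes

            filled = binary_fill_holes(mask)
            if filled is not None and filled.sum() >= 5:
                init = filled
        except (UnmeasurableFrame, ValueError):
            records.append(
                dict(time_s=t, a_px=np.nan, b_px=np.nan,
                     angle_vs_cut_deg=np.nan, measured=False)
            )
    frame_df = pd.DataFrame.from_records(records)
    n_bad = int((~frame_df["measured"]).sum())
    if n_bad > max_unmeasured_fraction * len(frame_df):
        raise ValueError(
            f"series rejected: {n_bad}/{len(frame_df)} frames unmeasurable"
        )
    return OpeningSeries(frame=frame_df, cut=movie.cut, pixel_size_um=movie.pixel_size_um)


def detect_repair_onset(
    series: OpeningSeries, *, smooth_n: int = 3, min_drop_fraction: float = 0.05
) -> float | None:
    """Time of repair onset, or None if the hole never reseals.

    Onset is the first frame starting three consecutive decreases of the
    running-mean-smoothed minor axis whose cumulative drop exceeds
    ``min_drop_fraction`` of the largest opening so far — the magnitude
    guard keeps measurement jitter from mimicking repair.
    """
    t = series.times_s
    b = series.b_um
    if len(b) < smooth_n + 3:
        return None
    kernel = np.ones(smooth_n) / smooth_n
    sb = np.convolve(b, kernel, mode="same")
    d = np.diff(sb)
    for i in range(len(d) - 2):
        run_drop = sb[i] - sb[i + 3]
        opened = float(np.max(sb[: i + 1])) > 1.02 * sb[0]
        if (
            opened
            and d[i] < 0 and d[i + 1] < 0 and d[i + 2] < 0
            and run_drop > min_drop_fraction * float(np.max(sb[: i + 1]))
        ):
            return float(t[i])
    return None


def equilibrium_opening(
    series: OpeningSeries, window_end_s: float = 10.0
) -> tuple[float, float, int]:
    """Equilibrium opening: mean b/l of the last five pre-repair time points.

    Frames after ``window_end_s`` or after the detected repair onset are
    excluded.  Returns ``(mean_b_over_l, se, n_frames)``.
    """
    t = series.times_s
    bl = series.b_over_l
    cutoff = window_end_s
    onset = detect_repair_onset(series)
    if onset is not None:
        cutoff = min(cutoff, onset)
    usable = t <= cutoff
    n = int(usable.sum())
    if n < 5:
        raise ValueError(
            f"only {n} usable frames before t = {cutoff:.2f} s; need >= 5"
        )
    last5 = bl[usable][-5:]
    return float(last5.mean()), float(last5.std(ddof=1) / math.sqrt(5)), 5


def fit_relaxation(series: OpeningSeries) -> RelaxationFit:
    """One-phase-association fit of the minor axis b(t) in µm.

    Requires >= 6 measured frames spanning at least two half-times of the
    fitted rate; gamma <= 0 or non-convergence is rejected with diagnostics.
    """
    t = series.times_s
    y = series.b_um
    if len(t) < 6:
        raise ValueError(f"need >= 6 measured frames, have {len(t)}")

    def model(t, y0, plateau, gamma):
        return y0 + (plateau - y0) * (1.0 - np.exp(-gamma * t))

    y0_guess = max(float(y[0]), 1e-6)
    plateau_guess = max(float(np.mean(y[-3:])), y0_guess * 1.01)
    gamma_guess = 0.5
    if np.ptp(y) < 1e-9 * max(abs(y).max(), 1e-12):
        raise ValueError("constant series: relaxation rate unidentifiable")
    try:
        popt, pcov = curve_fit(
            model, t, y, p0=(y0_guess, plateau_guess, gamma_guess), maxfev=20000
        )
    except RuntimeError as exc:  # pragma: no cover - scipy message passthrough
        raise ValueError(f"relaxation fit did not converge: {exc}") from exc
    y0, plateau, gamma = popt
    if gamma <= 0:
        raise ValueError(f"non-positive relaxation rate gamma = {gamma:.3g}")
    if plateau < y0:
        raise ValueError("fitted plateau below initial width: not a relaxation")
    span = t[-1] - t[0]
    if span < 2.0 * math.log(2.0) / gamma:
        raise ValueError(
            f"series spans {span:.2f} s < two half-times ({2 * math.log(2) / gamma:.2f} s)"
        )
    ses = np.sqrt(np.diag(pcov))
    return RelaxationFit(
        y0_um=float(y0), plateau_um=float(plateau), gamma_per_s=float(gamma),
        y0_se=float(ses[0]), plateau_se=float(ses[1]), gamma_se=float(ses[2]),
    )
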