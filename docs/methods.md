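# Methods

This note records the models, the numerical choices, and what the
synthetic data do and do not establish.

## Crack opening in a pre-stressed sheet

A laser line cut is modelled as a traction-free slit of length *l* in an
infinite plane-stress sheet under remote biaxial tension. For an isotropic
sheet the classical solution gives an elliptical opening profile with
maximum (minor axis) b = 2(σ_perp/E)·l; the scaled opening b/l is the
inference currency throughout because it is independent of *l*. Openings
are only meaningful for tensile perpendicular load — a compressive load
would close the slit and the linear crack model does not apply, so
negative loads raise errors rather than returning negative openings.

For an orthotropic sheet (axes AP = 1, DV = 2, compliance s₁₁, s₁₂, s₂₂,
s₆₆ with engineering shear), the opening of a slit along local axis 1
under σ₂₂ uses the classical orthotropic crack-opening factor

    H = sqrt(s₁₁′ s₂₂′ / 2) · sqrt( sqrt(s₂₂′/s₁₁′) + (2 s₁₂′ + s₆₆′)/(2 s₁₁′) )

in the crack-aligned frame, with b/l = 2 σ_perp H. H reduces exactly to
1/E in the isotropic limit for any Poisson ratio. Because the materials
here are orthotropic in the AP/DV frame and cuts are axis-aligned, frame
alignment is an index swap, not a general rotation.

H is not taken on trust: `embryomech.crack_fem` solves the slit-plate
problem directly — bilinear quadrilateral FEM on a geometrically graded
rectilinear mesh (tip element l/24, grading ratio 1.3, domain 20 l), slit
modelled by node duplication on its interior, remote stress applied as
consistent boundary tractions. On the isotropic case the centre opening is
within 2% of 2σl/E; closed form and FEM agree within 5% across random
positive-definite compliances and fiber-reinforced sheets (the acceptance
suite re-measures this).

## Fiber-reinforced constitutive model

The DV epidermis is an isotropic matrix (E₀, ν₀) with circumferential
fibers entering as a rank-one addition K·E₀ to the DV normal entry of the
plane-stress stiffness:

    Q = E₀/(1−ν₀²) · [[1, ν₀, 0], [ν₀, 1 + K(1−ν₀²)·…, 0], [0, 0, …]]   (schematically)

Inverting gives E_DV = 1/s₂₂ = E₀(1+K) exactly linear in K, and
E_AP = 1/s₁₁ = E₀(1+K)/(1+K(1−ν₀²)), monotone and concave with plateau
E₀/(1−ν₀²); the stiffness anisotropy is ω = E_DV/E_AP = 1+K(1−ν₀²). These
two signatures (linear fiber-direction modulus, saturating transverse
modulus) pin the constitutive family. The composite Poisson ratios that
enter the Hooke's-law forms are ν₁ = −s₁₂/s₂₂ = ν₀ and ν₂ = −s₁₂/s₁₁ =
ν₀/ω (reciprocity ν₁/E_DV = ν₂/E_AP holds by construction).

Cut-opening asymmetry: an AP-direction cut runs across the fibers and is
taken to destroy them locally, so its DV opening follows the isotropic law
with the bare matrix modulus E₀ and carries no information about K; a
DV-direction cut leaves the fibers intact and opens with the full
reinforced compliance through H(K), strictly decreasing in K. The plain
orthotropic comparison model applies the full compliance to both cut
directions (no severing asymmetry) and is provided for model comparison
only.

Parameters: ν₀ defaults to 0.5 (a 2-D incompressibility-leaning value; no
measured value exists, and every inference exposes it). The plotted
composite ν₁ = ν₂ = 1 appears only inside Hooke's-law strain formulas,
never in stiffness assembly, where ν = 1 is singular.

## Vessel model

Membrane equilibrium of an axisymmetric thin wall: σ_AP = (p/t)·r_circ/2
(meridional), σ_DV = σ_AP(2 − r_circ/r_merid) (hoop), so AS = 2 −
r_circ/r_merid depends on shape alone and the pressure scale cancels in
every AS output. The prolate head is evaluated at its equator (r_circ =
a₂, r_merid = a₁²/a₂ ⇒ AS = 2 − (a₂/a₁)², in (1, 2) for any a₁ > a₂); the
body is a straight cylinder (the bent-tube curvature correction is of
order R₂/bend radius and neglected); the body AS uses the constant-AP-
stress approximation anchored at the head equator, AS_body = 2R₂/r_circ
(head). The wall is thin (epidermis ~0.1–2 µm against a ~25 µm diameter),
so bending is ignored throughout.

## Movie quantification

Segmentation locates the dark ablation hole on a bright fibrous cortex
deterministically: Gaussian smooth (1 px), flat-field by a running median
(3.2 µm window, wider than any plausible opening; re-estimated once with
first-pass hole pixels masked, since the hole drags the median down near
its flanks), then a sub-pixel iso-contour of the frame/background ratio at
the level halfway between the hole floor (5th percentile under the cut)
and the typical background ratio — the unbiased crossing of a blurred
edge. A binary opening (disk radius 2 px, falling back to smaller radii
for thin early holes) severs dark inter-fiber bridges before the contour
is taken around the connected component under the cut. An intensity-based
active contour was tried first and rejected: on fibrous backgrounds the
darkness criterion alone merges the hole with inter-filament lakes, which
no contour regularisation reliably separates.

Ellipse fitting is the algebraic least-squares conic fit (exact on
noiseless elliptical input); during tracking the fit is repeated twice
with the worst-residual 20% of contour points discarded, which ignores
small non-elliptical lobes where dark cortex pockets touch the hole.
Frames without a measurable hole are carried as gaps (no interpolation);
a series with more than half its frames unmeasurable is rejected.

The equilibrium opening is the mean of the last five measured frames no
later than 10 s after the cut and before the detected repair onset. Onset
detection: three consecutive decreases of the 3-frame running mean whose
cumulative drop exceeds 5% of the largest opening so far, and only after
the series has risen above its initial width — the two guards keep
measurement jitter, and relaxations that approach equilibrium from above
(b_eq < y₀), from being mistaken for repair. A consequence is that repair
following a shrinking relaxation is not detected; such series do not occur
in the cohorts modelled here.

Relaxation kinetics use the one-phase association y(t) = y₀ +
(plateau−y₀)(1−e^{−γt}) fitted by nonlinear least squares on the measured
minor axis, requiring at least six frames spanning two half-times;
non-convergent fits, γ ≤ 0, and plateaus below y₀ are rejected with
diagnostics. t_1/2 = ln2/γ.

## Stress and stiffness inference

σ/E = (b/l)/2 per direction; AS is the ratio of the AP-cut (DV-direction)
to the DV-cut (AP-direction) opening with a delta-method standard error
(chosen over bootstrap for determinism; both openings positive). Group
comparisons are Welch two-tailed t-tests on per-embryo equilibrium means —
the embryo, not the frame, is the sampling unit — and two-sided Z-tests
with pooled SE for derived AS values; identical zero-variance groups short-
circuit to p = 1.

The matrix modulus ratio E₀_HYP7/E_H1 is the reciprocal slope of a
through-origin regression of HYP7 on H1 DV-direction (AP-cut) openings:
both cells share σ_DV by tension continuity across their junction, and the
AP cut severs HYP7's fibers so both respond with bare matrix moduli. The
origin is forced because zero stress must open neither cell.

K inversion: the HYP7 AP-cut opening fixes σ_DV/E₀; the seam-cell AS
transfers σ_AP/E₀ (stress continuity — the single strongest modelling
assumption here); the DV-cut opening then determines K through 2(σ_AP/E₀)
·E₀H(K) by Brent root finding on [0, 10³] (H monotone ⇒ unique root;
relative tolerance 10⁻⁹). Openings implying K < 0 or no root are reported
as inconsistent with the fiber-reinforced model rather than clamped.
Standard errors propagate through the inverse by central finite
differences. ω = 1+K(1−ν₀²) follows in closed form.

Detection of ω > AS is a statistical power question: with cohorts of 20
embryos and 10% multiplicative noise, the point-estimate comparison
reports ω > AS in ≈96% of replicates at the benchmark scenario (K = 4,
AS = 1.6) and ≈93% at a narrower relative margin (AS = 1.8) — the
flatness of H(K) at large K makes K̂, and hence ω̂, heavy-tailed.

## Texture analysis

Patches are Hann-windowed, FFT'd, and the power outside the
high-pass radius (default 1 cycle/µm) and inside Nyquist is binned into 45
four-degree orientation bins (bin centers at odd multiples of 2°, so 90° —
the DV axis — is a bin center), after rotating spectral angles by 90° so
reported angles are real-space orientations. Two corrections matter on a
4×4 µm patch: (i) bin weights are lattice-density corrected, since whole
frequency-lattice lines fall on the axis bins and would over-populate
them; (ii) each frequency ring is equalized to its mean power before
binning, restricted to rings clearing 3× the noise floor estimated from
the outer quarter of the pass band (all rings count if none clear it, so a
pure-noise patch stays flat). Without equalization the surviving annulus
of a small patch offers only a handful of independent speckle cells per
bin and orientation recovery fails; with it, the circumferential peak and
the mean direction are stable, at the cost of weighting all signal radii
equally rather than by raw power.

The DV-peak statistic sums the angular weight inside 90°±8°, with bins
partially covered by the window contributing their overlap fraction — a
flat spectrum gives exactly 16/180 regardless of binning and a delta at
90° gives 1. Single-patch direction estimates carry 4–12° of intrinsic
sampling-plus-speckle noise depending on concentration; analyses should
average over patches, as the cohort comparisons here do.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of (settings, seed) — reruns are
bit-identical.

Ablation movies render a dark ellipse (supersampled coverage, sharp edge)
whose minor axis follows b(t) = b_eq − (b_eq−y₀)e^{−γt} on a cortex built
from oriented filaments over a diffuse base (the soluble actin pool),
blurred at 0.3 µm; Poisson-Gaussian noise at the stated SNR; first frame
1.44 s after the cut; optional scripted linear resealing. Defaults: γ =
0.4 s⁻¹, y₀ = 0.6 µm (for scenarios whose equilibrium opening is below
0.6 µm, y₀ = 0.7·b_eq — a thinner initial cut — keeps the kinetics
physical), 0.1 µm/px, cut lengths 3–6 µm with a warning outside that
range. Texture patches draw filament orientations from a von Mises
distribution folded to [0, π) (κ = 0 ⇒ uniform), render anti-aliased
segments ~0.1 µm wide, blur with a 0.05 µm PSF — the deconvolved-confocal
scale at which angular analysis of a 4 µm patch is feasible — and add the
same noise model. Cohorts draw, per embryo and stage, the four openings
from the isotropic (H1) and fiber-reinforced (HYP7) forward models under
shared stresses, times mean-one lognormal noise of CV 0.10 (openings are
positive ratios, so the noise is multiplicative; the CV is a package
choice matched to typical cohort scatter). Stage defaults: AS rising
1.0 → 1.5 → 1.8, σ_DV/E_H1 rising 0.055 → 0.075 → 0.100, K rising
0.6 → 2 → 4 (so ω = 1.45 → 2.5 → 4 always exceeds AS), matrix ratio 1.5.
Geometry tables sit on the 25 µm embryo scale with a spherical head early
and a prolate head (14 × 10 µm) at the last stage.

What passing tests do not show: the renders have no photobleaching, drift,
z-sectioning, muscle twitching, or wound-healing biology; the cortex
texture is statistically stationary; opening noise is independent across
cuts, whereas real paired cuts share per-embryo factors. Recovery results
therefore validate the inference machinery under the stated noise model,
not the microscopy itself, and the original study's in-vivo numbers are
not reproducible from synthetic data.

## Problem sizes and tolerances

The in-silico opening-law grid runs l ∈ {3,…,6} µm × σ/E ∈ {0.02, 0.06,
0.10} with pixel size matched to the expected opening (px = b_eq/10,
capped at 0.1 µm — magnification matched to the measurement, as an
experimenter would) and 3 replicate movies per condition (6 when b_eq <
0.3 µm, where single-fiber edge noise dominates); recovery is within 5%
per condition with no cut-length dependence. The FEM oracle uses the mesh
above (~10⁴ degrees of freedom, seconds per solve). Recovery studies use
200 replicate cohorts (600 for the ω > AS detection frequency, a binomial
proportion near its threshold) of 20 embryos. Test-suite and acceptance
runs complete in a few minutes each on one core.
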