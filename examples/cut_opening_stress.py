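"""From laser-cut openings to cortical stress and its anisotropy.

A line cut of length l through a pre-tensed isotropic cortex relaxes into
an ellipse whose minor axis is b = 2 (sigma_perp / E) l.  The scaled
opening b/l therefore reads out stress over stiffness directly, and the
ratio of the openings of two orthogonal cuts gives the anisotropy of
stress AS = sigma_DV / sigma_AP with the unknown modulus cancelled.
"""

from embryomech import (
    CellOpeningRecord,
    anisotropy_of_stress,
    compare_AS_ztest,
    opening_isotropic,
    stress_from_opening,
)

# forward: a cortex under sigma_DV/E = 0.06, cut 5 um along AP
op = opening_isotropic(load_perp=0.06, l=5.0)
print(f"cut 5 um, sigma/E = 0.06  ->  opening b = {op.b_um:.2f} um (b/l = {op.b_over_l:.3f})")

# inverse: a measured equilibrium opening back to stress
rec_ap = CellOpeningRecord("H1", "1.7F", "AP", b_over_l=0.20, se=0.012, n_embryos=15)
rec_dv = CellOpeningRecord("H1", "1.7F", "DV", b_over_l=0.11, se=0.010, n_embryos=15)
est = stress_from_opening(rec_ap)
print(f"AP cut opened b/l = {rec_ap.b_over_l:.2f}  ->  sigma_{est.direction}/E = "
      f"{est.sigma_over_E:.3f} +- {est.se:.3f}")

# the anisotropy of stress from the pair of cuts in the same cell
res = anisotropy_of_stress(rec_ap, rec_dv)
print(f"AS({res.cell}, {res.stage}) = {res.AS:.2f} +- {res.se:.2f}  "
      "(DV stress exceeds AP stress when AS > 1)")

# is this cell's AS different from an isotropic AS = 1 reference?
z, p = compare_AS_ztest(res.AS, res.se, 1.0, 0.05)
print(f"Z-test vs isotropic reference: z = {z:.2f}, p = {p:.2g}")
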