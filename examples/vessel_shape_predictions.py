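"""Predicting the stress anisotropy from embryo geometry alone.

The embryo is modelled as a pressurised thin-wall vessel: a spherical or
prolate head joined to a cylindrical body.  Membrane equilibrium makes the
DV/AP stress ratio a pure function of shape - 1 on a sphere, 2 on a
cylinder, 2 - (a2/a1)^2 at a prolate equator - so diameters measured under
the microscope predict the anisotropy that laser ablation measures.
"""

import math

from embryomech import (
    AxisymmetricVessel,
    ProlateHead,
    SphereHead,
    hooke_isotropic_strains,
    membrane_stresses,
    predict_AS_body,
    predict_AS_head,
)

print("membrane stress anisotropy of canonical shapes:")
print(f"  sphere:   AS = {membrane_stresses(12.5, 12.5).AS:.2f}")
print(f"  cylinder: AS = {membrane_stresses(12.5, math.inf).AS:.2f}")

late_head = ProlateHead(a1=14.0, a2=10.0)
vessel = AxisymmetricVessel(head=late_head, R2=8.0)
print(f"  prolate head (a1 = 14, a2 = 10 um): AS = {predict_AS_head(vessel):.2f}")

early = AxisymmetricVessel(head=SphereHead(R1=12.5), R2=10.0)
print(f"body next to a 12.5-um spherical head, R2 = 10 um: "
      f"AS_body = {predict_AS_body(early):.2f}")

# what those stresses do to an isotropic seam cell (contractile, 2-D):
for AS in (1.0, 1.5, 2.0):
    eps_ap, eps_dv = hooke_isotropic_strains(0.1, AS, nu=1.0)
    print(f"  seam cell at sigma_AP/E = 0.1, AS = {AS}: "
          f"eps_AP = {eps_ap:+.3f}, eps_DV = {eps_dv:+.3f}")
print("(AS > 1 elongates the cell along AP while narrowing it along DV)")
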