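"""Dose-volume metrics of a conformal dose on a spherical phantom.

Builds a 15 mm-radius spherical target with a 20 mm prescription isodose
shell, computes the standard coverage and sparing quantities, and prints
them.  V_xGy is the structure volume receiving at least x Gy (percent or
cm³); D_p% is the minimum dose received by the best-covered p % of the
structure.
"""

from dprfeas import CohortConfig, DoseGrid, StructureSet, d_percent, rasterize_ellipsoid, v_dose
from dprfeas.synthetic import make_plan_dose

config = CohortConfig(spacing=2.0)
grid = config.grid()
target = rasterize_ellipsoid((0, 0, 0), (15, 15, 15), grid)
ptv = rasterize_ellipsoid((0, 0, 0), (20, 20, 20), grid)
oar = rasterize_ellipsoid((0, -32, 0), (8, 8, 30), grid)  # rectum-like tube

anatomy = StructureSet({"prostate": target, "ptv_psv": ptv, "rectum": oar})
dose = make_plan_dose(anatomy, config)

print(f"target V_36.25Gy = {v_dose(dose, target, 36.25, 'rel'):6.1f} %   "
      "(fraction of the target covered by the prescription)")
print(f"PTV    V_36.25Gy = {v_dose(dose, ptv, 36.25, 'rel'):6.1f} %")
print(f"PTV    D_98%     = {d_percent(dose, ptv, 98.0):6.2f} Gy  "
      "(dose to the coldest 2 % of the PTV)")
print(f"rectum V_36Gy    = {v_dose(dose, oar, 36.0, 'abs'):6.2f} cm3 "
      "(near-prescription dose spilling into the rectum)")
print(f"rectum V_18.1Gy  = {v_dose(dose, oar, 18.1, 'rel'):6.1f} %   "
      "(half-prescription bath)")
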