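"""Fit a Kriging response surface to virtual measurements and locate its
optimum.

Measures an 80-point space-filling design on the virtual instrument (the
default ground-truth enzyme with KCl and fructose-1,6-bisphosphate
activation bumps), fits the GP surrogate with GCV-chosen smoothing and
ML-tuned per-axis length scales, and reports the surface optimum.  The
predicted optimum location should sit near the simulator's true optimum
(KCl 90.6 mM, Fru 4.1 mM, pH approximately 6.85 at 1 mM PEP).
"""
from autoassay import (Axis, GroundTruth, ModulatorEffect, ParameterSpace,
                       fit_surface, measure_design, space_filling_design,
                       surface_optimum)

space = ParameterSpace((Axis("pH", 4.75, 9.2),
                        Axis("KCl", 0.0, 266.6),
                        Axis("Fru", 0.0, 10.0)))
truth = GroundTruth(
    modulators=[ModulatorEffect("KCl", c_opt=90.6, width=1.2, floor=0.05),
                ModulatorEffect("Fru", c_opt=4.1, width=0.9, floor=0.05)],
)
design = space_filling_design(space, n=80, seed=2)
table = measure_design(truth, design, seed=2)
print(f"measured {len(table)} wells; activity range "
      f"{table.activity_mU.min():.3f} - {table.activity_mU.max():.3f} mU")

model = fit_surface(space, design.conditions, table["activity_mU"])
print(f"GCV smoothing {model.smoothing:.3g}, "
      f"length scales {dict(zip(space.names, model.lengthscales.round(2)))}")

cond, pred = surface_optimum(model, maximize=True, seed=0)
print("surface optimum (predicted best assay conditions):")
for k, v in cond.values.items():
    print(f"  {k:4s} = {v:.2f}")
print(f"  predicted activity {pred.mean:.3f} +/- {pred.se:.3f} mU")
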