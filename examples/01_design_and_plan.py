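"""Generate a space-filling design and turn it into pipettable well plans.

Builds the three-axis buffer-optimization space (pH, KCl, fructose
1,6-bisphosphate), draws a 20-point maximin Latin-hypercube design, and
converts the first few conditions into per-well volumes for the standard
225 ul reaction mixture.  The printed volumes are what a liquid-handling
worklist would dispense; water always fills the well exactly to 225 ul.
"""
import numpy as np

from autoassay import (Axis, ParameterSpace, StockComponent,
                       plan_mixture_volumes, space_filling_design,
                       synthetic_buffer_calibration, buffer_fraction_for_pH)

space = ParameterSpace((Axis("pH", 4.75, 9.2),
                        Axis("KCl", 0.0, 266.6),
                        Axis("Fru", 0.0, 10.0)))
design = space_filling_design(space, n=20, seed=1)
print(f"{len(design)}-point space-filling design over {space.names}")

stocks = [
    StockComponent("KCl", stock_conc=2000.0, max_volume=30.0),
    StockComponent("Fru", stock_conc=56.25, max_volume=40.0),
    StockComponent("PEP", stock_conc=40.0, max_volume=45.0),
    StockComponent("NADH", stock_conc=14.0625, fixed_volume=10.0),
    StockComponent("buffer", stock_conc=50.0, fixed_volume=62.5),
]
cal = synthetic_buffer_calibration()

print("\nfirst three wells:")
for cond in design.conditions[:3]:
    targets = {"KCl": cond.values["KCl"], "Fru": cond.values["Fru"],
               "PEP": 1.0}
    try:
        plan = plan_mixture_volumes(stocks, targets, end_volume=225.0)
    except Exception as e:   # sub-pipettable volumes near the axis origin
        print(f"  {cond.id}: skipped ({e})")
        continue
    frac = buffer_fraction_for_pH(cal, cond.values["pH"])
    vols = ", ".join(f"{k}={v:.1f}ul" for k, v in plan.volumes.items())
    print(f"  {cond.id}: pH {cond.values['pH']:.2f} "
          f"(basic-buffer fraction {frac:.2f}); {vols}, "
          f"water={plan.water:.1f}ul (total {plan.end_volume:.0f}ul)")
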