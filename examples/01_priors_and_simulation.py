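"""Load the 58-parameter prior table and simulate a 1 g oral dose.

The prior table carries the 21 originally calibrated metabolism/elimination
parameters and the 37 physiological parameters that were historically fixed.
The simulation prints plasma concentrations (mg/L) of acetaminophen and its
glucuronide/sulfate conjugates at the standard sensitivity-analysis times.
"""

import numpy as np

import pbpkgsa as pg

table = pg.load_prior_table()
print(f"{len(table)} priors: {len(table.subset('original'))} original, "
      f"{len(table.subset('additional'))} additional\n")
print(table.to_frame().head(8).to_string(index=False), "\n")

params = pg.build_default_parameters(table)
res = pg.simulate(params, pg.DoseSpec(1000.0), np.asarray(pg.GSA_TIMES))
print("plasma concentrations (mg/L) after a 1,000 mg oral dose:")
print(res.plasma.round(3).to_string())
print("\nAPAP falls over ~6 h while the conjugates peak near 1.5-2 h and "
      "decline as they are cleared renally.")
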