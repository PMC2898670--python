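#!/usr/bin/env python
"""Oscillatory regions of the variant circuits.

1. Generalized non-competitive model at Delta=1 (equal degradation rates):
   a trimeric activator (n=3) rescues oscillations that dimers cannot
   produce, and higher repressor multimerization m widens the region.
2. Effective Atkinson model (competition with quartic DNA-loop occupancy,
   n=m=4, Delta=10): sharper nonlinearity, yet a much smaller oscillatory
   region than the non-competitive dimer circuit.
3. Smolen-type circuit (both genes read one competitively regulated
   promoter, monomer repressor): oscillates at Delta=4 in its own corner
   of parameter space, not at Delta=1, and never with a monomer activator.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from oscirc.models import ModelParams
from oscirc.sweep import oscillatory_fraction, smolen_sweep, sweep_2d

ap = argparse.ArgumentParser()
ap.add_argument("--points", type=int, default=30)
ap.add_argument("--out", default="results")
args = ap.parse_args()
out = Path(args.out)
out.mkdir(parents=True, exist_ok=True)
n = args.points
beta = np.geomspace(1e-2, 1e1, n)
gamma = np.geomspace(1e-3, 1e0, n)
report = {}

print("generalized non-competitive circuit, Delta=1, n=3:")
for m in (1, 2, 3):
    fixed = ModelParams(alpha=50, delta_ratio=1, sigma=1, n=3, m=m)
    pm = sweep_2d("GENERALIZED_III", fixed, beta, gamma)
    pm.to_csv(out / f"periodmap_GENERALIZED_III_n3_m{m}.csv")
    frac, count = oscillatory_fraction(pm)
    report[f"generalized_n3_m{m}"] = {"fraction": frac, "cells": count}
    print(f"  m={m}: {count} oscillatory cells (fraction {frac:.3f})")
pm = sweep_2d("GENERALIZED_III", ModelParams(alpha=50, delta_ratio=1, sigma=1, n=2, m=2),
              beta, gamma)
frac, count = oscillatory_fraction(pm)
report["generalized_n2_delta1"] = {"fraction": frac, "cells": count}
print(f"  n=2 control: {count} cells — dimers cannot oscillate at Delta=1")

atk = sweep_2d("ATKINSON_COMP", ModelParams(alpha=50, delta_ratio=10, sigma=1, n=4, m=4),
               beta, gamma)
atk.to_csv(out / "periodmap_ATKINSON_COMP.csv")
iii = sweep_2d("DESIGN_III", ModelParams(alpha=50, delta_ratio=10, sigma=1), beta, gamma)
fa, ca = oscillatory_fraction(atk)
f3, c3 = oscillatory_fraction(iii)
report["atkinson"] = {"fraction": fa, "cells": ca, "design_iii_fraction": f3}
print(f"\nAtkinson full-competition (n=m=4): fraction {fa:.3f} vs "
      f"non-competitive dimer circuit {f3:.3f} — competition shrinks the "
      "region even with stronger nonlinearity")

print("\nSmolen-type shared-promoter circuit:")
for D in (4.0, 1.0):
    pm = smolen_sweep(delta_ratio=D,
                      beta_grid=np.geomspace(1e-1, 1e2, n),
                      gamma_grid=np.geomspace(1e-2, 1e1, n))
    pm.to_csv(out / f"periodmap_SMOLEN_D{D:g}.csv")
    frac, count = oscillatory_fraction(pm)
    report[f"smolen_D{D:g}"] = {"fraction": frac, "cells": count}
    print(f"  Delta={D:g}: {count} oscillatory cells")
mono = smolen_sweep(delta_ratio=4.0, n=1,
                    beta_grid=np.geomspace(1e-1, 1e2, max(n // 2, 10)),
                    gamma_grid=np.geomspace(1e-2, 1e1, max(n // 2, 10)))
frac, count = oscillatory_fraction(mono)
report["smolen_monomer"] = {"fraction": frac, "cells": count}
print(f"  monomer activator (n=1): {count} cells — a dimer activator is required")

(out / "variant_circuits.json").write_text(json.dumps(report, indent=2))
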