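#!/usr/bin/env python
"""Period maps over (beta, gamma) for the competitive (Design I) and
non-competitive (Design III) circuits at the reference condition
alpha=50, Delta=10, sigma=1 — the headline comparison.

Writes results/periodmap_DESIGN_{I,III}.csv and a comparison JSON; prints
the oscillatory fractions and period/amplitude distribution summaries.
Default grid 40x40 (pass --points 60 for the full-resolution map).
"""

import argparse
import json
from pathlib import Path

import numpy as np

from oscirc.models import ModelParams
from oscirc.sweep import compare_designs, plot_map, sweep_2d

ap = argparse.ArgumentParser()
ap.add_argument("--points", type=int, default=40)
ap.add_argument("--out", default="results")
ap.add_argument("--plots", action="store_true")
args = ap.parse_args()

out = Path(args.out)
out.mkdir(parents=True, exist_ok=True)
fixed = ModelParams(alpha=50, delta_ratio=10, sigma=1)
beta = np.geomspace(1e-2, 1e1, args.points)
gamma = np.geomspace(1e-3, 1e0, args.points)

maps = []
for design in ("DESIGN_I", "DESIGN_III"):
    m = sweep_2d(design, fixed, beta, gamma, progress=True)
    m.to_csv(out / f"periodmap_{design}.csv")
    if args.plots:
        plot_map(m, out / f"periodmap_{design}.png")
    maps.append(m)

rep = compare_designs(maps)
(out / "periodmap_comparison.json").write_text(json.dumps(rep, indent=2))

f1 = rep["DESIGN_I"]["fraction"]
f3 = rep["DESIGN_III"]["fraction"]
print(f"\noscillatory fraction: competitive {f1:.3f} vs non-competitive {f3:.3f} "
      f"({f3 / f1:.1f}x larger without promoter competition)")
print(f"period spread P95/P5: competitive {rep['DESIGN_I']['period']['spread']:.2f} "
      f"vs non-competitive {rep['DESIGN_III']['period']['spread']:.2f}")
print(f"activator amplitude P95: competitive {rep['DESIGN_I']['amp_x']['p95']:.1f} "
      f"vs non-competitive {rep['DESIGN_III']['amp_x']['p95']:.2f}")
print("-> avoiding transcription-factor competition at the activator promoter "
      "widens the oscillatory region and confines period and amplitude.")
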