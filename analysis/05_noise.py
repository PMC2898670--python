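#!/usr/bin/env python
"""Intrinsic-noise behaviour near the deterministic oscillation boundaries.

Each design is parked just outside its own oscillatory region at
gamma=0.05 (the competitive circuit past its saddle-node exit, the
post-translational and non-competitive circuits just below their Hopf
entries), realised as a molecule-count jump process, and simulated
exactly.  Noise induces oscillations in all three, but with different
fingerprints: broad, long-tailed inter-peak intervals for the competitive
(excitable) circuit; a narrow distribution at the deterministic focus
frequency for the non-competitive one; the post-translational design in
between.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from oscirc.bifurcation import _bisect_stability_edge, _resolve_factory
from oscirc.models import ModelParams
from oscirc.stochastic import build_network, noise_induced_analysis, ssa_run

ap = argparse.ArgumentParser()
ap.add_argument("--omega", type=float, default=500.0)
ap.add_argument("--runs", type=int, default=50)
ap.add_argument("--t-end", type=float, default=200.0)
ap.add_argument("--seed", type=int, default=0)
ap.add_argument("--out", default="results")
args = ap.parse_args()
out = Path(args.out)
out.mkdir(parents=True, exist_ok=True)

base = dict(alpha=50.0, delta_ratio=10.0, sigma=1.0, gamma=0.05)
fac1 = _resolve_factory("DESIGN_I", "beta", ModelParams(**base))
fac2 = _resolve_factory("DESIGN_II", "beta",
                        ModelParams(**base, sigma_prime=1.0))
fac3 = _resolve_factory("DESIGN_III", "beta", ModelParams(**base))

snic = _bisect_stability_edge(fac1, 1.2, 0.8)
hopf2 = _bisect_stability_edge(fac2, 0.05, 0.3)
hopf3 = _bisect_stability_edge(fac3, 0.1, 0.3)
models = {
    "DESIGN_I": fac1(snic * 1.01),
    "DESIGN_II": fac2(hopf2 * 0.99),
    "DESIGN_III": fac3(hopf3 * 0.99),
}
print("sub-threshold operating points:",
      {k: round(m.params.beta, 4) for k, m in models.items()})

rep = noise_induced_analysis(models, omega=args.omega, n_runs=args.runs,
                             seed=args.seed, t_end=args.t_end)
for label, model in models.items():
    tr = ssa_run(build_network(model, omega=args.omega), t_end=args.t_end,
                 seed=args.seed + 1)
    pd.DataFrame({"tau": tr.t, "X": tr.X, "Y": tr.Y}).to_csv(
        out / f"ssa_{label}.csv", index=False)
    r = rep[label]
    print(f"{label}: {r['n_intervals']} noise-induced peaks, "
          f"interval CV {r['period_cv']:.3f}, tail index P95/P50 {r['tail_index']:.2f}")

(out / "noise_comparison.json").write_text(json.dumps(rep, indent=2))
print("\n-> all three circuits oscillate under intrinsic noise; the "
      "competitive one is unreliable in period (long tail), the "
      "non-competitive one keeps its characteristic frequency.")
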