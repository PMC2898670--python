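#!/usr/bin/env python
"""Waveform fingerprints at the printed comparison point
(alpha=50, Delta=11, beta=1.58, gamma=0.079).

Both designs oscillate here, but the competitive circuit — just past its
saddle-node onset — produces giant relaxation pulses, while the
non-competitive one cycles smoothly at small amplitude and its own
characteristic frequency.  Writes the two time series and a summary.
"""

import json
from pathlib import Path

import pandas as pd

from oscirc.dynamics import classify_asymptotics, integrate
from oscirc.models import make_model, to_hours

out = Path("results")
out.mkdir(exist_ok=True)
kw = dict(alpha=50, beta=1.58, gamma=0.079, delta_ratio=11, sigma=1)

summary = {}
for design in ("DESIGN_I", "DESIGN_III"):
    model = make_model(design, **kw)
    tr = integrate(model, t_end=100.0)
    pd.DataFrame({"tau": tr.t, "x": tr.x, "y": tr.y}).to_csv(
        out / f"timeseries_{design}.csv", index=False)
    s = classify_asymptotics(model)
    summary[design] = {
        "verdict": s.verdict, "period": s.period,
        "period_hours_at_dR_0.02": to_hours(s.period, 0.02),
        "amplitude_x": s.amplitude_x, "spikiness": s.spikiness,
    }
    print(f"{design}: {s.verdict}, period {s.period:.2f} (1/delta_R units), "
          f"x amplitude {s.amplitude_x:.2f}, smoothness {s.spikiness:.3f}")

(out / "timeseries_summary.json").write_text(json.dumps(summary, indent=2))
r = summary["DESIGN_I"]["amplitude_x"] / summary["DESIGN_III"]["amplitude_x"]
print(f"\n-> competitive pulses are {r:.0f}x larger in amplitude and far less "
      "sinusoidal (smoothness "
      f"{summary['DESIGN_I']['spikiness']:.2f} vs "
      f"{summary['DESIGN_III']['spikiness']:.2f}; 1 = pure sine).")
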