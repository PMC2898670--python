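# oscirc

**Does transcription-factor competition at a promoter help or hurt a genetic
oscillator?**  `oscirc` is an analysis package for the simplest two-gene
relaxation oscillator — an activator **A** driving itself and a repressor
**R**, with **R** feeding back on **A** — in which the *implementation* of
the negative feedback is the design variable:

| design | mechanism | activator production term |
|---|---|---|
| I | A and R compete for one promoter site | β(1+αx²)/(1+x²+σy²) |
| II | R catalyses degradation of A | β(1+αx²)/(1+x²), loss x(1+σ′y) |
| III | separate sites, no competition | β(1+αx²)/[(1+x²)(1+σy²)] |

In nondimensional form (x, y scaled by DNA-binding constants, time by the
repressor degradation rate δ_R, Δ = δ_A/δ_R):

    dx/dτ = Δ [ β f(x,y) − x L(y) ],    dy/dτ = Δγ (1+αxⁿ)/(1+xⁿ) − y

with α the promoter fold-activation, β, γ the transcription–translation
strengths, and σ the relative repressor affinity.  Three variants reuse the
machinery: a generalized non-competitive model with free Hill exponents
(n-mer activator, m-mer repressor), an effective DNA-looping construct
(competition with n = m = 4), and a shared-promoter circuit with an
autoregulated monomer repressor.

The package maps where each family oscillates in (β, γ), classifies how
oscillations are born and die along one-parameter scans (supercritical /
subcritical Hopf vs saddle-node-on-circle, from eigenvalue crossings,
amplitude/period scaling laws, equilibrium collisions and hysteresis
evidence), and simulates exact molecule-count (Gillespie) counterparts to
compare intrinsic-noise behaviour.  The headline result it reproduces:
**avoiding competition widens the oscillatory region severalfold and trades
the competitive design's giant, irregular pulses for a confined amplitude
and a characteristic frequency** — robustly, both deterministically and
under molecular noise.

## Worked example

```python
import numpy as np
from oscirc import ModelParams, make_model, classify_asymptotics, sweep_2d, \
                   compare_designs

# the printed comparison point: alpha=50, Delta=11, beta=1.58, gamma=0.079
for design in ("DESIGN_I", "DESIGN_III"):
    m = make_model(design, alpha=50, beta=1.58, gamma=0.079,
                   delta_ratio=11, sigma=1)
    s = classify_asymptotics(m)
    print(design, s.verdict, round(s.period, 2), round(s.amplitude_x, 2),
          round(s.spikiness, 3))

ref = ModelParams(alpha=50, delta_ratio=10, sigma=1)
maps = [sweep_2d(d, ref, np.geomspace(1e-2, 1e1, 24), np.geomspace(1e-3, 1, 24))
        for d in ("DESIGN_I", "DESIGN_III")]
rep = compare_designs(maps)
print({d: round(rep[d]["fraction"], 3) for d in rep})
```

prints

```
DESIGN_I sustained 6.77 74.66 0.069
DESIGN_III sustained 1.67 1.31 0.268
{'DESIGN_I': 0.111, 'DESIGN_III': 0.181}
```

— both designs oscillate at this point, but the competitive circuit fires
74-units-high relaxation pulses (smoothness 0.07; 1.0 would be a pure
sine) with a 6.8 period, while the non-competitive one cycles smoothly at
amplitude 1.3; and across the (β, γ) plane the non-competitive design
oscillates over 1.6x the area.  Periods are in units of 1/δ_R:
at δ_R = 0.02 h⁻¹ a characteristic period of ~1.7 is ~86 hours
(`to_hours`).

## The analysis

Numbered drivers under `analysis/` rebuild the full study and write their
tables under `results/`:

1. `01_period_maps.py` — (β, γ) period maps and the region/period/amplitude
   comparison between Designs I and III.
2. `02_bifurcation_routes.py` — β- and Δ-scans with classified transitions:
   Hopf-bounded non-competitive bands (damped "gray" flanks, onset
   β_c ≈ 0.225 at the γ = 0.01 cross-section) vs saddle-node exits of the
   competitive design.
3. `03_time_series.py` — the pulse-like vs sinusoidal waveform contrast.
4. `04_variant_circuits.py` — generalized Hill exponents at Δ = 1, the
   quartic DNA-looping competition model, and the shared-promoter circuit.
5. `05_noise.py` — exact SSA ensembles near each design's oscillation
   boundary: noise-induced oscillation with long-tailed intervals for the
   competitive design, a preserved characteristic period for the
   non-competitive one.

A thin CLI mirrors these: `oscirc sweep|bifurcation|simulate|noise-compare|
reproduce-figure {3,4,5,6,7,9,10}`.

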