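# rushquant

Tools for studying how **newly synthesized integrins** reach the cell surface
and what their delivery does to cell–matrix adhesions. The package serves two
kinds of users: modelers who want a stochastic **motor-clutch simulation** of
adhesion growth under increased integrin availability, and microscopists who
want a reproducible quantification pipeline for **RUSH-release trafficking
movies** (adhesion recruitment, pHluorin exocytosis detection with a spatial
null, protrusion/retraction polarity, micropattern enrichment) — plus a
synthetic-data generator that produces all of these inputs with exact ground
truth, so the whole pipeline is testable without microscope data.

## The model

Myosin motors pull actin rearward with speed
`v = v0 (1 − ΣF/(n_m F_stall))`, loading integrin "clutches" that bind free
substrate sites at rate `k_on · d_int` and unbind with a catch–slip law
`k_off(F) = k_c0 e^(−F/F_c) + k_s0 e^(F/F_s)`. Talin in each engaged clutch
unfolds with Bell kinetics `k_u(F) = k_u0 e^(F/F_u)`; every unfolding event
is an adhesion-reinforcement event that raises the integrin density by
`d_add`, up to a hard cap of 3× the initial density. Only growth is modeled,
so the normalized density trace starts at 1, never decreases and never
exceeds the cap. Increased delivery of new integrins enters through `d_add`
alone: high availability (`d_add = 0.01` integrins/µm²) predicts faster
adhesion growth than low (`0.005`).

## Worked example

```python
import numpy as np
from rushquant import clutch as cl

high = cl.simulate_many(cl.ClutchParams(d_add=0.01), 50, base_seed=100)
low  = cl.simulate_many(cl.ClutchParams(d_add=0.005), 50, base_seed=100)
for name, traces in [("high", high), ("low", low)]:
    finals = [tr.normalized_density[-1] for tr in traces]
    print(f"d_add {name}: final density {np.mean(finals):.2f} +/- {np.std(finals):.2f}")
```

prints

```
d_add high: final density 2.20 +/- 0.11
d_add low: final density 1.58 +/- 0.06
```

i.e. after 30 simulated minutes the adhesion (tracked as integrin density
normalized to its starting value) has grown to ~2.2× under high integrin
availability versus ~1.6× under low — the model's core prediction that
delivery of new receptors drives adhesion growth.

The imaging pipeline runs the same way from Python or the shell:

```bash
rushquant synth tirf --seed 7 --out scene/          # flash movie + truth
rushquant detect-exo --movie scene/tirf.tif --seed 7 --out scene/exo/
```

`detect-exo` divides each frame by the previous, segments high-ratio spots
into exocytosis events, and compares their nearest-adhesion distances with
uniformly random points in the cell; `scene/exo/distance_result.json` holds
the group means and the unpaired t-test p-value. Other subcommands:
`simulate`, `quantify-adhesions`, `polarity`, `pattern-profile`, `metrics`.

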