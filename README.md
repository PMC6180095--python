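# playfall

Playground surfacing is certified by dropping an instrumented hemispherical
headform (4.6 kg) and requiring a Head Injury Criterion below 1000 and a
peak resultant linear acceleration below 200 g from the surface's *critical
height*. Those thresholds were inherited from adult automotive research, and
children of different ages respond very differently to the same fall.
`playfall` is a toolkit for studying exactly that question: it evaluates
impact kinematics the way the testing standards do, simulates headform drops
onto hysteretic rubber surfacing with a fast reduced-order model, turns
tissue fields into injury metrics, and runs the cross-age statistics needed
to argue for age-dependent playground injury thresholds. It is aimed at
injury-biomechanics researchers and surfacing engineers.

## What it computes

**Head Injury Criterion.** For a resultant linear acceleration a(t) in g,

    HIC = max_{t1<t2} (t2 - t1) * [ 1/(t2-t1) * ∫_{t1}^{t2} a(t) dt ]^2.5

maximized exactly over all ordered sample pairs (trapezoid integration).
HIC15 and HIC36 cap t2 − t1 at 15 / 36 ms; the playground standard uses the
unlimited window. Before HIC the trace is filtered with a 2-pole Butterworth
applied forwards and backwards (zero phase) at 2077.5 Hz; peak kinematics
use a 180 Hz cutoff.

**Headform drop model.** A single-degree-of-freedom drop m·ẍ = m·g − F(x, ẋ)
onto a rubber layer with loading force F = scale·σ(x/h)·A(x), spherical-cap
contact area A, and energy-based hysteretic unloading
s = 1 − (1 − hu)·(1 − W/W_max)^shape (hu = 0.5, shape = 2.0 by default),
integrated with fixed-step RK4. The *critical height* (drop height where
HIC = 1000) is found by bracketing and bisection on the monotone
height–HIC response; material families are anchored by calibrating their
stress scale to a target HIC at a target height.

**Tissue metrics.** MPS — the 95th percentile over brain elements of each
element's peak 1st principal Green–Lagrange strain (0.3 ≈ 50% mild-TBI
risk) — and peak von-Mises skull stress.

**Age statistics.** Direction spreads 100·(max − min)/max, direction
averages with range bars, linear/exponential age regressions with R² on the
original scale, the linear HIC–MPS relation and its evaluation at a strain
threshold, and ratio-rule scaling of the HIC = 1000 reference into
age-dependent thresholds.

**Synthetic data.** Seeded generators for direction-dependent impact
pulses, per-age kinematics tables with linear age trends anchored to
published landmark values, and element strain fields with an exact target
percentile.

## Worked example

```python
from playfall import (Headform, SurfaceLayer, baseline_material,
                      scale_material, find_critical_height, height_to_velocity)

head, layer = Headform(), SurfaceLayer()        # 4.6 kg, R=0.08 m, 0.10 m tile
base = baseline_material()                      # calibrated rubber family

print(f"impact velocity from 1.59 m: {height_to_velocity(1.59):.2f} m/s")
for name, factor in [("stiff x5", 5.0), ("baseline", 1.0), ("soft x0.2", 0.2)]:
    r = find_critical_height(scale_material(base, factor), head, layer)
    print(f"{name:9s}: critical height {r.height:.2f} m (HIC {r.hic_at_height:.0f})")
```

prints

```
impact velocity from 1.59 m: 5.59 m/s
stiff x5 : critical height 1.15 m (HIC 995)
baseline : critical height 1.59 m (HIC 1002)
soft x0.2: critical height 2.24 m (HIC 1001)
```

i.e. a fall from 1.59 m onto the baseline tile just meets the HIC = 1000
criterion (5.59 m/s impact), a five-fold stiffer tile only protects up to
1.15 m, and a five-fold softer one up to 2.24 m — softer surfacing buys
fall height, stiffer surfacing loses it.

The same pipeline is scriptable from the shell (`playfall metrics`,
`playfall drop`, `playfall critical-height`, `playfall tissue`,
`playfall age-report`, `playfall synth ...`).

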