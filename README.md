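# casyn

Tools for studying how the **bound calcium pool** of the presynapse shapes
synaptic transmission: a coupled short-term-plasticity / calcium-buffering
model with its closed-form steady state, and the analysis pipeline for
correlative NanoSIMS ion imaging and fluorescence microscopy (layer
alignment, disc-ROI quantification, ⁴⁶Ca/⁴⁰Ca enrichment, trace metrics,
and the accompanying statistics).

Most intracellular Ca²⁺ is not free but bound to buffer proteins and
organelles. Fluorescent indicators see only the free pool; ion
micro-imaging of embedded samples sees only the bound pool (free ions are
washed out during preparation). `casyn` provides both halves of the
analysis such experiments need: quantifying bound Ca²⁺ in ion images at
synaptic regions of interest, and a model that links buffer capacity to
vesicle release.

## The model

Vesicle dynamics follow the canonical depression/facilitation scheme with
drive R (Hz), readily releasable fraction x, release probability u and
synaptic weight w = u·x:

    dx/dt = (1 − x)/τ_d − u·x·R
    du/dt = (U − u)/τ_f + U(1 − u)·R,   U(c) = 2/(1 + e^(−c/λ)) − 1

The baseline release probability U saturates in free calcium c, and free
and bound calcium (c, b) exchange through a buffer of capacity B:

    dc/dt = −c/τ_c − λ_cb(B − b)c + λ_bc·b + μR
    db/dt = −b/τ_b + λ_cb(B − b)c − λ_bc·b

Under constant drive the fixed point is closed-form: c* solves a quadratic
(solved in a cancellation-free formulation, stable root selected by a
dynamical sign test), and u*, x*, w* follow algebraically. See
`docs/methods.md` for the full derivation, parameter table and numerical
choices.

## Worked example

Steady state and buffer-size predictions at the reference parameters
(τ_d = 0.2 s, τ_f = 1.5 s, τ_c = 100 s, τ_b = 10⁴ s, λ_cb = 200,
λ_bc = 30, μ = 0.001, λ = 1, R = 20 Hz):

```python
import numpy as np
from casyn import ModelParams, steady_state_full, sweep_weight_curves

p = ModelParams(B=200.0, mu=0.001, lam=1.0)
ss = steady_state_full(p, R=20.0)
print(f"c*={ss.c_star:.4f} b*={ss.b_star:.2f} "
      f"u*={ss.u_star:.4f} x*={ss.x_star:.4f} w*={ss.w_star:.4f}")

res = sweep_weight_curves(p, [50, 100, 200, 400, 800],
                          np.geomspace(0.1, 200, 40))
print(res.summary)
```

prints

```
c*=0.4778 b*=152.22 u*=0.9047 x*=0.2165 w*=0.1959
       B     w_max      R_max
0   50.0  0.353529   7.279801
1  100.0  0.307522   8.846292
2  200.0  0.252007  10.749867
3  400.0  0.199708  13.063058
4  800.0  0.159440  19.289833
```

At 20 Hz a 200-unit buffer binds 152 units of calcium (76% occupied),
leaving c* ≈ 0.48 free; release probability is facilitated to u* ≈ 0.90,
which depletes the releasable pool to x* ≈ 0.22. The sweep shows the
model's predictions: larger buffers lower the peak synaptic weight w_max
(0.35 → 0.16 across this range) and push the rate R_max that attains it
upward (7.3 → 19.3 Hz).

The same functionality is exposed on the command line (`casyn simulate`,
`casyn steady`, `casyn sweep`, `casyn align`, `casyn ratio`, `casyn roi`,
`casyn traces`, `casyn stats`, `casyn synth`); every image/table input has
a synthetic generator with recorded ground truth under `casyn synth`.

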