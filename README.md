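# spindlescale

Spindle elongation scales with cell size during early *C. elegans*
development; chromosome segregation barely does. This package implements
the computational side of that observation for researchers studying
mitotic scaling: a stoichiometric model of cortical pulling forces that
simulates anaphase spindle elongation in spherical cells, stage-wise
inference of the microtubule catastrophe rate, and the quantification
layer used around such data — sigmoid/exponential trajectory fits,
kymograph peak readout, laser-ablation velocity windows, and
electron-tomography microtubule classification — together with synthetic
generators for every input, so the whole pipeline runs without any
external data.

## The model in brief

Two asters nucleate microtubules at rate `n_dot = N_T λ` (growth velocity
`V_g`, catastrophe rate `λ`). Cortical motors bind at most one
microtubule each; the bound fraction at cortical point `Y` engaged with
aster `i` evolves as

    ∂P_i/∂t = Ω_i (1 − P_1 − P_2) − κ P_i,
    Ω_i = N_T λ (r² / 4 d_i²) e^(−λ d_i / V_g),

and pulls pole `i` with `F_i = (M f₀ / A) ∫ P_i ξ̂ dA`. Pole motion
balances cytoplasmic drag `η` and a viscous pole–chromosome coupling `ν`
along the spindle axis `ŝ`:

    η ẋ_i + ν ((ẋ_i − ċ_i)·ŝ) ŝ = F_i,

with chromatid separation imposed as `Δc(t) = c_f (1 − e^(−t/τ))`
(`c_f = 6.2` µm, `τ = 29` s). Per developmental stage only the cell
radius, the initial pole separation and `λ` change; `λ` is inferred by
differential evolution against a target pole-to-pole trajectory.
Trajectories are summarised by `FLPP = L1 + L2` and
`ERPP = (L2/4τ_s)·60` µm/min from the sigmoid fit, and `FLCC = a`,
`SRCC = (a/k)·60` µm/min from the exponential fit. See
`docs/methods.md` for the full account.

## Worked example

Simulate the 2-cell configuration, fit both traces, and infer the
catastrophe rate back from the simulation's own output:

```python
import spindlescale as ss

traj = ss.simulate_spindle(ss.STAGE_TABLE[2])      # R=23 um, D0=13 um, lambda=0.038
sig = ss.fit_sigmoid(traj)
exp = ss.fit_exponential(traj)
print(f"final spindle length {sig.flpp:.2f} um, "
      f"final chromosome separation {exp.flcc:.2f} um, k = {exp.k:.1f} s")

de = ss.DEConfig(seed=1, population_size=20, max_generations=16)
res = ss.fit_catastrophe_rate(traj, ss.STAGE_TABLE[2], de, search_n_patches=256)
print(f"recovered catastrophe rate {res.lambda_hat:.4f} 1/s")
```

prints

```
final spindle length 21.18 um, final chromosome separation 6.20 um, k = 29.0 s
recovered catastrophe rate 0.0382 1/s
```

The spindle elongates from 13 to ~21 µm and plateaus; the chromosome
trace is the imposed saturating exponential, so the fit returns its 29 s
time constant; and the optimiser recovers the generating catastrophe rate
from the trajectory alone.

The same operations are exposed on the command line:

```bash
spindlescale simulate --stage 2 --out traj.csv
spindlescale synth atlas --seed 1 --out atlas/
spindlescale quantify --traj atlas/trajectories.csv --meta atlas/metadata.csv --out cells.csv
```

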