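# angiodyn

Simulation and dynamical-systems analysis of a five-compartment ODE model
of solid-tumour growth with angiogenesis.

## The problem

A solid tumour cannot grow beyond a harmless avascular mass unless it
recruits its own blood supply.  This package implements a minimal
Lotka–Volterra-type model of that process in a single organ: normal cells
`C` and their pre-existing vasculature (epithelial cells `E`) sit at a
logistic steady state; a mutation event converts an amount `Cm` of normal
cells into tumour cells `T`; tumour cells induce sprouts
(pre-angiogenesis cells `P`) from the existing vessels, which mature into a
new, tumour-owned vasculature `A` that in turn feeds tumour growth.  For
`t > 0`:

    dC/dt = α₁C(1 − C/k₁) − β₁CT − μ₁C
    dE/dt = α₂E(1 − E/k₂) − γET − μ₂E
    dT/dt = α₃AT(1 − T/k₃) − β₂CT − μ₃T
    dP/dt = γET − (δ + μ₄)P
    dA/dt = δP + εTA(1 − A/k₄) − μ₅A

with the pulse initial condition `(C₀ − Cm, E₀, Cm, 0, 0)` from the
cancer-free equilibrium `(C₀, E₀, 0, 0, 0)`.  The model is bistable: the
cancer-free state is always locally stable, and a vascularised-tumour state
coexists with it over wide parameter ranges.  Whether a pulse regresses or
progresses is decided by which side of the break-point's stable manifold
(the separatrix) it starts on.

The package answers, quantitatively and reproducibly:

* **Which steady states exist?**  Non-trivial tumour levels are the roots
  of a quartic balance `f(T) = g₁(T) + g₂(T)` inside
  `(0, min(TE, TA))`, subject to positivity bounds
  `TC = (α₁−μ₁)/β₁`, `TE = (α₂−μ₂)/γ`, `TA = k₃` and
  `Tg = α₁μ₃/(β₁β₂k₁) + TC` (`equilibria` module).
* **Are they stable?**  5×5 Jacobian spectra, and a generalised
  diagonal-dominance (M-matrix) certificate for the displaced state with
  `C = 0` (`stability` module).
* **Where are the tipping points?**  Saddle-node folds in `β₂`, `γ`, `ε`;
  the displacement value `β₁c` where tumour cells exclude the normal
  tissue; the oscillation window in `γ` (Hopf onset by eigenvalue
  crossing, cycle exit by simulation); basin-of-attraction boundaries by
  bisection on RK4 trajectories (`bifurcation` + `simulate` modules).

## Worked example

```python
import angiodyn as ad

params = ad.load_preset("fixed")        # benchmark parameter values
points = ad.find_cancer_equilibria(params)
for pt in points:
    rep = ad.stability_report(params, pt)
    print(pt.label, tuple(round(v, 2) for v in pt.coords), rep.classification)
```

prints

```
small (8.92, 9.85, 0.08, 0.07, 0.71) unstable
big (5.32, 2.64, 3.68, 0.88, 1.96) stable_focus
```

i.e. a break-point with a tiny tumour load `T = 0.08` cells per unit
volume (unstable, leading eigenvalue `+0.028`/day) and a full tumour state
`T = 3.68` (a stable focus).  Simulating the mutation pulse
(`examples/01_pulse_simulation.py`):

```
pulse Cm = 1.023: final state (C=9.00, E=10.00, T=0.0000, P=0.00, A=0.00)  [no onset]
pulse Cm = 1.024: final state (C=5.32, E=2.64, T=3.6805, P=0.88, A=1.96)  [onset at 421 days]
```

a one-in-a-thousand difference in the initial number of mutated cells
decides between full repair and a relapse to cancer after ~400 days of
dormancy.  The `examples/` directory has one short script per capability
(pulse simulation, equilibria and stability, thresholds and the
oscillation window, basin boundaries), and the same operations are exposed
on the command line:

```bash
angiodyn equilibria --preset fixed
angiodyn threshold --param beta2 --lo 0.04 --hi 0.06
angiodyn basin --cm-lo 0.5 --cm-hi 2.0 --tol 1e-3 --full-c0
angiodyn reproduce
```

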