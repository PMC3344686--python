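# Methods

## Model

Five well-mixed compartments (concentrations in cells per arbitrary unit
volume, time in days): normal cells `C`, epithelial cells of the
pre-existing vasculature `E`, tumour cells `T`, pre-angiogenesis sprouts
`P`, and new (tumour-induced) vasculature `A`.  `C` and `E` grow
logistically and are independent of each other; tumour growth is
proportional to the new vasculature (`α₃AT(1−T/k₃)`) and suppressed by
normal cells (`β₂CT`); sprouting moves mass from nowhere into `P` at rate
`γET` (the epithelial pool is reduced through its own `γET` term), and
sprouts mature into functional vessels at rate `δ`, so `1/δ` is the mean
vascularisation delay and `δ/(δ+μ₄)` the probability a sprout ever
matures.  The model deliberately omits space, oxygen/nutrient transport,
immune response and treatment; carrying capacities are constants.

Cancer initiation is a pulse: at `t = 0` an amount `Cm` of normal cells is
re-assigned to the tumour compartment,
`(C(0), E(0), T(0), P(0), A(0)) = (C₀−Cm, E₀, Cm, 0, 0)`.  The pulse is
implemented as an initial condition, not as a forcing term — for `t > 0`
the system is autonomous.  When `Cm > C₀` the normal cells are left at
`C₀` (the organ cannot supply more cells than it has); a `full_c0` flag
additionally supports the convention `C(0) = C₀` for any `Cm`, in which
the mutated cells arrive "on top of" an undisturbed organ.  Several of
the benchmark basin boundaries for the `fixed` preset are only consistent
with that convention (the baseline boundary is 1.0240 with `C(0)=C₀`
versus 0.9716 with `C(0)=C₀−Cm`), while the `alternative`-preset
boundaries match the subtractive pulse; the reproduction suite uses the
convention under which each benchmark run is reproducible, and both are
exposed in the API.

## Steady states

Setting the derivatives to zero and eliminating `C`, `E`, `P`, `A` leaves
`f(T) = g₁(T) + g₂(T)` with `f` of degree 4 and `g₁+g₂` of degree 3 (the
balance of the `A` equation after substituting the other four).  The
residual `f − g` is negative at `T = 0` (value `−g₀ < 0`) and at
`Tm = min(TE, TA)`, so inside the feasibility interval there are 0 or 2
roots: the break-point `T<` and the tumour state `T>`.  Roots are located
by evaluating the residual on a uniform grid of 10⁴ points over
`(10⁻¹²·Tm, Tm(1−10⁻⁹))` and refining each sign change by bisection to
relative tolerance 10⁻¹²; a unit test checks the bracket set against a
10⁶-point scan for the benchmark preset and 20 random ±20% perturbations.
Roots closer than `10⁻⁶·Tm` are flagged as a degenerate (fold) pair;
roots within `10⁻⁹·Tm` of a feasibility bound are flagged as boundary
cases rather than silently kept.  Feasibility comparisons are strict
(`T < bound`).

Degenerate limits: at `γ = 0` the quartic side vanishes and the cubic
factors as `h(T)·q(T)` with `q` quadratic — the quadratic roots are the
vasculogenic equilibria (with `P = 0` and `E` at its cancer-free value),
and the factor root `T = Tg` is recorded but always infeasible (it implies
`C < 0`).  At `ε = 0` the shared factor `(k₃−T)` is divided out.  At
`δ → ∞` the survival factor `δ/(μ₄+δ)` in `f` is dropped; the coordinates
use `Ē` from the general relations with `P̄ = 0` (the actual limit).  The
displaced state with `C = 0` solves the same balance with the
normal-cell term removed from the vessel relation, which makes its tumour
level independent of `β₁`; it is the continuation of the tumour branch
past `β₁c = (α₁−μ₁)/T̄` and is reported infeasible below that.

## Stability

At interior equilibria the Jacobian is assembled in the balance-reduced
form (diagonal entries collapse to pure self-limitation terms); at the
cancer-free state, where that reduction is invalid, the exact partial
derivatives are used, and a test verifies both forms agree at the roots.
Eigenvalues come from `numpy.linalg.eigvals`.  Classification: unstable if
max Re λ > 10⁻⁸/day, marginal within ±10⁻⁸, otherwise a stable node or
(with a complex pair) focus.  The tolerance sits below the ~10⁻⁷/day real
parts that occur next to the oscillation onset.

For the displaced state the 4×4 `(E,T,P,A)` block (negated) is certified
stable without eigenvalues by constructing a positive diagonal scaling `D`
that makes `AD` strictly diagonally dominant.  The admissible scaling
interval is `0 < φ < φn/φd`; `φ` is taken at the midpoint.  `φn` is
linear in `ε` at fixed equilibrium, so the certificate threshold
`ε_min` is obtained by solving `φn(ε) = 0` directly (equivalent to, and
more robust than, the quadratic-form expression of the certificate).  The
certificate is sufficient only; eigenvalues remain the authoritative
classifier, and a test checks the implication (certificate ⇒ Hurwitz
block) and that the certificate fails at the break-point.  Whether
`Ā` is above or below `k₄` (an assumption of the certificate's
derivation) is recorded in the report rather than branched on silently.

## Simulation

Classical fixed-step RK4, default `dt = 0.01` day, default horizon 5000
days (transients of interest run to ~1000 days; near-separatrix
classification retries at 20000 days).  The last step is shortened to land
exactly on `t_end`.  No adaptive control: determinism and the absence of
step-size hysteresis matter more here than efficiency, and the error is
audited by step halving (final-state change < 10⁻⁶).  Components in
`[−10⁻⁹, 0)` are clipped to zero (polynomial right-hand sides can
undershoot at a finite step); anything below −10⁻⁹ aborts, as does any
component exceeding 10⁶·max(k).  The inner loop is numba-compiled
(~3×10⁶ steps/s on one core) with an identical pure-Python fallback.

**Attractor verdicts** use the final 20% of the time span: a trajectory is
assigned to a candidate equilibrium if it stays within `10⁻³·max(k)` of it
over that whole window; it is a limit cycle if the tumour component keeps
oscillating with peak-to-peak amplitude > 10⁻³ and a window-to-window
amplitude ratio in [0.99, 1.01]; otherwise it is undecided and should be
integrated longer.  Within ~10⁻⁴ of the oscillation onset the cycle's
settling time exceeds 10⁵ days, so verdicts there need near-equilibrium
starts and long horizons (the reproduction tests use 2×10⁶ days for the
just-past-onset check).

**Onset time** is the first upward crossing of `T` through `0.5·T̄>` — an
operational convention (onset is conventionally read off trajectory
plots); a pulse that starts above the threshold, dips and relapses is
timed at the relapse.

## Continuation and special points

All detectors are bisections with relative tolerance 10⁻⁶ (≤80
iterations):

* **Saddle-node folds** (`β₂th`, `γth`, `εth` at `γ=0`): the root pair
  exists iff the interior maximum of `f − g` over `(0, Tm)` is positive,
  so the fold is bisected on the sign of that maximum and the collision
  `T` is the polished maximiser.  This stays exact arbitrarily close to
  the fold, where sign-change root counting fails.
* **Displacement values**: `β₁c` bisects the crossing `T>(β₁) = TC(β₁)`
  (cross-checked in a test against the `β₁`-independent displaced root);
  `β₁A` bisects `T>(β₁) = Tg(β₁)` (where the new vasculature would reach
  zero).
* **Oscillation onset** `γ1c`: sign change of the leading complex
  eigenvalue pair's real part along the tumour branch.
* **Cycle exit** `γ2c`: the spectrum has *no* second crossing — the
  branch stays weakly unstable well past the window — so the death of the
  stable cycle is a global bifurcation.  It is located by bisecting the
  simulated verdict (limit cycle vs regression) of a standard pulse
  (`Cm = 0.42`, 20000 days).  The quoted resolution is therefore
  limited by the verdict horizon: very close to the exit, transient
  oscillations can outlive any fixed horizon.
* **Basin boundaries**: bisection on `Cm` between verified endpoints,
  then snapped onto the `Cm`-grid of the requested resolution (endpoint
  verdicts re-verified) so brackets read like conventionally quoted ones,
  e.g. (1.023, 1.024).

## Presets, problem sizes and limitations

The two packaged presets are the benchmark parameter tables: `fixed`
(tumour capacities comparable to the host's, chosen to make the structure
visible) and `alternative` (tumour/vessel capacities 50- and 5-fold
smaller — the more realistic relative scale; α₃, ε, μ₃, γ rescaled
accordingly).  Default problem sizes — 10⁴-point root grids, 61-point
Hopf scan, `dt = 0.01` with 5000–20000-day horizons — were chosen so the
full reproduction (all thresholds plus seven basin boundaries) runs in
about a minute on one core; halving `dt` or lengthening horizons changes
no reported bracket.

What the analysis does and does not show: every quantity refers to this
ODE model at the packaged presets.  The model has no spatial structure,
no immune surveillance, no treatment, constant carrying capacities, and a
deterministic pulse initiation; reproducing its thresholds says nothing
about the calibration of those rates to any real tissue.  Two benchmark
reference values for the saddle-node folds (`β₂th` with its collision
level, and `γth`) are internally inconsistent with the model's own root
balance — the faithful computation places the folds at `β₂ = 4.8047×10⁻²`
(collision at `T = 0.842`) and `γ = 5.4275×10⁻⁴` — and the reference
`γ2c = 2.5161×10⁻²` is likewise inconsistent with the simulated cycle
exit at `2.5198×10⁻²`; the reproduction report flags these rather than
matching them.
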