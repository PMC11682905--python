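# Methods

## Model structure

Neutrophil formation is modeled per clone as a chain of ordinary
differential equations: one hematopoietic stem cell (HSC) compartment,
`n = 15` progenitor/precursor (HPC) stages and one mature neutrophil
(PMN) compartment, all in cells per kg of body weight. Division is
described by a proliferation rate `p_i` and a self-renewal probability
`a_i` — the probability that a daughter cell remains in its parent's
compartment; `1 − a_i` is the probability of moving to the next stage.
Only the HSC compartment self-renews indefinitely; a progenitor stage
with `a < 1/2` passes an incoming cell flux on amplified by
`r(a) = 2(1 − a)/(1 − 2a)`. Mature cells are cleared at `d = 2.3/day`
(7–8 h blood half-life). Per-liter blood values convert to per-kg values
with the fixed anthropometry 5 l blood / 80 kg (1 cell/l = 1/16 cell/kg).

Two regulatory signals, both first-order Hill functions, close the
feedback loops: a systemic signal `s_sys = 1/(1 + k_sys·M)` of the total
mature count (the endogenous G-CSF axis) and a niche signal
`s_niche = 1/(1 + k_niche·H)` of the total HSC count. Three variants
route the signals: `baseline` (everything systemic), `niche_selfrenewal`
(HSC self-renewal follows the niche) and
`niche_selfrenewal_proliferation` (HSC self-renewal and proliferation
follow the niche). HPC properties always follow the systemic signal.
The qualitative conclusions are variant-independent (tested).

Responses to a signal `x`:

* HSC self-renewal `a_0(x) = clip(a_max·x, 0, 1)` with `a_max = 1`.
* HPC self-renewal (equivalently progenitor amplification)
  `a(x) = clip(a_hom + β (x − s*), 0, 0.99)`.
* proliferation `p(x) = p_hom · g(x)` with `g` piecewise linear,
  `g(s*) = 1`, `g(1) = 4` (the measured ~4-fold cytokine-stimulated
  increase) and a floor of 0.25 below the operating point.

## Calibration

Gains are fixed at `k_sys = 1/M*`, `k_niche = 1/H*`, so both signals
equal `s* = 1/2` at the target state (`M* = 3.1e8/kg`, `H* = 1250/kg`).
The HSC steady state forces `a_0(s*) = 1/2`, which the choice
`a_max = 1` satisfies exactly. Homeostatic proliferation rates rise in
equal arithmetic steps from 2/365.25 per day (HSC) to 1/day (last
mitotic stage). The uniform homeostatic HPC self-renewal `a_hom ≈ 0.294`
is solved from the required total flux amplification
`d·M*/(p_0·H*) ≈ 1.04e8 = r(a_hom)^15`; stage concentrations follow from
the same flux balances, giving an exactly stationary equilibrium
(residual ~1e-16 relative).

The slope β of the HPC self-renewal response is the one genuinely free
feedback parameter. It controls how strongly progenitor amplification
rises under stimulation and therefore the speed of post-transplant
recovery. A through-origin linear response (`a = 2 a_hom x`) makes
regeneration so explosive that any multi-million-cell graft engrafts in
under 9 days regardless of composition; β is instead calibrated once to
β = 0.12, which puts the reference transplant (4.7×10⁶ CD34+/kg, 50%
homing) at 14.6 days to 5×10⁸ neutrophils/l, inside the clinical 10–20
day window. The through-origin form is the special case β = 2·a_hom.

## Transplantation

A graft of `dose` CD34+ cells/kg is split into an HSC portion
(`hsc_fraction`, default 1250/4.7e6 ≈ 2.7e-4, i.e. 10⁵ HSCs in the
reference graft — consistent with >1000 mutated HSCs at donor VAF 0.005)
and an HPC portion distributed over the stages proportionally to the
homeostatic marrow profile. The HSC fraction is the largest unconstrained
degree of freedom of the model; it is fixed in the defaults and scales
with dose. Homing is instantaneous: 50% of transplanted cells (per clone
and compartment class, configurable) seed the recipient's marrow; grafted
mature neutrophils are discarded (cleared within days, no lasting
contribution). Varying the global homing percentage between 30% and 70%
shifts engraftment timing but not the qualitative clonal pattern
(tested).

## Clones

Mutant clones modify the wildtype kinetics in three composable ways:

1. multiplicative factors on proliferation, self-renewal (clipped at the
   probability bound) and clearance;
2. aberrant sensitivity: a clone with factor σ perceives the signal
   `s* + σ(s − s*)` (clipped to (0, 1]); responses steepen around the
   homeostatic point but coincide with wildtype at it, so such clones
   are exactly neutral at homeostasis and advantaged only under stress
   (post-transplant, inflammation). Linear steepening is the minimal
   monotone choice preserving the homeostatic fixed point;
3. homing differences.

VAF is computed from mature cells only:
`VAF = c_M/(c_WT + c_M)/2` for heterozygous clones (≤ 0.5), without the
factor 1/2 for homozygous ones.

A strong HSC-level advantage reproduces a real transient: under full
stimulation mutant HSCs self-renew almost exclusively and emit no
progenitors, so the peripheral VAF dips before it rises. The dip length
grows with σ and with recovery duration; it is why the virtual-cohort
archetypes (below) keep HSC-level advantages moderate.

Trajectory patterns are classified with explicit, configurable rules:
`none` if the VAF stays within 0.005 of the donor VAF; `persistent` if
the mean slope over years 2–5 exceeds 0.005 VAF/year; `saturated` if the
trajectory plateaus above the donor VAF (late slope < 10% of the early
expansion rate); otherwise `transient`.

## Inflammation

Mutant mature cells raise a systemic inflammatory burden
`I = B0 + α·c_M` (quasi-steady state of fast linear production/decay;
`B0` is a CHIP-independent host burden, constant in time when α = 0).
Burden units are arbitrary — the Hill constant θ normalizes them in the
saturating effect `e = I/(I + θ) ∈ [0, 1)`. Coupling modes:
`mutant_boost` multiplies mutant self-renewal/proliferation/amplification
by `(1 − δ + λ·e)` where δ is a fitness deficit the clone pays in the
absence of inflammation; `wildtype_exhaustion` multiplies wildtype
self-renewal and amplification by `(1 − μ·e)` (optionally raising
wildtype proliferation). The multiplicative form is a reconstruction:
directions and saturation are fixed by the biology, the algebra is not.
Couplings compose *after* the feedback responses, so homeostatic
calibration is untouched when the mode is off (bit-identical
trajectories, tested). With α > 0 and δ > 0 the clone is self-sustaining
above a critical graft VAF, which a bisection utility brackets.

## Growth-factor pharmacokinetics

Pegfilgrastim-like kinetics: subcutaneous depot → plasma (rate `ka`),
first-order elimination (`ke`), closed-form superposition over doses.
`(ka, ke) = (0.668, 0.363)/day` are solved from two targets: peak at 2
days post injection and half-of-peak 3.5 days after the peak (the
(1.0, 0.198) root hits the peak target but misses the 3–4 day decay
window). Dose amounts are normalized to 1; the drug adds to the systemic
signal, `s_eff = min(1, s + γ·C(t))`, acting on wildtype and mutant
cells alike and passing through the mutant sensitivity transform like
the endogenous signal. γ = 0.5 is calibrated so one dose on day 3
shortens the cohort's median engraftment by ≈ 3 days.

## Virtual trials

Each virtual patient perturbs the reference parameters multiplicatively
with uniform draws: slope factor U(0.70, 1.08) on β (engraftment time
responds convexly and asymmetrically to β, hence the skewed range), ±3%
on the fastest division rate and the proliferation fold, ±5% on
clearance, ±10% on homing, ±40% on the graft HSC fraction. These widths
are frozen so the n = 1000 cohort's engraftment times at the reference
dose span the 11–25 day clinical range (min ≈ 11.2, max ≈ 25.0 across
seeds). The cohort median (≈ 17.5 d) is not a calibration target; only
the range endpoints are anchored. One root seed feeds per-patient
`SeedSequence` substreams, so cohorts are bit-reproducible and extending
a cohort never changes existing patients; the same cohort is reused
across all arms of a trial.

Donor PB VAFs are drawn U(0.005, 0.125). Clone archetypes: *saturated* —
sensitivities σ_HSC ~ U(1.0, 1.2), σ_HPC ~ U(1.5, 2.5); *persistent* —
HSC self-renewal multiplier U(1.03, 1.08), HSC proliferation multiplier
U(1.0, 1.5), plus σ_HPC ~ U(1.4, 2.0). The mixture is deliberate: the
progenitor-level stress advantage feeds mature output without lag, which
keeps the per-patient dose→VAF relation monotone at the 100-day horizon,
while the HSC-level component drives donor pre-donation expansion and
the multi-year recipient growth.

The dose trial transplants every patient at 1, 5, 10 and 15 ×10⁶
CD34+/kg; the composition trial scales HSC content 1:5:10:15 at fixed
HPC content (total fixed at 5×10⁶/kg) and vice versa, with one graft
shared between the arms. Donors are simulated over the pre-donation
year; grafts inherit the donor's per-compartment clonal fractions at
donation. Expansion metrics (VAF at 100 d and 1 y, Δ and π in donor and
recipient) are interpolated linearly at the exact horizons; associations
use Spearman rank correlation with average-rank ties.

## Numerics

Stiff integration uses `scipy.integrate.solve_ivp` (LSODA), rtol 1e-6,
atol 1e-3 cells/kg, output on a daily grid (finer on request), with the
horizon split at dose times (derivative kinks) and engraftment located
by event detection (robust to < 3e-5 day under tolerance doubling).
States are clipped at zero only within a small tolerance of zero;
larger negativity raises an integration error. Signals are floored at
1e-9 to stay in the open unit interval.

## Synthetic data and scope

All inputs are generated by the package itself (calibrated equilibria,
grafts, virtual cohorts); there is no patient data. The virtual cohort
emulates inter-individual variability only through the perturbed
parameters above — it does not model measurement noise in VAF assays,
sampling times, immune (T-cell) control of clones, acquisition of new
mutations, stochastic extinction of small clones (the ODE regime assumes
>1000 mutated HSCs in the graft, i.e. donor VAF ≥ 0.005 at the default
composition), or transplantation complications such as graft failure and
GvHD. Passing tests therefore demonstrate internal consistency with the
calibrated anchor points and the qualitative mechanism contrasts, not
predictive accuracy for individual patients.

Problem sizes in the test suite are chosen for quick, deterministic
runs: cohorts of 12–40 patients for per-patient monotonicity and
correlation-sign checks (n = 200–300 for cohort-level calibration
checks), with the full n = 1000 cohort exercised by the acceptance
script.

## Known limitations

* The exact functional forms of the feedback responses are constrained
  only at anchor points (homeostatic value, 4-fold proliferation, the
  engraftment window); different monotone forms satisfying the same
  anchors would change quantitative details.
* In the baseline variant an HSC-count perturbation relaxes only on a
  multi-year timescale (the mature-cell feedback restores output, not
  stem-cell count) — consistent with slow clinical HSC recovery, but it
  means `H*` is a weak attractor.
* The graft's HSC fraction and stage distribution are calibration
  choices; absolute engraftment times shift with them (logarithmically
  in the dose).
* Burden units, θ and the coupling coefficients of the inflammation
  module are effective parameters; only their ratios are identifiable.
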