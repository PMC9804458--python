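# Methods

## Scope and intent

`mesothresh` is a minimum realistic model: it contains only the components
needed to answer one management question — at which combined cat and rat
abundances does the red-tailed tropicbird population tip into decline — and
nothing else. It deliberately does **not** model cat–rat interaction
dynamics, multi-year population trajectories, functional responses
(satiation, prey switching, density dependence), or spatial structure.
Per-capita predation is a constant daily rate throughout the breeding
season, and the persistence indicator is a single-season mass balance.

## The indicator

The reproduction ratio η divides the juveniles hatched in the focal season
that survive to reproductive maturity (3 years) by the loss of breeding
adults over that season:

    η = N_J,3 / (N_A,0 − N_A,1)

Adult loss combines natural mortality with cat predation over the breeding
season T_B:

    N_A,0 − N_A,1 = N_A,0 μ_A + N_cats p_A,C T_B

Juvenile recruitment follows the season's mass balance: of β·N_A,0 eggs
laid, rats remove p_E,R·N_rats·T_I during incubation; a fraction ν of the
remainder hatches; hatchlings suffer natural mortality (1 − μ_H) and
predation by cats and rats over the nest period T_H; survivors endure
annual juvenile mortality μ_J for the T_mat years at sea:

    N_J,3 = [ν (β N_A,0 − N_rats p_E,R T_I)(1 − μ_H)
             − (N_cats p_H,C + N_rats p_H,R) T_H] (1 − μ_J)^T_mat

Three clamps keep the balance physical, applied in the order eggs →
hatchlings → adults: rat egg predation cannot exceed the eggs laid,
combined hatchling predation cannot exceed the hatched survivors, and cat
predation of adults cannot exceed the adult population (when it would, the
whole population is lost in the season). Within the unclamped region η is
affine in each predator abundance, so the η = η* level set is a straight
line whose intercept (critical rats), slope magnitude (cat equivalence) and
rat-free intercept (critical cats) have closed forms; `summarize_thresholds`
verifies at output time that both intercepts lie in the unclamped region and
warns otherwise. The target η* defaults to 1 but is a free parameter, so
risk-buffered targets (e.g. η* = 1.2) are supported. Negative closed-form
thresholds are reported as 0 with an explicit "not sustainable even without
this predator" status; a predator that exerts no predation at all yields an
infinite threshold, signalled by a warning rather than silently.

## Parameters

Defaults (the packaged `data/defaults.yaml`) describe the Christmas Island
case: 2800 breeding adults, 42-day incubation, 90-day nestling time,
122-day breeding season, maturity at 3 years, 15-year life span, ν = 0.99
viable eggs, μ_A = 0.125/yr (range 0.10–0.15), μ_J = 0.20/yr; cat/rat/adult
bird/egg masses 3250, 132, 700, 66.2 g (hatchling = half adult mass); bird
flesh 10.9 kJ/g, egg 29 kJ/g; diet fractions 0.382 (bird in cat diet), 0.02
and 0.04 (hatchling and egg in rat diet); field-metabolic allometries
1.67·m^0.869 (carnivores) and 5.48·m^0.712 (rodents), giving 1882 and 177
kJ/day at the default masses.

Three published derived-parameter formulas are typographically corrupted in
the source table, and we resolve them as follows (each resolution is
overridable through the configuration):

* **β** (eggs per adult per season) = 0.5·(α_R − α_M)/α_R = 0.4 — half an
  egg per adult (one per pair), discounted by the immature fraction of the
  life span. This is the only non-negative reading; the printed operand
  order gives −2.
* **μ_H** (hatchling natural mortality) scales annual juvenile survival to
  the nestling window: 1 − (1 − μ_J)^((T_B − T_I)/365) ≈ 0.0477. Because
  the printed durations do not satisfy T_B = T_I + T_H (122 ≠ 42 + 90), a
  `muH_mode="TH"` option uses the T_H/365 exponent instead. The printed
  T_B = 122 is used verbatim for adult predation exposure and T_I, T_H
  verbatim in the juvenile balance; no forced reconciliation.
* **T_mat** (years at sea before maturity) = α_M − T_B/365 ≈ 2.67 y;
  maturation occurs at α_M = 3 y, so the printed life span symbol is read
  as a typo.

The published bird fraction of cat diet (0.382, from scat studies) is
printed for both the adult and the hatchling stage. `catdiet_mode`
selects between using it twice (`"as_printed"`) and splitting it equally,
0.191 per stage (`"split"`). The split mode keeps the cat's total bird
intake at the observed fraction and reproduces the published cat-side
thresholds (critical cats ≈ 21); the printed mode doubles the cat's bird
intake and roughly halves them. Both are exposed; the rat-side outputs are
identical under either.

## Uncertainty propagation

Each non-temporal parameter row (including the derived rows β, μ_H, mass_H
and the metabolic demands, which the source table marks as uncertain) is
drawn independently from a normal with sd = 20% of its mean — the average
variation of the parameters with published ranges — truncated to the
published range where one exists and to the natural domain otherwise
(non-negative; proportions ≤ 1). Durations and ages are held fixed, and the
allometric regression constants enter only through the sampled metabolic
demands (sampling a power-law exponent with a 20% CV would rescale demand
by orders of magnitude, which no field uncertainty supports). An
`"assumed_range"` truncation policy (±20% of the mean) is available as an
alternative convention. All draws flow from one seeded generator; identical
plans give bit-identical streams.

Per draw the closed forms are evaluated. Draws whose critical-rats
numerator is non-positive describe a population that declines even with
zero predators of the focal kind: no finite threshold exists there, so such
draws (~16% at defaults) are excluded from the critical-rats and
critical-cats summaries and from the phase-space band lines, and their
count is reported. Cat equivalence exists for every draw with positive rat
predation and is summarised over all of them. Outputs are summarised by the
median and central 68%/95% credible intervals (percentiles at 16/84 and
2.5/97.5, linear interpolation between order statistics). Phase-space bands
evaluate each draw's threshold line on a cat-abundance grid and take the
five percentiles columnwise; `classify_scenario` interpolates the five
curves linearly at a scenario's cat abundance and assigns one of six
ordered decline/increase labels, with points exactly on a border assigned
to the riskier (decline-side) label — conservative for management.
Extrapolation beyond the grid is refused. The default 100,000 draws cost
about a second and leave Monte Carlo error in the reported quantiles well
below the parameter uncertainty itself.

## Sensitivity analysis

One-at-a-time, with a deliberately strong 75% variation so that weak
parameters register at all. Eligible parameters are all Table rows except
N_A,0, β and μ_A (cat equivalence is algebraically independent of them —
the package tests this exactly) and except the allometric regression
constants by default (a ±75% multiplicative shift of an exponent rescales
demand by ~200×, swamping the comparison; `include_allometric=True` ranks
them anyway). Perturbing a predator mass re-derives its metabolic demand,
and perturbing μ_J re-derives μ_H; hatchling mass is treated as an
independent parameter since it has its own published range. Two spread
measures are always reported: the deterministic endpoint spread
|CE(mean·1.75) − CE(mean·0.25)| (clipped to natural domains), and the width
of the central 95% interval of cat equivalence under truncated-normal draws
with sd = 0.75·mean. Ranking uses the endpoint spread by default: at a 75%
sd the natural-domain truncated normals place substantial mass near zero
for every hyperbolically-entering parameter, which inflates the MC spread
of adult-bird mass/energy past rat mass and muddies the comparison the
analysis is meant to make; the endpoint ranking is also seed-invariant.
Both modes agree that rat metabolic demand dominates, adult-bird mass and
energy come next, then cat metabolic demand, with hatchling parameters
(mass_H, energy_H, T_H, μ_H) at the bottom.

## Numerical choices and edge cases

* Predator abundances are real-valued throughout; rounding to whole animals
  happens only in human-facing report lines (abundances to integers, ratios
  to 3 significant figures); JSON/CSV always carry full precision.
* Quantiles: `numpy.percentile` linear interpolation.
* The closed forms are validated in the test suite against bracketed
  bisection roots of η itself (Brent's method between the zero-predation
  point and the stage-exhaustion point) to 1e-6 relative tolerance on 1000
  jittered parameter sets, and the identity critical_cats · cat_equivalence
  = critical_rats holds to 1e-9 relative.
* η is undefined when adult loss is zero (μ_A = 0 with no cats); this
  raises a domain error rather than returning an arbitrary value.
* Unsatisfiable truncation bounds, empty or negative cat grids, and
  configurations violating invariants (proportions outside [0, 1], diet
  fractions exceeding the daily budget, life span not exceeding maturity)
  fail loudly at load time with the offending value named.

## What the test fixtures do and do not show

Property tests run on parameter sets jittered ±30% around the defaults with
structural invariants enforced, which probes the algebra (closed forms,
clamps, monotonicity) far beyond the case-study corner of parameter space.
They do not validate the model against field data: the packaged defaults
are literature-derived point estimates, several from other islands or
congeneric studies, and the model's own simplifications (constant predation
rates, single-season balance, no predator interactions) are untested
assumptions. Passing tests show the implementation computes this model
correctly and reproducibly — not that Christmas Island tropicbirds will
follow it.

## Known limitations

* Thresholds are only as meaningful as the diet fractions, which are the
  weakest inputs (borrowed from other islands; the egg preference is an
  assumption that eggs are twice as findable as live prey).
* The closed forms lose validity where a clamp binds (extreme predator
  loads); the package warns rather than extrapolating, but the Monte Carlo
  bands near the axes inherit the unclamped algebra.
* Parameter draws are independent by construction; real masses, energies
  and demands co-vary, and ignoring that typically widens the true
  uncertainty relative to the reported intervals.
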