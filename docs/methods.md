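# Methods

`patchfr` studies how two spatial habitat properties — patch size and the
availability of prey refuges — shape the strength of a feeding interaction
(the functional response), and how that interaction in turn decides whether
a predator–prey pair can coexist on a patch. The pipeline has three layers:
an individual-based simulator generates feeding-trial data; a likelihood
layer fits Real's functional response with habitat-dependent parameters and
selects their scaling structure by BIC; and an allometric
Rosenzweig–MacArthur model converts the fitted interaction into equilibrium
densities and survival classifications.

## 1. The individual-based feeding trials

### Arena

A trial arena is a square grid of 1 cm × 1 cm cells (a patch of area *A*
m² has √(*A*·10⁴) cells on a side; only areas that resolve to an integer
side are valid — the built-in designs use 0.04–100 m²). Walls are
impenetrable. A fraction *R* of cells, drawn uniformly without replacement
and freshly for every trial, is marked as refuge: any individual may enter
a refuge cell, but no attack can take place there. Refuges are therefore a
pure feeding constraint, not a movement obstacle.

### Individuals and traits

One predator (default 100 mg) forages on `prey_count` prey (default 1 mg
each) for 3,600 one-second steps (one hour). All behavioural rates derive
from body mass *M* [mg]:

| trait | formula | 100 mg / 1 mg value |
|---|---|---|
| velocity [cm/s] | 0.546 · M^0.29 | predator 2.076, prey 0.546 |
| gut capacity [mg] | 0.5 · M^0.434 | 3.690 |
| digestion [mg/s] | 5·10⁻⁵ · M^0.75 | 1.58·10⁻³ |
| handling time [s] | 37.504 · Mp^−0.330 · Mn^0.173 | 8.2 (→ 8 steps) |
| attack success | 0.10 · ((R/100)·e^(1−R/100))^1, R = Mp/Mn | 0.10 |

Attack success follows a generalized Ricker curve of the predator:prey mass
ratio, maximal (0.10) at the optimal ratio of 100 — exactly the reference
pair, which is why that pair is the default.

### The step cycle

Each step, every prey takes one random-walk move (uniform direction in
[0, 2π), step length = velocity × 1 s, displacement truncated at the first
wall contact), then the predator acts in a fixed order:

1. **digest**: gut content decreases by D·1 s (floored at 0); digestion
   never pauses, including during handling and resting;
2. **handle**: if a capture is still being handled, decrement the counter
   and do nothing else;
3. **rest**: if the gut is at or above 60% of capacity, do nothing;
4. **move and attack**: otherwise random-walk one step; if the landing cell
   holds at least one prey and is not a refuge, attack one uniformly chosen
   prey with the allometric success probability. A success removes the
   victim, adds the prey mass to the gut, starts a handling counter of
   round(handling time) steps, and instantly inserts a replacement prey at
   a uniformly random position — prey density is exactly constant
   throughout a trial. A failed attack leaves the prey in place; at most
   one attack per step.

The predator starts with a **half-full gut**. An empty-gut start inflates
the first hour with a gut-filling burst (≈ +2 captures), a full start
suppresses it; starting half-way between empty and the satiation threshold
puts the predator into its digestion-limited steady state within the first
few captures, which is what a maximum-feeding *rate* trial is meant to
measure. This mirrors the standardized pre-feeding of laboratory trials.

With the reference traits the hourly intake is digestion-limited at
1 mg / (1.58·10⁻³ mg s⁻¹) ≈ 633 s per prey, giving ≈ 7 prey/h — the
physiological ceiling f_max, independent of patch size and refuge by
construction.

### Maximum-feeding trials

The non-spatial variant removes space: whenever the predator is hungry and
not handling, an attack happens with the allometric success probability.
Fifty replicates estimate f_max; an intercept-only Poisson GLM (log link)
turns the counts into ln(f_max) with a Wald standard error
(= 1/√Σcounts in closed form).

### Experiment design and the density ladder

The factorial design crosses patch sizes with refuge fractions. Two built-in
designs exist: the full design (12 areas 0.04–100 m² × refuge 5%–75% in 5%
steps) and the desk-scale design used by the tests and the acceptance
script (the five smallest areas 0.04–2.56 m² × refuge 5%–75% in 10% steps,
five replicates per density). Prey counts follow the ladder 2⁰, 2¹, …, 2ⁿ,
where n is chosen adaptively per design point: the ladder stops at the
first exponent whose 5-replicate mean feeding reaches 90% of the
non-spatial maximum-feeding estimate (the predator is "satiated"). The
5-replicate levels of the ladder are themselves the recorded trials — the
design runs five replicates per density either way, so separate pilot runs
would only duplicate compute. As a physical guard the ladder never climbs
past 16 prey per cell, far beyond any density the satiation rule needs.

Reproducibility: one master seed; each trial's seed is derived from
`SeedSequence([master, stage, area-index, refuge-index, exponent, rep])`,
so any recorded trial replays bit-identically in isolation. The simulator
has two engines — a numba kernel and a pure-Python reference — that share
the RNG stream and produce identical trials; the reference engine also
exposes per-step traces for invariant tests.

## 2. Fitting the functional response

Feeding counts are modelled by Real's response

  f(N) = f_max · N^h / (N0^h + N^h)

with density N in individuals/m² (counts divided by patch area), f_max
fixed at the GLM estimate, and habitat-dependent parameters through
ln-linear predictors

  ln N0 = ln C_N0 + a_N0·ln A + b_N0·R + γ_N0·ln A·R
  ln h  = ln C_h  + a_h ·ln A + b_h ·ln R + γ_h ·ln A·ln R

(the default forms: N0 a power law in patch size and exponential in refuge,
h power laws in both; a 16-model screen crossing power/exponential forms on
each covariate is available as `form_screen`). Errors are negative binomial
in the ecological (μ, k) parametrization, variance μ + μ²/k, with k
estimated jointly on the log scale. When the counts carry no
overdispersion the likelihood is monotone in k; k is then capped at e¹⁶
(numerically the Poisson limit) and reported without a standard error.

Optimisation is multi-start: short Nelder–Mead probes from a small grid
(N0 intercept at density quantiles, Hill intercept at 0 and 0.35, slopes at
0), full simplex refinement from the best probe, then a BFGS polish.
Standard errors are Wald, from the numerically differenced observed
information at the optimum. BIC = −2·logLik + p·ln(n) with p counting all
estimated parameters including k.

Model selection enumerates, per response, the five admissible term sets
{}, {a}, {b}, {a,b}, {a,b,γ} (an interaction requires both main effects) —
25 structures in total — and picks the minimum BIC, ties broken toward
fewer parameters. The Hill test compares ln C_h against 0 (h = 1, a
hyperbolic type II response) by a Wald z-test; h > 1 indicates a sigmoid
type III response.

## 3. Population dynamics on a patch

The fitted interaction enters a Rosenzweig–MacArthur system per day:

  dN/dt = r N (1 − N/K) − ω f(N) P
  dP/dt = e ω f(N) P − x P

f_max is converted from prey/h to prey/day (×24) and ω = 1/2 discounts for
a ~12 h daily foraging window; assimilation efficiency e = 0.85. The prey
rates r, K and the predator metabolism x come from empirical body-mass and
temperature scalings for temperate invertebrate communities (T = 282.65 K;
mass units per equation: K uses prey mass in grams, r in micrograms, x
predator mass in grams with a J s⁻¹→d⁻¹ conversion 12342.86/Mp[mg], times
a field-to-basal factor 3). At the defaults: K ≈ 2171.8 /m²,
r ≈ 0.0221 /d, x ≈ 0.0230 /d.

The interior equilibrium is analytic: the predator isocline
N* = (x·N0^h/(eωf_max − x))^(1/h) and the prey isocline
P(N) = r·N^(1−h)(K−N)(N0^h+N^h)/(KωF_max). Survival is decided against an
explicit extinction boundary of **two individuals per patch** (2/A per m²):
the predator is extinct if no interior equilibrium exists (energetic
infeasibility or N* ≥ K) or P(N*) < 2/A, in which case the prey sits at K
(and would itself be flagged extinct in the degenerate case K < 2/A, which
never occurs in the default ranges). This boundary — not any change in the
interaction, which is nearly patch-size-invariant — is what removes
predators from small patches; rising refuge availability raises N0, which
raises both equilibrium densities and lets predators persist on smaller
patches. Refuge reaches the ODE only through the fitted N0 (and h, had it
been selected); `coexistence_map` evaluates any (patch size, refuge) grid,
including refuge values off the 5% design lattice. The local Jacobian
eigenvalues are reported (`stable`) but do not alter the survival
classification, which is equilibrium-plus-boundary based.

## What the synthetic generator does and does not emulate

`make_synthetic_feeding_table` draws negative-binomial counts around Real's
response with known habitat scalings. It exercises the likelihood,
optimiser and model-selection machinery against ground truth, but its
errors are exactly the assumed NB family at every density — unlike
simulator output, whose dispersion is density-dependent and typically at or
below Poisson near satiation. Recovery tests on synthetic tables therefore
validate the fitting layer, not the adequacy of the NB assumption for the
simulator; the end-to-end checks on simulated trials cover the latter.

## Numerical choices and scales

- Desk-scale problem sizes: 50 maximum-feeding trials; the reduced
  factorial produces ≈ 2,200 trials (ladders reach 2¹¹–2¹⁴ at 2.56 m²) in
  roughly 8–10 minutes on one core; the 25-model selection adds ≈ 1 minute.
- The likelihood is evaluated on the log scale (`logaddexp`) so extreme
  densities and Hill exponents stay finite; non-finite parameter vectors
  return −∞ through an optimizer-safe sentinel.
- Wall handling: a proposed displacement stops at the first wall contact
  (with an ulp-level clamp so positions never leave the arena).
- Ties in BIC are broken toward the smaller parameter count; candidate
  fits that fail to converge are excluded from selection with a warning.
- The equilibrium classifier treats the predator branch first; prey
  extinction (K < 2/A) is checked only after predator extinction resolves.

## Known limitations

- Movement is an unbiased random walk: no chasing, hiding, wall-following
  or other behavioural responses, and a single predator per trial.
- Handling time is rounded to whole steps; sub-second handling vanishes.
- The NB dispersion is a single k across all densities.
- The ODE layer assumes the feeding trials' hourly rates extrapolate to a
  12 h foraging day, and treats refuge effects as fully mediated by N0.
- Whether digestion pauses during handling and whether replacement prey may
  appear in the predator's cell are not externally constrained; this
  implementation digests continuously and allows replacement anywhere.
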