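# patchfr

**In-silico functional-response experiments across patch sizes and refuge
availabilities — and what they imply for predator–prey coexistence.**

Measuring how the strength of a feeding interaction depends on habitat is
nearly impossible in the laboratory: a functional-response curve needs
thousands of prey at a single patch size, and field patches are orders of
magnitude larger than experimental arenas. `patchfr` replaces the
laboratory with an allometric individual-based model: one predator forages
by random walk on a grid of 1 cm² cells with prey refuges, governed by
body-mass scalings of velocity, gut capacity, digestion, handling time and
attack success. Simulated feeding trials across a factorial of patch sizes
(0.04–100 m²) and refuge fractions (5–75%) are then fitted with Real's
functional response,

    f(N) = f_max · N^h / (N0^h + N^h),

where `f_max` is the maximum feeding rate (fixed first from non-spatial
trials via a Poisson GLM), `N0` the half-saturation density and `h` the
Hill exponent (h > 1 ⇒ sigmoid, type III). The half-saturation density and
Hill exponent may scale with patch size `A` and refuge availability `R`,

    ln N0 = ln C_N0 + a_N0·ln A + b_N0·R + γ_N0·ln A·R
    ln h  = ln C_h  + a_h·ln A  + b_h·ln R + γ_h·ln A·ln R,

fitted by negative-binomial maximum likelihood with BIC selection over the
25 admissible term combinations (plus a 16-model power-vs-exponential form
screen). Finally, the fitted interaction parameterises an allometric
Rosenzweig–MacArthur model

    dN/dt = r N (1 − N/K) − ω f(N) P
    dP/dt = e ω f(N) P − x P

with empirically scaled r, K and x, and an explicit extinction boundary of
two individuals per patch (2/A m⁻²), to map where predator and prey
coexist. The headline findings the package reproduces: feeding is type III
(h ≈ 1.28); N0 rises exponentially with refuge availability and is nearly
patch-size invariant; and predators vanish from small patches purely
because the per-area extinction boundary rises as patches shrink — while
refuges, by weakening the interaction, *raise* both equilibrium densities
and rescue predators on smaller patches.

## Worked example

Library use — simulate one feeding trial and the maximum-feeding
experiment, then fit:

```python
import patchfr as pf

counts = pf.run_max_feeding_experiment(50, seed=1)
ln_fmax, se, p = pf.fit_max_feeding(counts)

trials = pf.run_experiment(seed=1, fmax_estimate=float(counts.mean()))
best, table = pf.select_model(trials, ln_fmax)
print(best.summary())
```

Command line — the same pipeline at desk scale, with CSV/JSON artifacts:

```bash
patchfr all --scale desk --seed 1 --outdir out/
```

With seed 1 at desk scale the selected model prints:

```
mean max feeding: 6.96  ln_fmax: 1.9402
Functional response fit (negative-binomial MLE)
==========================================================
n_obs: 2200    logLik: -2738.280    BIC: 5507.345
fixed ln(f_max): 1.9402   dispersion k: 8886110.521
forms: N0 ~ power(A) x exponential(R), h ~ power(A) x power(R)
----------------------------------------------------------
term            estimate      s.e.        z          p
ln_C_N0           4.5580    0.0614    74.27          0
b_N0              1.9515    0.1278    15.27   1.14e-52
ln_C_h            0.1860    0.0246     7.56   3.97e-14
ln_k             16.0000       nan      nan        nan
==========================================================
```

Read: the predator's maximum feeding rate is e^1.94 ≈ 7 prey/h; the
half-saturation density is e^4.56 ≈ 95 prey/m² at zero refuge and grows by
a factor e^1.95·ΔR with refuge fraction (≈ 3.9× across the 5–75% range);
the BIC winner drops the marginal patch-size term a_N0 entirely (when kept,
it is ≈ −0.01 and non-significant); and the Hill exponent e^0.186 ≈ 1.20 is
significantly above 1 — a type III response (the dispersion sits at its
Poisson-limit cap: trial counts are not overdispersed).
`patchfr map` then classifies every
(patch size, refuge) cell: predators are extinct below a few m² at low
refuge, and the survival frontier moves to smaller patches as refuge grows.

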