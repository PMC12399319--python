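# dunesync

Small-scale demographic asynchrony and portfolio effects in a
size-structured plant population.

## The problem

Populations persist through bad years partly because their subpopulations
do not all crash at once.  `dunesync` analyzes that mechanism at the scale
of a single monitoring plot: an annual tagged-plant census of a monocarpic
perennial (seedling → vegetative rosette, measured as ln taproot diameter →
one-time flowering → death) split into zones along an environmental
gradient, such as the foredune-to-backdune transect of a Great Lakes dune.
It is written for plant demographers and population ecologists who have a
long-format census table and a monthly climate record and want to know
*whether* the zones fluctuate out of step, *how much* that stabilizes the
whole plot, and *whether opposite responses to climate are the cause*.

The pipeline chains five analyses:

1. **Vital rates.** Plant-year transitions feed five mixed models — seedling
   survival `S1`, vegetative survival `S2(z)`, growth `G(z', z)`, flowering
   probability `A(z)`, new-plant size `D(z')` — each with a random effect of
   the year-by-zone interaction only, so zones may move in opposite
   directions within a year.
2. **Growth rates.** Per zone and year, an integral projection model with
   discrete seedling and adult stages and 200 size bins:
   `n(z', t+1) = S(t) s1 d(z') + ∫ s2(z) (1 − a(z)) G(z', z) n(z, t) dz`,
   with `S(t+1) = r A(t)` and `A(t+1) = ∫ s2(z) a(z) n(z, t) dz`; λ is the
   dominant eigenvalue, found by iteration.
3. **Synchrony and portfolio effect.** The synchrony index
   `φ = Var(Σᵢ Nᵢ) / (Σᵢ √Var(Nᵢ))²` (1 = lockstep, 0 = perfect
   compensation) and the mean–variance portfolio effect: fit Taylor's law
   `log Var(Nᵢ) = β₀ + z log E(Nᵢ)` across zones, predict the total's
   variance from it, and report `PE = Var_pred / Var_obs` (PE > 1 ⇒
   asynchrony stabilizes the total).
4. **Climate windows.** For each vital rate, scan all 703 windows of 1–37
   months before the June census × five climate variables, fitting
   `rate ~ size + zone + climate:zone + (1 | year)` and selecting by AICc
   against a no-climate baseline; a year-block randomization test reruns
   the scan on shuffled years to estimate the probability the winning
   support is spurious.
5. **Attribution.** Regress each zone's fitted climate slope on its
   correlation with zone 1: a significant association ties the asynchrony
   to the climate-by-zone interaction.

A fully parameterized synthetic generator (`dunesync.synthetic`) emulates
the study design with known truth — zone-specific climate slopes of
opposite sign, shared year noise, Poisson recruitment — so every stage is
validated end-to-end by parameter recovery.

## Worked example

```bash
python examples/04_portfolio_effect.py
```

prints, for the default simulated study (5 zones, 17 years):

```
synchrony phi           0.643
Taylor slope z          1.74
observed total variance 6,617
predicted (scaling law) 6,755
portfolio effect PE     1.02
```

φ = 0.64 says the zones are far from lockstep; PE near 1 says that for this
particular realization the scaling law predicts roughly the observed total
variance.  `examples/05_window_scan.py` then recovers the planted climate
driver:

```
best model: prcp, window open=8 close=4 months before the census
delta AICc vs baseline: -47.6
per-zone climate slopes: {1: -1.68, 2: -0.88, 3: -0.71, 4: 0.35, 5: 0.86}
```

— precipitation averaged over 4–8 months before the census, with slopes
running from negative (zone 1, foredune) to positive (zone 5, backdune),
exactly the generating structure.  The remaining examples cover simulation,
vital-rate fits, IPM growth rates and the attribution regression, each a
short narrative script.

The same pipeline runs from the shell on CSV inputs or the generator:

```bash
dunesync run-all --seed 1 --out results/
```

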