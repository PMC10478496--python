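# microhab

Bayesian analysis of microhabitat selection and colour background-matching in
the common lizard (*Zootoca vivipara*), built for used-vs-available habitat
data collected on quadrats and calibrated RGB colour measurements of lizards
and their basking sites.

## The problem and the model

Whether lizards *choose* where they sit is asked by comparing the habitat
composition of the quadrats where lizards were found basking with the
composition of randomly sampled quadrats. Each 0.5 × 0.5 m quadrat is scored
on a 5 × 5 grid, giving per-category proportions in {0, 1/25, …, 1} for nine
habitat categories (angiosperm, grass, leaf litter, moss, rock, water, wood,
cover, bare ground). Proportions of exactly 0 and 1 are common, so each
category is modelled with a **zero-and-one-inflated beta (ZOIB)**
distribution:

```
f(y; α, γ, μ, φ) = α(1−γ)              y = 0
                 = αγ                   y = 1
                 = (1−α)·Beta(y; μφ, (1−μ)φ)   0 < y < 1
```

α is the probability of an atom, γ the probability the atom is a 1, and the
interior follows a beta distribution with mean μ and precision φ. When a
category never fills a quadrat (no ones observed), γ is fixed at 0 and α is
simply the absence probability.

Selection is detected by a **nine-model ladder**: parameters (α, γ, μ) either
shared by all sites (null), split by lizard vs random site, or further split
by the lizard's sex, parity mode (egg-laying vs live-bearing), or both — each
non-null grouping with φ either shared or split lizard/random. Models are
fitted by MCMC (adaptive Metropolis-within-Gibbs on logit/log scales under
minimally informative normal priors) and compared by the **deviance
information criterion**, DIC = D̄ + pD with pD = D̄ − D̂; the chosen model is
the DIC minimiser unless a strictly simpler model lies within 2 DIC, in which
case the simpler model is preferred.

A companion suite of eight classical models (least squares, logistic, ANOVA)
relates dorsal colour in HSL space to sex, parity, body size, and the colour
of the basking site and surrounding habitat — the background-matching
(crypsis) analysis.

## Worked example

```python
from microhab import (HabitatCategory, MCMCConfig, fit_all_models,
                      posterior_summary, select_model)
from microhab.synthetic import generate_habitat_dataset, preset_scenario

obs = generate_habitat_dataset(preset_scenario("grass-lizard", seed=7))
comp = fit_all_models(obs, HabitatCategory.GRASS, config=MCMCConfig(seed=3))
sel = select_model(comp.dic_table)
print(sel.chosen, sel.rationale)
print(posterior_summary(comp.fits[sel.chosen]))
```

prints

```
lizard/shared lowest
  parameter   group       mean     median      q2.5      q97.5
0     alpha  random   0.374914   0.374102  0.309857   0.443998
1     alpha  lizard   0.294437   0.293896  0.232818   0.359215
2        mu  random   0.708814   0.709000  0.685244   0.731671
3        mu  lizard   0.542467   0.542494  0.517424   0.567356
4       phi     all  10.136573  10.108102  8.513370  11.905090
```

The generator drew grass proportions with μ = 0.70 at random sites and
μ = 0.55 at lizard sites (φ = 10, α = 0.3, no ones): the ladder selects the
lizard/random split and the posterior means recover the generating values —
lizards sitting in grass-poorer spots than chance would give them.

The same workflow is available from the shell (`microhab simulate / fit /
compare / select / colour-stats / run`), and the numbered scripts under
`analysis/` run the full narrative: simulate the study datasets, fit the
habitat ladders, re-derive the reference model selections, and fit the colour
suite, writing tables under `results/`.

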