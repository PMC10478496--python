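# Methods

## The ZOIB observation model

A quadrat proportion y ∈ [0, 1] is modelled as a three-part mixture: an atom
at 0 with probability α(1−γ), an atom at 1 with probability αγ, and a beta
density (1−α)·Beta(y; μφ, (1−μ)φ) on the interior. The beta component uses the
mean/precision parameterisation (mean μ ∈ (0,1), precision φ > 0; variance
μ(1−μ)/(1+φ)). We enforce φ > 0, not φ > 1: the mean/precision beta is a
proper density for every positive φ, and nothing in the likelihood or priors
requires the stronger bound (φ ≤ 1 merely gives U- or J-shaped interior
densities, which quadrat data can produce).

Atoms are exact floating 0.0 and 1.0. Interior values must be strictly inside
(0,1); no epsilon-squeezing of data is performed. When a category never
attains 1 in the data, γ is not identifiable and is pinned at 0 (symmetrically
pinned at 1 when 0 never occurs); with both atoms absent γ is pinned at 0 and
α models an empty zero mass, with a warning, so the likelihood stays proper.

## Grouped fitting

Nine model variants index (α, γ, μ) by observation group — pooled; lizard vs
random; random/female/male; random/oviparous/viviparous; random plus the four
parity × sex cells — with the precision φ either shared by all observations or
split lizard vs random (the null model only admits the shared φ). Every group
a scheme defines is parameterised even when unpopulated: empty groups keep
their prior, their draws are prior draws, and they contribute nothing to the
deviance.

Sampling is on transformed scales — logit(α), logit(γ), logit(μ), log(φ) —
with independent normal priors Normal(0, v): v_α = v_μ = 1000, v_γ = 1,
v_φ = 100. **v is read as a variance** (sd ≈ 31.6 for α′ and μ′), which is
the reading consistent with calling the priors minimally informative; the
BUGS-family precision reading (sd ≈ 0.03) would be extremely informative and
is available as `PriorSpec(interpret_as="precision")` for sensitivity
analysis.

The sampler is an adaptive random-walk Metropolis-within-Gibbs. The
likelihood reduces to per-group sufficient statistics — counts of zeros, ones
and interior values plus Σ log y and Σ log(1−y) — so every conditional
evaluation is O(1) in the sample size and a full default fit (4 chains ×
10,000 iterations, 2,000 burn-in, thin 1) takes well under a second.
Proposal scales adapt toward a 0.44 acceptance rate during burn-in only, so
the post-burn-in kernel is a fixed, valid Metropolis kernel. Chains are
seeded from a single `SeedSequence`, making every fit bit-reproducible.
Initial values come from data moments with per-chain jitter. Convergence is
monitored by split-R̂ and a Geyer initial-positive-sequence ESS per free
parameter; any R̂ > 1.05 attaches a warning to the fit rather than failing
it.

## DIC and selection

DIC = D̄ + pD with pD = D̄ − D̂, where D̄ is the mean of the per-draw deviance
(−2 log likelihood, priors excluded) and D̂ is the deviance at the posterior
means of the **transformed-scale** parameters — the plug-in convention of
hierarchical samplers that work on the sampled nodes, chosen over
natural-scale means and documented so results are reproducible.

The selection rule takes the DIC minimiser unless a strictly simpler model
lies strictly within 2 DIC of the minimum. Complexity is ordered by the
number of mean-parameter groups (null 1 < lizard 2 < sex = parity 3 <
parity × sex 5), then shared before variable precision. Sex and parity are
equal-complexity, so neither can displace the other via the simplicity
clause; between them the lower DIC wins. The rule reproduces all nine
published preferred models from the reference DIC table.

## Colour analysis

RGB channels (0–255) are converted to HSL with hue in degrees and
saturation/lightness in percent (the scale on which the printed ranges, e.g.
lightness 25.1–64.9, live). Hue is treated as a linear variable because
observed lizard and habitat hues (roughly 27–69°) sit far from the 0/360
wrap; a warning fires if values outside 10–300° enter a model. The eight-model
suite uses ordinary least squares, binomial GLMs (IRLS via statsmodels) and
one-way ANOVA; p-values are raw and two-sided — no multiple-testing
adjustment anywhere, matching the analysis design the suite mirrors. Pattern
enters logistic models as reticulated vs {intermediate, linear} by default
(the coding that retains nearly every individual); reticulated vs linear with
intermediates dropped is a switch. The anterior-body pattern category stands
for the individual by default since a single patterning response is fitted.

## Synthetic data

The habitat generator draws per-group proportions directly from the ZOIB
distribution — the exact generative counterpart of the fitted model — and can
snap interior draws to the k/25 grid of a 25-cell quadrat (atoms are
preserved and interior draws are never snapped to 0 or 1, so the γ-mode of
the scenario survives). Presets encode the study conditions: grass with
μ = 0.70 (random) vs 0.55 (lizard), φ = 10, α = 0.3; moss with
parity-structured zero-inflation (α 0.88/0.71/0.86 for
random/oviparous/viviparous).

The colour generator follows the dependency chain habitat → basking → dorsal:
habitat hue truncated-normal (mean 54.9, sd 7.2, bounds 33–69), basking hue =
25.9 + 0.39·habitat + noise, dorsal hue = 25.3 + 0.21·habitat + parity shift
+ noise, with a lightness analogue in which dorsal lightness responds weakly
and negatively (−0.10) to basking lightness — lizards on slightly darker
basking spots. Sample size defaults to 165 records (120 female), the number
with both colour surfaces measured. Means, slopes and habitat sds are
anchored to printed values; the printed response sds and R² are mutually
inconsistent for the hue chain, so noise sds were set once to match the
printed response sds and the implied R² is allowed to differ. Saturation is
generated without cross-surface structure. What the generators deliberately
omit: spatial autocorrelation between neighbouring quadrats, observer effects,
the circularity of hue, and any UV component — so passing tests demonstrate
correctness of the estimators under the assumed model, not robustness to
those real-data features.

## Problem sizes and numerical choices

Tests and the acceptance checks run the sampler at 2–4 chains and 1,500–10,000
iterations depending on the precision each check needs; the grid-posterior
oracle uses a 200³ lattice over (logit α, logit μ, log φ) wide enough to
contain all posterior mass at n = 50. Recovery and discrimination checks use
n = 150–200 observations per group and 10–20 seeded replicates. Degenerate
inputs: all-identical data fit with a diagnostics flag; a scheme requiring a
label the observation lacks raises; a DIC table with a single entry selects
it trivially.

## Known limitations

The sampler is single-site Metropolis and would mix slowly if μ and φ were
strongly correlated at very small interior counts; diagnostics expose this.
Covariate (continuous-predictor) ZOIB regression, WAIC/LOO comparison, and
avian/UV visual modelling are out of scope. The loader flags but does not
reproduce the record exclusions of the motivating study (283 of 394 usable
for microhabitat, 165 for both colour surfaces), whose causes are not stated
per record.
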