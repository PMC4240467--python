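# Methods

## The model

`commlda` fits a mixed-membership multinomial model (Latent Dirichlet
Allocation) to a P × S matrix of individual counts: P sampling units, S
species. Unit `l` has community proportions θ_l ∈ Δ^{C−1}; community `c`
has species proportions φ_c ∈ Δ^{S−1}. Each of the n_l individuals of
unit `l` independently draws a community z ~ Cat(θ_l) and then a species
~ Cat(φ_z). Dirichlet priors θ_l ~ Dir(α·1), φ_c ~ Dir(γ·1); the defaults
α = γ = 1 are uniform on the simplex.

Assumptions worth keeping in mind:

* counts are of *individuals* (the model conditions on the unit totals and
  treats individuals as exchangeable); it is not applicable to
  presence/absence or cover data;
* communities are shared across all units, and C is fixed per fit;
* individuals are independent given θ and φ — no within-unit clumping
  (overdispersion beyond the mixture is not modelled).

## Inference

θ and φ are integrated out analytically and a collapsed Gibbs sampler moves
over the individual community labels. For an individual of species `s` in a
fully observed unit `l` (all count tables excluding that individual):

    p(z = c) ∝ (n_lc + α) · (m_cs + γ) / (m_c + S·γ)

Runs default to 2000 sweeps, burn-in 1000, thinning 10 (100 retained
states). These lengths are generous for the data sizes the package targets:
chains initialised from independent random assignments agree on the retained
summaries, and the sampler is verified exactly against brute-force
enumeration of all C^N assignment vectors on small instances
(`exhaustive_posterior`, total-variation < 0.02).

**Posterior samples.** At every retained sweep, θ and φ are drawn from
their Dirichlet full conditionals given the count tables
(θ_l ~ Dir(n_l· + α), φ_c ~ Dir(m_c· + γ)). Sampling — rather than storing
the conditional means — matters: conditional means understate posterior
spread and give systematically narrow credible intervals.

**Point estimates.** Two rules, both from count tables:
posterior mean (n + α)/(n_tot + Cα) for reporting, and the MAP rule
(n + α − 1)/(n_tot + C(α − 1)) — raw proportions when α = 1, i.e. the
maximum-likelihood estimates — used for AIC. The "MAP state" is the retained
sweep with the highest collapsed joint probability. With α < 1 the MAP rule
can go negative on empty cells; those are clamped to zero and the row
renormalised.

**Label switching.** The mixture likelihood is invariant under community
relabelling, so before pooling, every retained (θ, φ) draw is permuted to
best match the MAP sweep's conditional-mean φ (Hungarian assignment on total
L1 distance between profile rows; ties resolve to the lowest-index
permutation). The raw assignment vectors and count tables are kept in
sampler orientation, which coincides with the relabelled orientation because
the reference is the MAP sweep itself.

**Credible intervals** are element-wise equal-tailed empirical quantiles of
the relabelled draws, with linear interpolation (numpy's default, type 7).

**Log-likelihood** is the observed-data multinomial log-likelihood at given
(θ, φ), omitting the multinomial coefficient (constant in the parameters);
values are therefore comparable only across fits to the same data set —
exactly how they are used.

## Choosing the number of communities

AIC = −2·logL(θ̂_MAP, φ̂_MAP) + 2·k with k = P(C−1) + C(S−1), the free
dimensions of the θ and φ simplices. `select_communities` fits every C in a
range (optionally replicated with independent seed streams — default one
replicate; increase it to probe run-to-run stability), tabulates AIC, and
picks the per-replicate argmin with ties broken toward smaller C; with
several replicates the modal choice is reported. Because the multinomial
coefficient is omitted, absolute AIC values are not comparable across data
sets; the argmin is what matters.

## Missing data

A masked cell means *this species was not surveyed at this unit* — distinct
from an observed zero. Masked cells contribute no individuals, and a unit
with masked species is modelled as a multinomial restricted to its observed
species: its per-species probabilities Σ_c θ_lc φ_cs are renormalised over
the observed set, and the sampler's φ-normaliser for that unit sums m_cs
only over those species (maintained incrementally per species). φ itself
remains defined over all S species, pooled across units, so a species
masked in one unit is informed by the units that did survey it; a species
masked everywhere is unidentifiable and is dropped with a warning. The
restricted normaliser makes the conditional a pseudo-collapsed
approximation (the restricted multinomial has no clean collapsed form); for
complete data it is exactly the collapsed sampler, which is the case the
enumeration oracle checks.

**Imputation.** For each masked cell, the Bayesian predictive relative
abundance p̂_ls = Σ_c θ_lc φ_cs is evaluated per posterior draw and reported
as a posterior mean with an equal-tailed interval. Imputation is on the
relative-abundance scale: the model conditions on unit totals, so counts
require a user-supplied total. Observed cells are never overwritten.

**Folding-in.** New units are projected onto a previous fit by Gibbs
sampling their individual labels only, with the φ term of the conditional
frozen at the reference fit's point estimate (restricted to the new unit's
observed species). Defaults: 500 sweeps, burn-in 250 — θ_new is
low-dimensional and mixes fast. Species absent from the reference model are
dropped with a warning (the model conditions on its original species list),
and joint refitting is out of scope — that is just a fresh fit on pooled
data.

## Synthetic study designs

`synthetic` regenerates the two designs used throughout the tests.

*Gradient*: units placed evenly on [0, 1]; θ rows are normalised Gaussian
bumps (width 0.25) centred at 0, 0.5, 1, so community 1 cedes to 2 and then
3 along the gradient; φ rows are block-structured — species split into C
near-equal contiguous blocks (for S = 200, C = 3: 67/66/67, boundaries after
species 67 and 133), block species `contrast` (default 9) times as abundant
as off-block species, every species present in every community; counts are
per-unit multinomial draws (default 100 individuals). The missingness
generator masks a random half of the species in a random half of the units,
redrawing a unit's subset if masking would leave it empty.

*Toy*: three units, three species, two communities with profiles
(0.8, 0.2, 0.0) and (0.0, 0.2, 0.8); unit 2 is an exact 50–50 mixture.
Counts are expected values (deterministic) or a seeded multinomial draw.

What the gradient design emulates: smooth compositional turnover with fully
shared species pools, equal survey effort per unit, and missingness from
heterogeneous survey protocols. What it does not: unequal unit totals,
overdispersion/clumping, rare-species long tails, spatial autocorrelation
beyond the single gradient, or detection error. Passing tests on it
demonstrate correctness of the inference machinery under the model's own
assumptions, not robustness to these real-data features.

The test suite runs the design at 200 units × 100 species × 100
individuals/unit (≈20 000 individuals), a size chosen so every end-to-end
check refits from scratch in seconds while keeping ≥60 individuals per φ
cell; the generator itself produces the full 1000 × 200 layout in under
five seconds when the larger design is wanted.

## Numerical and design choices

* RNG: one `numpy` `SeedSequence` per run; replicate fits spawn child
  streams. Identical inputs + seed reproduce results bit for bit (the
  per-sweep uniforms are drawn outside the compiled kernel).
* Initialisation: uniform random assignments; single chain by default,
  `replicates` for robustness probing.
* Ties: lowest index everywhere (AIC ties toward smaller C, assignment ties
  via the deterministic Hungarian solver).
* Degenerate inputs: C > total individuals warns but runs; a unit with no
  observed individuals is rejected at container construction; a
  non-finite collapsed joint aborts the fit with diagnostics.
* Long-format input treats absent (unit, species) pairs as observed zeros —
  surveys record all listed species — with an explicit mask sidecar for
  structural missingness; this avoids silently converting zeros to missing.

## Known limitations

* **Interval calibration near the simplex boundary.** When species profiles
  overlap substantially (e.g. the gradient design's 9:1 contrast, where one
  individual carries only 9:1 evidence between communities), the posterior
  for a community that is truly absent from a unit concentrates around a few
  percent rather than at zero, and equal-tailed 95% intervals then miss
  near-zero true proportions. The calibration check in the acceptance tests
  documents this at the scaled gradient design: coverage of true θ entries
  sits below the nominal level, with the shortfall confined to entries whose
  true value is ≈0. Sharper profiles or more individuals per unit restore
  near-nominal behaviour for interior entries; intervals for clearly present
  communities are reliable.
* θ recovery is information-limited by the per-unit sample: with 100
  individuals and 9:1 profiles, posterior-mean error around 0.05–0.07 per
  entry is the attainable range even with φ known.
* C is fixed per fit; AIC comparison is a pragmatic device, not a posterior
  over C.
* Abundance data only; no covariates on θ (e.g. Dirichlet regression) and
  no spatial model.
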