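# commlda — component communities from species abundance matrices

`commlda` decomposes a sampling-units × species matrix of individual counts
into **component communities** using the Latent Dirichlet Allocation (LDA)
mixed-membership model. Each sampling unit `l` (a plot, site, sample, …) gets
a probability vector θ_l over C communities — the relative abundance of each
community at that unit — and each community `c` gets a probability vector
φ_c over the S species — the relative abundance of species within that
community. The count matrix **D** is thereby factorised, in expectation,
as D/rowsum ≈ θ·φ.

Unlike hard clustering (k-means, hierarchical), a unit may be *partly* in
several communities, so gradual compositional turnover along environmental
or temporal gradients is represented directly instead of being chopped into
artificial groups. The model is fully generative, which buys three things
practitioners usually have to bolt on: credible intervals for every
parameter, principled handling of structurally missing cells (species not
surveyed at a unit), and projection of new units onto previously estimated
communities ("folding-in"). It applies to any taxon-abundance table — forest
inventories, microbiome OTU/ASV counts, invertebrate surveys.

## Model

For unit `l` with n_l observed individuals:

    θ_l ~ Dirichlet(α·1_C)          community mixture at unit l
    φ_c ~ Dirichlet(γ·1_S)          species profile of community c
    z_i ~ Categorical(θ_l)          community of individual i
    s_i ~ Categorical(φ_{z_i})      its species

α = γ = 1 (the default) gives priors uniform on the simplex. Inference is by
**collapsed Gibbs sampling** over the individual assignments z (θ and φ
integrated out analytically), with the full conditional

    p(z_i = c) ∝ (n_lc + α) · (m_cs + γ) / (m_c + S·γ)

where `n_lc` counts unit-l individuals in community c and `m_cs` community-c
individuals of species s, both excluding individual i. Cells flagged missing
contribute no individuals and a unit's species distribution is renormalised
over its observed species. The number of communities is chosen by fitting a
range of C and comparing AIC = −2·logL(θ̂_MAP, φ̂_MAP) + 2·[P(C−1) + C(S−1)].

## Worked example

Three units, three species: unit 1 drawn from species profile
(0.8, 0.2, 0.0), unit 3 from (0.0, 0.2, 0.8), unit 2 from their average,
1000 individuals each. With two communities the middle unit should come out
as an even mixture:

```python
import commlda

truth = commlda.toy_three_unit(1000)
model = commlda.CommunityLDA(truth.data, n_communities=2)
res = model.fit(seed=1)
print(res.summary())
print(res.theta_frame().round(3))
```

```
Component-community decomposition (collapsed Gibbs LDA)
============================================================
units (P):      3    species (S):      3    communities (C): 2
tokens:      3000    priors: alpha=1.0, gamma=1.0
iterations: 2000 (burn-in 1000, thin 10, 100 samples), seed 1
log-likelihood (MAP): -2057.42    AIC: 4128.83
------------------------------------------------------------
community_1: mean share 0.501, dominant in 2 units
  top species: sp_0001 (0.798), sp_0002 (0.201), sp_0003 (0.001)
community_2: mean share 0.499, dominant in 1 units
  top species: sp_0003 (0.799), sp_0002 (0.200), sp_0001 (0.001)

           community_1  community_2
unit_0001        0.999        0.001
unit_0002        0.502        0.498
unit_0003        0.001        0.999
```

The recovered profiles match the generating ones, unit 1 and unit 3 are
pure end-members, and the middle unit is a 50–50 mixture (posterior mean
0.502/0.498, 95% interval ≈ [0.46, 0.54] per community).

Model selection, missing data and folding-in follow the same pattern:

```python
sel = commlda.CommunityLDA.select(data, range(2, 7), seed=0)   # AIC table, sel.best_C
res = commlda.CommunityLDA(masked_data, sel.best_C).fit(seed=0)
res.impute_missing()          # predictive abundance for unsurveyed cells
res.fold_in(new_units_data)   # theta for new units, phi frozen
```

## Command line

```bash
commlda simulate --design gradient --units 200 --species 100 --seed 1 --out sim/
commlda select   --input sim/counts.csv --cmin 2 --cmax 6 --seed 1 --out sel/
commlda fit      --input sim/counts.csv --communities 3 --seed 1 --out fit/
commlda foldin   --fit-dir fit/ --input new_units.csv --out fold/
commlda summarize --fit-dir fit/
```

Each output directory is self-describing: the resolved `config.yaml`,
`metadata.json` (seed, iterations, AIC), labelled CSV matrices for the
estimates (`theta.csv`, `phi.csv`) and their 95% intervals, and a run log.

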