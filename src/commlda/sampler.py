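"""Collapsed Gibbs sampler for the mixed-membership community model.

The generative model: each sampling unit ``l`` has community proportions
θ_l ~ Dirichlet(α·1_C); each component community ``c`` has species
proportions φ_c ~ Dirichlet(γ·1_S); every individual (token) in unit ``l``
draws a community z ~ Categorical(θ_l), then a species ~ Categorical(φ_z).
With α = γ = 1 the priors are uniform on their simplices.

θ and φ are integrated out analytically and the sampler moves over the
individual community assignments z only (collapsed Gibbs).  Cells flagged
as structurally missing contribute no tokens; units with missing cells use
a normaliser restricted to their observed species (see
:func:`commlda._gibbs.gibbs_sweep`).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import gammaln

from ._gibbs import gibbs_sweep
from .data import AbundanceMatrix

__all__ = [
    "ModelSpec",
    "AssignmentState",
    "FitResult",
    "expand_to_tokens",
    "gibbs_conditional",
    "run_gibbs",
    "log_likelihood",
    "point_estimates",
    "relabel",
    "credible_interval",
    "exhaustive_posterior",
    "collapsed_log_joint",
]


@dataclass(frozen=True)
class ModelSpec:
    """Number of component communities and Dirichlet concentrations."""

    n_communities: int
    alpha: float = 1.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.n_communities < 1:
            raise ValueError("n_communities must be >= 1")
        if self.alpha <= 0 or self.gamma <= 0:
            raise ValueError("Dirichlet concentrations must be positive")


@dataclass
class AssignmentState:
    """Latent community label per token plus sufficient count tables."""

    z: np.ndarray  # (N,) labels in 0..C-1
    token_unit: np.ndarray  # (N,)
    token_species: np.ndarray  # (N,)
    n_uc: np.ndarray  # (P, C) tokens per unit per community
    m_cs: np.ndarray  # (C, S) tokens per community per species
    m_c: np.ndarray  # (C,)

    @classmethod
    def from_assignments(cls, token_unit, token_species, z, P, C, S) -> "AssignmentState":
        n_uc = np.zeros((P, C), dtype=np.int64)
        m_cs = np.zeros((C, S), dtype=np.int64)
        np.add.at(n_uc, (token_unit, z), 1)
        np.add.at(m_cs, (z, token_species), 1)
        return cls(
            z=np.asarray(z, dtype=np.int64),
            token_unit=np.asarray(token_unit, dtype=np.int64),
            token_species=np.asarray(token_species, dtype=np.int64),
            n_uc=n_uc,
            m_cs=m_cs,
            m_c=m_cs.sum(axis=1),
        )

    def tables_consistent(self) -> bool:
        """True when count tables equal a fresh tally of z (conservation)."""
        ref = AssignmentState.from_assignments(
            self.token_unit, self.token_species, self.z,
            self.n_uc.shape[0], self.n_uc.shape[1], self.m_cs.shape[1],
        )
        return (
            np.array_equal(ref.n_uc, self.n_uc)
            and np.array_equal(ref.m_cs, self.m_cs)
            and np.array_equal(ref.m_c, self.m_c)
        )


@dataclass
class FitResult:
    """Posterior samples (relabeled), point estimates and traces."""

    theta_samples: np.ndarray  # (n_samples, P, C)
    phi_samples: np.ndarray  # (n_samples, C, S)
    theta_map: np.ndarray  # (P, C)
    phi_map: np.ndarray  # (C, S)
    loglik_trace: np.ndarray  # observed-data loglik per recorded iteration
    logjoint_trace: np.ndarray  # collapsed log joint per recorded iteration
    map_index: int
    spec: ModelSpec
    seed: int | None
    n_iter: int
    burnin: int
    thin: int
    unit_ids: list[str]
    species_ids: list[str]
    relabeled: bool = True
    z_samples: np.ndarray | None = None
    n_uc_samples: np.ndarray | None = None
    m_cs_samples: np.ndarray | None = None
    diverged: bool = False
    _extra: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.theta_samples.shape[0]

    @property
    def theta_mean(self) -> np.ndarray:
        return self.theta_samples.mean(axis=0)

    @property
    def phi_mean(self) -> np.ndarray:
        return self.phi_samples.mean(axis=0)

    @property
    def loglik_map(self) -> float:
        return float(self.loglik_trace[self.map_index])

    def credible_interval(self, param: str = "theta", level: float = 0.95):
        samples = self.theta_samples if param == "theta" else self.phi_samples
        if not self.relabeled:
            raise ValueError("samples are not relabeled; intervals would mix labels")
        return credible_interval(samples, level=level)


def expand_to_tokens(data: AbundanceMatrix) -> tuple[np.ndarray, np.ndarray]:
    """One token per individual in each observed cell.

    Returns (token_unit, token_species) index arrays, ordered unit-major,
    species-minor — a deterministic ordering.
    """
    counts = np.where(data.observed_mask, data.counts, 0)
    units, species = np.nonzero(counts)
    reps = counts[units, species]
    return np.repeat(units, reps), np.repeat(species, reps)


def gibbs_conditional(
    state: AssignmentState,
    unit: int,
    species: int,
    spec: ModelSpec,
    restricted_denominator: np.ndarray | None = None,
    n_species_effective: int | None = None,
) -> np.ndarray:
    """Collapsed full conditional for one token, *after* its current label
    has been removed from the count tables (minus-i convention).

    p(c) ∝ (n_uc[l,c] + α)(m_cs[c,s] + γ)/(m_c[c] + S·γ); for a unit with
    masked species, pass the restricted sums and observed-species count.
    """
    S = state.m_cs.shape[1] if n_species_effective is None else n_species_effective
    denom = (state.m_c if restricted_denominator is None else restricted_denominator) + S * spec.gamma
    p = (state.n_uc[unit] + spec.alpha) * (state.m_cs[:, species] + spec.gamma) / denom
    total = p.sum()
    assert total > 0, "conditional is non-normalisable (requires alpha, gamma > 0)"
    return p / total


def _restricted_structures(data: AbundanceMatrix):
    """CSR list, per species, of restricted units observing it."""
    P, S = data.counts.shape
    is_restricted = ~data.observed_mask.all(axis=1)
    obs_count = data.observed_mask.sum(axis=1).astype(np.int64)
    per_species: list[list[int]] = [[] for _ in range(S)]
    for l in np.nonzero(is_restricted)[0]:
        for s in np.nonzero(data.observed_mask[l])[0]:
            per_species[s].append(int(l))
    lengths = np.array([len(v) for v in per_species], dtype=np.int64)
    sru_off = np.zeros(S + 1, dtype=np.int64)
    np.cumsum(lengths, out=sru_off[1:])
    sru_flat = (
        np.concatenate([np.asarray(v, dtype=np.int64) for v in per_species if v])
        if lengths.sum()
        else np.zeros(0, dtype=np.int64)
    )
    return is_restricted, obs_count, sru_flat, sru_off


def collapsed_log_joint(n_uc: np.ndarray, m_cs: np.ndarray, alpha: float, gamma: float) -> float:
    """Log of the collapsed joint p(z, tokens) up to assignment-independent
    constants: Dirichlet-multinomial terms for units and communities."""
    m_c = m_cs.sum(axis=1)
    S = m_cs.shape[1]
    return float(
        gammaln(n_uc + alpha).sum()
        + gammaln(m_cs + gamma).sum()
        - gammaln(m_c + S * gamma).sum()
    )


def point_estimates(
    n_uc: np.ndarray,
    m_cs: np.ndarray,
    spec: ModelSpec,
    rule: str = "posterior_mean",
) -> tuple[np.ndarray, np.ndarray]:
    """θ and φ from the count tables.

    ``posterior_mean``: (n + α)/(n_tot + C·α) per unit row (and the analogue
    with γ, S for φ).  ``map``: (n + α − 1)/(n_tot + C(α − 1)); with α = 1
    this is the raw token proportion, i.e. the maximum-likelihood estimate.
    MAP cells that go negative (α < 1 with zero counts) are clamped to 0 and
    the row renormalised.
    """
    C = n_uc.shape[1]
    S = m_cs.shape[1]
    if rule == "posterior_mean":
        theta = (n_uc + spec.alpha) / (n_uc.sum(axis=1, keepdims=True) + C * spec.alpha)
        phi = (m_cs + spec.gamma) / (m_cs.sum(axis=1, keepdims=True) + S * spec.gamma)
        return theta, phi
    if rule == "map":
        theta = _map_rows(n_uc, spec.alpha)
        phi = _map_rows(m_cs, spec.gamma)
        return theta, phi
    raise ValueError(f"unknown rule: {rule!r}")


def _map_rows(table: np.ndarray, conc: float) -> np.ndarray:
    K = table.shape[1]
    num = np.maximum(table + conc - 1.0, 0.0)
    denom = num.sum(axis=1, keepdims=True)
    out = np.divide(num, denom, out=np.full_like(num, 1.0 / K, dtype=float), where=denom > 0)
    return out


def _dirichlet_rows(rng: np.random.Generator, conc: np.ndarray) -> np.ndarray:
    """Row-wise Dirichlet draw with row-specific concentration vectors."""
    g = rng.standard_gamma(conc)
    return g / g.sum(axis=1, keepdims=True)


def log_likelihood(data: AbundanceMatrix, theta: np.ndarray, phi: np.ndarray) -> float:
    """Observed-data log-likelihood Σ_l Σ_{s observed} n_ls · log p_ls with
    p_ls = Σ_c θ_lc φ_cs, renormalised over each unit's observed species.

    The multinomial coefficient is omitted (constant in the parameters), so
    values are comparable only across fits to the same data set.
    """
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if theta.shape[0] != data.n_units or phi.shape[1] != data.n_species:
        raise ValueError("theta/phi dimensions do not match the data")
    p = theta @ phi
    mask = data.observed_mask
    p = np.where(mask, p, 0.0)
    norm = p.sum(axis=1, keepdims=True)
    p = np.divide(p, norm, out=np.zeros_like(p), where=norm > 0)
    counts = np.where(mask, data.counts, 0)
    active = counts > 0
    if np.any(p[active] == 0):
        warnings.warn("zero predicted probability for an observed count; loglik = -inf")
        return float("-inf")
    return float((counts[active] * np.log(p[active])).sum())


def relabel(
    phi_samples: np.ndarray,
    theta_samples: np.ndarray,
    reference: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Undo label switching: permute each sample's communities to best match
    a reference φ (minimum total L1 distance, Hungarian assignment).

    Returns (phi_relabeled, theta_relabeled, permutations) where
    ``permutations[k]`` maps reference slot j to the sample's original row
    ``permutations[k][j]``.  Idempotent; ties resolve to the lowest-index
    permutation via the assignment solver's deterministic output.
    """
    n = phi_samples.shape[0]
    C = reference.shape[0]
    phi_out = np.empty_like(phi_samples)
    theta_out = np.empty_like(theta_samples)
    perms = np.empty((n, C), dtype=np.int64)
    for k in range(n):
        cost = np.abs(phi_samples[k][:, None, :] - reference[None, :, :]).sum(axis=2)
        row, col = linear_sum_assignment(cost)
        # sample row i plays reference role col[i]; invert to reference order
        perm = np.empty(C, dtype=np.int64)
        perm[col] = row
        perms[k] = perm
        phi_out[k] = phi_samples[k][perm]
        theta_out[k] = theta_samples[k][:, perm]
    return phi_out, theta_out, perms


def credible_interval(samples: np.ndarray, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
    """Element-wise equal-tailed empirical interval (type-7 linear
    interpolation quantiles)."""
    if samples.shape[0] < 2:
        raise ValueError("need at least two samples for an interval")
    lo = (1.0 - level) / 2.0
    lower = np.quantile(samples, lo, axis=0)
    upper = np.quantile(samples, 1.0 - lo, axis=0)
    return lower, upper


def run_gibbs(
    data: AbundanceMatrix,
    spec: ModelSpec,
    n_iter: int = 2000,
    burnin: int = 1000,
    thin: int = 10,
    seed=None,
    keep_z: bool = False,
    log_every: int | None = None,
    logger=None,
) -> FitResult:
    """Fit the model by collapsed Gibbs sampling.

    Assignments are initialised uniformly at random, all tokens are swept
    each iteration, and states are recorded after ``burnin`` every ``thin``
    iterations.  At every recorded iteration θ and φ are *drawn* from their
    Dirichlet full conditionals given the count tables (θ_l ~ Dir(n_l + α),
    φ_c ~ Dir(m_c + γ)), so the stored samples carry the full posterior
    spread — the conditional-mean rule alone would understate it and produce
    too-narrow credible intervals.  Samples are relabeled against φ at the
    maximum-joint recorded iteration.  Deterministic given (data, spec, run
    parameters, seed).
    """
    if not (n_iter > burnin >= 0):
        raise ValueError("need n_iter > burnin >= 0")
    if thin < 1:
        raise ValueError("thin must be >= 1")

    # species observed nowhere are unidentifiable: drop with a warning
    observed_any = data.observed_mask.any(axis=0)
    if not observed_any.all():
        dropped = [data.species_ids[j] for j in np.nonzero(~observed_any)[0]]
        warnings.warn(f"dropping species masked in all units: {dropped}")
        data = AbundanceMatrix(
            data.counts[:, observed_any],
            data.observed_mask[:, observed_any],
            data.unit_ids,
            [s for s, keep in zip(data.species_ids, observed_any) if keep],
        )

    P, S = data.counts.shape
    C = spec.n_communities
    token_unit, token_species = expand_to_tokens(data)
    N = token_unit.shape[0]
    if C > N:
        warnings.warn(f"more communities ({C}) than tokens ({N}); model is degenerate")

    rng = np.random.default_rng(np.random.SeedSequence(seed) if seed is not None else None)
    z = rng.integers(0, C, size=N).astype(np.int64)
    state = AssignmentState.from_assignments(token_unit, token_species, z, P, C, S)

    is_restricted, obs_count, sru_flat, sru_off = _restricted_structures(data)
    d = np.zeros((P, C), dtype=np.int64)
    for l in np.nonzero(is_restricted)[0]:
        obs_sp = np.nonzero(data.observed_mask[l])[0]
        d[l] = state.m_cs[:, obs_sp].sum(axis=1)

    tu32 = token_unit.astype(np.int64)
    ts32 = token_species.astype(np.int64)

    rec_n_uc, rec_m_cs, rec_z, rec_theta, rec_phi = [], [], [], [], []
    logjoint, loglik = [], []
    for it in range(1, n_iter + 1):
        u = rng.random(N)
        gibbs_sweep(
            state.z, tu32, ts32, state.n_uc, state.m_cs, state.m_c,
            d, obs_count, is_restricted, sru_flat, sru_off,
            float(spec.alpha), float(spec.gamma), S, u,
        )
        record = it > burnin and (it - burnin) % thin == 0
        if record:
            rec_n_uc.append(state.n_uc.copy())
            rec_m_cs.append(state.m_cs.copy())
            if keep_z:
                rec_z.append(state.z.copy())
            rec_theta.append(_dirichlet_rows(rng, state.n_uc + spec.alpha))
            rec_phi.append(_dirichlet_rows(rng, state.m_cs + spec.gamma))
            lj = collapsed_log_joint(state.n_uc, state.m_cs, spec.alpha, spec.gamma)
            th, ph = point_estimates(state.n_uc, state.m_cs, spec, "posterior_mean")
            ll = log_likelihood(data, th, ph)
            if not np.isfinite(lj):
                raise FloatingPointError(
                    f"non-finite collapsed joint at iteration {it} "
                    f"(C={C}, N={N}); aborting"
                )
            logjoint.append(lj)
            loglik.append(ll)
        if log_every and logger is not None and it % log_every == 0:
            th, ph = point_estimates(state.n_uc, state.m_cs, spec, "posterior_mean")
            logger(it, log_likelihood(data, th, ph))

    if not state.tables_consistent():  # pragma: no cover - internal invariant
        raise AssertionError("count tables diverged from assignments")

    n_samples = len(rec_n_uc)
    logjoint = np.asarray(logjoint)
    loglik = np.asarray(loglik)
    map_index = int(np.argmax(logjoint))

    theta_samples = np.stack(rec_theta)
    phi_samples = np.stack(rec_phi)

    # relabel against the conditional-mean phi at the MAP iteration (a
    # stable reference; a single Dirichlet draw would be noisier)
    _, reference = point_estimates(rec_n_uc[map_index], rec_m_cs[map_index], spec, "posterior_mean")
    phi_samples, theta_samples, perms = relabel(phi_samples, theta_samples, reference)
    # count tables and assignments are kept in their raw sampler orientation;
    # since the relabeling reference is the MAP iteration's own phi, the
    # relabeled theta/phi samples share that orientation, and MAP estimates
    # can be taken from the raw MAP-iteration tables directly
    n_uc_samples = np.stack(rec_n_uc)
    m_cs_samples = np.stack(rec_m_cs)
    z_samples = np.stack(rec_z) if keep_z else None

    theta_map, phi_map = point_estimates(
        n_uc_samples[map_index], m_cs_samples[map_index], spec, "map"
    )

    return FitResult(
        theta_samples=theta_samples,
        phi_samples=phi_samples,
        theta_map=theta_map,
        phi_map=phi_map,
        loglik_trace=loglik,
        logjoint_trace=logjoint,
        map_index=map_index,
        spec=spec,
        seed=seed,
        n_iter=n_iter,
        burnin=burnin,
        thin=thin,
        unit_ids=list(data.unit_ids),
        species_ids=list(data.species_ids),
        relabeled=True,
        z_samples=z_samples,
        n_uc_samples=n_uc_samples,
        m_cs_samples=m_cs_samples,
    )


@dataclass
class ExactPosterior:
    """Exhaustive enumeration of p(z | data) for tiny instances."""

    assignments: np.ndarray  # (M, N)
    probs: np.ndarray  # (M,)
    marginals: np.ndarray  # (N, C) token-level marginals p(z_i = c)

    def prob_of(self, z) -> float:
        z = np.asarray(z)
        match = np.all(self.assignments == z[None, :], axis=1)
        return float(self.probs[match].sum())


def exhaustive_posterior(
    data: AbundanceMatrix,
    spec: ModelSpec,
    max_states: int = 1_000_000,
) -> ExactPosterior:
    """Exact posterior over assignment vectors by brute-force enumeration.

    Scores every one of the C^N assignments by the collapsed joint (product
    of Dirichlet-multinomial terms over units and communities) and
    normalises.  Only feasible for tiny instances; refuses above
    ``max_states`` states.
    """
    token_unit, token_species = expand_to_tokens(data)
    N = token_unit.shape[0]
    C = spec.n_communities
    P, S = data.counts.shape
    n_states = C**N
    if n_states > max_states:
        raise ValueError(f"{C}^{N} = {n_states} assignment vectors exceeds limit {max_states}")
    assignments = np.array(list(itertools.product(range(C), repeat=N)), dtype=np.int64)
    logp = np.empty(n_states)
    for m in range(n_states):
        st = AssignmentState.from_assignments(token_unit, token_species, assignments[m], P, C, S)
        logp[m] = collapsed_log_joint(st.n_uc, st.m_cs, spec.alpha, spec.gamma)
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    marginals = np.zeros((N, C))
    for c in range(C):
        marginals[:, c] = probs @ (assignments == c)
    return ExactPosterior(assignments=assignments, probs=probs, marginals=marginals)
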