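"""Missing-data handling, imputation, and folding-in of new sampling units.

A masked cell means the species was not surveyed at that unit, so the unit's
individuals are modelled as a multinomial restricted to its observed species.
The sampler itself handles masked data (tokens exist only for observed
cells; restricted normalisers); this module adds the post-fit operations:

* :func:`impute_missing` — Bayesian predictive relative abundances for the
  masked cells, with credible intervals, from the fit's posterior samples;
* :func:`fold_in` — estimate community proportions θ for *new* units while
  holding the community profiles φ fixed at values from a reference fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._gibbs import foldin_sweep
from .data import AbundanceMatrix
from .sampler import (
    FitResult,
    ModelSpec,
    _dirichlet_rows,
    credible_interval,
    expand_to_tokens,
    run_gibbs,
)

__all__ = [
    "FoldInResult",
    "restricted_unit_likelihood",
    "gibbs_with_missing",
    "impute_missing",
    "fold_in",
]


def restricted_unit_likelihood(
    theta_row: np.ndarray,
    phi: np.ndarray,
    mask_row: np.ndarray,
) -> np.ndarray:
    """Per-species probabilities for one unit, renormalised over the unit's
    observed species.  With nothing masked this is the plain mixture
    Σ_c θ_c φ_cs."""
    mask_row = np.asarray(mask_row, dtype=bool)
    if not mask_row.any():
        raise ValueError("all species masked for this unit")
    p = np.asarray(theta_row, dtype=float) @ np.asarray(phi, dtype=float)
    p = np.where(mask_row, p, 0.0)
    total = p.sum()
    if total <= 0:
        raise ValueError("zero probability mass on the unit's observed species")
    return p[mask_row] / total


def gibbs_with_missing(data: AbundanceMatrix, spec: ModelSpec, **run_kwargs) -> FitResult:
    """Fit with structurally missing cells.

    This is :func:`commlda.sampler.run_gibbs`, which already excludes masked
    cells from the token expansion and applies the restricted per-unit
    normaliser; the alias exists to make the missing-data entry point
    explicit.  With no masked cells the result is identical (same seed,
    bit for bit) to a plain fit.
    """
    return run_gibbs(data, spec, **run_kwargs)


def impute_missing(fit: FitResult, data: AbundanceMatrix, level: float = 0.95) -> pd.DataFrame:
    """Predictive relative abundance for every masked cell.

    For each posterior sample, the predictive probability of a masked cell
    (l, s) is p̂_ls = Σ_c θ_lc φ_cs (on the full-species scale, so imputed
    masked cells plus the model's observed-cell probabilities sum to one per
    unit).  Returns a DataFrame with posterior mean and equal-tailed
    interval per masked cell.  Observed cells are never imputed.
    """
    if not data.has_missing:
        raise ValueError("data has no masked cells to impute")
    cells = np.argwhere(~data.observed_mask)
    preds = np.einsum("klc,kcs->kls", fit.theta_samples, fit.phi_samples)
    rows = []
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    for l, s in cells:
        vals = preds[:, l, s]
        rows.append(
            {
                "unit": data.unit_ids[l],
                "species": data.species_ids[s],
                "p_mean": float(vals.mean()),
                "p_lower": float(np.quantile(vals, lo_q)),
                "p_upper": float(np.quantile(vals, hi_q)),
            }
        )
    return pd.DataFrame(rows)


def predictive_cell(fit: FitResult, data: AbundanceMatrix, unit: int, species: int) -> np.ndarray:
    """Per-sample predictive p̂ for one masked cell; refuses observed cells."""
    if data.observed_mask[unit, species]:
        raise ValueError(
            f"cell (unit {unit}, species {species}) is observed; observed data are never overwritten"
        )
    return np.einsum(
        "kc,kc->k", fit.theta_samples[:, unit, :], fit.phi_samples[:, :, species]
    )


@dataclass
class FoldInResult:
    """θ estimates for new units against a frozen φ."""

    theta_samples: np.ndarray  # (n_samples, P_new, C)
    theta_mean: np.ndarray  # (P_new, C)
    phi_used: np.ndarray  # (C, S) — unchanged by the operation
    unit_ids: list[str]
    species_ids: list[str]
    imputed: pd.DataFrame | None = None

    def credible_interval(self, level: float = 0.95):
        return credible_interval(self.theta_samples, level=level)


def fold_in(
    new_data: AbundanceMatrix,
    phi_fixed: np.ndarray,
    species_ids: list[str],
    spec: ModelSpec,
    n_iter: int = 500,
    burnin: int = 250,
    thin: int = 5,
    seed=None,
) -> FoldInResult:
    """Estimate community proportions for new units with φ frozen.

    Gibbs sampling runs over the new units' token labels only; the
    community-by-species term of the conditional uses the fixed φ
    probabilities (restricted to each unit's observed species) instead of
    evolving count tables.  Species in ``new_data`` absent from the model
    are dropped with a warning — the model conditions on its original
    species list, so abundance of novel species cannot inform predictions.
    """
    phi_fixed = np.asarray(phi_fixed, dtype=float)
    C = spec.n_communities
    if phi_fixed.shape != (C, len(species_ids)):
        raise ValueError("phi shape does not match spec/species_ids")
    model_index = {s: j for j, s in enumerate(species_ids)}
    keep = [j for j, s in enumerate(new_data.species_ids) if s in model_index]
    if not keep:
        raise ValueError("no species in common between new data and the model")
    extra = [s for s in new_data.species_ids if s not in model_index]
    if extra:
        warnings.warn(
            f"dropping {len(extra)} species absent from the model: {extra[:5]}"
            + ("..." if len(extra) > 5 else "")
        )
    sub = AbundanceMatrix(
        new_data.counts[:, keep],
        new_data.observed_mask[:, keep],
        new_data.unit_ids,
        [new_data.species_ids[j] for j in keep],
    )
    # columns of phi aligned to the retained new-data species
    col = np.array([model_index[s] for s in sub.species_ids])
    phi_cols = np.maximum(phi_fixed[:, col], 1e-300)

    P_new = sub.n_units
    token_unit, token_species = expand_to_tokens(sub)
    N = token_unit.shape[0]
    rng = np.random.default_rng(np.random.SeedSequence(seed) if seed is not None else None)
    z = rng.integers(0, C, size=N).astype(np.int64)
    n_uc = np.zeros((P_new, C), dtype=np.int64)
    np.add.at(n_uc, (token_unit, z), 1)

    # per-unit restricted phi normaliser (frozen for the whole run)
    denom = np.empty((P_new, C))
    for l in range(P_new):
        obs = sub.observed_mask[l]
        denom[l] = phi_cols[:, obs].sum(axis=1)
    if np.any(denom <= 0):
        raise ValueError("a new unit's observed species have zero mass under every community")

    if not (n_iter > burnin >= 0 and thin >= 1):
        raise ValueError("need n_iter > burnin >= 0 and thin >= 1")
    thetas = []
    for it in range(1, n_iter + 1):
        u = rng.random(N)
        foldin_sweep(z, token_unit.astype(np.int64), token_species.astype(np.int64),
                     n_uc, phi_cols, denom, float(spec.alpha), u)
        if it > burnin and (it - burnin) % thin == 0:
            thetas.append(_dirichlet_rows(rng, n_uc + spec.alpha))
    theta_samples = np.stack(thetas)

    imputed = None
    if sub.has_missing or len(keep) < len(species_ids):
        # predictive relative abundance (full model species scale) for
        # masked cells of the new units
        cells = np.argwhere(~sub.observed_mask)
        if cells.size:
            rows = []
            for l, j in cells:
                s_model = col[j]
                vals = theta_samples[:, l, :] @ phi_fixed[:, s_model]
                rows.append(
                    {
                        "unit": sub.unit_ids[l],
                        "species": sub.species_ids[j],
                        "p_mean": float(vals.mean()),
                        "p_lower": float(np.quantile(vals, 0.025)),
                        "p_upper": float(np.quantile(vals, 0.975)),
                    }
                )
            imputed = pd.DataFrame(rows)

    return FoldInResult(
        theta_samples=theta_samples,
        theta_mean=theta_samples.mean(axis=0),
        phi_used=phi_fixed,
        unit_ids=list(sub.unit_ids),
        species_ids=list(species_ids),
        imputed=imputed,
    )
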