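"""AIC and selection of the number of component communities.

The number of communities C is fixed within a fit, so models with C over a
candidate range are fitted separately and compared by AIC,
AIC = −2·logL(θ̂, φ̂) + 2·k, evaluated at the maximum-a-posteriori
estimates (with uniform simplex priors these approximate the maximum-
likelihood estimates).  The free-parameter count is

    k = P·(C − 1) + C·(S − 1)

— the dimensions of the θ (P rows of a C-simplex) and φ (C rows of an
S-simplex) matrices.  Because the log-likelihood omits the multinomial
coefficient, AIC values are comparable only between fits to the same data,
which is their only use here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import AbundanceMatrix
from .sampler import FitResult, ModelSpec, log_likelihood, run_gibbs

__all__ = ["param_count", "aic", "SelectionTable", "select_communities"]


def param_count(C: int, P: int, S: int) -> int:
    """Free parameters of the θ/φ factorisation: P(C−1) + C(S−1)."""
    if min(C, P, S) < 1:
        raise ValueError("C, P, S must all be >= 1")
    return P * (C - 1) + C * (S - 1)


def aic(fit: FitResult, data: AbundanceMatrix) -> float:
    """−2·loglik at the MAP estimates + 2·param_count."""
    ll = log_likelihood(data, fit.theta_map, fit.phi_map)
    k = param_count(fit.spec.n_communities, data.n_units, len(fit.species_ids))
    if not np.isfinite(ll):
        warnings.warn("MAP log-likelihood is -inf; AIC set to +inf")
        return float("inf")
    return -2.0 * ll + 2.0 * k


@dataclass
class SelectionTable:
    """Per-fit AIC table and the selected number of communities."""

    table: pd.DataFrame  # columns: C, replicate, seed, loglik_map, k_params, aic, failed
    best_C: int
    fits: dict  # (C, replicate) -> FitResult for successful fits

    def best_fit(self) -> FitResult:
        ok = self.table[~self.table["failed"] & (self.table["C"] == self.best_C)]
        row = ok.loc[ok["aic"].idxmin()]
        return self.fits[(int(row["C"]), int(row["replicate"]))]


def select_communities(
    data: AbundanceMatrix,
    C_range,
    replicates: int = 1,
    alpha: float = 1.0,
    gamma: float = 1.0,
    n_iter: int = 2000,
    burnin: int = 1000,
    thin: int = 10,
    seed=None,
    keep_fits: bool = True,
) -> SelectionTable:
    """Fit each candidate C (optionally several replicate chains with
    independent seed streams) and tabulate AIC.

    ``best_C`` is the modal per-replicate AIC argmin; ties break toward the
    smaller C (parsimony).  A fit that aborts is recorded as a failed row and
    selection proceeds on the rest.
    """
    C_range = list(C_range)
    if not C_range:
        raise ValueError("C_range is empty")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(C_range) * replicates)
    rows = []
    fits: dict = {}
    idx = 0
    for C in C_range:
        for rep in range(replicates):
            child_seed = int(children[idx].generate_state(1)[0] % (2**31))
            idx += 1
            spec = ModelSpec(n_communities=C, alpha=alpha, gamma=gamma)
            try:
                fit = run_gibbs(data, spec, n_iter=n_iter, burnin=burnin, thin=thin, seed=child_seed)
                a = aic(fit, data)
                ll = log_likelihood(data, fit.theta_map, fit.phi_map)
                rows.append(
                    dict(C=C, replicate=rep, seed=child_seed, loglik_map=ll,
                         k_params=param_count(C, data.n_units, len(fit.species_ids)),
                         aic=a, failed=False)
                )
                if keep_fits:
                    fits[(C, rep)] = fit
            except (FloatingPointError, ValueError) as exc:
                warnings.warn(f"fit failed for C={C}, replicate {rep}: {exc}")
                rows.append(
                    dict(C=C, replicate=rep, seed=child_seed, loglik_map=np.nan,
                         k_params=param_count(C, data.n_units, data.n_species),
                         aic=np.inf, failed=True)
                )
    table = pd.DataFrame(rows)
    ok = table[~table["failed"]]
    if ok.empty:
        raise RuntimeError("all fits failed; cannot select a model")
    # per-replicate argmin, ties to smaller C, then the modal choice
    per_rep = []
    for rep, grp in ok.groupby("replicate"):
        grp = grp.sort_values(["aic", "C"], kind="stable")
        per_rep.append(int(grp.iloc[0]["C"]))
    values, counts = np.unique(per_rep, return_counts=True)
    best = int(values[np.lexsort((values, -counts))][0])
    return SelectionTable(table=table, best_C=best, fits=fits)
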