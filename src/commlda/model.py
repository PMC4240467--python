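"""Model/Results interface for the component-community decomposition.

Typical use::

    import commlda

    model = commlda.CommunityLDA.from_dataframe(df, n_communities=3)
    res = model.fit(seed=1)
    print(res.summary())
    theta_lo, theta_hi = res.credible_interval("theta")

``CommunityLDA`` holds the data and prior settings; ``fit`` runs the
collapsed Gibbs sampler and returns a :class:`CommunityLDAResults` carrying
relabeled posterior samples, point estimates, credible intervals, AIC, and
the post-fit operations (imputation of masked cells, folding-in new units).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import foldin as _foldin
from . import selection as _selection
from .data import AbundanceMatrix
from .sampler import FitResult, ModelSpec, log_likelihood, run_gibbs

__all__ = ["CommunityLDA", "CommunityLDAResults"]


class CommunityLDA:
    """Mixed-membership multinomial model of a units × species count matrix.

    Parameters
    ----------
    data : AbundanceMatrix or (P, S) int array
        Individual counts per species per sampling unit.  Cells flagged as
        missing in the AbundanceMatrix mask are treated as "not surveyed".
    n_communities : int
        Number of component communities C.
    alpha, gamma : float
        Dirichlet concentrations for unit mixtures θ and community profiles
        φ; 1.0 gives priors uniform on the simplex.
    """

    def __init__(self, data, n_communities: int, alpha: float = 1.0, gamma: float = 1.0):
        if not isinstance(data, AbundanceMatrix):
            data = AbundanceMatrix(np.asarray(data))
        self.data = data
        self.spec = ModelSpec(n_communities=n_communities, alpha=alpha, gamma=gamma)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, n_communities: int, **kwargs) -> "CommunityLDA":
        """Wide DataFrame (rows = units, columns = species, NaN = missing)."""
        return cls(AbundanceMatrix.from_frame(df), n_communities, **kwargs)

    @property
    def n_communities(self) -> int:
        return self.spec.n_communities

    def fit(
        self,
        n_iter: int = 2000,
        burnin: int = 1000,
        thin: int = 10,
        seed=None,
        **kwargs,
    ) -> "CommunityLDAResults":
        """Run the collapsed Gibbs sampler; see
        :func:`commlda.sampler.run_gibbs` for the algorithm."""
        fit = run_gibbs(self.data, self.spec, n_iter=n_iter, burnin=burnin,
                        thin=thin, seed=seed, **kwargs)
        return CommunityLDAResults(self, fit)

    @staticmethod
    def select(data, C_range, **kwargs) -> _selection.SelectionTable:
        """AIC selection of the number of communities; see
        :func:`commlda.selection.select_communities`."""
        if not isinstance(data, AbundanceMatrix):
            data = AbundanceMatrix(np.asarray(data))
        return _selection.select_communities(data, C_range, **kwargs)


class CommunityLDAResults:
    """Posterior summaries of a fitted component-community decomposition."""

    def __init__(self, model: CommunityLDA, fit: FitResult):
        self.model = model
        self.fit = fit

    # -- point estimates ------------------------------------------------
    @property
    def theta_mean(self) -> np.ndarray:
        """Posterior-mean community proportions per unit (P × C)."""
        return self.fit.theta_mean

    @property
    def phi_mean(self) -> np.ndarray:
        """Posterior-mean species profiles per community (C × S)."""
        return self.fit.phi_mean

    @property
    def theta_map(self) -> np.ndarray:
        return self.fit.theta_map

    @property
    def phi_map(self) -> np.ndarray:
        return self.fit.phi_map

    @property
    def theta_samples(self) -> np.ndarray:
        return self.fit.theta_samples

    @property
    def phi_samples(self) -> np.ndarray:
        return self.fit.phi_samples

    # -- fit quality -----------------------------------------------------
    @property
    def loglik(self) -> float:
        """Observed-data log-likelihood at the MAP estimates."""
        return log_likelihood(self.model.data, self.fit.theta_map, self.fit.phi_map)

    @property
    def aic(self) -> float:
        return _selection.aic(self.fit, self.model.data)

    @property
    def loglik_trace(self) -> np.ndarray:
        return self.fit.loglik_trace

    def credible_interval(self, param: str = "theta", level: float = 0.95):
        return self.fit.credible_interval(param, level)

    # -- post-fit operations ----------------------------------------------
    def impute_missing(self, level: float = 0.95) -> pd.DataFrame:
        """Predictive relative abundance (mean + interval) per masked cell."""
        return _foldin.impute_missing(self.fit, self.model.data, level=level)

    def fold_in(self, new_data: AbundanceMatrix, use: str = "mean", **kwargs) -> _foldin.FoldInResult:
        """Estimate θ for new units, holding this fit's φ fixed.

        ``use``: which φ point estimate to freeze, "mean" or "map".
        """
        phi = self.phi_mean if use == "mean" else self.phi_map
        return _foldin.fold_in(new_data, phi, self.fit.species_ids, self.fit.spec, **kwargs)

    # -- tabular views -----------------------------------------------------
    def theta_frame(self) -> pd.DataFrame:
        cols = [f"community_{c + 1}" for c in range(self.fit.spec.n_communities)]
        return pd.DataFrame(self.theta_mean, index=self.fit.unit_ids, columns=cols)

    def phi_frame(self) -> pd.DataFrame:
        idx = [f"community_{c + 1}" for c in range(self.fit.spec.n_communities)]
        return pd.DataFrame(self.phi_mean, index=idx, columns=self.fit.species_ids)

    def top_species(self, n: int = 10) -> dict[str, list[tuple[str, float]]]:
        """Highest-relative-abundance species per community."""
        out = {}
        for c in range(self.fit.spec.n_communities):
            order = np.argsort(self.phi_mean[c])[::-1][:n]
            out[f"community_{c + 1}"] = [
                (self.fit.species_ids[j], float(self.phi_mean[c, j])) for j in order
            ]
        return out

    def dominant_community(self) -> pd.Series:
        """Index (1-based) of the largest posterior-mean community per unit."""
        return pd.Series(
            np.argmax(self.theta_mean, axis=1) + 1, index=self.fit.unit_ids, name="dominant"
        )

    def summary(self, top_n: int = 5) -> str:
        f = self.fit
        C = f.spec.n_communities
        P = len(f.unit_ids)
        S = len(f.species_ids)
        share = self.theta_mean.mean(axis=0)
        lines = [
            "Component-community decomposition (collapsed Gibbs LDA)",
            "=" * 60,
            f"units (P): {P:>6}    species (S): {S:>6}    communities (C): {C}",
            f"tokens:    {int(self.model.data.n_tokens):>6}    priors: alpha={f.spec.alpha}, gamma={f.spec.gamma}",
            f"iterations: {f.n_iter} (burn-in {f.burnin}, thin {f.thin}, {f.n_samples} samples), seed {f.seed}",
            f"log-likelihood (MAP): {self.loglik:.2f}    AIC: {self.aic:.2f}",
            "-" * 60,
        ]
        dom = self.dominant_community()
        tops = self.top_species(top_n)
        for c in range(C):
            name = f"community_{c + 1}"
            n_dom = int((dom == c + 1).sum())
            sp = ", ".join(f"{s} ({v:.3f})" for s, v in tops[name])
            lines.append(f"{name}: mean share {share[c]:.3f}, dominant in {n_dom} units")
            lines.append(f"  top species: {sp}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<CommunityLDAResults C={self.fit.spec.n_communities} "
            f"P={len(self.fit.unit_ids)} S={len(self.fit.species_ids)} "
            f"samples={self.fit.n_samples}>"
        )
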