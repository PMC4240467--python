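"""Synthetic study designs with known ground truth.

Two designs are provided, both small enough to regenerate at run time:

* a **gradient** design — sampling units placed systematically along a
  one-dimensional gradient on which three component communities replace one
  another gradually, with block-structured species profiles (each community
  favours a contiguous block of species by a configurable contrast ratio);
* a three-unit, three-species **toy** whose middle unit is an exact 50–50
  mixture of the two end-member communities.

The gradient design defaults to 3 communities, 200 species and 100
individuals per unit; per-unit mixing weights are normalised Gaussian bumps
centred at gradient positions 0, 0.5 and 1.  The missingness generator masks
a random half of the species in a random half of the units — the regime in
which mixed-membership models must pool information across units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import AbundanceMatrix

__all__ = [
    "SyntheticTruth",
    "gradient_theta",
    "block_phi",
    "sample_counts",
    "apply_missingness",
    "toy_three_unit",
    "make_gradient_dataset",
]


@dataclass
class SyntheticTruth:
    """Ground-truth parameters plus the counts drawn from them."""

    theta_true: np.ndarray  # (P, C)
    phi_true: np.ndarray  # (C, S)
    data: AbundanceMatrix
    design: dict

    @property
    def n_communities(self) -> int:
        return self.theta_true.shape[1]


def gradient_theta(n_units: int, n_communities: int = 3, width: float = 0.25) -> np.ndarray:
    """Community proportions along a gradient: Gaussian bumps at equally
    spaced centres on [0, 1], normalised per unit.

    Unit 1 is dominated by community 1 and the last unit by the last
    community; intermediate communities peak mid-gradient.
    """
    if n_units < n_communities:
        raise ValueError("need at least as many units as communities")
    x = np.linspace(0.0, 1.0, n_units)
    centres = np.linspace(0.0, 1.0, n_communities)
    bumps = np.exp(-((x[:, None] - centres[None, :]) ** 2) / (2.0 * width**2))
    return bumps / bumps.sum(axis=1, keepdims=True)


def _block_sizes(S: int, C: int) -> list[int]:
    # remainder species go to the outer blocks first: S=200, C=3 -> 67/66/67
    base, rem = divmod(S, C)
    sizes = [base] * C
    order: list[int] = []
    lo, hi = 0, C - 1
    while lo <= hi:
        order.append(lo)
        if hi != lo:
            order.append(hi)
        lo += 1
        hi -= 1
    for k in range(rem):
        sizes[order[k]] += 1
    return sizes


def block_phi(n_species: int = 200, n_communities: int = 3, contrast: float = 9.0) -> np.ndarray:
    """Block-structured species profiles.

    Species are partitioned into C contiguous blocks of near-equal size;
    community ``c`` gives each species of block ``c`` a relative abundance
    ``contrast`` times that of any off-block species.  All entries are
    strictly positive: every community shares all species.
    """
    if n_species < n_communities:
        raise ValueError("need at least as many species as communities")
    if contrast < 1:
        raise ValueError("contrast must be >= 1")
    sizes = _block_sizes(n_species, n_communities)
    bounds = np.cumsum([0] + sizes)
    phi = np.ones((n_communities, n_species), dtype=float)
    for c in range(n_communities):
        phi[c, bounds[c] : bounds[c + 1]] = contrast
    return phi / phi.sum(axis=1, keepdims=True)


def sample_counts(
    theta_true: np.ndarray,
    phi_true: np.ndarray,
    individuals_per_unit: int,
    seed,
) -> AbundanceMatrix:
    """Multinomial draw of ``individuals_per_unit`` per unit from θφ."""
    theta_true = np.asarray(theta_true, dtype=float)
    phi_true = np.asarray(phi_true, dtype=float)
    if theta_true.shape[1] != phi_true.shape[0]:
        raise ValueError("theta and phi community dimensions differ")
    if individuals_per_unit < 1:
        raise ValueError("individuals_per_unit must be >= 1")
    rng = np.random.default_rng(seed)
    probs = theta_true @ phi_true
    counts = np.vstack(
        [rng.multinomial(individuals_per_unit, probs[l]) for l in range(probs.shape[0])]
    )
    return AbundanceMatrix(counts=counts)


def apply_missingness(
    data: AbundanceMatrix,
    frac_units: float = 0.5,
    frac_species: float = 0.5,
    seed=None,
) -> AbundanceMatrix:
    """Mask a random ``frac_species`` subset of species in a random
    ``frac_units`` subset of units (independent subsets per unit).

    Guarantees every unit keeps at least one observed individual; a unit's
    species subset is redrawn if masking would empty it.
    """
    if not (0 <= frac_units < 1 and 0 <= frac_species < 1):
        raise ValueError("fractions must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    P, S = data.counts.shape
    n_mask_units = int(frac_units * P)
    n_mask_species = int(frac_species * S)
    mask = data.observed_mask.copy()
    if n_mask_units == 0 or n_mask_species == 0:
        return AbundanceMatrix(data.counts, mask, data.unit_ids, data.species_ids)
    units = rng.choice(P, size=n_mask_units, replace=False)
    for l in units:
        for _ in range(1000):
            sp = rng.choice(S, size=n_mask_species, replace=False)
            trial = mask[l].copy()
            trial[sp] = False
            if data.counts[l, trial].sum() > 0:
                mask[l] = trial
                break
        else:  # pragma: no cover - pathological inputs only
            raise RuntimeError(f"could not mask unit {l} without emptying it")
    return AbundanceMatrix(data.counts, mask, data.unit_ids, data.species_ids)


def toy_three_unit(individuals_per_unit: int = 1000, deterministic: bool = True, seed=None) -> SyntheticTruth:
    """Three units, three species, two communities.

    Unit 1 is pure community "red" (profile (0.8, 0.2, 0.0)), unit 3 pure
    community "green" ((0.0, 0.2, 0.8)) and unit 2 an exact 50–50 mixture of
    the two.  Counts are the expected counts rounded (deterministic, the
    default) or a seeded multinomial draw.
    """
    phi = np.array([[0.8, 0.2, 0.0], [0.0, 0.2, 0.8]])
    theta = np.array([[1.0, 0.0], [0.5, 0.5], [0.0, 1.0]])
    if deterministic:
        counts = np.rint(theta @ phi * individuals_per_unit).astype(np.int64)
        data = AbundanceMatrix(counts=counts)
    else:
        data = sample_counts(theta, phi, individuals_per_unit, seed)
    return SyntheticTruth(
        theta_true=theta,
        phi_true=phi,
        data=data,
        design={
            "name": "toy_three_unit",
            "n_units": 3,
            "n_species": 3,
            "n_communities": 2,
            "individuals_per_unit": individuals_per_unit,
            "deterministic": deterministic,
            "seed": seed,
        },
    )


def make_gradient_dataset(
    n_units: int = 1000,
    n_species: int = 200,
    n_communities: int = 3,
    individuals_per_unit: int = 100,
    contrast: float = 9.0,
    width: float = 0.25,
    frac_units_missing: float = 0.0,
    frac_species_missing: float = 0.0,
    seed=None,
) -> SyntheticTruth:
    """Full gradient design: θ from :func:`gradient_theta`, φ from
    :func:`block_phi`, counts sampled, optional missingness applied."""
    ss = np.random.SeedSequence(seed)
    seed_counts, seed_mask = ss.spawn(2)
    theta = gradient_theta(n_units, n_communities, width)
    phi = block_phi(n_species, n_communities, contrast)
    data = sample_counts(theta, phi, individuals_per_unit, seed_counts)
    if frac_units_missing > 0 and frac_species_missing > 0:
        data = apply_missingness(data, frac_units_missing, frac_species_missing, seed_mask)
    return SyntheticTruth(
        theta_true=theta,
        phi_true=phi,
        data=data,
        design={
            "name": "gradient",
            "n_units": n_units,
            "n_species": n_species,
            "n_communities": n_communities,
            "individuals_per_unit": individuals_per_unit,
            "contrast": contrast,
            "width": width,
            "frac_units_missing": frac_units_missing,
            "frac_species_missing": frac_species_missing,
            "seed": seed,
        },
    )
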