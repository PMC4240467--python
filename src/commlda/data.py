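"""Abundance-matrix container and readers/writers.

The central data structure is :class:`AbundanceMatrix`: a sites-by-species
matrix of individual counts together with an observed/missing mask.  A
masked cell means "this species was not surveyed at this sampling unit" —
structural missingness — which is fundamentally different from an observed
count of zero.  Masked cells carry no information and are excluded from all
likelihood computations; zeros are data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["AbundanceMatrix", "read_abundance", "write_abundance"]


@dataclass
class AbundanceMatrix:
    """Counts of individuals per species per sampling unit, with a mask.

    Parameters
    ----------
    counts : (P, S) int array
        Number of individuals of species ``s`` observed at unit ``l``.
    observed_mask : (P, S) bool array, optional
        True where the cell was surveyed.  Defaults to all observed.
    unit_ids, species_ids : sequences of str, optional
        Row/column labels; generated if omitted.
    """

    counts: np.ndarray
    observed_mask: np.ndarray | None = None
    unit_ids: list[str] = field(default_factory=list)
    species_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D units × species matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = np.asarray(self.counts, dtype=np.int64)
            if not np.array_equal(as_int, self.counts):
                raise ValueError("counts must be integers")
            self.counts = as_int
        else:
            self.counts = self.counts.astype(np.int64)
        P, S = self.counts.shape
        if self.observed_mask is None:
            self.observed_mask = np.ones((P, S), dtype=bool)
        self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
        if self.observed_mask.shape != (P, S):
            raise ValueError("observed_mask shape does not match counts")
        neg = np.argwhere(self.counts < 0)
        if neg.size:
            l, s = neg[0]
            raise ValueError(f"negative count at unit {l}, species {s}")
        # masked cells carry no counts
        self.counts = np.where(self.observed_mask, self.counts, 0)
        obs_tokens = (self.counts * self.observed_mask).sum(axis=1)
        if np.any(obs_tokens == 0):
            l = int(np.argmin(obs_tokens))
            raise ValueError(f"unit {l} has no observed tokens")
        if not self.unit_ids:
            self.unit_ids = [f"unit_{i + 1:04d}" for i in range(P)]
        if not self.species_ids:
            self.species_ids = [f"sp_{j + 1:04d}" for j in range(S)]
        if len(self.unit_ids) != P or len(self.species_ids) != S:
            raise ValueError("label lengths do not match matrix shape")
        if len(set(self.unit_ids)) != P or len(set(self.species_ids)) != S:
            raise ValueError("duplicate unit or species labels")

    @property
    def n_units(self) -> int:
        return self.counts.shape[0]

    @property
    def n_species(self) -> int:
        return self.counts.shape[1]

    @property
    def n_tokens(self) -> int:
        """Total observed individuals."""
        return int(self.counts.sum())

    @property
    def has_missing(self) -> bool:
        return not bool(self.observed_mask.all())

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame with NaN in masked cells."""
        vals = self.counts.astype(float)
        vals[~self.observed_mask] = np.nan
        return pd.DataFrame(vals, index=self.unit_ids, columns=self.species_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AbundanceMatrix":
        """Build from a wide DataFrame; NaN cells become masked."""
        vals = df.to_numpy(dtype=float)
        mask = ~np.isnan(vals)
        counts = np.where(mask, np.nan_to_num(vals), 0.0)
        if not np.array_equal(counts, np.round(counts)):
            raise ValueError("counts must be integers")
        return cls(
            counts=counts.astype(np.int64),
            observed_mask=mask,
            unit_ids=[str(u) for u in df.index],
            species_ids=[str(s) for s in df.columns],
        )


def read_abundance(path, format: str = "wide_csv", mask_path=None) -> AbundanceMatrix:
    """Read a count matrix from disk.

    ``wide_csv``: rows = units (first column holds unit ids), columns =
    species; an empty cell or ``NA`` marks a structurally missing cell.

    ``long_tsv``: three columns ``unit\tspecies\tcount``; pairs absent from
    the file are observed zeros, NOT missing (surveys record all listed
    species).  Structural missingness must come from an explicit ``mask_path``
    sidecar — a TSV of ``unit\tspecies`` pairs to mask.
    """
    if format == "wide_csv":
        df = pd.read_csv(path, index_col=0, na_values=["NA"], keep_default_na=True)
        if df.empty:
            raise ValueError(f"empty abundance file: {path}")
        return AbundanceMatrix.from_frame(df)
    if format == "long_tsv":
        df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
        if df.empty:
            raise ValueError(f"empty abundance file: {path}")
        df.columns = ["unit", "species", "count"]
        dup = df.duplicated(subset=["unit", "species"])
        if dup.any():
            pair = df.loc[dup.idxmax(), ["unit", "species"]].tolist()
            raise ValueError(f"duplicate (unit, species) row: {pair}")
        wide = df.pivot(index="unit", columns="species", values="count").fillna(0.0)
        data = AbundanceMatrix.from_frame(wide)
        if mask_path is not None:
            mdf = pd.read_csv(mask_path, sep="\t", dtype=str)
            mdf.columns = ["unit", "species"][: len(mdf.columns)]
            uidx = {u: i for i, u in enumerate(data.unit_ids)}
            sidx = {s: j for j, s in enumerate(data.species_ids)}
            mask = data.observed_mask.copy()
            for _, row in mdf.iterrows():
                mask[uidx[row["unit"]], sidx[row["species"]]] = False
            return AbundanceMatrix(data.counts, mask, data.unit_ids, data.species_ids)
        return data
    raise ValueError(f"unknown format: {format!r}")


def write_abundance(data: AbundanceMatrix, path) -> None:
    """Write wide CSV; masked cells become ``NA``."""
    df = data.to_frame()
    out = df.astype(object)
    obs = data.observed_mask
    vals = data.counts
    for i in range(data.n_units):
        for j in range(data.n_species):
            out.iat[i, j] = int(vals[i, j]) if obs[i, j] else "NA"
    out.index.name = "unit"
    out.to_csv(path)
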