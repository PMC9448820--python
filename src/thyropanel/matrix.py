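"""Sample-by-protein abundance matrices with explicit missingness.

The :class:`AbundanceMatrix` is the common currency of the pipeline: a
samples x proteins table of log2 intensities in which missing cells are
stored as NaN.  Text serialization uses TSV with empty cells for missing
values so that matrices survive round-trips without any binary format.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["AbundanceMatrix"]


@dataclass
class AbundanceMatrix:
    """Log2 abundance matrix (rows = samples, columns = proteins).

    Parameters
    ----------
    values
        Array of shape ``(n_samples, n_proteins)``; NaN encodes a missing
        (non-detected) measurement.  Observed entries must be finite.
    sample_ids, protein_ids
        Unique string identifiers for rows and columns.
    """

    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    protein_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-dimensional")
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.protein_ids = [str(p) for p in self.protein_ids]
        n, p = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.protein_ids) != p:
            raise ValueError(f"{len(self.protein_ids)} protein ids for {p} columns")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample ids are not unique")
        if len(set(self.protein_ids)) != p:
            raise ValueError("protein ids are not unique")
        observed = self.values[~np.isnan(self.values)]
        if observed.size and not np.all(np.isfinite(observed)):
            raise ValueError("observed values must be finite")

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_proteins(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean mask, True where the measurement is missing."""
        return np.isnan(self.values)

    @property
    def missing_fraction(self) -> float:
        return float(self.missing_mask.mean()) if self.values.size else 0.0

    def missing_rate_per_protein(self) -> pd.Series:
        return pd.Series(self.missing_mask.mean(axis=0), index=self.protein_ids)

    # ------------------------------------------------------------------
    def subset_samples(self, sample_ids: list[str]) -> "AbundanceMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            rows = [index[s] for s in sample_ids]
        except KeyError as exc:
            raise KeyError(f"unknown sample id {exc.args[0]!r}") from None
        return AbundanceMatrix(self.values[rows, :], list(sample_ids), list(self.protein_ids))

    def subset_proteins(self, protein_ids: list[str]) -> "AbundanceMatrix":
        index = {p: i for i, p in enumerate(self.protein_ids)}
        try:
            cols = [index[p] for p in protein_ids]
        except KeyError as exc:
            raise KeyError(f"unknown protein id {exc.args[0]!r}") from None
        return AbundanceMatrix(self.values[:, cols], list(self.sample_ids), list(protein_ids))

    def column(self, protein_id: str) -> np.ndarray:
        return self.values[:, self.protein_ids.index(protein_id)]

    # ------------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.protein_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "AbundanceMatrix":
        return cls(frame.to_numpy(dtype=float), list(map(str, frame.index)), list(map(str, frame.columns)))

    def write_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t", na_rep="")

    @classmethod
    def read_tsv(cls, path) -> "AbundanceMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls.from_frame(frame)

    def equals(self, other: "AbundanceMatrix") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and self.protein_ids == other.protein_ids
            and np.array_equal(self.values, other.values, equal_nan=True)
        )
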