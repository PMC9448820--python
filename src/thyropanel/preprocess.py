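"""Detection-limit imputation, discovery-anchored normalization, replicate QC.

Missing cells are filled with the ceiling of the minimum observed value of
the discovery matrix; each feature is then z-transformed with the mean and
standard deviation estimated on the (imputed) discovery matrix.  The fitted
model is applied unchanged to any test matrix, so test data never influence
the transform.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .matrix import AbundanceMatrix

__all__ = [
    "NormalizationModel",
    "QCReport",
    "fit_normalizer",
    "apply_normalizer",
    "impute_matrix",
    "aggregate_replicates",
    "filter_by_missing_rate",
    "replicate_qc",
]


@dataclass
class NormalizationModel:
    """Imputation constant and per-feature (mu, sigma) from a discovery set."""

    impute_value: float
    mu: np.ndarray
    sigma: np.ndarray
    feature_ids: list[str]
    dropped_features: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not float(self.impute_value).is_integer():
            raise ValueError("impute_value must be integer-valued (a ceiling)")
        if len(self.feature_ids) != self.mu.size or self.mu.size != self.sigma.size:
            raise ValueError("feature_ids, mu and sigma must have equal length")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma entries must be > 0 for all retained features")

    def to_json(self, path) -> None:
        payload = {
            "impute_value": self.impute_value,
            "feature_ids": self.feature_ids,
            "mu": self.mu.tolist(),
            "sigma": self.sigma.tolist(),
            "dropped_features": self.dropped_features,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "NormalizationModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            impute_value=payload["impute_value"],
            mu=np.array(payload["mu"]),
            sigma=np.array(payload["sigma"]),
            feature_ids=list(payload["feature_ids"]),
            dropped_features=list(payload.get("dropped_features", [])),
        )


@dataclass
class QCReport:
    """Replicate-level quality report."""

    cv_per_group: dict[str, np.ndarray]
    spearman_per_pair: dict[tuple[str, str], float]
    median_cv: float
    median_spearman: float
    skipped_groups: list[str] = field(default_factory=list)


def impute_matrix(matrix: AbundanceMatrix, impute_value: float) -> AbundanceMatrix:
    """Fill every missing cell with ``impute_value`` (idempotent)."""
    values = np.where(np.isnan(matrix.values), float(impute_value), matrix.values)
    return AbundanceMatrix(values, list(matrix.sample_ids), list(matrix.protein_ids))


def fit_normalizer(
    discovery: AbundanceMatrix,
    on_zero_variance: str = "drop",
) -> NormalizationModel:
    """Fit the imputation constant and per-feature (mu, sigma) on a discovery set.

    ``impute_value`` is the ceiling of the global minimum observed value;
    mu and sigma (ddof=1) are computed after imputation.  Features with zero
    variance after imputation are dropped with a warning (``on_zero_variance
    = "drop"``) or raise (``"error"``).
    """
    if discovery.n_samples < 2:
        raise ValueError("need at least 2 samples to fit a normalizer")
    observed = discovery.values[~np.isnan(discovery.values)]
    if observed.size == 0:
        raise ValueError("discovery matrix has no observed values")
    n_obs = (~np.isnan(discovery.values)).sum(axis=0)
    if np.any(n_obs < 2):
        bad = [p for p, n in zip(discovery.protein_ids, n_obs) if n < 2]
        raise ValueError(f"features observed fewer than twice: {bad[:5]}{'...' if len(bad) > 5 else ''}")
    impute_value = float(math.ceil(observed.min()))
    filled = np.where(np.isnan(discovery.values), impute_value, discovery.values)
    mu = filled.mean(axis=0)
    sigma = filled.std(axis=0, ddof=1)
    keep = sigma > 0
    dropped = [p for p, k in zip(discovery.protein_ids, keep) if not k]
    if dropped:
        if on_zero_variance == "error":
            raise ValueError(f"zero-variance features after imputation: {dropped}")
        warnings.warn(f"dropping {len(dropped)} zero-variance feature(s): {dropped[:5]}", stacklevel=2)
    return NormalizationModel(
        impute_value=impute_value,
        mu=mu[keep],
        sigma=sigma[keep],
        feature_ids=[p for p, k in zip(discovery.protein_ids, keep) if k],
        dropped_features=dropped,
    )


def apply_normalizer(model: NormalizationModel, matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Impute with the model constant and z-transform with the model (mu, sigma).

    The output is restricted to the model's features in model order and has
    no missing cells.  Every model feature must be present in ``matrix``.
    """
    missing = [p for p in model.feature_ids if p not in set(matrix.protein_ids)]
    if missing:
        raise KeyError(f"matrix lacks model features: {missing[:5]}{'...' if len(missing) > 5 else ''}")
    sub = matrix.subset_proteins(model.feature_ids)
    filled = np.where(np.isnan(sub.values), model.impute_value, sub.values)
    normalized = (filled - model.mu) / model.sigma
    return AbundanceMatrix(normalized, list(sub.sample_ids), list(sub.protein_ids))


def aggregate_replicates(
    matrix: AbundanceMatrix, replicate_groups: Mapping[str, Sequence[str]]
) -> AbundanceMatrix:
    """Average replicate samples per nodule, cell-wise on observed values.

    A cell missing in all replicates of a nodule stays missing.  Runs before
    imputation so the fill constant never biases replicate means.  Output
    rows are sorted by nodule id, so the result is independent of the
    mapping's iteration order.
    """
    nodules = sorted(replicate_groups)
    out = np.empty((len(nodules), matrix.n_proteins))
    for i, nodule in enumerate(nodules):
        sub = matrix.subset_samples(list(replicate_groups[nodule]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            out[i] = np.nanmean(sub.values, axis=0)
    return AbundanceMatrix(out, nodules, list(matrix.protein_ids))


def filter_by_missing_rate(matrix: AbundanceMatrix, max_missing: float = 0.9) -> AbundanceMatrix:
    """Keep features quantified with a missing rate strictly below ``max_missing``."""
    if not (0 < max_missing <= 1):
        raise ValueError("max_missing must lie in (0, 1]")
    rates = matrix.missing_mask.mean(axis=0)
    keep = [p for p, r in zip(matrix.protein_ids, rates) if r < max_missing]
    return matrix.subset_proteins(keep)


def replicate_qc(
    matrix: AbundanceMatrix,
    replicate_groups: Mapping[str, Sequence[str]],
    min_common: int = 3,
) -> QCReport:
    """Per-group CVs and pairwise Spearman correlations of replicates.

    CV = sd/mean per protein within a replicate group, computed on observed
    values only (proteins observed at least twice in the group).  Spearman
    correlations are computed per replicate pair on proteins observed in
    both samples (at least ``min_common``).  Groups with < 2 samples are
    skipped with a warning.
    """
    cvs: dict[str, np.ndarray] = {}
    rhos: dict[tuple[str, str], float] = {}
    skipped: list[str] = []
    for nodule in sorted(replicate_groups):
        sids = list(replicate_groups[nodule])
        if len(sids) < 2:
            skipped.append(nodule)
            warnings.warn(f"replicate group {nodule!r} has < 2 samples; skipped", stacklevel=2)
            continue
        sub = matrix.subset_samples(sids)
        vals = sub.values
        n_obs = (~np.isnan(vals)).sum(axis=0)
        ok = n_obs >= 2
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sd = np.nanstd(vals[:, ok], axis=0, ddof=1)
            mean = np.nanmean(vals[:, ok], axis=0)
        cv = np.where(mean != 0, sd / np.abs(mean), np.nan)
        cvs[nodule] = cv[~np.isnan(cv)]
        for a in range(len(sids)):
            for b in range(a + 1, len(sids)):
                both = ~np.isnan(vals[a]) & ~np.isnan(vals[b])
                if both.sum() < min_common:
                    continue
                rho = spearmanr(vals[a, both], vals[b, both]).statistic
                rhos[(sids[a], sids[b])] = float(rho)
    all_cv = np.concatenate([v for v in cvs.values()]) if cvs else np.array([])
    median_cv = float(np.median(all_cv)) if all_cv.size else float("nan")
    median_rho = float(np.median(list(rhos.values()))) if rhos else float("nan")
    return QCReport(cvs, rhos, median_cv, median_rho, skipped)
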