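"""Synthetic thyroid-nodule cohort generator.

Produces abundance matrices with the statistical structure the downstream
stages assume: a pooled log2 intensity distribution matched to target
quartiles, a planted subset of proteins that separate benign from malignant
nodules, detection-limit (MNAR) censoring calibrated to an overall missing
fraction, and optional replicate samples per nodule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .matrix import AbundanceMatrix

__all__ = [
    "BENIGN_HISTOTYPES",
    "MALIGNANT_HISTOTYPES",
    "HISTOTYPE_CLASS",
    "CohortConfig",
    "SyntheticCohort",
    "CalibrationError",
    "generate_cohort",
    "split_cohort",
]

BENIGN_HISTOTYPES = frozenset({"N", "MNG", "FA", "L", "HCA"})
MALIGNANT_HISTOTYPES = frozenset({"FTC", "PTC", "HCC", "fvPTC"})

#: Total, deterministic histotype -> class mapping.
HISTOTYPE_CLASS: dict[str, str] = {
    **{h: "benign" for h in sorted(BENIGN_HISTOTYPES)},
    **{h: "malignant" for h in sorted(MALIGNANT_HISTOTYPES)},
}

# Third quartile of the standard normal; used for the split-normal fit.
_Z75 = 0.6744897501960817


class CalibrationError(RuntimeError):
    """Raised when the missingness target cannot be reached by censoring."""


@dataclass
class CohortConfig:
    """Knobs of the cohort generator.

    ``effect_size`` is the log2-units mean shift applied to malignant
    nodules for the planted informative proteins (alternating up/down).
    ``noise_sd`` is the replicate-level technical noise, ``biological_sd``
    the between-nodule spread within a protein.
    """

    n_per_histotype: Mapping[str, int]
    n_proteins: int
    n_informative: int = 0
    effect_size: float = 2.0
    base_quartiles: tuple[float, float, float] = (18.0, 19.0, 20.3)
    missing_fraction_target: float = 0.51
    detection_steepness: float = 1.5
    replicate_count: int = 1
    noise_sd: float = 0.25
    biological_sd: float = 1.0
    histotype_offsets: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for h, n in self.n_per_histotype.items():
            if h not in HISTOTYPE_CLASS:
                raise ValueError(f"unknown histotype {h!r}")
            if n < 0:
                raise ValueError("histotype counts must be >= 0")
        if self.n_proteins < 0 or self.n_informative < 0:
            raise ValueError("counts must be >= 0")
        if self.n_informative > self.n_proteins:
            raise ValueError("n_informative must be <= n_proteins")
        if not (0.0 <= self.missing_fraction_target <= 0.95):
            raise ValueError("missing_fraction_target must lie in [0, 0.95]")
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be >= 1")
        q1, q2, q3 = self.base_quartiles
        if not (q1 < q2 < q3):
            raise ValueError("base_quartiles must be strictly increasing")
        if self.detection_steepness <= 0:
            raise ValueError("detection_steepness must be > 0")
        if self.noise_sd < 0 or self.biological_sd < 0:
            raise ValueError("standard deviations must be >= 0")

    @property
    def n_nodules(self) -> int:
        return int(sum(self.n_per_histotype.values()))

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["n_per_histotype"] = dict(self.n_per_histotype)
        payload["histotype_offsets"] = dict(self.histotype_offsets)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CohortConfig":
        with open(path) as fh:
            payload = json.load(fh)
        payload["base_quartiles"] = tuple(payload.get("base_quartiles", (18.0, 19.0, 20.3)))
        return cls(**payload)


@dataclass
class SyntheticCohort:
    """A generated cohort: matrix, per-sample annotation, and ground truth."""

    matrix: AbundanceMatrix
    annotation: pd.DataFrame
    truth_informative: frozenset[str]
    truth_detection_threshold: float

    def __post_init__(self) -> None:
        if list(self.annotation.index) != self.matrix.sample_ids:
            raise ValueError("annotation rows must match matrix samples one-to-one")
        labels = self.annotation["histotype"].map(HISTOTYPE_CLASS)
        if labels.isna().any():
            raise ValueError("annotation contains an unmapped histotype")
        if "label" in self.annotation and not (self.annotation["label"] == labels).all():
            raise ValueError("label column inconsistent with histotype mapping")

    @property
    def labels(self) -> pd.Series:
        """benign/malignant label per sample."""
        return self.annotation["label"]

    @property
    def replicate_groups(self) -> dict[str, list[str]]:
        """nodule id -> sample ids."""
        groups: dict[str, list[str]] = {}
        for sample, nodule in self.annotation["nodule_id"].items():
            groups.setdefault(nodule, []).append(sample)
        return groups

    def write(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.matrix.write_tsv(out / "matrix.tsv")
        ann = self.annotation.copy()
        ann.index.name = "sample_id"
        ann.to_csv(out / "annotation.tsv", sep="\t")
        truth = {
            "informative_proteins": sorted(self.truth_informative),
            "detection_threshold": self.truth_detection_threshold,
        }
        with open(out / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=2)


def _split_normal_from_draws(
    side: np.ndarray, mags: np.ndarray, quartiles: tuple[float, float, float]
) -> np.ndarray:
    """Two-piece normal with the given quartiles, from standardized draws.

    ``side`` (booleans, lower half) and ``mags`` (|N(0,1)| magnitudes) are
    drawn once so the output is a deterministic function of ``quartiles``.
    """
    q1, q2, q3 = quartiles
    sd_lo = (q2 - q1) / _Z75
    sd_hi = (q3 - q2) / _Z75
    return np.where(side, q2 - mags * sd_lo, q2 + mags * sd_hi)


def _calibrate_threshold(values: np.ndarray, target: float, steepness: float) -> float:
    """Solve for the logistic detection threshold giving the target missing rate.

    Missingness probability for a cell with latent intensity ``x`` is
    ``sigmoid(-steepness * (x - t))``: high below the threshold ``t``,
    vanishing far above it.
    """

    def mean_missing(t: float) -> float:
        return float(np.mean(expit(-steepness * (values - t)))) - target

    lo = float(values.min()) - 200.0 / steepness
    hi = float(values.max()) + 200.0 / steepness
    f_lo, f_hi = mean_missing(lo), mean_missing(hi)
    if f_lo > 0 or f_hi < 0:
        raise CalibrationError(
            f"missing fraction target {target} unreachable: attainable range "
            f"[{f_lo + target:.4g}, {f_hi + target:.4g}]"
        )
    return float(brentq(mean_missing, lo, hi, xtol=1e-10))


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a cohort deterministically from ``config`` (including its seed).

    Latent complete intensities are drawn so that the pooled distribution
    approximates ``base_quartiles``; the first ``n_informative`` proteins
    receive an ``effect_size`` malignant-vs-benign shift with alternating
    sign; cells are then censored to missing with probability decreasing in
    abundance, the threshold calibrated to ``missing_fraction_target``.
    """
    rng = np.random.default_rng(config.seed)
    width = max(4, len(str(max(config.n_proteins, 1))))
    protein_ids = [f"P{i:0{width}d}" for i in range(config.n_proteins)]
    informative = protein_ids[: config.n_informative]

    effects = np.zeros(config.n_proteins)
    if config.n_informative:
        signs = np.where(np.arange(config.n_informative) % 2 == 0, 1.0, -1.0)
        effects[: config.n_informative] = signs * config.effect_size

    nodule_rows = []
    for histotype in sorted(config.n_per_histotype):
        for k in range(config.n_per_histotype[histotype]):
            nodule_rows.append((f"{histotype}_{k:04d}", histotype))
    n_nodules = len(nodule_rows)
    n_samples = n_nodules * config.replicate_count

    # draw every random quantity once so the censoring calibration below is
    # a deterministic fixed-point iteration
    mean_side = rng.random(config.n_proteins) < 0.5
    mean_mags = np.abs(rng.standard_normal(config.n_proteins))
    # informative proteins are planted in the high-abundance tail (>= the
    # upper quartile): panel features are reported as more abundant than
    # the global median with very low missingness, and a heavily censored
    # protein cannot carry recoverable signal
    mean_side[: config.n_informative] = False
    mean_mags[: config.n_informative] = np.maximum(mean_mags[: config.n_informative], 1.15)
    bio_noise = rng.standard_normal((n_nodules, config.n_proteins)) * config.biological_sd
    rep_noise = rng.standard_normal((n_samples, config.n_proteins)) * config.noise_sd
    censor_u = rng.random((n_samples, config.n_proteins))

    sample_ids: list[str] = []
    ann_rows: list[dict] = []
    for i, (nodule_id, histotype) in enumerate(nodule_rows):
        for r in range(config.replicate_count):
            sid = nodule_id if config.replicate_count == 1 else f"{nodule_id}_rep{r + 1}"
            sample_ids.append(sid)
            ann_rows.append(
                {
                    "sample_id": sid,
                    "nodule_id": nodule_id,
                    "histotype": histotype,
                    "label": HISTOTYPE_CLASS[histotype],
                    "replicate": r + 1,
                }
            )

    def build_values(quartiles: tuple[float, float, float]) -> np.ndarray:
        protein_means = _split_normal_from_draws(mean_side, mean_mags, quartiles)
        vals = np.empty((n_samples, config.n_proteins))
        row = 0
        for i, (_nodule_id, histotype) in enumerate(nodule_rows):
            shift = effects if HISTOTYPE_CLASS[histotype] == "malignant" else 0.0
            nodule_mean = (
                protein_means + shift + config.histotype_offsets.get(histotype, 0.0) + bio_noise[i]
            )
            for _r in range(config.replicate_count):
                vals[row] = nodule_mean + rep_noise[row]
                row += 1
        return vals

    # Censoring removes preferentially low values, so the *observed*
    # distribution sits above the latent one.  Iterate the generating
    # quartiles so the post-censoring observed quartiles land on target.
    target_q = np.asarray(config.base_quartiles, dtype=float)
    working_q = target_q.copy()
    values = build_values(tuple(working_q))
    threshold = -np.inf
    censored = np.zeros(values.shape, dtype=bool)
    if values.size:
        for _iteration in range(6):
            if config.missing_fraction_target > 0:
                threshold = _calibrate_threshold(
                    values, config.missing_fraction_target, config.detection_steepness
                )
                p_miss = expit(-config.detection_steepness * (values - threshold))
                censored = censor_u < p_miss
            observed = values[~censored]
            err = target_q - np.quantile(observed, [0.25, 0.5, 0.75])
            if np.all(np.abs(err) < 1e-3):
                break
            working_q = working_q + err
            working_q.sort()  # guard monotonicity of the working quartiles
            values = build_values(tuple(working_q))
        values = np.where(censored, np.nan, values)

    matrix = AbundanceMatrix(values, sample_ids, protein_ids)
    annotation = pd.DataFrame(ann_rows).set_index("sample_id")
    return SyntheticCohort(matrix, annotation, frozenset(informative), threshold)


def _largest_remainder(total: int, fractions: Sequence[float]) -> list[int]:
    raw = [total * f for f in fractions]
    base = [int(np.floor(x)) for x in raw]
    short = total - sum(base)
    order = sorted(range(len(raw)), key=lambda j: raw[j] - base[j], reverse=True)
    for j in order[:short]:
        base[j] += 1
    return base


def split_cohort(
    cohort: SyntheticCohort,
    fractions: Sequence[float],
    stratify_by: str = "histotype",
    seed: int = 0,
) -> list[SyntheticCohort]:
    """Partition a cohort into stratified splits at nodule granularity.

    Replicates of a nodule never straddle splits.  Global split sizes (in
    nodules) follow the largest-remainder rounding of ``fractions``; within
    each stratum the allocation is as proportional as the global targets
    allow.
    """
    fractions = list(fractions)
    if any(f <= 0 for f in fractions):
        raise ValueError("fractions must be positive")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if stratify_by not in cohort.annotation.columns:
        raise KeyError(f"annotation has no column {stratify_by!r}")
    n_splits = len(fractions)

    # one stratum value per nodule (replicates share annotation values)
    nodule_ann = cohort.annotation.groupby("nodule_id")[stratify_by].first()
    strata: dict[str, list[str]] = {}
    for nodule, value in nodule_ann.items():
        strata.setdefault(str(value), []).append(nodule)

    rng = np.random.default_rng(seed)
    n_total = len(nodule_ann)
    targets = _largest_remainder(n_total, fractions)

    # per-stratum floor allocation, then hand out remainders to whichever
    # split is furthest below its global target
    alloc: dict[str, list[int]] = {}
    deficits = list(targets)
    extras: list[tuple[float, str, int]] = []
    for name in sorted(strata):
        nodules = strata[name]
        if len(nodules) < n_splits:
            raise ValueError(
                f"stratum {name!r} has {len(nodules)} nodules for {n_splits} splits"
            )
        raw = [len(nodules) * f for f in fractions]
        base = [int(np.floor(x)) for x in raw]
        alloc[name] = base
        for j in range(n_splits):
            deficits[j] -= base[j]
        extras.extend((raw[j] - base[j], name, j) for j in range(n_splits))
    # rank all (stratum, split) fractional remainders; greedily fill deficits
    extras.sort(key=lambda t: (-t[0], t[1], t[2]))
    remaining = {name: len(strata[name]) - sum(alloc[name]) for name in strata}
    for _, name, j in extras:
        if remaining[name] > 0 and deficits[j] > 0:
            alloc[name][j] += 1
            remaining[name] -= 1
            deficits[j] -= 1
    # any leftovers (deficit structure exhausted): assign arbitrarily but
    # deterministically
    for name in sorted(remaining):
        while remaining[name] > 0:
            j = int(np.argmax(deficits))
            alloc[name][j] += 1
            remaining[name] -= 1
            deficits[j] -= 1

    split_nodules: list[list[str]] = [[] for _ in range(n_splits)]
    for name in sorted(strata):
        nodules = list(strata[name])
        rng.shuffle(nodules)
        start = 0
        for j, count in enumerate(alloc[name]):
            split_nodules[j].extend(nodules[start : start + count])
            start += count

    groups = cohort.replicate_groups
    out = []
    for j in range(n_splits):
        sids = [s for nodule in split_nodules[j] for s in groups[nodule]]
        # preserve original sample order for determinism
        order = {s: i for i, s in enumerate(cohort.matrix.sample_ids)}
        sids.sort(key=order.__getitem__)
        out.append(
            SyntheticCohort(
                cohort.matrix.subset_samples(sids),
                cohort.annotation.loc[sids].copy(),
                cohort.truth_informative,
                cohort.truth_detection_threshold,
            )
        )
    sizes = [c.matrix.n_samples for c in out]
    if sum(sizes) != cohort.matrix.n_samples:
        raise AssertionError("split lost or duplicated samples")
    return out
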