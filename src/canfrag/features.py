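"""Sample-by-feature matrices from size distributions and repeated SVM-RFE selection.

Feature discovery follows the repeated-subsampling protocol: 100 iterations,
each drawing a stratified 70% training subset, standardizing per column with
train statistics, and running linear-SVM recursive feature elimination down to
a fixed number of survivors.  Per-position survival frequencies are aggregated
over iterations and thresholded into maximal contiguous base-pair regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.feature_selection import RFE
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC

from .fragdist import FragmentSizeDistribution, bin_distribution
from .reference import SIZE_MAX, SIZE_MIN

logger = logging.getLogger(__name__)

LABEL_CODES = {"normal": 0, "hemangiosarcoma": 1, "post_operative": 1}


@dataclass(frozen=True)
class FeatureSpec:
    """What to extract per sample: the full 1-bp grid, listed positions, or 5-bp bins."""

    name: str
    kind: str = "full_grid"  # full_grid | positions | bins
    positions: tuple = ()
    description: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("full_grid", "positions", "bins"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.kind == "positions":
            if not self.positions:
                raise ValueError("positions spec needs at least one position")
            if len(set(self.positions)) != len(self.positions):
                raise ValueError("duplicate positions")
            for p in self.positions:
                if not SIZE_MIN <= p <= SIZE_MAX:
                    raise ValueError(f"position {p} outside [{SIZE_MIN}, {SIZE_MAX}]")


@dataclass
class FeatureMatrix:
    sample_ids: list[str]
    labels: np.ndarray  # 0 normal, 1 hemangiosarcoma
    values: np.ndarray  # samples x features
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.feature_names)):
            raise ValueError("values shape inconsistent with ids/names")
        if len(self.labels) != len(self.sample_ids):
            raise ValueError("label count != sample count")
        if np.isnan(self.values).any():
            raise ValueError("feature matrix contains missing values")


@dataclass
class SelectionResult:
    """Per-position survival frequencies and the merged selected regions."""

    feature_names: list[str]
    positions: np.ndarray  # bp position per feature (grid/bin start)
    selection_frequency: np.ndarray  # in [0, 1]
    selected_regions: list[tuple[int, int]]  # inclusive bp intervals
    n_iterations: int
    train_fraction: float
    frequency_cutoff: float


def build_feature_matrix(dists: list[FragmentSizeDistribution], labels,
                         spec: FeatureSpec = FeatureSpec("full_grid")) -> FeatureMatrix:
    """Assemble the samples x features density matrix for one feature spec.

    ``labels`` may be group names (mapped via :data:`LABEL_CODES`) or 0/1 codes.
    """
    if not dists:
        raise ValueError("no distributions")
    grids = {(d.size_min, d.size_max) for d in dists}
    if len(grids) != 1:
        raise ValueError("all samples must share the size grid")
    codes = np.array([LABEL_CODES[l] if isinstance(l, str) else int(l) for l in labels])
    if spec.kind == "full_grid":
        values = np.vstack([d.density for d in dists])
        names = [f"size_{s}" for s in dists[0].sizes]
    elif spec.kind == "positions":
        idx = [p - dists[0].size_min for p in spec.positions]
        values = np.vstack([d.density[idx] for d in dists])
        names = [f"size_{p}" for p in spec.positions]
    else:  # bins
        binned = [bin_distribution(d) for d in dists]
        values = np.vstack([b.density for b in binned])
        names = [f"bin_{s}" for s in binned[0].bin_starts]
    return FeatureMatrix([d.sample_id for d in dists], codes, values, names)


def _feature_positions(names: list[str]) -> np.ndarray:
    return np.array([int(n.split("_")[1]) for n in names])


def merge_regions(positions: np.ndarray, selected: np.ndarray,
                  gap_tolerance: int = 2) -> list[tuple[int, int]]:
    """Merge selected bp positions into maximal runs, bridging gaps <= tolerance.

    Idempotent; returns sorted, disjoint inclusive intervals.
    """
    pos = np.sort(positions[selected])
    if pos.size == 0:
        return []
    regions = []
    start = prev = int(pos[0])
    for p in pos[1:]:
        if p - prev <= gap_tolerance + 1:
            prev = int(p)
        else:
            regions.append((start, prev))
            start = prev = int(p)
    regions.append((start, prev))
    return regions


def svm_rfe_select(matrix: FeatureMatrix, n_iterations: int = 100,
                   train_fraction: float = 0.7, frequency_cutoff: float = 0.5,
                   n_survivors: int = 20, step_fraction: float = 0.1,
                   gap_tolerance: int = 2, seed: int = 0) -> SelectionResult:
    """Repeated stratified-subsample linear-SVM RFE feature discovery.

    Each iteration: stratified 70% draw, per-column standardization with train
    statistics, recursive elimination (dropping ``step_fraction`` of remaining
    features per step) down to ``n_survivors``; survivors are tallied and
    positions with frequency >= ``frequency_cutoff`` merged into regions.
    """
    X, y = matrix.values, matrix.labels
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("need at least two samples per class for stratified draws")
    n_survivors = min(n_survivors, X.shape[1])
    rng = np.random.default_rng(seed)
    hits = np.zeros(X.shape[1])
    for _ in range(n_iterations):
        it_seed = int(rng.integers(2**31))
        X_tr, _, y_tr, _ = train_test_split(
            X, y, train_size=train_fraction, stratify=y, random_state=it_seed)
        mu = X_tr.mean(axis=0)
        sd = X_tr.std(axis=0)
        sd[sd == 0] = 1.0
        Z = (X_tr - mu) / sd
        rfe = RFE(SVC(kernel="linear"), n_features_to_select=n_survivors,
                  step=step_fraction)
        rfe.fit(Z, y_tr)
        hits += rfe.support_
    freq = hits / n_iterations
    positions = _feature_positions(matrix.feature_names)
    regions = merge_regions(positions, freq >= frequency_cutoff, gap_tolerance)
    return SelectionResult(matrix.feature_names, positions, freq, regions,
                           n_iterations, train_fraction, frequency_cutoff)


def fold_change_screen(cohort_a: list[FragmentSizeDistribution],
                       cohort_b: list[FragmentSizeDistribution],
                       region: tuple[int, int]) -> np.ndarray:
    """Per-position ratio of mean densities A/B over an inclusive bp region.

    Zero denominators yield +inf (flagged by a warning).
    """
    lo, hi = region
    size_min = cohort_a[0].size_min
    size_max = cohort_a[0].size_max
    if not (size_min <= lo <= hi <= size_max):
        raise ValueError(f"region {region} outside grid")
    sl = slice(lo - size_min, hi - size_min + 1)
    mean_a = np.vstack([d.density for d in cohort_a]).mean(axis=0)[sl]
    mean_b = np.vstack([d.density for d in cohort_b]).mean(axis=0)[sl]
    with np.errstate(divide="ignore"):
        ratio = np.where(mean_b > 0, mean_a / np.where(mean_b > 0, mean_b, 1.0), np.inf)
    if np.isinf(ratio).any():
        logger.warning("fold_change_screen: %d positions with zero denominator",
                       int(np.isinf(ratio).sum()))
    return ratio
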