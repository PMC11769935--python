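"""Normalized fragment-size distributions, 5-bp binning, and cohort summaries.

A per-sample histogram is rescaled so its densities sum to one; cohort curves
are per-size means with (n-1)-denominator standard deviations. All statistics
are computed at native 1-bp resolution; the 5-bp binning is a display/feature
view (the oscillation sub-peaks live at 1-bp positions and would be destroyed
by binning first).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .fragio import FragmentLengthHistogram
from .reference import BIN_WIDTH, SIZE_MAX, SIZE_MIN

logger = logging.getLogger(__name__)


@dataclass
class FragmentSizeDistribution:
    """Per-sample fragment-size density on the 1-bp grid [size_min, size_max]; sums to 1."""

    sample_id: str
    density: np.ndarray
    size_min: int = SIZE_MIN
    size_max: int = SIZE_MAX

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=float)
        expected = self.size_max - self.size_min + 1
        if self.density.shape != (expected,):
            raise ValueError(f"density must have length {expected}")
        if (self.density < 0).any():
            raise ValueError("densities must be non-negative")
        if abs(self.density.sum() - 1.0) > 1e-9:
            raise ValueError(f"densities must sum to 1 (got {self.density.sum():.12f})")

    @property
    def sizes(self) -> np.ndarray:
        return np.arange(self.size_min, self.size_max + 1)

    def density_at(self, size_bp: int) -> float:
        if not self.size_min <= size_bp <= self.size_max:
            raise KeyError(f"size {size_bp} outside grid")
        return float(self.density[size_bp - self.size_min])


@dataclass
class BinnedDistribution:
    """Fragment-size density summed into half-open width-``width`` bins."""

    sample_id: str
    bin_starts: np.ndarray
    density: np.ndarray
    width: int = BIN_WIDTH


@dataclass
class CohortSummary:
    """Per-size mean and standard deviation of a group's distributions."""

    group_label: str
    mean_density: np.ndarray
    sd_density: np.ndarray
    n_samples: int
    size_min: int = SIZE_MIN
    size_max: int = SIZE_MAX

    @property
    def sizes(self) -> np.ndarray:
        return np.arange(self.size_min, self.size_max + 1)

    def mean_distribution(self) -> FragmentSizeDistribution:
        """The cohort mean as a distribution (itself a valid density)."""
        return FragmentSizeDistribution(
            f"{self.group_label}:mean", self.mean_density, self.size_min, self.size_max
        )


def normalize(hist: FragmentLengthHistogram) -> FragmentSizeDistribution:
    """Scale counts so the aggregate fragment-size density equals 1."""
    total = hist.total
    if total == 0:
        raise ValueError(f"{hist.sample_id}: empty sample (zero total count)")
    return FragmentSizeDistribution(
        hist.sample_id, hist.counts / total, hist.size_min, hist.size_max
    )


def bin_distribution(dist: FragmentSizeDistribution, width: int = BIN_WIDTH) -> BinnedDistribution:
    """Sum 1-bp densities into half-open [start, start+width) bins from size_min.

    The number of bins is the integer part of span/width (73 for the default
    grid and width 5, bin starts 74..434); the final bin absorbs any trailing
    remainder of the inclusive grid so total mass is conserved exactly.
    """
    if width <= 0:
        raise ValueError("width must be > 0")
    n_sizes = dist.size_max - dist.size_min + 1
    n_bins = max(n_sizes // width, 1)
    starts = dist.size_min + width * np.arange(n_bins)
    density = np.array([
        dist.density[i * width:(i + 1) * width].sum() if i < n_bins - 1
        else dist.density[i * width:].sum()
        for i in range(n_bins)
    ])
    return BinnedDistribution(dist.sample_id, starts, density, width)


def cohort_summary(dists: list[FragmentSizeDistribution], group_label: str) -> CohortSummary:
    """Per-size arithmetic mean and sample (n-1) standard deviation of a cohort."""
    if not dists:
        raise ValueError("need at least one distribution")
    grids = {(d.size_min, d.size_max) for d in dists}
    if len(grids) != 1:
        raise ValueError(f"mixed grids in cohort: {sorted(grids)}")
    stack = np.vstack([d.density for d in dists])
    mean = stack.mean(axis=0)
    if len(dists) == 1:
        warnings.warn(f"{group_label}: single-sample cohort, sd set to 0", stacklevel=2)
        sd = np.zeros_like(mean)
    else:
        sd = stack.std(axis=0, ddof=1)
    return CohortSummary(group_label, mean, sd, len(dists), dists[0].size_min, dists[0].size_max)


def proportion_below(dist: FragmentSizeDistribution, threshold_bp: int = 174) -> float:
    """Total density of fragments strictly shorter than ``threshold_bp``."""
    if not dist.size_min <= threshold_bp <= dist.size_max:
        raise ValueError(f"threshold {threshold_bp} outside grid")
    return float(dist.density[: threshold_bp - dist.size_min].sum())


# ---------------------------------------------------------------------------
# cohort manifest I/O and plotting

VALID_GROUPS = {"normal", "hemangiosarcoma", "post_operative"}


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest TSV: sample_id, group, histogram_path."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "group", "histogram_path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
    if df.empty:
        raise ValueError(f"{path}: empty manifest")
    bad = set(df["group"]) - VALID_GROUPS
    if bad:
        raise ValueError(f"{path}: unknown groups {sorted(bad)}")
    return df


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def summary_to_frame(summaries: list[CohortSummary]) -> pd.DataFrame:
    """Long-format table (size_bp, group, mean, sd) for one or more summaries."""
    frames = [
        pd.DataFrame({"size_bp": s.sizes, "group": s.group_label,
                      "mean": s.mean_density, "sd": s.sd_density})
        for s in summaries
    ]
    return pd.concat(frames, ignore_index=True)


def plot_cohorts(summaries: list[CohortSummary], path: str | Path,
                 colors: dict[str, str] | None = None) -> None:
    """Mean +/- sd fragment-size curves per group (size on x, density on y)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = colors or {"normal": "black", "hemangiosarcoma": "red"}
    band = {"normal": "green", "hemangiosarcoma": "orange"}
    fig, ax = plt.subplots(figsize=(9, 4.5))
    for s in summaries:
        c = colors.get(s.group_label, None)
        ax.plot(s.sizes, s.mean_density, color=c, lw=1.2,
                label=f"{s.group_label} (n={s.n_samples})")
        ax.fill_between(s.sizes, s.mean_density - s.sd_density,
                        s.mean_density + s.sd_density,
                        color=band.get(s.group_label, c), alpha=0.3, lw=0)
    ax.set_xlabel("fragment size (bp)")
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
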