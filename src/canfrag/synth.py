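"""Synthetic cfDNA cohorts: fragment-size mixtures with nucleosome periodicity,
tumor-fraction mixing, and binned genome coverage with GC bias and spiked CNAs.

The fragment-size profile of each group is a normalized mixture of
* a sharp main-peak Gaussian fixing the mode (165 bp normal, 160 bp tumor),
* a broad mono-nucleosome envelope carrying the bulk of the mass,
* a di-nucleosome shoulder near 330 bp (strongly reduced in tumors, producing
  the 5-20x normal excess of long fragments around 336-395 bp),
* eight sub-peak Gaussians at 81..154 bp whose amplitudes equal the published
  per-cycle diff statistics of each group (so oscillation contrasts are
  anchored to printed values, not invented effect sizes),
* an exponential short-fragment floor (heavier in tumors).

Tumor samples are multinomial draws from (1-f)*normal + f*tumor mixtures with
per-sample tumor fraction f ~ Beta(5, 2); normals use f = 0.  All generators
are pure functions of (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .fragio import FragmentLengthHistogram, write_histogram_tsv
from .fragdist import FragmentSizeDistribution
from .reference import (
    MAIN_PEAK_NORMAL_BP,
    MAIN_PEAK_TUMOR_BP,
    REFERENCE_DIFFS,
    SIZE_MAX,
    SIZE_MIN,
    SUBPEAK_POSITIONS_BP,
)

#: sub-peak Gaussian amplitudes are the published per-cycle diff statistics
#: scaled by this factor (the measured diff of a bump riding a sloped envelope
#: is smaller than its amplitude) and floored for detectability
SUBPEAK_AMPLITUDE_SCALE = 1.8
SUBPEAK_AMPLITUDE_FLOOR = 0.0012

_SQRT_2PI = float(np.sqrt(2.0 * np.pi))


@dataclass(frozen=True)
class ProfileParams:
    """Mixture parameters of one group's fragment-size density.

    Component weights are mixture masses (they are normalized jointly, so only
    ratios matter); sub-peak weights default to the published per-cycle diff
    amplitudes converted to Gaussian masses.
    """

    main_peak_bp: float
    main_peak_sd: float
    main_peak_weight: float
    envelope_bp: float
    envelope_sd: float
    envelope_weight: float
    dinucleosome_bp: float
    dinucleosome_sd: float
    dinucleosome_weight: float
    subpeak_positions: tuple = tuple(SUBPEAK_POSITIONS_BP)
    subpeak_weights: tuple = ()
    subpeak_sd: float = 2.0
    baseline_decay: float = 25.0
    baseline_weight: float = 0.033
    uniform_weight: float = 0.002  # flat noise floor; dominates beyond ~400 bp

    def __post_init__(self) -> None:
        for name in ("main_peak_sd", "envelope_sd", "dinucleosome_sd",
                     "subpeak_sd", "baseline_decay"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if len(self.subpeak_weights) != len(self.subpeak_positions):
            raise ValueError("subpeak_weights must match subpeak_positions")
        if any(w < 0 for w in self.subpeak_weights) or self.main_peak_weight < 0 \
                or self.envelope_weight < 0 or self.dinucleosome_weight < 0 \
                or self.baseline_weight < 0 or self.uniform_weight < 0:
            raise ValueError("all weights must be >= 0")


def _amplitudes_to_masses(amplitudes: np.ndarray, sd: float) -> tuple:
    """Convert desired Gaussian peak amplitudes (density units) to mixture masses."""
    return tuple(float(a) * sd * _SQRT_2PI for a in amplitudes)


def _subpeak_amplitudes(group: str) -> np.ndarray:
    return np.maximum(SUBPEAK_AMPLITUDE_SCALE * REFERENCE_DIFFS[group],
                      SUBPEAK_AMPLITUDE_FLOOR)


def normal_profile_params() -> ProfileParams:
    """Default healthy-dog profile: mode 165 bp, published normal diff amplitudes."""
    sd = 2.0
    return ProfileParams(
        main_peak_bp=MAIN_PEAK_NORMAL_BP, main_peak_sd=2.5, main_peak_weight=0.0564,
        envelope_bp=188.0, envelope_sd=42.0, envelope_weight=1.19,
        dinucleosome_bp=332.0, dinucleosome_sd=35.0, dinucleosome_weight=0.057,
        subpeak_weights=_amplitudes_to_masses(_subpeak_amplitudes("normal"), sd),
        subpeak_sd=sd, baseline_decay=25.0, baseline_weight=0.033,
        uniform_weight=0.002,
    )


def tumor_profile_params() -> ProfileParams:
    """Default hemangiosarcoma profile: mode 160 bp, ~2x oscillation amplitudes,
    heavier short-fragment floor, strongly reduced di-nucleosome shoulder."""
    sd = 2.0
    return ProfileParams(
        main_peak_bp=MAIN_PEAK_TUMOR_BP, main_peak_sd=1.6, main_peak_weight=0.0481,
        envelope_bp=166.0, envelope_sd=27.0, envelope_weight=0.893,
        dinucleosome_bp=325.0, dinucleosome_sd=30.0, dinucleosome_weight=0.006,
        subpeak_weights=_amplitudes_to_masses(_subpeak_amplitudes("hemangiosarcoma"), sd),
        subpeak_sd=sd, baseline_decay=22.0, baseline_weight=0.045,
        uniform_weight=0.004,
    )


def _gaussian(grid: np.ndarray, mu: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((grid - mu) / sd) ** 2) / (sd * _SQRT_2PI)


def build_profile(params: ProfileParams,
                  size_min: int = SIZE_MIN, size_max: int = SIZE_MAX
                  ) -> FragmentSizeDistribution:
    """Evaluate the mixture on the 1-bp grid and normalize it to sum to 1."""
    grid = np.arange(size_min, size_max + 1, dtype=float)
    y = params.baseline_weight * np.exp(-(grid - size_min) / params.baseline_decay) \
        / params.baseline_decay
    y = y + params.envelope_weight * _gaussian(grid, params.envelope_bp, params.envelope_sd)
    y = y + params.main_peak_weight * _gaussian(grid, params.main_peak_bp, params.main_peak_sd)
    y = y + params.dinucleosome_weight * _gaussian(
        grid, params.dinucleosome_bp, params.dinucleosome_sd)
    y = y + params.uniform_weight / len(grid)
    for pos, w in zip(params.subpeak_positions, params.subpeak_weights):
        y = y + w * _gaussian(grid, pos, params.subpeak_sd)
    total = y.sum()
    if total <= 0:
        raise ValueError("degenerate profile: zero total mass")
    return FragmentSizeDistribution("profile", y / total, size_min, size_max)


def sample_histogram(profile: FragmentSizeDistribution, n_fragments: int,
                     tumor_fraction: float = 1.0,
                     background_profile: FragmentSizeDistribution | None = None,
                     seed: int = 0, sample_id: str = "sample"
                     ) -> FragmentLengthHistogram:
    """Multinomial draw of ``n_fragments`` from (1-f)*background + f*profile."""
    if n_fragments <= 0:
        raise ValueError("n_fragments must be > 0")
    if not 0.0 <= tumor_fraction <= 1.0:
        raise ValueError("tumor_fraction must be in [0, 1]")
    if background_profile is None:
        density = profile.density
    else:
        density = (1.0 - tumor_fraction) * background_profile.density \
            + tumor_fraction * profile.density
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_fragments, density / density.sum())
    return FragmentLengthHistogram(sample_id, counts, profile.size_min, profile.size_max)


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Study-scale cohort: 36 normals, 21 hemangiosarcoma, ~2e6 fragments each."""

    n_normal: int = 36
    n_tumor: int = 21
    fragments_per_sample: int = 2_000_000
    tumor_fraction_beta: tuple[float, float] = (5.0, 2.0)
    jitter_sd: float = 0.05
    seed: int = 0
    normal_params: ProfileParams = field(default_factory=normal_profile_params)
    tumor_params: ProfileParams = field(default_factory=tumor_profile_params)

    def __post_init__(self) -> None:
        if self.n_normal < 1 or self.n_tumor < 1:
            raise ValueError("need at least one sample per group")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")


@dataclass
class SyntheticCohort:
    """Generated histograms, labels, and per-sample truth for recovery tests."""

    histograms: list
    manifest: pd.DataFrame  # sample_id, group, histogram_path
    truth: list  # per-sample dicts: group, tumor_fraction, n_fragments

    def group_histograms(self, group: str) -> list:
        ids = set(self.manifest.loc[self.manifest["group"] == group, "sample_id"])
        return [h for h in self.histograms if h.sample_id in ids]

    def write(self, outdir: str | Path) -> Path:
        """Write per-sample histogram TSVs, the manifest TSV and truth JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest = self.manifest.copy()
        paths = []
        for hist in self.histograms:
            p = outdir / f"{hist.sample_id}.hist.tsv"
            write_histogram_tsv(hist, p)
            paths.append(str(p))
        manifest["histogram_path"] = paths
        manifest_path = outdir / "manifest.tsv"
        manifest.to_csv(manifest_path, sep="\t", index=False, lineterminator="\n")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)
        return manifest_path


def _jitter_params(params: ProfileParams, rng: np.random.Generator,
                   jitter_sd: float) -> ProfileParams:
    """Per-sample multiplicative lognormal perturbation of component weights."""
    if jitter_sd == 0:
        return params
    j = lambda: float(np.exp(rng.normal(0.0, jitter_sd)))  # noqa: E731
    return replace(
        params,
        main_peak_weight=params.main_peak_weight * j(),
        envelope_weight=params.envelope_weight * j(),
        dinucleosome_weight=params.dinucleosome_weight * j(),
        baseline_weight=params.baseline_weight * j(),
        subpeak_weights=tuple(w * j() for w in params.subpeak_weights),
    )


def generate_cohort(config: SyntheticCohortConfig = SyntheticCohortConfig()
                    ) -> SyntheticCohort:
    """Generate the labeled cohort plus a truth record of per-sample parameters."""
    rng = np.random.default_rng(config.seed)
    normal_base = build_profile(config.normal_params)
    histograms, rows, truth = [], [], []
    for i in range(config.n_normal):
        sid = f"normal_{i + 1:03d}"
        params = _jitter_params(config.normal_params, rng, config.jitter_sd)
        profile = build_profile(params)
        hist = sample_histogram(profile, config.fragments_per_sample, 1.0, None,
                                seed=int(rng.integers(2**31)), sample_id=sid)
        histograms.append(hist)
        rows.append({"sample_id": sid, "group": "normal", "histogram_path": ""})
        truth.append({"sample_id": sid, "group": "normal", "tumor_fraction": 0.0,
                      "n_fragments": config.fragments_per_sample})
    a, b = config.tumor_fraction_beta
    for i in range(config.n_tumor):
        sid = f"tumor_{i + 1:03d}"
        f = float(rng.beta(a, b))
        params = _jitter_params(config.tumor_params, rng, config.jitter_sd)
        profile = build_profile(params)
        hist = sample_histogram(profile, config.fragments_per_sample, f, normal_base,
                                seed=int(rng.integers(2**31)), sample_id=sid)
        histograms.append(hist)
        rows.append({"sample_id": sid, "group": "hemangiosarcoma", "histogram_path": ""})
        truth.append({"sample_id": sid, "group": "hemangiosarcoma", "tumor_fraction": f,
                      "n_fragments": config.fragments_per_sample})
    return SyntheticCohort(histograms, pd.DataFrame(rows), truth)


# ---------------------------------------------------------------------------
# binned-coverage cohort with GC bias and spiked copy-number segments

@dataclass(frozen=True)
class CNASpike:
    """A gain/loss segment applied to a subset of tumor samples."""

    chrom: str
    start: int
    end: int
    copy_ratio: float  # 1.5 = single-copy gain at full clonality, 0.5 = loss
    n_carriers: int

    def __post_init__(self) -> None:
        if self.copy_ratio <= 0:
            raise ValueError("copy_ratio must be > 0")
        if self.start >= self.end:
            raise ValueError("spike start must be < end")

    @property
    def state(self) -> str:
        return "gain" if self.copy_ratio > 1 else "loss"


def default_toy_genome() -> dict[str, int]:
    """5 chromosomes x 25 Mb (50 x 500 kb bins each) for desk-scale runs."""
    return {f"chr{i}": 25_000_000 for i in range(1, 6)}


@dataclass(frozen=True)
class SyntheticCNAConfig:
    genome: tuple = tuple(default_toy_genome().items())
    bin_width: int = 500_000
    n_normal: int = 27
    n_tumor: int = 21
    depth_mean: float = 8000.0  # reads per 500 kb bin (~2.4x coverage at 150 bp PE)
    nb_dispersion: float = 800.0  # negative-binomial size parameter
    gc_beta: tuple[float, float] = (42.0, 58.0)
    gc_bias_width: float = 0.10
    low_mappability_fraction: float = 0.04
    spikes: tuple = (
        CNASpike("chr2", 5_000_000, 10_000_000, 1.5, 8),
        CNASpike("chr4", 2_000_000, 7_000_000, 0.5, 10),
    )
    seed: int = 0

    def genome_dict(self) -> dict[str, int]:
        return dict(self.genome)

    def __post_init__(self) -> None:
        genome = dict(self.genome)
        for sp in self.spikes:
            if sp.chrom not in genome or sp.end > genome[sp.chrom]:
                raise ValueError(f"spike {sp} outside genome")
            if sp.n_carriers > self.n_tumor:
                raise ValueError("spike carriers exceed tumor count")


@dataclass
class SyntheticCNACohort:
    bins: dict[str, pd.DataFrame]  # sample_id -> chrom,start,end,gc,mappability,count
    labels: dict[str, str]
    truth: pd.DataFrame  # chrom,start,end,state,carriers

    @property
    def normal_ids(self) -> list[str]:
        return sorted(s for s, g in self.labels.items() if g == "normal")

    @property
    def tumor_ids(self) -> list[str]:
        return sorted(s for s, g in self.labels.items() if g == "hemangiosarcoma")

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for sid, df in self.bins.items():
            df.to_csv(outdir / f"{sid}.bins.tsv", sep="\t", index=False,
                      lineterminator="\n")
        self.truth.to_csv(outdir / "truth_cna.tsv", sep="\t", index=False,
                          lineterminator="\n")


def _gc_bias(gc: np.ndarray, width: float) -> np.ndarray:
    """Unimodal coverage bias peaking at GC 0.42 (amplitude ~0.6-1.4)."""
    return 0.6 + 0.8 * np.exp(-0.5 * ((gc - 0.42) / width) ** 2)


def _bin_grid(genome: dict[str, int], bin_width: int) -> pd.DataFrame:
    rows = []
    for chrom, length in genome.items():
        starts = np.arange(0, length, bin_width)
        ends = np.minimum(starts + bin_width, length)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return pd.concat(rows, ignore_index=True)


def generate_cna_cohort(config: SyntheticCNAConfig = SyntheticCNAConfig()
                        ) -> SyntheticCNACohort:
    """Per-sample negative-binomial bin counts with GC bias and spiked segments."""
    rng = np.random.default_rng(config.seed)
    genome = config.genome_dict()
    grid = _bin_grid(genome, config.bin_width)
    n_bins = len(grid)
    a, b = config.gc_beta
    gc = rng.beta(a, b, size=n_bins)
    mappability = rng.uniform(0.92, 1.0, size=n_bins)
    low = rng.random(n_bins) < config.low_mappability_fraction
    mappability[low] = rng.uniform(0.5, 0.85, size=int(low.sum()))
    bias = _gc_bias(gc, config.gc_bias_width)

    tumor_ids = [f"cna_tumor_{i + 1:03d}" for i in range(config.n_tumor)]
    normal_ids = [f"cna_normal_{i + 1:03d}" for i in range(config.n_normal)]

    # assign carriers per spike (deterministic under seed)
    spike_rows = []
    carrier_map: dict[int, np.ndarray] = {}
    for k, sp in enumerate(config.spikes):
        carriers = rng.choice(config.n_tumor, size=sp.n_carriers, replace=False)
        carrier_map[k] = carriers
        spike_rows.append({"chrom": sp.chrom, "start": sp.start, "end": sp.end,
                           "state": sp.state,
                           "carriers": ",".join(tumor_ids[i] for i in sorted(carriers))})

    def draw_sample(sample_idx: int | None) -> pd.DataFrame:
        copy_ratio = np.ones(n_bins)
        if sample_idx is not None:
            for k, sp in enumerate(config.spikes):
                if sample_idx in carrier_map[k]:
                    in_spike = ((grid["chrom"] == sp.chrom)
                                & (grid["start"] < sp.end)
                                & (grid["end"] > sp.start)).to_numpy()
                    copy_ratio[in_spike] = sp.copy_ratio
        library = float(np.exp(rng.normal(0.0, 0.05)))
        mu = config.depth_mean * bias * copy_ratio * library * mappability
        p = config.nb_dispersion / (config.nb_dispersion + mu)
        counts = rng.negative_binomial(config.nb_dispersion, p)
        df = grid.copy()
        df["gc"] = gc
        df["mappability"] = mappability
        df["count"] = counts
        return df

    bins = {sid: draw_sample(None) for sid in normal_ids}
    bins.update({sid: draw_sample(i) for i, sid in enumerate(tumor_ids)})
    labels = {sid: "normal" for sid in normal_ids}
    labels.update({sid: "hemangiosarcoma" for sid in tumor_ids})
    return SyntheticCNACohort(bins, labels, pd.DataFrame(spike_rows))
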