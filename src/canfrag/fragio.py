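"""Fragment-length extraction from paired-end alignments, depth capping, and histogram I/O.

Fragment lengths are taken as ``|TLEN|`` of the first-in-pair read of each
properly paired alignment (samtools ``-f 66 -q 30`` semantics), restricted to
the [74, 439] bp grid.  Samples sequenced above the target mean coverage are
thinned to the cap by per-size binomial subsampling of the histogram, which is
distributionally equivalent to read-level subsampling for every per-sample
statistic downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .reference import SIZE_MAX, SIZE_MIN

logger = logging.getLogger(__name__)

FLAG_PAIRED = 0x1
FLAG_PROPER_PAIR = 0x2
FLAG_FIRST_IN_PAIR = 0x40
#: paired + proper pair + first in pair — the samtools "flag 66" contract
DEFAULT_REQUIRED_FLAG_BITS = FLAG_PAIRED | FLAG_PROPER_PAIR | FLAG_FIRST_IN_PAIR  # 66 with 0x40


@dataclass(frozen=True)
class FragmentFilter:
    """Alignment-record filter for fragment counting.

    ``required_flag_bits`` must all be set on a record for it to count
    (samtools ``-f`` semantics); default 66 = paired + proper pair, combined
    here with first-in-pair so each template is counted exactly once.
    """

    required_flag_bits: int = DEFAULT_REQUIRED_FLAG_BITS
    min_mapping_quality: int = 30
    size_min: int = SIZE_MIN
    size_max: int = SIZE_MAX

    def __post_init__(self) -> None:
        if self.size_min >= self.size_max:
            raise ValueError("size_min must be < size_max")
        if self.min_mapping_quality < 0:
            raise ValueError("min_mapping_quality must be >= 0")


@dataclass
class FragmentLengthHistogram:
    """Integer counts of template lengths per 1-bp size on [size_min, size_max]."""

    sample_id: str
    counts: np.ndarray
    size_min: int = SIZE_MIN
    size_max: int = SIZE_MAX

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        expected = self.size_max - self.size_min + 1
        if self.counts.shape != (expected,):
            raise ValueError(
                f"counts must have length {expected} for grid "
                f"[{self.size_min}, {self.size_max}], got {self.counts.shape}"
            )
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def sizes(self) -> np.ndarray:
        return np.arange(self.size_min, self.size_max + 1)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def count_at(self, size_bp: int) -> int:
        if not self.size_min <= size_bp <= self.size_max:
            raise KeyError(f"size {size_bp} outside grid")
        return int(self.counts[size_bp - self.size_min])

    @classmethod
    def empty(cls, sample_id: str, size_min: int = SIZE_MIN, size_max: int = SIZE_MAX):
        return cls(sample_id, np.zeros(size_max - size_min + 1, dtype=np.int64), size_min, size_max)

    @classmethod
    def from_counts(cls, sample_id: str, counts: dict[int, int],
                    size_min: int = SIZE_MIN, size_max: int = SIZE_MAX):
        """Build from a {size_bp: count} mapping; sizes must lie on the grid."""
        hist = cls.empty(sample_id, size_min, size_max)
        for size, count in counts.items():
            if not size_min <= size <= size_max:
                raise ValueError(f"size {size} outside grid [{size_min}, {size_max}]")
            hist.counts[size - size_min] = count
        return hist


@dataclass(frozen=True)
class DepthCapPolicy:
    """Thin samples whose mean coverage exceeds ``max_mean_depth`` (fold-coverage)."""

    max_mean_depth: float = 2.0
    genome_size: float = 2.4e9  # canine genome
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_mean_depth <= 0:
            raise ValueError("max_mean_depth must be > 0")


def extract_fragment_lengths(
    alignment_stream: Iterable,
    filt: FragmentFilter = FragmentFilter(),
    sample_id: str = "sample",
) -> FragmentLengthHistogram:
    """Tally |TLEN| of records passing flag/quality/size filters into a histogram.

    ``alignment_stream`` is any iterable of records exposing ``flag``,
    ``mapping_quality`` and ``template_length`` (e.g. pysam AlignedSegment).
    Records missing a template length (TLEN 0 / None) are skipped and counted
    in the log.
    """
    hist = FragmentLengthHistogram.empty(sample_id, filt.size_min, filt.size_max)
    n_missing_tlen = 0
    for rec in alignment_stream:
        if (rec.flag & filt.required_flag_bits) != filt.required_flag_bits:
            continue
        if rec.mapping_quality < filt.min_mapping_quality:
            continue
        tlen = rec.template_length
        if tlen is None or tlen == 0:
            n_missing_tlen += 1
            continue
        size = abs(int(tlen))
        if filt.size_min <= size <= filt.size_max:
            hist.counts[size - filt.size_min] += 1
    if n_missing_tlen:
        logger.warning("%s: skipped %d records without template length",
                       sample_id, n_missing_tlen)
    return hist


def extract_from_bam(path: str | Path, filt: FragmentFilter = FragmentFilter(),
                     sample_id: str | None = None) -> FragmentLengthHistogram:
    """Extract a fragment-length histogram from a SAM/BAM/CRAM file via pysam."""
    import pysam

    path = Path(path)
    sid = sample_id or path.stem
    mode = "r" if path.suffix.lower() == ".sam" else "rb"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as af:
        return extract_fragment_lengths(af.fetch(until_eof=True), filt, sid)


def estimate_mean_depth(n_fragments: int, read_length: int,
                        genome_size: float = 2.4e9) -> float:
    """Mean fold-coverage estimate: (pairs x read length x 2) / genome size."""
    return n_fragments * read_length * 2 / genome_size


def cap_depth(hist: FragmentLengthHistogram, observed_mean_depth: float,
              policy: DepthCapPolicy = DepthCapPolicy()) -> FragmentLengthHistogram:
    """Binomially thin a histogram so the expected depth equals the cap.

    Returns the input unchanged when observed depth is at or below the cap;
    otherwise each per-size count is thinned independently with retention
    probability ``cap / observed`` under the policy seed.
    """
    if observed_mean_depth <= 0:
        raise ValueError("observed_mean_depth must be > 0")
    if observed_mean_depth <= policy.max_mean_depth:
        return hist
    retention = policy.max_mean_depth / observed_mean_depth
    rng = np.random.default_rng(policy.seed)
    thinned = rng.binomial(hist.counts, retention)
    logger.info("%s: depth %.2fX capped to %.2fX (retention %.3f, %d -> %d fragments)",
                hist.sample_id, observed_mean_depth, policy.max_mean_depth,
                retention, hist.total, int(thinned.sum()))
    return FragmentLengthHistogram(hist.sample_id, thinned, hist.size_min, hist.size_max)


# ---------------------------------------------------------------------------
# histogram TSV I/O ("size_bp\tcount")

def write_histogram_tsv(hist: FragmentLengthHistogram, path: str | Path) -> None:
    df = pd.DataFrame({"size_bp": hist.sizes, "count": hist.counts})
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_histogram_tsv(path: str | Path, sample_id: str | None = None,
                       size_min: int = SIZE_MIN, size_max: int = SIZE_MAX
                       ) -> FragmentLengthHistogram:
    """Read a ``size_bp\\tcount`` TSV; rejects off-grid sizes and negative counts."""
    path = Path(path)
    sid = sample_id or path.stem
    try:
        df = pd.read_csv(path, sep="\t", dtype={"size_bp": np.int64, "count": np.int64})
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"{path}: malformed histogram TSV: {exc}") from exc
    if list(df.columns[:2]) != ["size_bp", "count"]:
        raise ValueError(f"{path}: expected columns size_bp, count; got {list(df.columns)}")
    hist = FragmentLengthHistogram.empty(sid, size_min, size_max)
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        if row.count < 0:
            raise ValueError(f"{path}:{line_no}: negative count {row.count}")
        if not size_min <= row.size_bp <= size_max:
            raise ValueError(f"{path}:{line_no}: size {row.size_bp} outside "
                             f"grid [{size_min}, {size_max}]")
        hist.counts[row.size_bp - size_min] += row.count
    return hist
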