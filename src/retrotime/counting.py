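"""Overlap counting of aligned-read intervals over repeat loci.

Counting follows bedtools-coverage semantics: a locus' count is the number
of reads overlapping it by at least ``min_overlap_bp``; a read spanning k
loci contributes to all k; strand is ignored.  Locus-level counts are then
summed to subfamily-level analysis units (with subfamily length = summed
locus length, used later for RPKM).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .repeat_annotation import RepeatLocus, RepeatTaxonomy

__all__ = [
    "ReadInterval",
    "CountsMatrix",
    "SampleSheet",
    "count_reads_over_loci",
    "aggregate_to_subfamily",
    "read_bed_intervals",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReadInterval:
    """A single aligned block, 0-based half-open."""

    chrom: str
    start: int
    end: int
    read_id: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"empty read interval {self.chrom}:{self.start}-{self.end}")


@dataclass
class SampleSheet:
    """Per-sample metadata: series (control/starved) and time in hours."""

    frame: pd.DataFrame  # index = sample id; columns: series, time_h

    def __post_init__(self) -> None:
        required = {"series", "time_h"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        bad = set(self.frame["series"]) - {"control", "starved"}
        if bad:
            raise ValueError(f"series must be control/starved, got {sorted(bad)}")
        if (self.frame["time_h"] <= 0).any():
            raise ValueError("sample times must be positive")
        pairs = list(zip(self.frame["series"], self.frame["time_h"]))
        if len(set(pairs)) != len(pairs):
            raise ValueError("(series, time_h) pairs must be unique")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def samples_in(self, series: str, times: Iterable[float] | None = None) -> list[str]:
        mask = self.frame["series"] == series
        if times is not None:
            mask &= self.frame["time_h"].isin(list(times))
        return list(self.frame.index[mask])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleSheet":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(frame=frame)

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="sample")


@dataclass
class CountsMatrix:
    """Non-negative integer feature x sample count table with feature lengths.

    ``level`` tags what a row is: a genomic locus, a repeat subfamily, or a
    gene.  Lengths are in bp and feed the RPKM transform.
    """

    counts: pd.DataFrame          # features x samples, integer
    lengths: pd.Series            # bp per feature
    level: str = "subfamily"      # {locus, subfamily, gene}

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("feature ids must be unique")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            raise ValueError("every feature needs a length")
        if (self.lengths <= 0).any():
            raise ValueError("feature lengths must be positive")

    @property
    def features(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def to_tsv(self, counts_path: str | Path, lengths_path: str | Path | None = None) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="feature")
        if lengths_path is not None:
            self.lengths.rename("length_bp").to_csv(
                lengths_path, sep="\t", index_label="feature"
            )

    @classmethod
    def from_tsv(
        cls,
        counts_path: str | Path,
        lengths_path: str | Path | None = None,
        level: str = "subfamily",
    ) -> "CountsMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        if lengths_path is not None:
            lengths = pd.read_csv(lengths_path, sep="\t", index_col=0).iloc[:, 0]
        else:
            # length unknown: fall back to 1 kb so RPKM degrades to CPM
            lengths = pd.Series(1000, index=counts.index)
        return cls(counts=counts, lengths=lengths, level=level)


def read_bed_intervals(path: str | Path) -> list[ReadInterval]:
    """Read intervals from a BED3+ file (name column used as read id)."""
    out: list[ReadInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED line needs >=3 fields")
            out.append(ReadInterval(
                chrom=fields[0], start=int(fields[1]), end=int(fields[2]),
                read_id=fields[3] if len(fields) > 3 else f"read{lineno}",
            ))
    return out


def count_reads_over_loci(
    reads: Sequence[ReadInterval],
    loci: Sequence[RepeatLocus],
    min_overlap_bp: int = 1,
) -> tuple[np.ndarray, int]:
    """Count reads over loci with bedtools-coverage semantics.

    Returns ``(per_locus_counts, n_ignored)`` where counts are aligned with
    the input locus order and ``n_ignored`` is the number of reads on
    chromosomes absent from the annotation (reported with a warning).
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    trees: dict[str, IntervalTree] = {}
    for i, locus in enumerate(loci):
        trees.setdefault(locus.chrom, IntervalTree()).addi(locus.start, locus.end, i)
    counts = np.zeros(len(loci), dtype=np.int64)
    n_ignored = 0
    for read in reads:
        tree = trees.get(read.chrom)
        if tree is None:
            n_ignored += 1
            continue
        for iv in tree.overlap(read.start, read.end):
            overlap = min(read.end, iv.end) - max(read.start, iv.begin)
            if overlap >= min_overlap_bp:
                counts[iv.data] += 1
    if n_ignored:
        warnings.warn(
            f"{n_ignored} reads on chromosomes absent from the annotation were ignored",
            stacklevel=2,
        )
        logger.warning("%d reads ignored (unknown chromosome)", n_ignored)
    return counts, n_ignored


def aggregate_to_subfamily(
    locus_counts: CountsMatrix,
    loci: Sequence[RepeatLocus],
    taxonomy: RepeatTaxonomy,
) -> CountsMatrix:
    """Sum locus-level counts (and lengths) to subfamily analysis units.

    Column sums are conserved exactly.  Subfamilies whose loci all have zero
    counts are kept with count 0.
    """
    if len(loci) != len(locus_counts.counts):
        raise ValueError("locus list and locus count matrix differ in length")
    subfams = []
    for locus in loci:
        if locus.subfamily not in taxonomy.parent:
            raise KeyError(f"subfamily {locus.subfamily!r} absent from taxonomy")
        subfams.append(locus.subfamily)
    key = pd.Index(subfams, name="subfamily")
    agg_counts = locus_counts.counts.groupby(key, sort=True).sum()
    lengths = pd.Series([l.length for l in loci], index=key).groupby(level=0).sum()
    return CountsMatrix(counts=agg_counts, lengths=lengths, level="subfamily")


def locus_counts_matrix(
    loci: Sequence[RepeatLocus],
    per_sample_counts: Mapping[str, np.ndarray],
) -> CountsMatrix:
    """Assemble a locus-level CountsMatrix from per-sample count vectors."""
    index = pd.Index([f"locus{i:06d}" for i in range(len(loci))], name="locus")
    counts = pd.DataFrame(
        {s: np.asarray(v, dtype=np.int64) for s, v in per_sample_counts.items()},
        index=index,
    )
    lengths = pd.Series([l.length for l in loci], index=index)
    return CountsMatrix(counts=counts, lengths=lengths, level="locus")
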