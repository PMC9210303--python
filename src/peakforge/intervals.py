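"""Genomic intervals, consensus-peak construction and fragment counting.

Coordinates are 0-based half-open throughout, matching BED. Consensus
peaks are built by transitively merging per-sample peak calls that lie
within ``merge_gap`` bp of one another; each merged peak carries a
*support* value, the number of distinct samples that contributed at
least one call to it. Peaks supported by too few samples are discarded
before any counting or testing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "ConsensusPeak",
    "CountMatrix",
    "read_peaks",
    "write_peaks",
    "write_consensus",
    "merge_with_support",
    "filter_support",
    "separate_size_specific",
    "SizeSplit",
    "count_fragments",
]


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    sample: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (start >= end)"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class ConsensusPeak:
    """Merged peak with the set of per-sample calls it absorbed.

    ``support`` counts distinct contributing samples; a sample whose two
    calls fall into the same merged peak counts once.
    """

    chrom: str
    start: int
    end: int
    support: int
    members: list[tuple[str | None, GenomicInterval]] = field(default_factory=list)

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @property
    def width(self) -> int:
        return self.end - self.start

    def as_interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


@dataclass
class CountMatrix:
    """Features x samples integer counts with per-sample library sizes."""

    counts: pd.DataFrame
    library_sizes: pd.Series

    def __post_init__(self) -> None:
        self.library_sizes = self.library_sizes.reindex(self.counts.columns)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.library_sizes <= 0).any():
            raise ValueError("library sizes must be positive")

    @property
    def feature_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns


# ---------------------------------------------------------------------------
# BED / narrowPeak I/O
# ---------------------------------------------------------------------------

def read_peaks(path: str | Path, sample: str | None = None) -> list[GenomicInterval]:
    """Read a BED3+ or narrowPeak file into a list of intervals.

    narrowPeak signal (column 7) is kept as ``score``; for plain BED the
    column-5 score is used when present. Malformed lines raise with the
    offending line number.
    """
    path = Path(path)
    out: list[GenomicInterval] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            score: float | None = None
            if len(fields) >= 10:  # narrowPeak: signalValue in column 7
                score = float(fields[6])
            elif len(fields) >= 5 and fields[4] not in (".", ""):
                score = float(fields[4])
            try:
                out.append(GenomicInterval(chrom, start, end, sample=sample, score=score))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_peaks(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED6 (name = sample or '.', score or 0)."""
    with Path(path).open("w") as fh:
        for iv in intervals:
            score = 0 if iv.score is None else iv.score
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.sample or '.'}\t{score}\t.\n"
            )


def write_consensus(peaks: Iterable[ConsensusPeak], path: str | Path) -> None:
    """Write consensus peaks as BED6 with the support value in column 5."""
    with Path(path).open("w") as fh:
        for pk in peaks:
            fh.write(f"{pk.chrom}\t{pk.start}\t{pk.end}\t{pk.name}\t{pk.support}\t.\n")


# ---------------------------------------------------------------------------
# Consensus construction
# ---------------------------------------------------------------------------

def _chrom_sort_key(chrom: str) -> tuple:
    m = re.match(r"(?:chr)?(\d+)$", chrom)
    return (0, int(m.group(1)), "") if m else (1, 0, chrom)


def merge_with_support(
    peaks: Sequence[GenomicInterval], merge_gap: int = 10
) -> list[ConsensusPeak]:
    """Transitively merge peaks within ``merge_gap`` bp into consensus peaks.

    Two intervals on the same chromosome belong together when the gap
    between them (next.start - prev.end; <= 0 for overlap or book-ended
    contact) is at most ``merge_gap``. The merged set is the transitive
    closure of that relation, so the result does not depend on input
    order, and consecutive consensus peaks are separated by more than
    ``merge_gap`` bp.
    """
    if merge_gap < 0:
        raise ValueError(f"merge_gap must be non-negative, got {merge_gap}")
    ordered = sorted(
        peaks, key=lambda iv: (_chrom_sort_key(iv.chrom), iv.start, iv.end)
    )
    out: list[ConsensusPeak] = []
    for iv in ordered:
        cur = out[-1] if out else None
        if cur is not None and cur.chrom == iv.chrom and iv.start - cur.end <= merge_gap:
            cur.end = max(cur.end, iv.end)
            cur.members.append((iv.sample, iv))
        else:
            out.append(
                ConsensusPeak(iv.chrom, iv.start, iv.end, support=1, members=[(iv.sample, iv)])
            )
    for pk in out:
        pk.support = len({s for s, _ in pk.members})
    return out


def filter_support(
    consensus: Sequence[ConsensusPeak], min_support: int = 3
) -> list[ConsensusPeak]:
    """Drop consensus peaks present in fewer than ``min_support`` samples."""
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    return [pk for pk in consensus if pk.support >= min_support]


# ---------------------------------------------------------------------------
# Size-class sharing
# ---------------------------------------------------------------------------

class _OverlapIndex:
    """Per-chromosome sorted-start index answering 'does anything overlap?'."""

    def __init__(self, intervals: Iterable[GenomicInterval]):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        grouped: dict[str, list[GenomicInterval]] = {}
        for iv in intervals:
            grouped.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in grouped.items():
            ivs.sort(key=lambda i: i.start)
            starts = np.array([i.start for i in ivs])
            ends = np.maximum.accumulate(np.array([i.end for i in ivs]))
            self._by_chrom[chrom] = (starts, ends)

    def overlaps(self, iv: GenomicInterval) -> bool:
        entry = self._by_chrom.get(iv.chrom)
        if entry is None:
            return False
        starts, cummax_ends = entry
        hi = int(np.searchsorted(starts, iv.end, side="left"))
        return hi > 0 and cummax_ends[hi - 1] > iv.start


@dataclass
class SizeSplit:
    """Partition of per-class peak sets by cross-class overlap.

    shared: peaks overlapping >=1 peak of every other class.
    specific: peaks overlapping no peak of any other class.
    partial: peaks overlapping some but not all other classes.
    """

    shared: dict[str, list[GenomicInterval]]
    specific: dict[str, list[GenomicInterval]]
    partial: dict[str, list[GenomicInterval]]


def separate_size_specific(
    peaksets: Mapping[str, Sequence[GenomicInterval]]
) -> SizeSplit:
    """Split per-size-class peak sets into shared / class-specific / partial."""
    classes = list(peaksets)
    if len(classes) < 2:
        raise ValueError("need at least two size classes")
    indexes = {c: _OverlapIndex(peaksets[c]) for c in classes}
    shared: dict[str, list[GenomicInterval]] = {c: [] for c in classes}
    specific: dict[str, list[GenomicInterval]] = {c: [] for c in classes}
    partial: dict[str, list[GenomicInterval]] = {c: [] for c in classes}
    for c in classes:
        others = [o for o in classes if o != c]
        for iv in peaksets[c]:
            hits = sum(indexes[o].overlaps(iv) for o in others)
            if hits == len(others):
                shared[c].append(iv)
            elif hits == 0:
                specific[c].append(iv)
            else:
                partial[c].append(iv)
    return SizeSplit(shared=shared, specific=specific, partial=partial)


# ---------------------------------------------------------------------------
# Fragment counting over the consensus set
# ---------------------------------------------------------------------------

def count_fragments(
    consensus: Sequence[ConsensusPeak], fragments: pd.DataFrame
) -> CountMatrix:
    """Count fragments overlapping each consensus peak by >=1 bp, per sample.

    ``fragments`` is a data frame with columns chrom/start/end/sample
    (the output of :func:`peakforge.qc.filter_fragments`); counting is
    unstranded. The per-sample library size is the total number of
    (filtered) fragments, whether or not they fall in a peak.
    """
    peaks = sorted(consensus, key=lambda p: (_chrom_sort_key(p.chrom), p.start))
    for a, b in zip(peaks, peaks[1:]):
        if a.chrom == b.chrom and b.start < a.end:
            raise ValueError(
                f"consensus peaks overlap: {a.name} and {b.name}; merge first"
            )
    names = [p.name for p in peaks]
    order = {name: i for i, name in enumerate(names)}
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in {p.chrom for p in peaks}:
        sub = [p for p in peaks if p.chrom == chrom]
        by_chrom[chrom] = (
            np.array([p.start for p in sub]),
            np.array([p.end for p in sub]),
            np.array([order[p.name] for p in sub]),
        )

    samples = sorted(fragments["sample"].unique())
    mat = np.zeros((len(peaks), len(samples)), dtype=np.int64)
    lib = pd.Series(0, index=pd.Index(samples, name="sample"), dtype=np.int64)
    for j, sample in enumerate(samples):
        sub = fragments[fragments["sample"] == sample]
        lib[sample] = len(sub)
        for chrom, grp in sub.groupby("chrom", observed=True):
            entry = by_chrom.get(str(chrom))
            if entry is None:
                continue
            starts, ends, idx = entry
            fs = grp["start"].to_numpy()
            fe = grp["end"].to_numpy()
            # disjoint sorted peaks: a fragment overlaps the contiguous run
            # of peaks with end > frag.start and start < frag.end
            lo = np.searchsorted(ends, fs, side="right")
            hi = np.searchsorted(starts, fe, side="left")
            delta = np.zeros(len(starts) + 1, dtype=np.int64)
            np.add.at(delta, lo, 1)
            np.add.at(delta, hi, -1)
            mat[idx, j] += np.cumsum(delta[:-1])
    counts = pd.DataFrame(mat, index=pd.Index(names, name="peak"), columns=samples)
    return CountMatrix(counts=counts, library_sizes=lib)
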