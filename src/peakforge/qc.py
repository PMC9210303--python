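"""ATAC library quality-control metrics.

Fragments are carried as a pandas data frame with columns
``chrom, start, end, mapq, flags, sample`` (0-based half-open, SAM-style
flag bitfield). Metrics follow the ENCODE ATAC conventions: fragment
size distribution, TSS enrichment score, FRiP, library complexity
(NRF/PBC) and the nucleosome-free-region score.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval

__all__ = [
    "FragmentRecord",
    "FRAGMENT_COLUMNS",
    "PROPER_PAIR",
    "EXCLUDE_FLAGS",
    "read_fragments",
    "write_fragments",
    "filter_fragments",
    "fragment_size_distribution",
    "FragmentSizeDistribution",
    "tss_enrichment",
    "TssEnrichment",
    "frip",
    "library_complexity",
    "LibraryComplexity",
    "nfr_score",
    "binned_correlation",
    "chromosome_coverage",
    "qc_report",
]

FRAGMENT_COLUMNS = ["chrom", "start", "end", "mapq", "flags", "sample"]

PROPER_PAIR = 0x2
# unmapped | mate unmapped | QC fail | PCR duplicate (samtools -F1548)
EXCLUDE_FLAGS = 0x4 | 0x8 | 0x200 | 0x400

# ENCODE nucleosomal fragment-length bands (bp)
NFR_MAX = 100
MONO_RANGE = (180, 247)
DI_RANGE = (315, 473)


@dataclass(frozen=True)
class FragmentRecord:
    """A single sequenced fragment after alignment."""

    chrom: str
    start: int
    end: int
    mapq: int
    flags: int
    sample: str | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"fragment end must exceed start: {self.start}..{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


def fragments_frame(records: Iterable[FragmentRecord]) -> pd.DataFrame:
    """Collect fragment records into the canonical data frame."""
    rows = [(r.chrom, r.start, r.end, r.mapq, r.flags, r.sample) for r in records]
    return pd.DataFrame(rows, columns=FRAGMENT_COLUMNS)


def read_fragments(path: str | Path, sample: str | None = None) -> pd.DataFrame:
    """Read a fragment BED (chrom, start, end, name, mapq, flags)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "mapq", "flags"],
        dtype={"chrom": str},
    )
    df["sample"] = sample if sample is not None else df["name"]
    return df[FRAGMENT_COLUMNS]


def write_fragments(frags: pd.DataFrame, path: str | Path) -> None:
    out = frags[["chrom", "start", "end", "sample", "mapq", "flags"]]
    out.to_csv(path, sep="\t", header=False, index=False)


def filter_fragments(
    frags: pd.DataFrame,
    min_mapq: int = 10,
    exclude_chroms: Iterable[str] = ("MT",),
) -> pd.DataFrame:
    """Apply the high-quality fragment filter.

    Keeps proper pairs with mapping quality >= ``min_mapq`` that carry
    none of the unmapped / mate-unmapped / QC-fail / duplicate bits, and
    discards excluded chromosomes (mitochondrial by default).
    """
    excl = set(exclude_chroms)
    flags = frags["flags"].to_numpy()
    keep = (
        (frags["mapq"].to_numpy() >= min_mapq)
        & ((flags & PROPER_PAIR) == PROPER_PAIR)
        & ((flags & EXCLUDE_FLAGS) == 0)
        & ~frags["chrom"].isin(excl).to_numpy()
    )
    return frags.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Fragment-size distribution
# ---------------------------------------------------------------------------

@dataclass
class FragmentSizeDistribution:
    counts: pd.Series  # length (bp) -> fragment count
    log2_density: pd.Series  # log2(count / max count)
    nfr_count: int
    mono_count: int
    di_count: int


def fragment_size_distribution(frags: pd.DataFrame) -> FragmentSizeDistribution:
    """Histogram of fragment lengths with log2(count/max) density.

    Lengths are also tallied into the nucleosome-free (<100 bp),
    mono-nucleosome (180-247 bp) and di-nucleosome (315-473 bp) bands.
    """
    if len(frags) == 0:
        raise ValueError("no fragments")
    lengths = (frags["end"] - frags["start"]).to_numpy()
    counts = pd.Series(lengths).value_counts().sort_index()
    counts.index.name = "length"
    log2_density = np.log2(counts / counts.max())
    return FragmentSizeDistribution(
        counts=counts,
        log2_density=log2_density,
        nfr_count=int((lengths < NFR_MAX).sum()),
        mono_count=int(((lengths >= MONO_RANGE[0]) & (lengths <= MONO_RANGE[1])).sum()),
        di_count=int(((lengths >= DI_RANGE[0]) & (lengths <= DI_RANGE[1])).sum()),
    )


def nfr_score(frags: pd.DataFrame) -> float:
    """log2 ratio of nucleosome-free to mono-nucleosome fragment counts."""
    dist = fragment_size_distribution(frags)
    if dist.mono_count == 0:
        raise ValueError("no mono-nucleosome fragments; NFR score undefined")
    if dist.nfr_count == 0:
        raise ValueError("no nucleosome-free fragments; NFR score undefined")
    return float(np.log2(dist.nfr_count / dist.mono_count))


# ---------------------------------------------------------------------------
# TSS enrichment
# ---------------------------------------------------------------------------

@dataclass
class TssEnrichment:
    window_scores: np.ndarray  # one score per window tiling [-flank, +flank)
    tss_es: float


def _coverage_profiles(
    frags: pd.DataFrame,
    tss_list: Sequence[tuple],
    flank: int,
) -> np.ndarray:
    """Aggregate per-base fragment coverage over [tss-flank, tss+flank).

    Profiles are oriented 5'->3' on the gene strand (reversed for minus
    strand TSSs) and summed over all TSSs.
    """
    profile = np.zeros(2 * flank, dtype=float)
    by_chrom = {str(c): g for c, g in frags.groupby("chrom", observed=True)}
    for entry in tss_list:
        chrom, pos = str(entry[0]), int(entry[1])
        strand = entry[2] if len(entry) > 2 else "+"
        grp = by_chrom.get(chrom)
        if grp is None:
            continue
        lo, hi = pos - flank, pos + flank
        s = np.clip(grp["start"].to_numpy() - lo, 0, 2 * flank)
        e = np.clip(grp["end"].to_numpy() - lo, 0, 2 * flank)
        ok = e > s
        delta = np.zeros(2 * flank + 1)
        np.add.at(delta, s[ok], 1.0)
        np.add.at(delta, e[ok], -1.0)
        cov = np.cumsum(delta[:-1])
        profile += cov[::-1] if strand == "-" else cov
    return profile


def tss_enrichment(
    frags: pd.DataFrame,
    tss_list: Sequence[tuple],
    window: int = 100,
    flank: int = 1000,
) -> TssEnrichment:
    """TSS enrichment score of one library.

    The +/- ``flank`` region around each TSS is tiled into ``window``-bp
    windows (20 by default); each window's score is its mean aggregate
    depth divided by the mean depth of the two outermost (flank-end)
    windows, and the TSS enrichment score is the maximum window score.
    """
    if not tss_list:
        raise ValueError("need at least one TSS")
    if (2 * flank) % window != 0:
        raise ValueError("2*flank must be a multiple of the window size")
    profile = _coverage_profiles(frags, tss_list, flank)
    n_win = 2 * flank // window
    win_depth = profile.reshape(n_win, window).mean(axis=1)
    flank_depth = (win_depth[0] + win_depth[-1]) / 2
    if flank_depth == 0:
        raise ValueError("zero depth at flank ends; TSS enrichment undefined")
    scores = win_depth / flank_depth
    return TssEnrichment(window_scores=scores, tss_es=float(scores.max()))


# ---------------------------------------------------------------------------
# FRiP
# ---------------------------------------------------------------------------

def frip(frags: pd.DataFrame, peaks: Sequence[GenomicInterval]) -> float:
    """Fraction of fragments overlapping any peak by >=1 bp."""
    if len(frags) == 0:
        raise ValueError("no fragments")
    peak_index: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {p.chrom for p in peaks}:
        sub = sorted((p for p in peaks if p.chrom == chrom), key=lambda p: p.start)
        starts = np.array([p.start for p in sub])
        ends = np.maximum.accumulate(np.array([p.end for p in sub]))
        peak_index[chrom] = (starts, ends)
    n_in = 0
    for chrom, grp in frags.groupby("chrom", observed=True):
        entry = peak_index.get(str(chrom))
        if entry is None:
            continue
        starts, cummax_ends = entry
        hi = np.searchsorted(starts, grp["end"].to_numpy(), side="left")
        fs = grp["start"].to_numpy()
        has = hi > 0
        n_in += int((has & (cummax_ends[np.maximum(hi - 1, 0)] > fs)).sum())
    return n_in / len(frags)


# ---------------------------------------------------------------------------
# Library complexity
# ---------------------------------------------------------------------------

@dataclass
class LibraryComplexity:
    nrf: float
    pbc1: float
    pbc2: float  # +inf when no position is seen exactly twice
    pbc2_defined: bool


def library_complexity(frags: pd.DataFrame) -> LibraryComplexity:
    """NRF and PCR bottlenecking coefficients over distinct fragment positions.

    Positions are the full (chrom, start, end) triples of the paired-end
    fragments. NRF = distinct/total; PBC1 = (positions seen once)/distinct;
    PBC2 = (seen once)/(seen twice).
    """
    if len(frags) == 0:
        raise ValueError("no fragments")
    mult = frags.groupby(["chrom", "start", "end"], observed=True).size()
    total = len(frags)
    distinct = len(mult)
    m1 = int((mult == 1).sum())
    m2 = int((mult == 2).sum())
    return LibraryComplexity(
        nrf=distinct / total,
        pbc1=m1 / distinct,
        pbc2=(m1 / m2) if m2 > 0 else float("inf"),
        pbc2_defined=m2 > 0,
    )


# ---------------------------------------------------------------------------
# Binned coverage correlation
# ---------------------------------------------------------------------------

def binned_correlation(frags: pd.DataFrame, bin_size: int = 100) -> pd.DataFrame:
    """Pearson correlation of per-sample binned fragment counts.

    The genome is tiled into fixed-width bins; each fragment is assigned
    to the bin containing its midpoint, and the correlation is computed
    between the per-bin count vectors of every sample pair.
    """
    samples = sorted(frags["sample"].unique())
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    mid = ((frags["start"] + frags["end"]) // 2) // bin_size
    key = frags["chrom"].astype(str) + ":" + mid.astype(str)
    table = (
        pd.DataFrame({"bin": key, "sample": frags["sample"]})
        .groupby(["bin", "sample"], observed=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=samples, fill_value=0)
    )
    corr = np.corrcoef(table.to_numpy().T)
    return pd.DataFrame(corr, index=samples, columns=samples)


def chromosome_coverage(
    frags: pd.DataFrame, chrom_sizes: Mapping[str, int]
) -> pd.Series:
    """Mean per-base coverage per chromosome (sum of fragment lengths / length)."""
    lengths = frags["end"] - frags["start"]
    per_chrom = lengths.groupby(frags["chrom"], observed=True).sum()
    out = pd.Series(
        {c: per_chrom.get(c, 0) / size for c, size in chrom_sizes.items()},
        name="mean_coverage",
    )
    return out


# ---------------------------------------------------------------------------
# Combined report
# ---------------------------------------------------------------------------

def qc_report(
    frags: pd.DataFrame,
    peaks_by_sample: Mapping[str, Sequence[GenomicInterval]],
    tss_list: Sequence[tuple],
    chrom_sizes: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Per-sample QC table over pre-filtered fragments.

    Columns: tss_es, frip, nrf, pbc1, pbc2, nfr_score, n_fragments and
    (when ``chrom_sizes`` is given) mean autosomal coverage. FRiP uses
    each sample's own peak calls.
    """
    rows = {}
    for sample, grp in frags.groupby("sample", observed=True):
        complexity = library_complexity(grp)
        row = {
            "n_fragments": len(grp),
            "tss_es": tss_enrichment(grp, tss_list).tss_es,
            "frip": frip(grp, peaks_by_sample.get(str(sample), [])),
            "nrf": complexity.nrf,
            "pbc1": complexity.pbc1,
            "pbc2": complexity.pbc2,
            "nfr_score": nfr_score(grp),
        }
        if chrom_sizes is not None:
            autosomes = {c: s for c, s in chrom_sizes.items() if c != "MT"}
            row["mean_autosome_cov"] = chromosome_coverage(grp, autosomes).mean()
        rows[str(sample)] = row
    report = pd.DataFrame.from_dict(rows, orient="index")
    report.index.name = "sample"
    return report
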