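"""Peak-to-feature annotation and the peak/gene proximity overlay.

Peaks are assigned to one of eleven genomic feature categories
(promoter windows by TSS distance, UTRs, exons, introns, downstream,
distal intergenic) by a fixed precedence rule anchored at the peak
midpoint. A coarser five-way vocabulary (Promoter / Proximal / Intronic
/ CDS / Exonic / UTRs / Intergenic) is provided for summarising
differential peaks. The overlay links peaks to genes within a +/-10-kb
window using a signed start-distance coordinate: positive when the
peak's 5'-most boundary lies within the gene or its 10-kb upstream
region, negative when it lies within 10 kb past the 3' end.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval

__all__ = [
    "GeneModel",
    "FeatureCall",
    "OverlayRecord",
    "CATEGORIES",
    "classify_peak",
    "classify_peaks",
    "summarize_features",
    "table3_category",
    "signed_start_distance",
    "overlay_table",
    "read_annotation",
    "write_annotation",
]


@dataclass
class GeneModel:
    """A gene with exon structure and strand-aware TSS."""

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    start: int  # 0-based half-open span
    end: int
    exons: list[tuple[int, int]]
    utr5: list[tuple[int, int]]
    utr3: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"exon ({s},{e}) outside gene {self.gene_id}")

    @property
    def tss(self) -> int:
        """Strand-aware 5' end (transcription start site)."""
        return self.start if self.strand == "+" else self.end

    @property
    def three_prime(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def exons_in_order(self) -> list[tuple[int, int]]:
        """Exons in transcription order (first exon contains the TSS side)."""
        exons = sorted(self.exons)
        return exons if self.strand == "+" else exons[::-1]

    def introns_in_order(self) -> list[tuple[int, int]]:
        exons = sorted(self.exons)
        introns = [(a[1], b[0]) for a, b in zip(exons, exons[1:]) if b[0] > a[1]]
        return introns if self.strand == "+" else introns[::-1]


CATEGORIES = [
    "Promoter (<=1 kb)",
    "Promoter (1-2 kb)",
    "Promoter (2-3 kb)",
    "5' UTR",
    "3' UTR",
    "1st exon",
    "Other exon",
    "1st intron",
    "Other intron",
    "Downstream (<=3 kb)",
    "Distal intergenic",
]


@dataclass
class FeatureCall:
    peak: GenomicInterval
    category: str
    gene_id: str | None


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def _in_any(pos: int, intervals: Iterable[tuple[int, int]]) -> bool:
    return any(s <= pos < e for s, e in intervals)


def classify_peak(
    peak: GenomicInterval,
    genes: Sequence[GeneModel],
    promoter_windows: tuple[int, int, int] = (1000, 2000, 3000),
    downstream: int = 3000,
    anchor: str = "midpoint",
) -> FeatureCall:
    """Assign a peak to exactly one feature category.

    The anchor position (peak midpoint by default) is tested against a
    fixed precedence: promoter windows by absolute distance to the
    nearest TSS, then 5' UTR, 3' UTR, first exon, other exon, first
    intron, other intron, downstream (<=3 kb past the 3' end), and
    finally distal intergenic. A peak on a chromosome absent from the
    annotation falls through to distal intergenic.
    """
    pos = peak.midpoint if anchor == "midpoint" else peak.start
    same_chrom = [g for g in genes if g.chrom == peak.chrom]
    if not same_chrom:
        return FeatureCall(peak, "Distal intergenic", None)

    # promoter: nearest TSS within the outermost window
    nearest = min(same_chrom, key=lambda g: abs(pos - g.tss))
    d_tss = abs(pos - nearest.tss)
    w1, w2, w3 = promoter_windows
    if d_tss <= w1:
        return FeatureCall(peak, "Promoter (<=1 kb)", nearest.gene_id)
    if d_tss <= w2:
        return FeatureCall(peak, "Promoter (1-2 kb)", nearest.gene_id)
    if d_tss <= w3:
        return FeatureCall(peak, "Promoter (2-3 kb)", nearest.gene_id)

    for g in same_chrom:
        if _in_any(pos, g.utr5):
            return FeatureCall(peak, "5' UTR", g.gene_id)
    for g in same_chrom:
        if _in_any(pos, g.utr3):
            return FeatureCall(peak, "3' UTR", g.gene_id)
    for g in same_chrom:
        exons = g.exons_in_order()
        if exons and _in_any(pos, exons[:1]):
            return FeatureCall(peak, "1st exon", g.gene_id)
    for g in same_chrom:
        if _in_any(pos, g.exons_in_order()[1:]):
            return FeatureCall(peak, "Other exon", g.gene_id)
    for g in same_chrom:
        introns = g.introns_in_order()
        if introns and _in_any(pos, introns[:1]):
            return FeatureCall(peak, "1st intron", g.gene_id)
    for g in same_chrom:
        if _in_any(pos, g.introns_in_order()[1:]):
            return FeatureCall(peak, "Other intron", g.gene_id)
    for g in same_chrom:
        if g.strand == "+" and g.end <= pos < g.end + downstream:
            return FeatureCall(peak, "Downstream (<=3 kb)", g.gene_id)
        if g.strand == "-" and g.start - downstream < pos < g.start:
            return FeatureCall(peak, "Downstream (<=3 kb)", g.gene_id)
    return FeatureCall(peak, "Distal intergenic", None)


def classify_peaks(
    peaks: Iterable[GenomicInterval], genes: Sequence[GeneModel], **kwargs
) -> list[FeatureCall]:
    return [classify_peak(p, genes, **kwargs) for p in peaks]


def _round_sig(x: float, sig: int = 3) -> float:
    if x == 0:
        return 0.0
    return float(f"{x:.{sig}g}")


def summarize_features(
    calls: Iterable[FeatureCall] | Mapping[str, int]
) -> pd.DataFrame:
    """Category frequency table: count, percent, and 3-significant-figure
    percent as conventionally printed.

    Accepts either a list of feature calls or a precomputed
    category -> count mapping.
    """
    if isinstance(calls, Mapping):
        counts = pd.Series(dict(calls), dtype=int)
    else:
        counts = pd.Series([c.category for c in calls]).value_counts()
    total = int(counts.sum())
    if total == 0:
        raise ValueError("no feature calls to summarise")
    percent = 100.0 * counts / total
    out = pd.DataFrame(
        {
            "count": counts,
            "percent": percent,
            "percent_printed": percent.map(_round_sig),
        }
    ).sort_values("count", ascending=False)
    out.index.name = "category"
    return out


#: Surjection from the fine (promoter-window) vocabulary onto the coarse
#: five-way vocabulary used for differential-peak summaries. Promoter
#: windows beyond 2 kb collapse into "Proximal"; downstream regions are
#: likewise gene-proximal; exonic calls map to CDS for the first exon
#: (where coding sequence typically starts) and Exonic otherwise.
_TABLE3_MAP = {
    "Promoter (<=1 kb)": "Promoter",
    "Promoter (1-2 kb)": "Promoter",
    "Promoter (2-3 kb)": "Proximal",
    "Downstream (<=3 kb)": "Proximal",
    "5' UTR": "5' UTR",
    "3' UTR": "3' UTR",
    "1st exon": "CDS",
    "Other exon": "Exonic",
    "1st intron": "Intronic",
    "Other intron": "Intronic",
    "Distal intergenic": "Intergenic",
}


def table3_category(category: str) -> str:
    """Map a fine feature category onto the coarse summary vocabulary."""
    return _TABLE3_MAP[category]


# ---------------------------------------------------------------------------
# Signed start-distance overlay
# ---------------------------------------------------------------------------

def signed_start_distance(
    gene: GeneModel, peak: GenomicInterval, window: int = 10000
) -> int | None:
    """Signed distance from the gene's 5' end to the peak's 5'-most boundary.

    Positive when the peak's 5'-most boundary lies within the gene body
    or within ``window`` bp upstream of the 5' end; negative when it
    lies within ``window`` bp past the 3' end; None outside that range.
    The magnitude is the strand-aware distance from the 5' end, so
    |value| <= gene length + window always holds.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if gene.chrom != peak.chrom:
        return None
    if gene.strand == "+":
        p5 = peak.start
        mag = abs(p5 - gene.start)
        if gene.start - window <= p5 < gene.end:
            return mag
        if gene.end <= p5 <= gene.end + window:
            return -mag
        return None
    p5 = peak.end
    mag = abs(gene.end - p5)
    if gene.start < p5 <= gene.end + window:
        return mag
    if gene.start - window <= p5 <= gene.start:
        return -mag
    return None


@dataclass
class OverlayRecord:
    gene_id: str
    peak: GenomicInterval
    start_dist: int
    peak_width: int
    specificity: str
    de_status: bool


def overlay_table(
    de_genes: Iterable[str],
    peaks_by_specificity: Mapping[str, Sequence[GenomicInterval]],
    genes: Sequence[GeneModel],
    window: int = 10000,
) -> pd.DataFrame:
    """All (gene, nearby peak) pairs with signed distance and specificity.

    ``peaks_by_specificity`` maps a specificity label (e.g. "shared",
    "small-only") to a peak list; one row is emitted for each gene/peak
    pair whose signed start-distance is defined, flagged by whether the
    gene is differentially expressed.
    """
    de = set(de_genes)
    rows = []
    for spec_label, peaks in peaks_by_specificity.items():
        for gene in genes:
            for pk in peaks:
                d = signed_start_distance(gene, pk, window=window)
                if d is None:
                    continue
                rows.append(
                    {
                        "gene_id": gene.gene_id,
                        "peak": f"{pk.chrom}:{pk.start}-{pk.end}",
                        "chrom": pk.chrom,
                        "peak_start": pk.start,
                        "peak_end": pk.end,
                        "start_dist": d,
                        "peak_width": pk.width,
                        "specificity": spec_label,
                        "de_status": gene.gene_id in de,
                    }
                )
    cols = [
        "gene_id", "peak", "chrom", "peak_start", "peak_end",
        "start_dist", "peak_width", "specificity", "de_status",
    ]
    out = pd.DataFrame(rows, columns=cols)
    return out.sort_values(["gene_id", "chrom", "peak_start"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# GTF-like annotation I/O (1-based closed coordinates on disk)
# ---------------------------------------------------------------------------

def write_annotation(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as GTF-like lines (gene/exon/UTR features)."""
    with Path(path).open("w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}";'

            def line(feature: str, s: int, e: int) -> str:
                # 0-based half-open -> 1-based closed
                return (
                    f"{g.chrom}\tpeakforge\t{feature}\t{s + 1}\t{e}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )

            fh.write(line("gene", g.start, g.end))
            for s, e in sorted(g.exons):
                fh.write(line("exon", s, e))
            for s, e in sorted(g.utr5):
                fh.write(line("five_prime_utr", s, e))
            for s, e in sorted(g.utr3):
                fh.write(line("three_prime_utr", s, e))


def read_annotation(path: str | Path) -> list[GeneModel]:
    """Read gene models written by :func:`write_annotation`."""
    raw: dict[str, dict] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GTF fields")
            chrom, _src, feature, start1, end1, _score, strand, _frame, attrs = fields[:9]
            m = [a for a in attrs.split(";") if "gene_id" in a]
            if not m:
                raise ValueError(f"{path}:{lineno}: missing gene_id attribute")
            gene_id = m[0].split('"')[1]
            s, e = int(start1) - 1, int(end1)
            rec = raw.setdefault(
                gene_id,
                {"chrom": chrom, "strand": strand, "span": None,
                 "exons": [], "utr5": [], "utr3": []},
            )
            if feature == "gene":
                rec["span"] = (s, e)
            elif feature == "exon":
                rec["exons"].append((s, e))
            elif feature == "five_prime_utr":
                rec["utr5"].append((s, e))
            elif feature == "three_prime_utr":
                rec["utr3"].append((s, e))
    genes = []
    for gene_id, rec in raw.items():
        span = rec["span"]
        if span is None:
            exons = rec["exons"]
            span = (min(s for s, _ in exons), max(e for _, e in exons))
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chrom=rec["chrom"],
                strand=rec["strand"],
                start=span[0],
                end=span[1],
                exons=sorted(rec["exons"]),
                utr5=sorted(rec["utr5"]),
                utr3=sorted(rec["utr3"]),
            )
        )
    return genes
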