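"""Synthetic inputs emulating a developmental muscle ATAC/RNA study design.

Everything downstream of alignment is generated here with the
statistical structure the analysis assumes: a toy two-autosome (+ MT)
genome with non-overlapping gene models; per-sample fragment sets whose
lengths follow a tri-modal (nucleosome-free / mono- / di-nucleosome)
mixture and which pile up around TSSs; per-sample peak calls built from
a shared core set plus size-class-specific peaks; and negative-binomial
count matrices with planted timepoint and size effects. The default
sample design mirrors an unbalanced five-stage litter study: 24 samples
over gestational days 45/60/90 and postnatal weeks 1/6, each litter
contributing its smallest, average and largest piglet where available.

All outputs are deterministic functions of the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel, write_annotation
from .intervals import ConsensusPeak, CountMatrix, GenomicInterval
from .qc import FRAGMENT_COLUMNS, PROPER_PAIR

__all__ = [
    "SimulationConfig",
    "ToyGenome",
    "PeakCalls",
    "make_design_table",
    "make_annotation",
    "make_fragments",
    "make_peak_calls",
    "make_count_matrix",
    "make_expression_matrix",
    "simulate_all",
]

TIMEPOINTS = ("D45", "D60", "D90", "1WK", "6WK")
SIZES = ("small", "average", "large")

#: (timepoint, litter, sizes present) — unbalanced by design: complete
#: litters only at the two earliest stages, several litters at day 90,
#: and partial litters postnatally.
DEFAULT_DESIGN = (
    ("D45", "L1", ("small", "average", "large")),
    ("D60", "L2", ("small", "average", "large")),
    ("D90", "L3", ("small", "average", "large")),
    ("D90", "L4", ("small", "average", "large")),
    ("D90", "L5", ("small", "average", "large")),
    ("D90", "L6", ("small", "large")),
    ("1WK", "L7", ("small", "large")),
    ("6WK", "L8", ("small", "average")),
    ("6WK", "L9", ("small", "average", "large")),
)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the emulated design."""

    seed: int = 0
    chrom_sizes: dict = field(
        default_factory=lambda: {"chr1": 1_000_000, "chr2": 1_000_000, "MT": 16_000}
    )
    n_genes: int = 60
    timepoints: tuple = TIMEPOINTS
    sizes: tuple = SIZES
    # fragment-length mixture: (mean bp, sd bp, weight) per component —
    # nucleosome-free, mono-nucleosome, di-nucleosome
    frag_mixture: tuple = ((50.0, 12.0, 0.50), (180.0, 25.0, 0.32), (350.0, 40.0, 0.18))
    tss_frag_fraction: float = 0.40  # fragments centered within 1 kb of a TSS
    peak_frag_fraction: float = 0.30  # fragments placed inside planted peaks
    tss_peak_fraction: float = 0.55  # peaks centered within 1 kb of a TSS
    fail_fraction: float = 0.08  # fragments failing the quality filter
    mt_fraction: float = 0.02  # fragments on the mitochondrial chromosome
    dup_unmarked_fraction: float = 0.04  # position-duplicate fragments that
    # survive filtering, so NRF/PBC have something to measure
    n_core_peaks: int = 150
    n_noise_peaks: int = 3  # extra private peaks per sample
    n_size_specific: int = 8  # per size class, planted at day 90
    peak_jitter: int = 20  # max boundary jitter of shared peaks (bp)
    nb_dispersion: float = 0.1
    effect_log2fc: float = 2.5  # planted timepoint effect (accessibility)
    effect_fraction: float = 0.10  # fraction of peaks carrying a time effect
    expr_effect_log2fc: float = 2.0  # planted size effect (expression)
    expr_effect_fraction: float = 0.10
    libsize_log_sd: float = 0.3  # log-normal spread of library-size factors

    def __post_init__(self) -> None:
        w = sum(c[2] for c in self.frag_mixture)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"fragment-mixture weights must sum to 1, got {w}")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if not 0 <= self.tss_frag_fraction <= 1:
            raise ValueError("tss_frag_fraction must be in [0, 1]")
        if self.mt_fraction + self.tss_frag_fraction + self.peak_frag_fraction > 1:
            raise ValueError("fragment placement fractions exceed 1")
        if any(size <= 0 for size in self.chrom_sizes.values()):
            raise ValueError("chromosome sizes must be positive")

    @property
    def autosomes(self) -> list[str]:
        return [c for c in self.chrom_sizes if c != "MT"]


def _rng(seed: int, *keys: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, keys)]))


# stream ids so independent outputs draw from independent substreams
_K_ANNOT, _K_FRAG, _K_PEAKS, _K_COUNTS, _K_EXPR = 1, 2, 3, 4, 5


@dataclass
class ToyGenome:
    chrom_sizes: dict
    genes: list[GeneModel]

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            raise ValueError("gene ids must be unique")
        for g in self.genes:
            if g.chrom not in self.chrom_sizes:
                raise ValueError(f"{g.gene_id} on unknown chromosome {g.chrom}")
            if not (0 <= g.start < g.end <= self.chrom_sizes[g.chrom]):
                raise ValueError(f"{g.gene_id} outside chromosome bounds")

    def tss_list(self) -> list[tuple[str, int, str]]:
        return [(g.chrom, g.tss, g.strand) for g in self.genes]


def make_design_table(config: SimulationConfig | None = None) -> pd.DataFrame:
    """Sample sheet of the emulated study (24 samples, unbalanced)."""
    config = config or SimulationConfig()
    rows = []
    for tp, litter, sizes in DEFAULT_DESIGN:
        for size in sizes:
            rows.append((f"{tp}_{size}_{litter}", tp, size, litter))
    df = pd.DataFrame(rows, columns=["sample", "timepoint", "size", "litter"])
    df["timepoint"] = pd.Categorical(df["timepoint"], categories=config.timepoints,
                                     ordered=True)
    df["size"] = pd.Categorical(df["size"], categories=config.sizes)  # small = ref
    return df.set_index("sample")


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def make_annotation(config: SimulationConfig) -> ToyGenome:
    """Random non-overlapping gene models on the autosomes.

    Gene lengths are 3-15 kb with 2-6 exons; the 5' and 3' UTRs are the
    outer fifths of the terminal exons. Raises when the requested gene
    count cannot fit the genome.
    """
    rng = _rng(config.seed, _K_ANNOT)
    margin, min_gap = 2_000, 1_000
    autosomes = config.autosomes
    weights = np.array([config.chrom_sizes[c] for c in autosomes], dtype=float)
    n_per = np.floor(weights / weights.sum() * config.n_genes).astype(int)
    for i in range(config.n_genes - n_per.sum()):
        n_per[i % len(autosomes)] += 1

    genes: list[GeneModel] = []
    gid = 0
    for chrom, n in zip(autosomes, n_per):
        if n == 0:
            continue
        usable = config.chrom_sizes[chrom] - 2 * margin
        lengths = rng.integers(3_000, 15_001, size=n)
        needed = lengths.sum() + (n - 1) * min_gap
        if needed > usable:
            raise ValueError(
                f"cannot place {n} genes on {chrom}: need {needed} bp, have {usable}"
            )
        slack = usable - needed
        cuts = np.sort(rng.uniform(0, slack, size=n))
        offsets = margin + cuts + np.concatenate([[0], np.cumsum(lengths[:-1] + min_gap)])
        for start, length in zip(offsets.astype(int), lengths):
            end = start + int(length)
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(2, 7))
            # exon/intron structure: 2*n_exons - 1 alternating blocks
            bounds = np.sort(rng.choice(
                np.arange(start + 50, end - 50), size=2 * n_exons - 2, replace=False
            ))
            edges = np.concatenate([[start], bounds, [end]])
            exons = [(int(edges[i]), int(edges[i + 1]))
                     for i in range(0, 2 * n_exons - 1, 2)]
            first, last = (exons[0], exons[-1]) if strand == "+" else (exons[-1], exons[0])
            if strand == "+":
                utr5 = [(first[0], first[0] + max(1, (first[1] - first[0]) // 5))]
                utr3 = [(last[1] - max(1, (last[1] - last[0]) // 5), last[1])]
            else:
                utr5 = [(first[1] - max(1, (first[1] - first[0]) // 5), first[1])]
                utr3 = [(last[0], last[0] + max(1, (last[1] - last[0]) // 5))]
            genes.append(GeneModel(
                gene_id=f"G{gid:04d}", chrom=chrom, strand=strand,
                start=start, end=end, exons=exons, utr5=utr5, utr3=utr3,
            ))
            gid += 1
    return ToyGenome(chrom_sizes=dict(config.chrom_sizes), genes=genes)


# ---------------------------------------------------------------------------
# Fragments
# ---------------------------------------------------------------------------

def _draw_lengths(rng: np.random.Generator, config: SimulationConfig, n: int) -> np.ndarray:
    means, sds, weights = (np.array(v) for v in zip(*config.frag_mixture))
    comp = rng.choice(len(means), size=n, p=weights)
    lengths = rng.normal(means[comp], sds[comp])
    return np.maximum(np.round(lengths), 15).astype(int)


def make_fragments(
    genome: ToyGenome,
    config: SimulationConfig,
    per_sample_depth: int,
    sample_ids: Sequence[str],
    calls: "PeakCalls | None" = None,
    design: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-sample fragment sets with the configured length mixture.

    A ``tss_frag_fraction`` share of fragments is centered within 1 kb
    of a TSS (triangular pile-up peaking at the TSS itself); the rest
    are uniform over the autosomes, with a small share on MT. A
    ``fail_fraction`` share is made to fail the quality filter via low
    mapping quality, a duplicate flag, or a broken proper-pair flag.

    When planted peak calls and the sample design are supplied, a
    ``peak_frag_fraction`` share of fragments lands inside the core
    peaks with per-peak rates; a peak planted with a time effect has
    its rate scaled by 2^(sign * effect_log2fc) in samples from its
    active timepoint, so the differential signal is recoverable from
    fragment counting alone.
    """
    if per_sample_depth <= 0:
        raise ValueError("per_sample_depth must be positive")
    autosomes = [c for c in genome.chrom_sizes if c != "MT"]
    sizes = np.array([genome.chrom_sizes[c] for c in autosomes], dtype=float)
    tss = [(g.chrom, g.tss) for g in genome.genes if g.chrom != "MT"]

    peak_w = None
    tp_by_sample: dict = {}
    if calls is not None and calls.core:
        wrng = _rng(config.seed, _K_FRAG, 999_999)
        peak_w = np.exp(wrng.normal(0.0, 0.5, size=len(calls.core)))
        if design is not None:
            tp_by_sample = {s: str(t) for s, t in design["timepoint"].items()}

    frames = []
    for si, sample in enumerate(sample_ids):
        rng = _rng(config.seed, _K_FRAG, si)
        n = per_sample_depth
        lengths = _draw_lengths(rng, config, n)

        chroms = np.empty(n, dtype=object)
        centers = np.empty(n, dtype=int)
        u = rng.random(n)
        p_mt = config.mt_fraction
        p_peak = config.peak_frag_fraction if peak_w is not None else 0.0
        on_mt = u < p_mt
        in_peak = (~on_mt) & (u < p_mt + p_peak)
        near_tss = (~on_mt) & (~in_peak) & (u < p_mt + p_peak + config.tss_frag_fraction) \
            if tss else np.zeros(n, dtype=bool)
        uniform = ~(on_mt | in_peak | near_tss)

        if on_mt.any():
            chroms[on_mt] = "MT"
            centers[on_mt] = rng.integers(0, genome.chrom_sizes["MT"], size=on_mt.sum())
        if in_peak.any():
            w = peak_w.copy()
            if calls.core_time_sign is not None and sample in tp_by_sample:
                hit = calls.core_active_tp == tp_by_sample[sample]
                w = w * np.power(
                    2.0, hit * calls.core_time_sign * config.effect_log2fc
                )
            w = w / w.sum()
            pick = rng.choice(len(calls.core), size=in_peak.sum(), p=w)
            chroms[in_peak] = [calls.core[i].chrom for i in pick]
            lo = np.array([calls.core[i].start for i in pick])
            hi = np.array([calls.core[i].end for i in pick])
            centers[in_peak] = lo + (rng.random(in_peak.sum()) * (hi - lo)).astype(int)
        if near_tss.any():
            pick = rng.integers(0, len(tss), size=near_tss.sum())
            offs = rng.triangular(-1000, 0, 1000, size=near_tss.sum()).astype(int)
            chroms[near_tss] = [tss[i][0] for i in pick]
            centers[near_tss] = np.array([tss[i][1] for i in pick]) + offs
        if uniform.any():
            ci = rng.choice(len(autosomes), size=uniform.sum(), p=sizes / sizes.sum())
            chroms[uniform] = [autosomes[i] for i in ci]
            centers[uniform] = (rng.random(uniform.sum())
                                * sizes[ci]).astype(int)

        starts = np.maximum(centers - lengths // 2, 0)
        bound = np.array([genome.chrom_sizes[c] for c in chroms])
        ends = np.minimum(starts + lengths, bound)
        starts = np.minimum(starts, ends - 1)

        n_dup = int(round(config.dup_unmarked_fraction * n))
        if n_dup and n > 1:
            dup_idx = rng.choice(n, size=n_dup, replace=False)
            src_idx = rng.integers(0, n, size=n_dup)
            chroms[dup_idx] = chroms[src_idx]
            starts[dup_idx] = starts[src_idx]
            ends[dup_idx] = ends[src_idx]

        mapq = np.full(n, 60)
        flags = np.full(n, PROPER_PAIR)
        n_fail = int(round(config.fail_fraction * n))
        if n_fail:
            fail_idx = rng.choice(n, size=n_fail, replace=False)
            mode = rng.integers(0, 3, size=n_fail)
            mapq[fail_idx[mode == 0]] = rng.integers(0, 10, size=(mode == 0).sum())
            flags[fail_idx[mode == 1]] |= 0x400  # PCR duplicate
            flags[fail_idx[mode == 2]] &= ~PROPER_PAIR
        frames.append(pd.DataFrame({
            "chrom": chroms, "start": starts, "end": ends,
            "mapq": mapq, "flags": flags, "sample": sample,
        }))
    return pd.concat(frames, ignore_index=True)[FRAGMENT_COLUMNS]


# ---------------------------------------------------------------------------
# Peak calls
# ---------------------------------------------------------------------------

@dataclass
class PeakCalls:
    """Per-sample peak calls plus the planted truth behind them."""

    by_sample: dict  # sample -> list[GenomicInterval]
    core: list  # the shared true peaks
    size_specific: dict  # size class -> list of planted class-only peaks
    core_time_sign: np.ndarray | None = None  # per core peak: -1/0/+1 time effect
    core_active_tp: np.ndarray | None = None  # timepoint at which the effect acts


def _place_separated(
    rng: np.random.Generator,
    genome: ToyGenome,
    config: SimulationConfig,
    n: int,
    existing: list[GenomicInterval],
    min_sep: int,
    width_range: tuple[int, int] = (200, 600),
) -> list[GenomicInterval]:
    """Greedily place ``n`` peaks separated from each other and ``existing``."""
    autosomes = [c for c in genome.chrom_sizes if c != "MT"]
    sizes = np.array([genome.chrom_sizes[c] for c in autosomes], dtype=float)
    tss = [(g.chrom, g.tss) for g in genome.genes if g.chrom != "MT"]
    placed = list(existing)
    out: list[GenomicInterval] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 200 * max(n, 1):
            raise ValueError("cannot place peaks with the required separation")
        width = int(rng.integers(*width_range))
        if tss and rng.random() < config.tss_peak_fraction:
            chrom, pos = tss[int(rng.integers(0, len(tss)))]
            center = pos + int(rng.integers(-500, 501))
        else:
            ci = int(rng.choice(len(autosomes), p=sizes / sizes.sum()))
            chrom = autosomes[ci]
            center = int(rng.random() * sizes[ci])
        start = max(center - width // 2, 0)
        end = min(start + width, genome.chrom_sizes[chrom])
        if end - start < width_range[0]:
            continue
        cand = GenomicInterval(chrom, start, end)
        if any(p.chrom == cand.chrom
               and cand.start - min_sep < p.end and p.start < cand.end + min_sep
               for p in placed):
            continue
        placed.append(cand)
        out.append(cand)
    return out


def make_peak_calls(
    genome: ToyGenome,
    config: SimulationConfig,
    design: pd.DataFrame | None = None,
    merge_gap: int = 10,
) -> PeakCalls:
    """Per-sample peak calls: shared core + size-specific + private noise.

    Core peaks appear in every sample with boundary jitter up to
    ``peak_jitter`` bp; size-specific peaks appear in every day-90
    sample of one size class only; noise peaks are private to one
    sample. All planted peaks are separated widely enough that jitter
    can never merge two distinct truths into one consensus peak.
    """
    design = design if design is not None else make_design_table(config)
    rng = _rng(config.seed, _K_PEAKS)
    min_sep = merge_gap + 2 * config.peak_jitter + 10
    core = _place_separated(rng, genome, config, config.n_core_peaks, [], min_sep)
    n_eff = int(round(config.effect_fraction * len(core)))
    core_time_sign = np.zeros(len(core))
    core_active_tp = np.array([""] * len(core), dtype=object)
    if n_eff:
        idx = rng.choice(len(core), size=n_eff, replace=False)
        core_time_sign[idx] = rng.choice([-1.0, 1.0], size=n_eff)
        core_active_tp[idx] = rng.choice([str(t) for t in config.timepoints],
                                         size=n_eff)
    specific: dict[str, list[GenomicInterval]] = {}
    placed = list(core)
    for size in config.sizes:
        specific[size] = _place_separated(
            rng, genome, config, config.n_size_specific, placed, min_sep
        )
        placed.extend(specific[size])

    by_sample: dict[str, list[GenomicInterval]] = {}
    for si, (sample, row) in enumerate(design.iterrows()):
        srng = _rng(config.seed, _K_PEAKS, 100 + si)
        calls: list[GenomicInterval] = []
        j = config.peak_jitter
        for pk in core:
            a = pk.start + int(srng.integers(-j, j + 1)) if j else pk.start
            b = pk.end + int(srng.integers(-j, j + 1)) if j else pk.end
            calls.append(GenomicInterval(pk.chrom, max(a, 0), max(b, a + 50),
                                         sample=sample))
        if str(row["timepoint"]) == "D90":
            for pk in specific.get(str(row["size"]), []):
                calls.append(GenomicInterval(pk.chrom, pk.start, pk.end, sample=sample))
        if config.n_noise_peaks:
            noise = _place_separated(
                srng, genome, config, config.n_noise_peaks, placed, min_sep
            )
            calls.extend(GenomicInterval(p.chrom, p.start, p.end, sample=sample)
                         for p in noise)
        by_sample[sample] = sorted(calls, key=lambda p: (p.chrom, p.start))
    return PeakCalls(by_sample=by_sample, core=core, size_specific=specific,
                     core_time_sign=core_time_sign, core_active_tp=core_active_tp)


# ---------------------------------------------------------------------------
# Count matrices with planted effects
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    if alpha < 1e-12:
        return rng.poisson(mu)
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mu))


def make_count_matrix(
    peaks: Sequence[ConsensusPeak] | Sequence[str] | int,
    design: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[CountMatrix, pd.DataFrame]:
    """NB counts over peaks with a planted time effect on a subset.

    Each affected peak is assigned one "active" timepoint at which its
    mean is scaled by 2^(s_i * effect_log2fc) (sign s_i random), so
    every developmental stage carries its own marker peaks:
    mean[i, j] = libfactor_j * base_i * 2^(s_i * effect_log2fc *
    [timepoint_j == active_i]); dispersion is ``nb_dispersion``.
    Returns the count matrix and a truth table (affected, sign, active
    timepoint, true max-contrast log2FC).
    """
    if isinstance(peaks, int):
        names = [f"peak{i:05d}" for i in range(peaks)]
    elif peaks and isinstance(peaks[0], ConsensusPeak):
        names = [p.name for p in peaks]
    else:
        names = [str(p) for p in peaks]
    n_feat, n_samp = len(names), len(design)
    if config.effect_fraction > 0 and design["timepoint"].nunique() < 2:
        raise ValueError("need >=2 timepoints to plant a time effect")
    rng = _rng(config.seed, _K_COUNTS)
    base = np.exp(rng.normal(np.log(100.0), 1.0, size=n_feat))
    libfac = np.exp(rng.normal(0.0, config.libsize_log_sd, size=n_samp))

    n_affected = int(round(config.effect_fraction * n_feat))
    affected_idx = rng.choice(n_feat, size=n_affected, replace=False)
    signs = np.zeros(n_feat)
    signs[affected_idx] = rng.choice([-1.0, 1.0], size=n_affected)

    tp = design["timepoint"].astype(str).to_numpy()
    levels = [str(l) for l in (
        design["timepoint"].cat.categories
        if isinstance(design["timepoint"].dtype, pd.CategoricalDtype)
        else sorted(design["timepoint"].unique())
    ) if str(l) in set(tp)]
    active = np.array([""] * n_feat, dtype=object)
    active[affected_idx] = rng.choice(levels, size=n_affected)
    delta = np.where(active[:, None] == tp[None, :], 1.0, 0.0) \
        * (signs * config.effect_log2fc)[:, None]
    mu = base[:, None] * libfac[None, :] * np.power(2.0, delta)
    counts = _nb_draw(rng, mu, config.nb_dispersion)
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(names, name="peak"),
                            columns=design.index),
        library_sizes=pd.Series(counts.sum(axis=0), index=design.index),
    )
    truth = pd.DataFrame(
        {"affected": signs != 0, "sign": signs, "active_timepoint": active,
         "log2fc": signs * config.effect_log2fc},
        index=cm.feature_ids,
    )
    return cm, truth


def make_expression_matrix(
    genome: ToyGenome,
    design: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Transcript-level NB counts with a planted size-class effect.

    Affected genes shift large-size samples by the full
    ``expr_effect_log2fc`` and average-size samples by half of it,
    relative to small (the reference class). Returns counts and truth.
    """
    names = [g.gene_id for g in genome.genes]
    n_feat, n_samp = len(names), len(design)
    rng = _rng(config.seed, _K_EXPR)
    base = np.exp(rng.normal(np.log(200.0), 1.0, size=n_feat))
    libfac = np.exp(rng.normal(0.0, config.libsize_log_sd, size=n_samp))

    n_affected = int(round(config.expr_effect_fraction * n_feat))
    affected_idx = rng.choice(n_feat, size=n_affected, replace=False) \
        if n_affected else np.array([], dtype=int)
    signs = np.zeros(n_feat)
    if n_affected:
        signs[affected_idx] = rng.choice([-1.0, 1.0], size=n_affected)

    size = design["size"].astype(str).to_numpy()
    size_scale = np.where(size == "large", 1.0, np.where(size == "average", 0.5, 0.0))
    delta = np.outer(signs * config.expr_effect_log2fc, size_scale)
    mu = base[:, None] * libfac[None, :] * np.power(2.0, delta)
    counts = _nb_draw(rng, mu, config.nb_dispersion)
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(names, name="gene"),
                            columns=design.index),
        library_sizes=pd.Series(counts.sum(axis=0), index=design.index),
    )
    truth = pd.DataFrame(
        {"affected": signs != 0, "sign": signs,
         "log2fc_large": signs * config.expr_effect_log2fc},
        index=cm.feature_ids,
    )
    return cm, truth


# ---------------------------------------------------------------------------
# Writing a full input set
# ---------------------------------------------------------------------------

def simulate_all(
    config: SimulationConfig,
    out_dir: str | Path,
    per_sample_depth: int = 8000,
) -> dict:
    """Generate and write every pipeline input; returns the paths."""
    from .intervals import write_peaks
    from .qc import write_fragments

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = make_annotation(config)
    design = make_design_table(config)
    calls = make_peak_calls(genome, config, design)
    frags = make_fragments(genome, config, per_sample_depth, list(design.index),
                           calls=calls, design=design)

    paths = {"annotation": out / "annotation.gtf", "design": out / "design.tsv"}
    write_annotation(genome.genes, paths["annotation"])
    design.to_csv(paths["design"], sep="\t")
    peak_dir = out / "peaks"
    peak_dir.mkdir(exist_ok=True)
    for sample, ivs in calls.by_sample.items():
        write_peaks(ivs, peak_dir / f"{sample}.bed")
    paths["peaks_dir"] = peak_dir
    frag_dir = out / "fragments"
    frag_dir.mkdir(exist_ok=True)
    for sample, grp in frags.groupby("sample", observed=True):
        write_fragments(grp, frag_dir / f"{sample}.bed")
    paths["fragments_dir"] = frag_dir

    chrom_path = out / "chrom.sizes"
    with chrom_path.open("w") as fh:
        for c, s in genome.chrom_sizes.items():
            fh.write(f"{c}\t{s}\n")
    paths["chrom_sizes"] = chrom_path
    return paths
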