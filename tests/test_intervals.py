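"""Consensus-peak construction: merging, support, sharing, counting."""

import numpy as np
import pandas as pd
import pytest

from peakforge.intervals import (
    CountMatrix,
    GenomicInterval,
    count_fragments,
    filter_support,
    merge_with_support,
    read_peaks,
    separate_size_specific,
    write_consensus,
    write_peaks,
)


def random_intervals(rng, n, n_samples=5, chroms=("chr1", "chr2"), span=5000):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, span))
        out.append(
            GenomicInterval(
                chrom=str(rng.choice(chroms)),
                start=start,
                end=start + int(rng.integers(1, 120)),
                sample=f"s{int(rng.integers(n_samples))}",
            )
        )
    return out


def brute_force_merge(peaks, gap):
    """Transitive closure of the within-gap relation via union-find."""
    n = len(peaks)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = peaks[i], peaks[j]
            if a.chrom != b.chrom:
                continue
            d = max(a.start, b.start) - min(a.end, b.end)
            if d <= gap:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(peaks[i])
    result = set()
    for members in groups.values():
        result.add(
            (
                members[0].chrom,
                min(p.start for p in members),
                max(p.end for p in members),
                len({p.sample for p in members}),
            )
        )
    return result


class TestInterval:
    def test_rejects_inverted_and_negative(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 200, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 100, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -5, 100)


class TestPeakIO:
    def test_bed3_line(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\n")
        (iv,) = read_peaks(p)
        assert (iv.chrom, iv.start, iv.end) == ("chr1", 100, 200)

    def test_narrowpeak_retains_signal(self, tmp_path):
        p = tmp_path / "a.narrowPeak"
        p.write_text("chr1\t100\t200\tpeak1\t850\t.\t12.5\t30.1\t25.2\t40\n")
        (iv,) = read_peaks(p)
        assert iv.score == pytest.approx(12.5)

    def test_malformed_line_names_lineno(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\nchr1\t300\t250\n")
        with pytest.raises(ValueError, match=":2"):
            read_peaks(p)

    def test_round_trip(self, tmp_path, rng):
        peaks = random_intervals(rng, 30)
        path = tmp_path / "rt.bed"
        write_peaks(peaks, path)
        back = read_peaks(path)
        assert [(p.chrom, p.start, p.end) for p in back] == [
            (p.chrom, p.start, p.end) for p in peaks
        ]


class TestMerge:
    def test_two_peaks_within_gap_merge(self):
        peaks = [
            GenomicInterval("chr1", 100, 200, sample="sA"),
            GenomicInterval("chr1", 205, 300, sample="sB"),
        ]
        (merged,) = merge_with_support(peaks, merge_gap=10)
        assert (merged.start, merged.end, merged.support) == (100, 300, 2)

    def test_gap_above_threshold_stays_split(self):
        peaks = [
            GenomicInterval("chr1", 100, 200, sample="sA"),
            GenomicInterval("chr1", 211, 300, sample="sB"),
        ]
        assert len(merge_with_support(peaks, merge_gap=10)) == 2

    def test_single_peak_identity(self):
        (m,) = merge_with_support([GenomicInterval("chr1", 5, 50, sample="x")])
        assert (m.start, m.end, m.support) == (5, 50, 1)

    def test_same_sample_counts_once(self):
        peaks = [
            GenomicInterval("chr1", 100, 200, sample="sA"),
            GenomicInterval("chr1", 150, 300, sample="sA"),
        ]
        (m,) = merge_with_support(peaks)
        assert m.support == 1

    def test_negative_gap_rejected(self):
        with pytest.raises(ValueError):
            merge_with_support([], merge_gap=-1)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        peaks = random_intervals(rng, 200)
        merged = merge_with_support(peaks, merge_gap=10)
        got = {(m.chrom, m.start, m.end, m.support) for m in merged}
        assert got == brute_force_merge(peaks, 10)

    def test_idempotent_and_separated(self, rng):
        peaks = random_intervals(rng, 150)
        once = merge_with_support(peaks, merge_gap=10)
        again = merge_with_support([m.as_interval() for m in once], merge_gap=10)
        assert [(m.chrom, m.start, m.end) for m in again] == [
            (m.chrom, m.start, m.end) for m in once
        ]
        by_chrom = {}
        for m in once:
            by_chrom.setdefault(m.chrom, []).append(m)
        for group in by_chrom.values():
            group.sort(key=lambda m: m.start)
            for a, b in zip(group, group[1:]):
                assert b.start - a.end > 10

    def test_support_conservation_and_order_invariance(self, rng):
        peaks = random_intervals(rng, 120)
        merged = merge_with_support(peaks, merge_gap=10)
        assert sum(len(m.members) for m in merged) == len(peaks)
        shuffled = list(peaks)
        rng.shuffle(shuffled)
        merged2 = merge_with_support(shuffled, merge_gap=10)
        key = lambda ms: sorted((m.chrom, m.start, m.end, m.support) for m in ms)
        assert key(merged) == key(merged2)


class TestFilterSupport:
    def test_threshold_three(self, rng):
        peaks = []
        for i, support in enumerate([1, 2, 3, 5]):
            for s in range(support):
                peaks.append(
                    GenomicInterval("chr1", 1000 * i, 1000 * i + 100, sample=f"s{s}")
                )
        merged = merge_with_support(peaks)
        kept = filter_support(merged, min_support=3)
        assert [m.support for m in kept] == [3, 5]

    def test_empty_and_identity(self):
        assert filter_support([], 3) == []
        peaks = merge_with_support([GenomicInterval("chr1", 0, 10, sample="a")])
        assert filter_support(peaks, 1) == peaks

    def test_min_support_below_one_rejected(self):
        with pytest.raises(ValueError):
            filter_support([], 0)


class TestSizeSpecific:
    def test_identical_sets_all_shared(self):
        peaks = [GenomicInterval("chr1", i * 1000, i * 1000 + 100) for i in range(5)]
        split = separate_size_specific({"small": peaks, "large": list(peaks)})
        assert all(len(v) == 5 for v in split.shared.values())
        assert all(len(v) == 0 for v in split.specific.values())

    def test_planted_small_only_recovered(self):
        shared = [GenomicInterval("chr1", 1000, 1200)]
        small_only = [GenomicInterval("chr1", 5000, 5300)]
        split = separate_size_specific(
            {
                "small": shared + small_only,
                "average": list(shared),
                "large": list(shared),
            }
        )
        assert split.specific["small"] == small_only
        assert split.shared["small"] == shared

    def test_partial_reported_separately(self):
        pk = [GenomicInterval("chr1", 0, 100)]
        split = separate_size_specific({"a": pk, "b": list(pk), "c": []})
        assert split.partial["a"] == pk and split.partial["b"] == pk
        assert not split.shared["a"] and not split.specific["a"]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            separate_size_specific({"small": []})

    @pytest.mark.parametrize("seed", [3, 4])
    def test_matches_pairwise_overlap_oracle(self, seed):
        rng = np.random.default_rng(seed)
        sets = {c: random_intervals(rng, 40) for c in ("small", "average", "large")}
        split = separate_size_specific(sets)
        for c, peaks in sets.items():
            others = [o for o in sets if o != c]
            for iv in peaks:
                hits = sum(
                    any(iv.overlaps(q) for q in sets[o]) for o in others
                )
                if hits == len(others):
                    assert iv in split.shared[c]
                elif hits == 0:
                    assert iv in split.specific[c]
                else:
                    assert iv in split.partial[c]


def _frag_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "sample"]).assign(
        mapq=60, flags=0x2
    )


class TestCountFragments:
    def test_hand_count_and_library_size(self):
        consensus = merge_with_support([GenomicInterval("chr1", 100, 200, sample="a")])
        rows = [("chr1", 120, 180, "s1")] * 3 + [("chr1", 5000, 5100, "s1")] * 7
        cm = count_fragments(consensus, _frag_frame(rows))
        assert cm.counts.iloc[0, 0] == 3
        assert cm.library_sizes["s1"] == 10

    def test_overlapping_consensus_rejected(self):
        a = merge_with_support([GenomicInterval("chr1", 0, 100, sample="x")])[0]
        b = merge_with_support([GenomicInterval("chr1", 50, 150, sample="x")])[0]
        with pytest.raises(ValueError, match="overlap"):
            count_fragments([a, b], _frag_frame([("chr1", 0, 10, "s1")]))

    def test_matches_all_pairs_oracle(self, rng):
        base = random_intervals(rng, 60, n_samples=3)
        consensus = merge_with_support(base, merge_gap=10)
        rows = []
        for _ in range(400):
            start = int(rng.integers(0, 5200))
            rows.append(
                (str(rng.choice(["chr1", "chr2"])), start,
                 start + int(rng.integers(20, 400)), f"s{int(rng.integers(3))}")
            )
        frags = _frag_frame(rows)
        cm = count_fragments(consensus, frags)
        for i, pk in enumerate(sorted(consensus, key=lambda p: (p.chrom, p.start))):
            for s in cm.sample_ids:
                sub = frags[(frags["sample"] == s) & (frags["chrom"] == pk.chrom)]
                expect = ((sub["start"] < pk.end) & (sub["end"] > pk.start)).sum()
                assert cm.counts.loc[pk.name, s] == expect


class TestCountMatrix:
    def test_rejects_negative_counts_and_bad_libsize(self):
        df = pd.DataFrame({"s1": [1, -2]})
        with pytest.raises(ValueError):
            CountMatrix(counts=df, library_sizes=pd.Series({"s1": 10}))
        with pytest.raises(ValueError):
            CountMatrix(
                counts=pd.DataFrame({"s1": [1, 2]}),
                library_sizes=pd.Series({"s1": 0}),
            )


def test_consensus_bed_has_support_column(tmp_path):
    peaks = merge_with_support(
        [
            GenomicInterval("chr1", 0, 100, sample="a"),
            GenomicInterval("chr1", 50, 150, sample="b"),
        ]
    )
    path = tmp_path / "cons.bed"
    write_consensus(peaks, path)
    fields = path.read_text().strip().split("\t")
    assert fields[4] == "2"
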