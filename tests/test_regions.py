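"""Switching-region detection: worked examples, oracle equivalence, properties."""

import numpy as np
import pytest

from dismir.io import GenomicRegion, MethylRead, cpg_count, methylation_ratio
from dismir.regions import (
    MIN_CPG_SITES,
    RegionReadIndex,
    bin_genome,
    detect_switching_regions,
    extract_region_reads,
    filter_regions,
    flag_switching_reads,
    fsr,
)


def read_with_ratio(ratio_num, ratio_den, chrom="chr1", start=0, rid="r"):
    """A read with ratio_num methylated of ratio_den CpG calls (>= 3)."""
    assert ratio_den >= MIN_CPG_SITES
    calls = "M" * ratio_num + "U" * (ratio_den - ratio_num)
    seq = "CA" * ratio_den
    meth = "".join(c + "." for c in calls)
    return MethylRead(rid, chrom, start, "+", seq, meth)


class TestBinGenome:
    def test_partial_final_bin_included(self):
        bins = bin_genome({"chr1": 1200}, 500)
        assert [(b.start, b.end) for b in bins] == [(0, 500), (500, 1000), (1000, 1200)]

    def test_exact_single_bin(self):
        assert bin_genome({"chr1": 500}, 500) == [GenomicRegion("chr1", 0, 500)]

    def test_zero_bin_size_rejected(self):
        with pytest.raises(ValueError):
            bin_genome({"chr1": 500}, 0)

    def test_zero_length_chrom_skipped(self):
        assert bin_genome({"chr0": 0, "chr1": 10}, 5) == [
            GenomicRegion("chr1", 0, 5), GenomicRegion("chr1", 5, 10)]


class TestAssignment:
    def test_boundary_reads_assigned_by_start(self):
        bins = bin_genome({"chr1": 1000}, 500)
        index = RegionReadIndex(bins)
        index.add_reads([read_with_ratio(3, 3, start=499, rid="a"),
                         read_with_ratio(3, 3, start=500, rid="b")], "healthy")
        assert [r.read_id for r in index.reads[bins[0]]["healthy"]] == ["a"]
        assert [r.read_id for r in index.reads[bins[1]]["healthy"]] == ["b"]

    def test_low_cpg_reads_dropped(self):
        bins = bin_genome({"chr1": 500}, 500)
        index = RegionReadIndex(bins)
        low = MethylRead("r", "chr1", 0, "+", "CACA", "M.U.")  # 2 CpGs
        index.add_reads([low], "healthy")
        assert index.n_dropped_low_cpg == 1 and not index.reads

    def test_read_beyond_chromosome_dropped(self):
        bins = bin_genome({"chr1": 500}, 500)
        index = RegionReadIndex(bins)
        index.add_reads([read_with_ratio(3, 3, start=700)], "healthy")
        assert index.n_dropped_unbinned == 1


class TestFilterRegions:
    def build(self, n_healthy, n_tumor):
        bins = bin_genome({"chr1": 500}, 500)
        index = RegionReadIndex(bins)
        index.add_reads([read_with_ratio(3, 3, rid=f"h{i}") for i in range(n_healthy)],
                        "healthy")
        index.add_reads([read_with_ratio(0, 3, rid=f"t{i}") for i in range(n_tumor)],
                        "tumor")
        return filter_regions(index)

    def test_24_pooled_reads_removed(self):
        assert not self.build(12, 12).reads

    def test_missing_class_removed_despite_depth(self):
        assert not self.build(30, 0).reads

    def test_25_pooled_with_both_classes_kept(self):
        assert len(self.build(13, 12).reads) == 1


class TestDetect:
    def detect(self, healthy_ratios, tumor_ratios, threshold, direction):
        bins = bin_genome({"chr1": 500}, 500)
        index = RegionReadIndex(bins)
        den = 20  # ratios expressed in twentieths for exactness
        index.add_reads(
            [read_with_ratio(int(r * den), den, rid=f"h{i}")
             for i, r in enumerate(healthy_ratios)], "healthy")
        index.add_reads(
            [read_with_ratio(int(r * den), den, rid=f"t{i}")
             for i, r in enumerate(tumor_ratios)], "tumor")
        return detect_switching_regions(index, threshold, direction)

    def test_hypo_emission_with_boundaries(self):
        (sr,) = self.detect([0.9, 0.8, 1.0], [0.2, 0.9], 0.3, "hypo")
        assert sr.boundary_healthy == pytest.approx(0.8)
        assert sr.boundary_tumor == pytest.approx(0.2)
        assert sr.delta == pytest.approx(0.6)

    def test_delta_at_threshold_not_emitted(self):
        assert self.detect([0.5], [0.2], 0.3, "hypo") == []

    def test_hyper_uses_maxima(self):
        (sr,) = self.detect([0.1, 0.2], [0.9, 0.95], 0.5, "hyper")
        assert sr.delta == pytest.approx(0.75)
        assert sr.boundary_healthy == pytest.approx(0.2)


class TestFlagAndExtract:
    def setup_region(self):
        bins = bin_genome({"chr1": 500}, 500)
        index = RegionReadIndex(bins)
        index.add_reads([read_with_ratio(16, 20, rid="h")], "healthy")  # H_min 0.8
        index.add_reads([read_with_ratio(2, 20, rid="t")], "tumor")
        return detect_switching_regions(index, 0.3, "hypo")

    def test_strictly_below_boundary_flags(self):
        regions = self.setup_region()
        below = read_with_ratio(10, 20)   # 0.5 < 0.8
        at = read_with_ratio(16, 20)      # 0.8, strict inequality
        outside = read_with_ratio(10, 20, start=10_000)
        assert flag_switching_reads([below, at, outside], regions) == [
            True, False, False]

    def test_extraction_is_not_flagging(self):
        regions = self.setup_region()
        high = read_with_ratio(19, 20)  # ratio above H_min, still extracted
        out = extract_region_reads([high], regions)
        assert out == [high]

    def test_flagged_subset_of_extracted(self, rng):
        regions = self.setup_region()
        reads = [read_with_ratio(int(rng.integers(0, 21)), 20,
                                 start=int(rng.integers(0, 1000)), rid=f"x{i}")
                 for i in range(50)]
        flags = flag_switching_reads(reads, regions)
        extracted = set(r.key for r in extract_region_reads(reads, regions))
        for read, flag in zip(reads, flags):
            if flag:
                assert read.key in extracted


class TestFsr:
    def build_reads(self, n_switching, n_total):
        # region with H_min = 0.8: reads at ratio 0.5 switch, at 0.9 do not
        reads = [read_with_ratio(10, 20, rid=f"s{i}") for i in range(n_switching)]
        reads += [read_with_ratio(18, 20, rid=f"n{i}")
                  for i in range(n_total - n_switching)]
        return reads

    def region(self):
        bins = bin_genome({"chr1": 500}, 500)
        index = RegionReadIndex(bins)
        index.add_reads([read_with_ratio(16, 20, rid="h")], "healthy")
        index.add_reads([read_with_ratio(2, 20, rid="t")], "tumor")
        return detect_switching_regions(index, 0.3, "hypo")

    @pytest.mark.parametrize("n_sw,n_tot,expected", [(3, 12, 0.25), (0, 12, 0.0),
                                                     (12, 12, 1.0)])
    def test_fraction(self, n_sw, n_tot, expected):
        assert fsr(self.build_reads(n_sw, n_tot), self.region()) == pytest.approx(expected)

    def test_no_region_reads_undefined(self):
        with pytest.raises(ValueError):
            fsr([read_with_ratio(10, 20, start=10_000)], self.region())


# ---------------------------------------------------------------------------
# Brute-force oracle equivalence
# ---------------------------------------------------------------------------

def brute_force_detect(reads_by_class, chrom_sizes, bin_size, min_reads,
                       threshold, direction):
    """Independent re-derivation: enumerate every bin, recompute from scratch."""
    out = []
    for chrom, length in chrom_sizes.items():
        start = 0
        while start < length:
            end = min(start + bin_size, length)
            per_class = {}
            for label, reads in reads_by_class.items():
                per_class[label] = [
                    r for r in reads
                    if r.chrom == chrom and start <= r.start < end
                    and r.meth.count("M") + r.meth.count("U") >= 3
                ]
            total = sum(len(v) for v in per_class.values())
            h, t = per_class.get("healthy", []), per_class.get("tumor", [])
            if total >= min_reads and h and t:
                def ratio(r):
                    m = r.meth.count("M")
                    return m / (m + r.meth.count("U"))
                if direction == "hypo":
                    bh = min(ratio(r) for r in h)
                    bt = min(ratio(r) for r in t)
                    delta = bh - bt
                else:
                    bh = max(ratio(r) for r in h)
                    bt = max(ratio(r) for r in t)
                    delta = bt - bh
                if delta > threshold:
                    out.append((chrom, start, end, bh, bt))
            start = end
    return out


def brute_force_flags(reads, detected, direction):
    flags = []
    for r in reads:
        m, u = r.meth.count("M"), r.meth.count("U")
        flag = False
        if m + u >= 3:
            for chrom, start, end, bh, _ in detected:
                if r.chrom == chrom and start <= r.start < end:
                    ratio = m / (m + u)
                    flag = ratio < bh if direction == "hypo" else ratio > bh
        flags.append(flag)
    return flags


def random_toy_cohort(rng):
    n_bins = int(rng.integers(2, 20))
    bin_size = int(rng.choice([50, 100]))
    chrom_sizes = {"chr1": n_bins * bin_size - int(rng.integers(0, bin_size // 2))}
    reads_by_class = {"healthy": [], "tumor": []}
    n_reads = int(rng.integers(5, 50))
    for i in range(n_reads):
        label = "healthy" if rng.random() < 0.5 else "tumor"
        start = int(rng.integers(0, chrom_sizes["chr1"]))
        k = int(rng.integers(2, 7))  # some reads fail the >= 3 CpG filter
        n_m = int(rng.integers(0, k + 1))
        calls = "M" * n_m + "U" * (k - n_m)
        seq = "CA" * k
        meth = "".join(c + "." for c in calls)
        reads_by_class[label].append(
            MethylRead(f"{label}{i}", "chr1", start, "+", seq, meth))
    return chrom_sizes, reads_by_class, bin_size


@pytest.mark.parametrize("direction", ["hypo", "hyper"])
def test_oracle_equivalence_on_random_cohorts(direction):
    """Module output identical to the brute-force detector on toy cohorts."""
    rng = np.random.default_rng(42 if direction == "hypo" else 43)
    for trial in range(60):
        chrom_sizes, reads_by_class, bin_size = random_toy_cohort(rng)
        min_reads = int(rng.integers(1, 8))
        threshold = float(rng.uniform(0.0, 0.8))
        bins = bin_genome(chrom_sizes, bin_size)
        index = RegionReadIndex(bins)
        for label, reads in reads_by_class.items():
            index.add_reads(reads, label)
        got = detect_switching_regions(
            filter_regions(index, min_reads), threshold, direction)
        expected = brute_force_detect(
            reads_by_class, chrom_sizes, bin_size, min_reads, threshold, direction)
        assert [
            (sr.region.chrom, sr.region.start, sr.region.end,
             sr.boundary_healthy, sr.boundary_tumor)
            for sr in got
        ] == expected
        all_reads = reads_by_class["healthy"] + reads_by_class["tumor"]
        assert flag_switching_reads(all_reads, got) == brute_force_flags(
            all_reads, expected, direction)


def test_threshold_monotonicity(rng):
    """Raising the threshold never yields more regions."""
    chrom_sizes, reads_by_class, bin_size = random_toy_cohort(rng)
    bins = bin_genome(chrom_sizes, bin_size)
    index = RegionReadIndex(bins)
    for label, reads in reads_by_class.items():
        index.add_reads(reads, label)
    index = filter_regions(index, 1)
    counts = [len(detect_switching_regions(index, t, "hypo"))
              for t in np.linspace(0, 0.9, 10)]
    assert counts == sorted(counts, reverse=True)
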