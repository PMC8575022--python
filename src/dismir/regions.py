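"""Switching-region DMR detection from training-cohort reads.

A *switching region* is a fixed-size genomic bin in which the extreme per-read
methylation ratios of the two training classes are separated by more than a
threshold.  For hypomethylated regions the healthy-plasma minimum ratio H_min
and the tumor-tissue minimum T_min are compared: the bin is emitted when
H_min - T_min exceeds the threshold (default 0.3).  Hypermethylated regions
use the maxima with their own threshold (default 0.5).  A *switching read* is
a read inside a switching region whose ratio lies beyond the healthy extremum
(strictly below H_min for hypo, strictly above H_max for hyper).

Only reads with at least three called CpG sites participate; bins whose
pooled qualifying-read count across the whole training cohort is below 25 are
discarded before extrema are compared.
"""

from __future__ import annotations

from bisect import bisect_right
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io import GenomicRegion, MethylRead, cpg_count, methylation_ratio

__all__ = [
    "SwitchingRegion",
    "RegionReadIndex",
    "bin_genome",
    "assign_reads",
    "filter_regions",
    "detect_switching_regions",
    "flag_switching_reads",
    "extract_region_reads",
    "fsr",
    "MIN_CPG_SITES",
]

#: Reads must carry at least this many CpG calls to qualify for any analysis.
MIN_CPG_SITES = 3

HEALTHY = "healthy"
TUMOR = "tumor"


@dataclass(frozen=True)
class SwitchingRegion:
    """A bin passing the extrema-separation criterion.

    ``boundary_healthy`` is H_min (hypo) or H_max (hyper); ``boundary_tumor``
    is T_min or T_max; ``delta`` is H_min - T_min for hypo and T_max - H_max
    for hyper, and is strictly positive for any emitted region.
    """

    region: GenomicRegion
    direction: str
    boundary_healthy: float
    boundary_tumor: float
    delta: float
    n_reads_healthy: int = 0
    n_reads_tumor: int = 0

    def __post_init__(self):
        if self.direction not in ("hypo", "hyper"):
            raise ValueError(f"direction must be hypo/hyper, got {self.direction!r}")
        for name in ("boundary_healthy", "boundary_tumor"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.delta <= 0:
            raise ValueError("emitted switching region must have delta > 0")


class RegionReadIndex:
    """Bin -> per-class lists of qualifying reads.

    Each read with >= 3 CpG calls is assigned to the unique bin containing its
    start coordinate (5'-most aligned base); reads falling outside the binned
    genome or with too few CpGs are dropped and counted.
    """

    def __init__(self, bins: Sequence[GenomicRegion]):
        self.bins = list(bins)
        self._bin_size: dict[str, int] = {}
        self._by_chrom: dict[str, dict[int, GenomicRegion]] = defaultdict(dict)
        for b in self.bins:
            self._by_chrom[b.chrom][b.start] = b
        # bins are uniform tilings anchored at 0; width from the first bin per chrom
        for chrom, d in self._by_chrom.items():
            first = d.get(0) or min(d.values())
            self._bin_size[chrom] = first.end - first.start
        self.reads: dict[GenomicRegion, dict[str, list[MethylRead]]] = defaultdict(
            lambda: defaultdict(list)
        )
        self.n_dropped_low_cpg = 0
        self.n_dropped_unbinned = 0

    def bin_for(self, read: MethylRead) -> GenomicRegion | None:
        d = self._by_chrom.get(read.chrom)
        if d is None:
            return None
        width = self._bin_size[read.chrom]
        return d.get((read.start // width) * width)

    def add_reads(self, reads: Iterable[MethylRead], class_label: str) -> None:
        if class_label not in (HEALTHY, TUMOR):
            raise ValueError(f"class_label must be '{HEALTHY}' or '{TUMOR}'")
        for r in reads:
            if cpg_count(r) < MIN_CPG_SITES:
                self.n_dropped_low_cpg += 1
                continue
            b = self.bin_for(r)
            if b is None:
                self.n_dropped_unbinned += 1
                continue
            self.reads[b][class_label].append(r)

    def pooled_count(self, region: GenomicRegion) -> int:
        per_class = self.reads.get(region, {})
        return sum(len(v) for v in per_class.values())

    def subset(self, regions: Iterable[GenomicRegion]) -> "RegionReadIndex":
        out = RegionReadIndex(self.bins)
        for reg in regions:
            if reg in self.reads:
                for label, rs in self.reads[reg].items():
                    out.reads[reg][label] = list(rs)
        return out


def bin_genome(
    chrom_sizes: dict[str, int], bin_size: int = 500
) -> list[GenomicRegion]:
    """Tile each chromosome into non-overlapping [k*bin, (k+1)*bin) bins.

    The final partial bin is included; zero-length chromosomes are skipped.
    """
    if bin_size <= 0:
        raise ValueError(f"bin_size must be positive, got {bin_size}")
    bins: list[GenomicRegion] = []
    for chrom, length in chrom_sizes.items():
        if length <= 0:
            continue
        for start in range(0, length, bin_size):
            bins.append(GenomicRegion(chrom, start, min(start + bin_size, length)))
    return bins


def assign_reads(
    labeled_reads: Iterable[tuple[MethylRead, str]],
    bins: Sequence[GenomicRegion],
) -> RegionReadIndex:
    """Build a RegionReadIndex from (read, class_label) pairs."""
    index = RegionReadIndex(bins)
    grouped: dict[str, list[MethylRead]] = defaultdict(list)
    for read, label in labeled_reads:
        grouped[label].append(read)
    for label, reads in grouped.items():
        index.add_reads(reads, label)
    return index


def filter_regions(index: RegionReadIndex, min_reads: int = 25) -> RegionReadIndex:
    """Drop bins with < min_reads pooled qualifying reads or an empty class.

    The pooled count is taken across all training samples of both classes;
    at least one read per class is additionally required so that both
    extrema exist.
    """
    keep = [
        reg
        for reg in index.reads
        if index.pooled_count(reg) >= min_reads
        and len(index.reads[reg].get(HEALTHY, [])) >= 1
        and len(index.reads[reg].get(TUMOR, [])) >= 1
    ]
    return index.subset(keep)


def _extremum(ratios: Sequence[float], direction: str, quantile: float | None) -> float:
    arr = np.asarray(ratios, dtype=float)
    if quantile is None:
        return float(arr.min() if direction == "hypo" else arr.max())
    q = quantile if direction == "hypo" else 1.0 - quantile
    return float(np.quantile(arr, q))


def detect_switching_regions(
    index: RegionReadIndex,
    threshold: float = 0.3,
    direction: str = "hypo",
    quantile: float | None = None,
) -> list[SwitchingRegion]:
    """Emit bins whose class extrema are separated by more than ``threshold``.

    hypo: H_min - T_min > threshold; hyper: T_max - H_max > threshold
    (strict inequalities).  ``quantile`` optionally replaces the true
    min/max with a robust quantile (e.g. 0.05) for noise experiments;
    the default is the exact extremum.
    """
    if direction not in ("hypo", "hyper"):
        raise ValueError(f"direction must be hypo/hyper, got {direction!r}")
    out: list[SwitchingRegion] = []
    for reg in sorted(index.reads, key=lambda r: (r.chrom, r.start)):
        per_class = index.reads[reg]
        h_reads = per_class.get(HEALTHY, [])
        t_reads = per_class.get(TUMOR, [])
        if not h_reads or not t_reads:
            continue
        h_ext = _extremum([methylation_ratio(r) for r in h_reads], direction, quantile)
        t_ext = _extremum([methylation_ratio(r) for r in t_reads], direction, quantile)
        delta = (h_ext - t_ext) if direction == "hypo" else (t_ext - h_ext)
        if delta > threshold:
            out.append(
                SwitchingRegion(
                    region=reg,
                    direction=direction,
                    boundary_healthy=h_ext,
                    boundary_tumor=t_ext,
                    delta=delta,
                    n_reads_healthy=len(h_reads),
                    n_reads_tumor=len(t_reads),
                )
            )
    return out


def _region_lookup(regions: Iterable[SwitchingRegion]):
    """chrom -> (sorted starts, parallel SwitchingRegion list) for bisect."""
    per_chrom: dict[str, list[SwitchingRegion]] = defaultdict(list)
    for sr in regions:
        per_chrom[sr.region.chrom].append(sr)
    lut = {}
    for chrom, srs in per_chrom.items():
        srs.sort(key=lambda s: s.region.start)
        lut[chrom] = ([s.region.start for s in srs], srs)
    return lut


def _region_of(read: MethylRead, lut) -> SwitchingRegion | None:
    entry = lut.get(read.chrom)
    if entry is None:
        return None
    starts, srs = entry
    i = bisect_right(starts, read.start) - 1
    if i >= 0 and srs[i].region.contains(read.chrom, read.start):
        return srs[i]
    return None


def flag_switching_reads(
    sample_reads: Sequence[MethylRead], regions: Sequence[SwitchingRegion]
) -> list[bool]:
    """Per-read flag: qualifying read in a switching region beyond H extremum.

    hypo: ratio strictly below boundary_healthy; hyper: strictly above.
    Reads outside any switching region, or with < 3 CpGs, are not flagged.
    """
    lut = _region_lookup(regions)
    flags = []
    for r in sample_reads:
        if cpg_count(r) < MIN_CPG_SITES:
            flags.append(False)
            continue
        sr = _region_of(r, lut)
        if sr is None:
            flags.append(False)
            continue
        ratio = methylation_ratio(r)
        if sr.direction == "hypo":
            flags.append(ratio < sr.boundary_healthy)
        else:
            flags.append(ratio > sr.boundary_healthy)
    return flags


def extract_region_reads(
    sample_reads: Sequence[MethylRead], regions: Sequence[SwitchingRegion]
) -> list[MethylRead]:
    """All qualifying reads located in switching regions (not only flagged ones).

    This is the model's input set: every read with >= 3 CpG calls whose start
    falls in a switching region, whatever its methylation ratio.
    """
    lut = _region_lookup(regions)
    return [
        r
        for r in sample_reads
        if cpg_count(r) >= MIN_CPG_SITES and _region_of(r, lut) is not None
    ]


def fsr(
    sample_reads: Sequence[MethylRead], regions: Sequence[SwitchingRegion]
) -> float:
    """Fraction of switching reads among qualifying reads in switching regions.

    Model-free baseline statistic for cohort classification.
    """
    region_reads = extract_region_reads(sample_reads, regions)
    if not region_reads:
        raise ValueError("no qualifying reads in switching regions (FSR undefined)")
    flags = flag_switching_reads(region_reads, regions)
    return sum(flags) / len(flags)
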