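"""Synthetic bisulfite-read cohorts with known ground truth.

The generator emulates the statistical structure the detection method relies
on, with every latent quantity recorded as truth:

* a random reference genome with CpG dinucleotides planted at a controlled
  density, tiled into fixed-size bins of which a designated subset is
  *switching* (tumor-hypomethylated);
* class-dependent per-read methylation: each read draws a methylation level
  from a Beta distribution — healthy reads (and tumor reads outside
  switching bins) from a high-mean Beta, tumor reads inside switching bins
  from a low-mean Beta — and then methylates each of its CpG sites
  independently at that level.  Drawing the level once per read reproduces
  the read-level bimodality that extrema-based region detection exploits;
* per-site flip noise modelling bisulfite miscalls;
* plasma mixtures: each read of a test sample is tumor-origin with
  probability ``true_r``;
* an optional planted sequence motif, written into switching bins of the
  reference and/or into reads of one class, so sequence-driven signal is
  available for kernel-recovery experiments.

Sequence background is i.i.d. uniform over ACGT with accidental CG
dinucleotides broken, so CpG sites are exactly the planted ones (plus any
introduced by a planted motif).  Reads are single-end, fixed-length and
forward-strand by default; a fraction can be emitted as reverse-complement
reads with CpG-dyad methylation transfer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .encoding import reverse_complement_read
from .io import (
    GenomicRegion,
    MethylRead,
    SampleMetadata,
    write_chrom_sizes,
    write_manifest,
    write_reads_tsv,
)
from .regions import bin_genome

__all__ = [
    "BetaParams",
    "PlantedMotif",
    "SimConfig",
    "Reference",
    "simulate_reference",
    "simulate_sample",
    "simulate_cohort",
    "CohortSample",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class BetaParams:
    """Beta(a, b) parameters for per-read methylation levels."""

    a: float
    b: float

    @property
    def mean(self) -> float:
        return self.a / (self.a + self.b)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.beta(self.a, self.b, size=n)


@dataclass(frozen=True)
class PlantedMotif:
    """A sequence motif enriched in one read class and/or the reference.

    ``read_insert_prob``: probability a read of ``enrich_class`` carries the
    motif (written at a random offset).  ``ref_insert_prob``: probability the
    motif is written into each switching bin of the reference.
    """

    sequence: str
    enrich_class: str = "tumor"
    read_insert_prob: float = 0.5
    ref_insert_prob: float = 0.0


@dataclass(frozen=True)
class SimConfig:
    """Study-condition defaults for the synthetic cohorts.

    330 bins of 500 bp (30 switching, 300 background); CpG-island-like
    density of ~1 CpG per 8 bp, as in the CpG-rich regions where cancer
    hypomethylation is called; 80-bp reads; healthy methylation level
    ~ Beta(85, 15) (mean 0.85, tight — the leukocyte background of plasma
    is homogeneous at these loci), tumor level inside switching bins
    ~ Beta(15, 85) (mean 0.15); 5% per-site flip noise; 10^4 reads per
    sample.
    """

    n_chroms: int = 1
    chrom_length: int = 165_000
    bin_size: int = 500
    n_bins_switching: int = 30
    cpg_density: float = 0.12
    read_length: int = 80
    healthy_meth: BetaParams = BetaParams(85.0, 15.0)
    tumor_meth_switching: BetaParams = BetaParams(15.0, 85.0)
    tumor_meth_background: BetaParams | None = None  # None -> healthy_meth
    per_site_flip_noise: float = 0.05
    planted_motif: PlantedMotif | None = None
    reads_per_sample: int = 10_000
    reverse_strand_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.per_site_flip_noise < 0.5):
            raise ValueError("per_site_flip_noise must be in [0, 0.5)")
        if not (0.0 < self.cpg_density <= 0.4):
            raise ValueError("cpg_density out of plausible range (0, 0.4]")
        if self.read_length <= 0 or self.chrom_length < self.read_length:
            raise ValueError("chrom_length must exceed read_length > 0")

    @property
    def background_meth(self) -> BetaParams:
        return self.tumor_meth_background or self.healthy_meth


@dataclass
class Reference:
    """Simulated genome: sequences, bin tiling and per-bin switching truth."""

    sequences: dict[str, str]
    bins: list[GenomicRegion]
    switching_bins: set[tuple[str, int]]
    bin_size: int

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def bin_truth(self) -> pd.DataFrame:
        rows = [
            {"chrom": b.chrom, "start": b.start, "end": b.end,
             "is_switching": (b.chrom, b.start) in self.switching_bins}
            for b in self.bins
        ]
        return pd.DataFrame(rows)


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    seq = rng.choice(4, size=length)
    # break accidental CG dinucleotides (C=1, G=2): G -> T; cannot create new CG
    acc = np.flatnonzero((seq[:-1] == 1) & (seq[1:] == 2))
    seq[acc + 1] = 3
    return seq


def simulate_reference(cfg: SimConfig,
                       rng: np.random.Generator | None = None) -> Reference:
    """Generate the reference genome, CpG placement and switching-bin truth."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    sequences: dict[str, str] = {}
    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1}"
        seq = _random_sequence(rng, cfg.chrom_length)
        n_sites = rng.binomial(cfg.chrom_length, cfg.cpg_density)
        if n_sites > cfg.chrom_length // 3:
            raise ValueError("cpg_density too high to place non-adjacent CpGs")
        pos = np.sort(rng.choice(cfg.chrom_length - 1, size=n_sites, replace=False))
        keep = []
        prev = -2
        for p in pos:  # enforce >= 2 bp spacing so sites never overlap
            if p >= prev + 2:
                keep.append(p)
                prev = p
        kp = np.array(keep, dtype=int)
        seq[kp] = 1      # C
        seq[kp + 1] = 2  # G
        sequences[chrom] = "".join(_BASES[seq])
    bins = bin_genome({c: len(s) for c, s in sequences.items()}, cfg.bin_size)
    n_sw = min(cfg.n_bins_switching, len(bins))
    chosen = rng.choice(len(bins), size=n_sw, replace=False)
    switching = {(bins[i].chrom, bins[i].start) for i in chosen}
    motif = cfg.planted_motif
    if motif is not None and motif.ref_insert_prob > 0:
        for b in bins:
            if (b.chrom, b.start) not in switching:
                continue
            if rng.random() >= motif.ref_insert_prob:
                continue
            width = b.end - b.start
            if width < len(motif.sequence):
                continue
            off = b.start + rng.integers(0, width - len(motif.sequence) + 1)
            s = sequences[b.chrom]
            sequences[b.chrom] = s[:off] + motif.sequence + s[off + len(motif.sequence):]
    return Reference(sequences=sequences, bins=bins, switching_bins=switching,
                     bin_size=cfg.bin_size)


def _methylate(seq: str, level: float, flip: float,
               rng: np.random.Generator) -> str:
    meth = ["."] * len(seq)
    for i in range(len(seq) - 1):
        if seq[i] == "C" and seq[i + 1] == "G":
            m = rng.random() < level
            if rng.random() < flip:
                m = not m
            meth[i] = "M" if m else "U"
    return "".join(meth)


def simulate_sample(
    cfg: SimConfig,
    reference: Reference,
    class_label: str,
    true_r: float,
    rng: np.random.Generator,
    sample_id: str = "sample",
    n_reads: int | None = None,
) -> tuple[list[MethylRead], pd.DataFrame]:
    """Draw one sample's reads and per-read truth.

    ``class_label`` follows the manifest vocabulary: ``tumor_tissue`` forces
    true_r = 1, ``healthy_plasma`` forces 0, ``test_plasma`` mixes at
    ``true_r``.
    """
    if class_label == "tumor_tissue":
        true_r = 1.0
    elif class_label == "healthy_plasma":
        true_r = 0.0
    elif class_label != "test_plasma":
        raise ValueError(f"unknown class_label {class_label!r}")
    if not 0.0 <= true_r <= 1.0:
        raise ValueError("true_r must be in [0, 1]")
    n = cfg.reads_per_sample if n_reads is None else n_reads
    chroms = list(reference.sequences)
    lengths = np.array([len(reference.sequences[c]) for c in chroms], dtype=float)
    weights = lengths / lengths.sum()
    motif = cfg.planted_motif
    reads: list[MethylRead] = []
    truth_rows = []
    for i in range(n):
        ci = int(rng.choice(len(chroms), p=weights))
        chrom = chroms[ci]
        refseq = reference.sequences[chrom]
        start = int(rng.integers(0, len(refseq) - cfg.read_length + 1))
        seq = refseq[start:start + cfg.read_length]
        origin = "tumor" if rng.random() < true_r else "healthy"
        if (motif is not None and motif.read_insert_prob > 0
                and origin == motif.enrich_class
                and rng.random() < motif.read_insert_prob
                and cfg.read_length >= len(motif.sequence)):
            off = int(rng.integers(0, cfg.read_length - len(motif.sequence) + 1))
            seq = seq[:off] + motif.sequence + seq[off + len(motif.sequence):]
        bin_start = (start // cfg.bin_size) * cfg.bin_size
        in_switching = (chrom, bin_start) in reference.switching_bins
        if origin == "tumor" and in_switching:
            dist = cfg.tumor_meth_switching
        elif origin == "tumor":
            dist = cfg.background_meth
        else:
            dist = cfg.healthy_meth
        level = float(dist.sample(rng, 1)[0])
        meth = _methylate(seq, level, cfg.per_site_flip_noise, rng)
        read = MethylRead(
            read_id=f"{sample_id}_r{i:06d}", chrom=chrom, start=start,
            strand="+", seq=seq, meth=meth,
        )
        if cfg.reverse_strand_fraction > 0 and rng.random() < cfg.reverse_strand_fraction:
            read = reverse_complement_read(read)
        reads.append(read)
        truth_rows.append({
            "read_id": read.read_id, "chrom": chrom, "start": read.start,
            "origin": origin, "bin_start": bin_start,
            "in_switching": in_switching, "meth_level": level,
        })
    truth = pd.DataFrame(truth_rows)
    truth.attrs["sample_id"] = sample_id
    truth.attrs["true_r"] = true_r
    return reads, truth


@dataclass
class CohortSample:
    meta: SampleMetadata
    true_r: float
    reads: list[MethylRead]
    truth: pd.DataFrame


def simulate_cohort(
    cfg: SimConfig,
    design: Sequence[tuple[str, float, int]],
    out_dir: str | Path | None = None,
    seed: int | None = None,
    reference: Reference | None = None,
) -> tuple[Reference, list[CohortSample]]:
    """Simulate a cohort from a design of (class_label, true_r, n_reads) rows.

    Fully reproducible from ``seed`` (defaults to ``cfg.seed``).  When
    ``out_dir`` is given, the reference FASTA, chrom.sizes, one reads TSV per
    sample, per-read truth TSVs and the manifest are written there.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    if reference is None:
        reference = simulate_reference(cfg, rng)
    samples: list[CohortSample] = []
    counters: dict[str, int] = {}
    for class_label, true_r, n_reads in design:
        counters[class_label] = counters.get(class_label, 0) + 1
        sample_id = f"{class_label}_{counters[class_label]:03d}"
        reads, truth = simulate_sample(
            cfg, reference, class_label, true_r, rng,
            sample_id=sample_id, n_reads=n_reads,
        )
        file_path = f"{sample_id}.reads.tsv"
        meta = SampleMetadata(sample_id, class_label, file_path)
        samples.append(CohortSample(meta=meta, true_r=truth.attrs["true_r"],
                                    reads=reads, truth=truth))
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "reference.fasta", "w") as fh:
            for chrom, seq in reference.sequences.items():
                fh.write(f">{chrom}\n")
                for lo in range(0, len(seq), 80):
                    fh.write(seq[lo:lo + 80] + "\n")
        write_chrom_sizes(reference.chrom_sizes, out / "chrom.sizes")
        reference.bin_truth().to_csv(out / "bin_truth.tsv", sep="\t", index=False)
        for s in samples:
            write_reads_tsv(s.reads, out / s.meta.file_path)
            s.truth.to_csv(out / f"{s.meta.sample_id}.truth.tsv", sep="\t",
                           index=False)
        write_manifest([s.meta for s in samples], out / "manifest.tsv")
    return reference, samples
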