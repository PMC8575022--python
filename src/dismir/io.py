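"""On-disk formats for bisulfite reads, regions, d-scores and chromosome sizes.

A bisulfite read carries, next to its aligned sequence, a per-base methylation
call string over the alphabet ``{M, U, .}``: ``M`` marks a methylated CpG
cytosine, ``U`` an unmethylated CpG cytosine, and ``.`` any other base.  Two
read dialects are supported:

* a 6-column TSV (``read_id  chrom  start  strand  seq  meth``) used by the
  simulator and convenient for fixtures, and
* SAM/BAM with a per-read string tag holding the aligner's methylation calls
  (Bismark-style ``Z``/``z`` by default), remapped to ``{M, U, .}`` on ingest.

Coordinates are 0-based half-open everywhere (SAM POS is converted on ingest).
Reads are kept in aligner-reported orientation and are never re-expressed on
the reference forward strand: raw and reverse-complement reads are distinct
model inputs downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
import pysam

__all__ = [
    "MethylRead",
    "SampleMetadata",
    "GenomicRegion",
    "ReadParseError",
    "BISMARK_METH_MAP",
    "parse_reads_tsv",
    "write_reads_tsv",
    "parse_reads_sam",
    "write_reads_sam",
    "cpg_count",
    "methylation_ratio",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "write_regions_bed",
    "read_regions_bed",
    "write_dscores",
    "read_dscores",
    "read_manifest",
    "write_manifest",
]

_VALID_SEQ = re.compile(r"^[ACGTN]+$")
_VALID_METH = re.compile(r"^[MU.]+$")

#: Default mapping from Bismark-style per-base methylation calls to {M, U, .}.
#: ``Z``/``z`` are CpG-context calls; all other contexts (CHG/CHH/unknown)
#: collapse to '.' because only CpG methylation is modelled.
BISMARK_METH_MAP = {"Z": "M", "z": "U"}

CLASS_LABELS = ("healthy_plasma", "tumor_tissue", "test_plasma")


class ReadParseError(ValueError):
    """Malformed read record; carries the offending line number when known."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


@dataclass(frozen=True)
class MethylRead:
    """One aligned bisulfite read with per-base CpG methylation calls.

    ``meth`` has the same length as ``seq``; every ``M``/``U`` sits on a
    position where ``seq`` is ``C`` (read-orientation representation of the
    CpG cytosine).  ``start`` is the 0-based leftmost aligned position.
    """

    read_id: str
    chrom: str
    start: int
    strand: str
    seq: str
    meth: str

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not _VALID_SEQ.match(self.seq):
            raise ValueError(f"invalid sequence characters in {self.seq!r}")
        if not _VALID_METH.match(self.meth):
            raise ValueError(f"invalid methylation characters in {self.meth!r}")
        if len(self.meth) != len(self.seq):
            raise ValueError(
                f"meth length {len(self.meth)} != seq length {len(self.seq)}"
            )
        for i, m in enumerate(self.meth):
            if m in "MU" and self.seq[i] != "C":
                raise ValueError(
                    f"methylation call {m!r} at position {i} sits on "
                    f"{self.seq[i]!r}, not 'C'"
                )

    @property
    def end(self) -> int:
        return self.start + len(self.seq)

    @property
    def key(self) -> tuple[str, str, int]:
        """Identity for joins: duplicate read_ids are legal in aligner output."""
        return (self.read_id, self.chrom, self.start)


@dataclass(frozen=True)
class SampleMetadata:
    """Cohort manifest entry mapping a sample to its class and read file."""

    sample_id: str
    class_label: str
    file_path: str

    def __post_init__(self):
        if self.class_label not in CLASS_LABELS:
            raise ValueError(
                f"class_label must be one of {CLASS_LABELS}, got {self.class_label!r}"
            )


@dataclass(frozen=True, order=True)
class GenomicRegion:
    """Half-open genomic interval [start, end) in BED convention."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must be > start ({self.start})")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


def cpg_count(read: MethylRead) -> int:
    """Number of CpG sites called on the read (M or U entries)."""
    return read.meth.count("M") + read.meth.count("U")


def methylation_ratio(read: MethylRead) -> float:
    """Fraction of the read's CpG sites that are methylated, #M / (#M + #U)."""
    n_m = read.meth.count("M")
    n_u = read.meth.count("U")
    if n_m + n_u == 0:
        raise ValueError(f"read {read.read_id} has no CpG calls")
    return n_m / (n_m + n_u)


# ---------------------------------------------------------------------------
# TSV read dialect
# ---------------------------------------------------------------------------

def parse_reads_tsv(path: str | Path) -> Iterator[MethylRead]:
    """Yield validated reads from the 6-column TSV dialect.

    Columns: read_id, chrom, start, strand, seq, meth.  Lines starting with
    '#' are headers/comments.  Malformed records raise :class:`ReadParseError`
    with the 1-based line number.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ReadParseError(
                    f"expected 6 tab-separated columns, got {len(fields)}", lineno
                )
            read_id, chrom, start_s, strand, seq, meth = fields
            try:
                start = int(start_s)
            except ValueError:
                raise ReadParseError(f"malformed start {start_s!r}", lineno) from None
            try:
                yield MethylRead(read_id, chrom, start, strand, seq, meth)
            except ValueError as exc:
                raise ReadParseError(str(exc), lineno) from None


def write_reads_tsv(reads: Iterable[MethylRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#read_id\tchrom\tstart\tstrand\tseq\tmeth\n")
        for r in reads:
            fh.write(f"{r.read_id}\t{r.chrom}\t{r.start}\t{r.strand}\t{r.seq}\t{r.meth}\n")


# ---------------------------------------------------------------------------
# SAM/BAM read dialect
# ---------------------------------------------------------------------------

def parse_reads_sam(
    path: str | Path,
    meth_tag: str = "XM",
    meth_map: dict[str, str] | None = None,
    stats: dict | None = None,
) -> Iterator[MethylRead]:
    """Yield reads from SAM/BAM with a per-read methylation call tag.

    The tag value maps 1:1 to read bases; ``meth_map`` converts the aligner's
    alphabet to {M, U} (Bismark default: Z -> M, z -> U), anything unmapped
    becomes '.'.  Unmapped reads are skipped; reads missing the tag are
    skipped and counted in ``stats['missing_tag']`` when a dict is supplied.
    """
    if meth_map is None:
        meth_map = BISMARK_METH_MAP
    counters = stats if stats is not None else {}
    counters.setdefault("missing_tag", 0)
    counters.setdefault("unmapped", 0)
    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                counters["unmapped"] += 1
                continue
            if not aln.has_tag(meth_tag):
                counters["missing_tag"] += 1
                continue
            raw = aln.get_tag(meth_tag)
            seq = aln.query_sequence
            meth = "".join(meth_map.get(c, ".") for c in raw)
            strand = "-" if aln.is_reverse else "+"
            yield MethylRead(
                read_id=aln.query_name,
                chrom=aln.reference_name,
                start=aln.reference_start,
                strand=strand,
                seq=seq,
                meth=meth,
            )


def write_reads_sam(
    reads: Iterable[MethylRead],
    chrom_sizes: dict[str, int],
    path: str | Path,
    meth_tag: str = "XM",
) -> None:
    """Write reads as text SAM with Bismark-style calls in ``meth_tag``.

    Inverse of :func:`parse_reads_sam` under the default mapping; used to
    produce paired fixtures for the two dialects.
    """
    inverse = {"M": "Z", "U": "z", ".": "."}
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": int(n)} for c, n in chrom_sizes.items()],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for r in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.read_id
            a.query_sequence = r.seq
            a.flag = 16 if r.strand == "-" else 0
            a.reference_name = r.chrom
            a.reference_start = r.start
            a.mapping_quality = 60
            a.cigarstring = f"{len(r.seq)}M"
            a.set_tag(meth_tag, "".join(inverse[c] for c in r.meth))
            out.write(a)


# ---------------------------------------------------------------------------
# Chromosome sizes, BED regions, d-score tables, manifests
# ---------------------------------------------------------------------------

def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a UCSC chrom.sizes file (chrom <tab> length)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"],
                     dtype={"chrom": str, "length": int}, comment="#")
    return dict(zip(df["chrom"], df["length"]))


def write_chrom_sizes(sizes: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")


def write_regions_bed(regions, path: str | Path) -> None:
    """Write switching regions as BED6+3.

    Columns: chrom, start, end, name, score = round(1000*|delta|), strand '.',
    direction, boundary_healthy, boundary_tumor (boundaries to 6 decimals).
    """
    lines = []
    for i, sr in enumerate(regions, start=1):
        reg = sr.region
        if reg.end <= reg.start:  # defensive; GenomicRegion enforces this too
            raise ValueError(f"region {reg} has end <= start")
        score = round(1000 * abs(sr.delta))
        lines.append(
            f"{reg.chrom}\t{reg.start}\t{reg.end}\tSR{i}\t{score}\t.\t"
            f"{sr.direction}\t{sr.boundary_healthy:.6f}\t{sr.boundary_tumor:.6f}"
        )
    with open(path, "w") as fh:
        for line in lines:
            fh.write(line + "\n")


def read_regions_bed(path: str | Path):
    """Re-parse a BED6+3 switching-region file (round-trips write_regions_bed)."""
    from .regions import SwitchingRegion  # deferred: regions builds on io

    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 9:
                raise ReadParseError("expected 9 BED6+3 columns", lineno)
            chrom, start, end = f[0], int(f[1]), int(f[2])
            direction = f[6]
            bh, bt = float(f[7]), float(f[8])
            delta = (bh - bt) if direction == "hypo" else (bt - bh)
            out.append(
                SwitchingRegion(
                    region=GenomicRegion(chrom, start, end),
                    direction=direction,
                    boundary_healthy=bh,
                    boundary_tumor=bt,
                    delta=delta,
                )
            )
    return out


def write_dscores(table: pd.DataFrame, path: str | Path) -> None:
    """Write a d-score table (read_id, region, dscore) as TSV, 6 decimals."""
    required = ["read_id", "region", "dscore"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"d-score table missing columns {missing}")
    bad = table[(table["dscore"] < 0) | (table["dscore"] > 1)]
    if len(bad):
        raise ValueError("d-scores must lie in [0, 1]")
    out = table[required].copy()
    out["dscore"] = out["dscore"].map(lambda v: f"{v:.6f}")
    out.to_csv(path, sep="\t", index=False)


def read_dscores(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str, "region": str})
    if list(df.columns) != ["read_id", "region", "dscore"]:
        raise ReadParseError(f"unexpected d-score columns {list(df.columns)}")
    vals = pd.to_numeric(df["dscore"], errors="coerce")
    bad = df.index[vals.isna() | (vals < 0) | (vals > 1)]
    if len(bad):
        # +2: 1-based, plus header line
        raise ReadParseError("d-score outside [0,1] or non-numeric",
                             int(bad[0]) + 2)
    df["dscore"] = vals
    return df


def read_manifest(path: str | Path) -> list[SampleMetadata]:
    """Read a cohort manifest TSV (sample_id, class_label, file_path)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    entries = [
        SampleMetadata(row.sample_id, row.class_label, row.file_path)
        for row in df.itertuples()
    ]
    ids = [e.sample_id for e in entries]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id in manifest")
    return entries


def write_manifest(entries: Iterable[SampleMetadata], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tclass_label\tfile_path\n")
        for e in entries:
            fh.write(f"{e.sample_id}\t{e.class_label}\t{e.file_path}\n")
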