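"""Fixed-size numeric encoding of bisulfite reads for the read classifier.

Each read is trimmed (5 bp off the 5' end against adapter contamination, then
cut at the 3' end to a common length L = 66) and encoded as an L x 5 matrix:
four one-hot base columns (A, C, G, T; N rows are all-zero) plus a methylation
column that is 1 exactly where the read carries a methylated CpG cytosine.
Unmethylated CpG cytosines and non-CpG bases are both 0 in that column — the
base columns already distinguish C from non-C.

Trimming is in read orientation (as sequenced), not reference orientation.
Reads shorter than trim5 + L are rejected rather than padded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io import MethylRead

__all__ = [
    "EncoderConfig",
    "EncodedRead",
    "trim_read",
    "encode",
    "encode_batch",
    "reverse_complement_read",
    "balance_and_split",
    "BASE_COLUMNS",
]

BASE_COLUMNS = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASE_COLUMNS)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class EncoderConfig:
    """Trim/length parameters; defaults are 5 bp 5'-trim and L = 66."""

    trim5: int = 5
    length: int = 66

    def __post_init__(self):
        if self.trim5 < 0:
            raise ValueError("trim5 must be >= 0")
        if self.length <= 0:
            raise ValueError("length must be positive")


@dataclass(frozen=True)
class EncodedRead:
    """L x 5 matrix (A, C, G, T, methylation) with optional class label."""

    matrix: np.ndarray
    label: int | None = None
    read_ref: tuple | None = None

    def __post_init__(self):
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 5:
            raise ValueError(f"matrix must be Lx5, got {self.matrix.shape}")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError("label must be 0 (healthy plasma) or 1 (tumor tissue)")


def trim_read(read: MethylRead, cfg: EncoderConfig = EncoderConfig()) -> MethylRead | None:
    """Drop the first trim5 bases, keep the next L; None if the read is shorter."""
    lo, hi = cfg.trim5, cfg.trim5 + cfg.length
    if len(read.seq) < hi:
        return None
    # seq index 0 is the 5' end in read orientation; for '-' reads that is the
    # reference right edge, so the leftmost reference coordinate moves by the
    # amount cut off the 3' end instead of the 5' trim.
    if read.strand == "+":
        new_start = read.start + lo
    else:
        new_start = read.start + (len(read.seq) - hi)
    return MethylRead(
        read_id=read.read_id,
        chrom=read.chrom,
        start=new_start,
        strand=read.strand,
        seq=read.seq[lo:hi],
        meth=read.meth[lo:hi],
    )


def encode(read: MethylRead, cfg: EncoderConfig = EncoderConfig()) -> EncodedRead:
    """Encode an already-trimmed read of length L as an L x 5 matrix."""
    if len(read.seq) != cfg.length:
        raise ValueError(
            f"read length {len(read.seq)} != configured L={cfg.length}; trim first"
        )
    mat = np.zeros((cfg.length, 5), dtype=np.float32)
    for i, (base, call) in enumerate(zip(read.seq, read.meth)):
        j = _BASE_INDEX.get(base)
        if j is not None:  # N stays all-zero
            mat[i, j] = 1.0
        if call == "M":
            mat[i, 4] = 1.0
    return EncodedRead(matrix=mat, read_ref=read.key)


def encode_batch(
    reads: Iterable[MethylRead],
    cfg: EncoderConfig = EncoderConfig(),
    label: int | None = None,
) -> list[EncodedRead]:
    out = []
    for r in reads:
        enc = encode(r, cfg)
        out.append(EncodedRead(matrix=enc.matrix, label=label, read_ref=enc.read_ref))
    return out


def stack_matrices(encoded: Sequence[EncodedRead]) -> np.ndarray:
    """(N, L, 5) array from a list of encoded reads."""
    return np.stack([e.matrix for e in encoded]).astype(np.float32)


def stack_labels(encoded: Sequence[EncodedRead]) -> np.ndarray:
    labels = [e.label for e in encoded]
    if any(l is None for l in labels):
        raise ValueError("all encoded reads must be labeled")
    return np.asarray(labels, dtype=np.float32)


def reverse_complement_read(read: MethylRead) -> MethylRead:
    """Reverse-complement a read, transferring CpG-dyad methylation states.

    For every CpG dinucleotide on the read, the M/U state of its cytosine is
    carried to the cytosine of the complementary-strand CpG (which, after
    reverse-complementing, is again a 'C' followed by 'G').  All other
    positions become '.'.  The operation is an involution.
    """
    n = len(read.seq)
    rc_seq = read.seq.translate(_COMPLEMENT)[::-1]
    rc_meth = ["."] * n
    for i in range(n - 1):
        if read.seq[i] == "C" and read.seq[i + 1] == "G" and read.meth[i] in "MU":
            # the complementary strand's CpG cytosine pairs with our G at i+1
            rc_meth[n - 2 - i] = read.meth[i]
    return MethylRead(
        read_id=read.read_id + "_RC",
        chrom=read.chrom,
        start=read.start,
        strand="-" if read.strand == "+" else "+",
        seq=rc_seq,
        meth="".join(rc_meth),
    )


def balance_and_split(
    encoded: Sequence[EncodedRead],
    seed: int | np.random.Generator,
    reserve_fraction: float = 0.2,
) -> tuple[list[EncodedRead], list[EncodedRead]]:
    """Class-balance by downsampling, then reserve a random 20% holdout.

    The majority class is subsampled uniformly at random down to the minority
    count; a ``reserve_fraction`` of the balanced pool is then held out (for
    kernel visualization) and excluded from training.  Reproducible from the
    seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    by_class: dict[int, list[EncodedRead]] = {0: [], 1: []}
    for e in encoded:
        if e.label is None:
            raise ValueError("balance_and_split requires labeled reads")
        by_class[e.label].append(e)
    n0, n1 = len(by_class[0]), len(by_class[1])
    if n0 == 0 or n1 == 0:
        raise ValueError(f"both classes must be present (got {n0} vs {n1} reads)")
    n_keep = min(n0, n1)
    pool: list[EncodedRead] = []
    for label in (0, 1):
        cls = by_class[label]
        if len(cls) > n_keep:
            idx = rng.choice(len(cls), size=n_keep, replace=False)
            cls = [cls[i] for i in sorted(idx)]
        pool.extend(cls)
    perm = rng.permutation(len(pool))
    n_reserved = int(round(reserve_fraction * len(pool)))
    reserved = [pool[i] for i in perm[:n_reserved]]
    train = [pool[i] for i in perm[n_reserved:]]
    return train, reserved
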