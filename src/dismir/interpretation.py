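"""Model introspection: kernel PFMs, methylation-perturbation deltas, effect sizes.

Three complementary views of what the trained read classifier learned:

* **Kernel PFMs** — each first-convolution kernel is slid over a reserved
  read set at every valid offset; the top 1% of activation values select
  windows that are superposed, weighted by activation, into a position
  frequency matrix.  A 4-letter PFM (A, C, G, T) serves motif comparison
  (MEME export); a 5-letter variant splits C into methylated ('M') and
  unmethylated C to show joint sequence+methylation preferences.

* **Δ d-scores** — within a region, every length-L window with >= 3 CpGs is
  scored with all CpGs methylated (baseline), then re-scored after
  demethylating one CpG at a time (Δ_single), or all at once (Δ_all);
  Δ_sum = Σ Δ_single.  Sign convention: Δ = d(perturbed) − d(baseline).
  |Δ_all| exceeding |Δ_sum| indicates super-additive attention to global
  methylation change — robustness against single-site technical noise.

* **Effect sizes** — distribution shifts are quantified with the rank AUC
  derived from the Mann–Whitney U test; p-values across repeated trainings
  combine via Fisher's method; quadrant membership vs motif annotation is
  summarized with an odds ratio and Fisher's exact test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .encoding import BASE_COLUMNS, EncodedRead
from .io import GenomicRegion
from .model import DScoreModel

__all__ = [
    "PFM",
    "DeltaWindow",
    "DeltaScores",
    "conv1_kernels",
    "kernel_pfm",
    "pfm_probabilities",
    "write_meme",
    "delta_scores",
    "kernel_activated_reads",
    "mwu_effect_size",
    "fisher_combine",
    "quadrant_summary",
    "motif_match_correlation",
]


@dataclass(frozen=True)
class PFM:
    """Activation-weighted position frequency matrix of one conv kernel.

    ``counts4`` columns are A, C, G, T; ``counts5`` columns are A, C, G, T, M
    where M is methylated C and the C column then holds unmethylated C only.
    Row sums of the two agree by construction.
    """

    kernel_id: int
    width: int
    counts4: np.ndarray
    counts5: np.ndarray
    n_contributing: int


@dataclass(frozen=True)
class DeltaWindow:
    start: int
    cpg_positions: tuple[int, ...]
    baseline: float
    delta_single: np.ndarray
    delta_all: float

    @property
    def delta_sum(self) -> float:
        return float(self.delta_single.sum())


@dataclass(frozen=True)
class DeltaScores:
    region: GenomicRegion
    windows: list[DeltaWindow]

    @property
    def delta_all(self) -> np.ndarray:
        return np.array([w.delta_all for w in self.windows])

    @property
    def delta_sum(self) -> np.ndarray:
        return np.array([w.delta_sum for w in self.windows])


def _as_matrix(reads) -> np.ndarray:
    if isinstance(reads, np.ndarray):
        return reads.astype(np.float32, copy=False)
    return np.stack([e.matrix if isinstance(e, EncodedRead) else e for e in reads])


def conv1_kernels(model: DScoreModel) -> tuple[np.ndarray, np.ndarray]:
    """(width, 5, n_filters) kernel stack and (n_filters,) bias of conv layer 1."""
    conv = model.network.layers[0]
    W = conv.params["W"].reshape(conv.width, conv.in_channels, conv.filters)
    return W, conv.params["b"]


def _window_activations(reads: np.ndarray, kernel: np.ndarray, bias: float):
    """ReLU activations of one kernel at every valid offset: (N, P) plus windows.

    float64 throughout so PFM superposition is reproducible to tight
    tolerance regardless of the training dtype.
    """
    w = kernel.shape[0]
    win = np.lib.stride_tricks.sliding_window_view(
        reads.astype(np.float64, copy=False), w, axis=1)
    win = win.transpose(0, 1, 3, 2)  # (N, P, w, 5)
    act = np.maximum(
        np.einsum("npwc,wc->np", win, kernel.astype(np.float64)) + float(bias),
        0.0)
    return act, win


def kernel_pfm(model: DScoreModel, reserved, top_fraction: float = 0.01,
               kernel_ids=None) -> list[PFM]:
    """PFMs from the activation-weighted top windows of the reserved reads.

    For each first-layer kernel, activations at every valid (read, offset)
    pair are ranked; the top ``top_fraction`` windows are superposed with
    their activation values as weights.  ``counts4`` accumulates the base
    one-hot; ``counts5`` additionally splits C rows by the methylation
    channel.
    """
    reads = _as_matrix(reserved)
    if len(reads) == 0:
        raise ValueError("reserved read set is empty")
    kernels, biases = conv1_kernels(model)
    w = kernels.shape[0]
    if reads.shape[1] < w:
        raise ValueError("reserved reads shorter than kernel width")
    ids = range(kernels.shape[2]) if kernel_ids is None else kernel_ids
    pfms = []
    for k in ids:
        act, win = _window_activations(reads, kernels[:, :, k], biases[k])
        flat = act.ravel()
        n_top = max(1, int(np.ceil(top_fraction * flat.size)))
        top_idx = np.argpartition(-flat, n_top - 1)[:n_top]
        weights = flat[top_idx]
        if not np.any(weights > 0):
            raise ValueError(
                f"kernel {k}: no positive activation among top windows"
            )
        rows = top_idx // act.shape[1]
        offs = top_idx % act.shape[1]
        windows = win[rows, offs]  # (n_top, w, 5)
        weighted = windows * weights[:, None, None]
        counts4 = weighted[:, :, :4].sum(axis=0)
        meth = weighted[:, :, 4].sum(axis=0)          # mass on methylated C
        counts5 = np.zeros((w, 5))
        counts5[:, [0, 2, 3]] = counts4[:, [0, 2, 3]]  # A, G, T
        counts5[:, 4] = meth
        counts5[:, 1] = counts4[:, 1] - meth           # unmethylated C
        pfms.append(PFM(kernel_id=int(k), width=w, counts4=counts4,
                        counts5=counts5, n_contributing=int(n_top)))
    return pfms


def pfm_probabilities(pfm: PFM) -> np.ndarray:
    """Row-normalized counts4 -> position probability matrix (width x 4)."""
    sums = pfm.counts4.sum(axis=1, keepdims=True)
    if np.any(sums <= 0):
        raise ValueError(f"kernel {pfm.kernel_id}: all-zero PFM row")
    return pfm.counts4 / sums


def write_meme(pfms, path, background=(0.25, 0.25, 0.25, 0.25)) -> None:
    """Write PFMs as MEME minimal motif format (alphabet ACGT)."""
    lines = [
        "MEME version 4", "",
        "ALPHABET= ACGT", "",
        "Background letter frequencies",
        " ".join(f"{b} {f:.3f}" for b, f in zip(BASE_COLUMNS, background)), "",
    ]
    for pfm in pfms:
        probs = pfm_probabilities(pfm)  # raises on degenerate rows
        lines.append(f"MOTIF kernel_{pfm.kernel_id}")
        lines.append(
            f"letter-probability matrix: alength= 4 w= {pfm.width} "
            f"nsites= {pfm.n_contributing} E= 0"
        )
        for row in probs:
            lines.append(" " + " ".join(f"{p:.6f}" for p in row))
        lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


# ---------------------------------------------------------------------------
# Methylation-perturbation (delta d-score) analysis
# ---------------------------------------------------------------------------

def _encode_window(seq: str, meth_mask: np.ndarray, cpg_pos) -> np.ndarray:
    L = len(seq)
    mat = np.zeros((L, 5), dtype=np.float32)
    for i, base in enumerate(seq):
        j = BASE_COLUMNS.find(base)
        if j >= 0:
            mat[i, j] = 1.0
    for p, m in zip(cpg_pos, meth_mask):
        if m:
            mat[p, 4] = 1.0
    return mat


def delta_scores(scorer, region: GenomicRegion, region_sequence: str,
                 L: int = 66, min_cpgs: int = 3, stride: int = 1) -> DeltaScores:
    """Per-window methylation-perturbation deltas across a region.

    ``scorer`` maps an (N, L, 5) array to N d-scores (a trained model's
    ``predict``, an ensemble closure, or any callable).  Every length-L
    window (stride 1 by default) with at least ``min_cpgs`` CpG
    dinucleotides is scored fully methylated (baseline), with each single
    CpG demethylated, and fully demethylated.  Deltas are
    d(perturbed) − d(baseline).
    """
    if len(region_sequence) < L:
        raise ValueError("region sequence shorter than window length")
    jobs = []  # (start, cpg_positions, first_variant_index)
    variants = []
    for start in range(0, len(region_sequence) - L + 1, stride):
        seq = region_sequence[start:start + L]
        cpg = tuple(i for i in range(L - 1) if seq[i] == "C" and seq[i + 1] == "G")
        if len(cpg) < min_cpgs:
            continue
        k = len(cpg)
        base_mask = np.ones(k, bool)
        jobs.append((start, cpg, len(variants)))
        variants.append(_encode_window(seq, base_mask, cpg))        # baseline
        for j in range(k):
            mask = base_mask.copy()
            mask[j] = False
            variants.append(_encode_window(seq, mask, cpg))         # single j
        variants.append(_encode_window(seq, np.zeros(k, bool), cpg))  # all
    windows: list[DeltaWindow] = []
    if jobs:
        scores = np.asarray(scorer(np.stack(variants)), dtype=float)
        for start, cpg, base_idx in jobs:
            k = len(cpg)
            baseline = scores[base_idx]
            singles = scores[base_idx + 1: base_idx + 1 + k] - baseline
            d_all = scores[base_idx + 1 + k] - baseline
            windows.append(DeltaWindow(
                start=start, cpg_positions=cpg, baseline=float(baseline),
                delta_single=singles, delta_all=float(d_all)))
    return DeltaScores(region=region, windows=windows)


def kernel_activated_reads(model: DScoreModel, kernel_id: int, reads,
                           top_fraction: float = 0.001) -> np.ndarray:
    """Indices of reads whose max kernel activation is in the top fraction.

    Reads are ranked by the maximum activation of the kernel over all
    offsets; ties at the cutoff break by stable input order.  When fewer
    than 1/top_fraction reads are supplied, at least one is returned with a
    warning.
    """
    x = _as_matrix(reads)
    kernels, biases = conv1_kernels(model)
    act, _ = _window_activations(x, kernels[:, :, kernel_id], biases[kernel_id])
    per_read = act.max(axis=1)
    n_top = int(len(x) * top_fraction)
    if n_top < 1:
        warnings.warn(
            f"fewer than {int(1 / top_fraction)} reads; returning the single "
            "top-activated read"
        )
        n_top = 1
    if np.all(per_read == per_read[0]) and len(x) > 1:
        warnings.warn("degenerate ranking: all reads activate equally")
    order = np.argsort(-per_read, kind="stable")
    return np.sort(order[:n_top])


# ---------------------------------------------------------------------------
# Effect sizes and combined tests
# ---------------------------------------------------------------------------

def mwu_effect_size(x, y) -> float:
    """Rank-AUC effect size: P(Y > X) + 0.5 P(Y = X)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    u_y = stats.mannwhitneyu(y, x, alternative="two-sided").statistic
    return float(u_y / (x.size * y.size))


def fisher_combine(pvalues, truncate: bool = False) -> float:
    """Fisher's combined probability: chi2 = -2 Σ ln p on 2k df, upper tail.

    ``truncate=True`` clips inputs above 1 down to 1 with a warning (useful
    when combining E-values, which may exceed 1); otherwise p > 1 errors.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any(p <= 0):
        raise ValueError("p-values must be > 0")
    if np.any(p > 1):
        if not truncate:
            raise ValueError("p-values must be <= 1 (pass truncate=True for E-values)")
        warnings.warn("values > 1 truncated to 1 before combining")
        p = np.minimum(p, 1.0)
    chi2 = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(chi2, df=2 * p.size))


def quadrant_summary(es_pairs, motif_flags):
    """2x2 association between 4th-quadrant kernels and motif annotation.

    A kernel lies in the 4th quadrant when ES(Δ_all) > 0.5 and
    ES(Δ_sum) < 0.5 — it reacts to global demethylation while filtering
    single-site change.  Returns ``(table, odds_ratio, p_value)`` with the
    Haldane 0.5 correction applied to the odds ratio when any cell is zero;
    the p-value is the two-sided Fisher's exact test on the uncorrected
    table.  A degenerate table (an all-zero margin) raises.
    """
    pairs = np.asarray(es_pairs, dtype=float)
    flags = np.asarray(motif_flags, dtype=bool)
    if pairs.size == 0:
        raise ValueError("empty input")
    if len(pairs) != len(flags):
        raise ValueError("es_pairs and motif_flags must align")
    in_q4 = (pairs[:, 0] > 0.5) & (pairs[:, 1] < 0.5)
    table = np.array([
        [int(np.sum(in_q4 & flags)), int(np.sum(in_q4 & ~flags))],
        [int(np.sum(~in_q4 & flags)), int(np.sum(~in_q4 & ~flags))],
    ])
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError(f"degenerate contingency table {table.tolist()}")
    t = table.astype(float)
    if np.any(table == 0):
        t = t + 0.5  # Haldane correction
    odds_ratio = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    _, p_value = stats.fisher_exact(table, alternative="two-sided")
    return table, float(odds_ratio), float(p_value)


def motif_match_correlation(pfm: PFM, motif: str, min_overlap: int = 4) -> float:
    """Best ungapped Pearson correlation between a PFM and a motif.

    The motif is taken as a one-hot position probability matrix and slid
    across the PFM's probability columns; the correlation is computed on the
    flattened overlapping columns and maximized over offsets with at least
    ``min_overlap`` aligned positions.
    """
    probs = pfm_probabilities(pfm)
    onehot = np.zeros((len(motif), 4))
    for i, b in enumerate(motif):
        j = BASE_COLUMNS.find(b)
        if j < 0:
            raise ValueError(f"motif base {b!r} not in {BASE_COLUMNS}")
        onehot[i, j] = 1.0
    w, m = len(probs), len(onehot)
    best = -1.0
    for off in range(-(m - min_overlap), w - min_overlap + 1):
        lo_p, hi_p = max(0, off), min(w, off + m)
        if hi_p - lo_p < min_overlap:
            continue
        a = probs[lo_p:hi_p].ravel()
        b = onehot[lo_p - off:hi_p - off].ravel()
        if np.std(a) == 0 or np.std(b) == 0:
            continue
        best = max(best, float(np.corrcoef(a, b)[0, 1]))
    return best
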