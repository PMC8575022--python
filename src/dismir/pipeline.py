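"""End-to-end convenience: cohort -> regions -> model -> per-sample estimate.

Thin orchestration over the library modules, mirroring the standard
workflow: detect switching regions on the training cohort (healthy plasma
vs tumor tissue), collect qualifying reads from those regions, trim/encode,
class-balance with a 20% reserve, train the d-score ensemble, then score
test samples and maximize the read-mixture posterior for r-hat.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .encoding import (
    EncodedRead,
    EncoderConfig,
    balance_and_split,
    encode,
    stack_matrices,
    trim_read,
)
from .io import MethylRead
from .model import (
    EnsembleModel,
    ModelConfig,
    build_model,
    ensemble_dscore,
    train_ensemble,
)
from .regions import (
    RegionReadIndex,
    SwitchingRegion,
    bin_genome,
    detect_switching_regions,
    extract_region_reads,
    filter_regions,
)
from .tumor_fraction import TumorFractionEstimate, estimate_tumor_fraction

__all__ = ["TrainedPipeline", "detect_regions", "train_pipeline",
           "score_sample", "estimate_sample", "encode_region_reads"]


@dataclass
class TrainedPipeline:
    regions: list[SwitchingRegion]
    ensemble: EnsembleModel
    encoder_cfg: EncoderConfig
    reserved: list[EncodedRead] = field(default_factory=list)
    training_logs: list = field(default_factory=list)


def detect_regions(
    healthy_reads: Sequence[MethylRead],
    tumor_reads: Sequence[MethylRead],
    chrom_sizes: dict[str, int],
    bin_size: int = 500,
    min_reads: int = 25,
    threshold: float = 0.3,
    direction: str = "hypo",
) -> list[SwitchingRegion]:
    """Bin the genome, index the training reads and call switching regions."""
    bins = bin_genome(chrom_sizes, bin_size)
    index = RegionReadIndex(bins)
    index.add_reads(healthy_reads, "healthy")
    index.add_reads(tumor_reads, "tumor")
    index = filter_regions(index, min_reads=min_reads)
    return detect_switching_regions(index, threshold=threshold, direction=direction)


def encode_region_reads(
    reads: Sequence[MethylRead],
    regions: Sequence[SwitchingRegion],
    encoder_cfg: EncoderConfig = EncoderConfig(),
    label: int | None = None,
) -> list[EncodedRead]:
    """Extract qualifying switching-region reads, trim and encode them."""
    out = []
    for r in extract_region_reads(reads, regions):
        trimmed = trim_read(r, encoder_cfg)
        if trimmed is None:
            continue
        enc = encode(trimmed, encoder_cfg)
        out.append(EncodedRead(matrix=enc.matrix, label=label, read_ref=r.key))
    return out


def train_pipeline(
    healthy_reads: Sequence[MethylRead],
    tumor_reads: Sequence[MethylRead],
    chrom_sizes: dict[str, int],
    bin_size: int = 500,
    min_reads: int = 25,
    threshold: float = 0.3,
    direction: str = "hypo",
    encoder_cfg: EncoderConfig = EncoderConfig(),
    model_cfg: ModelConfig = ModelConfig(),
    n_members: int = 10,
    seed: int = 0,
) -> TrainedPipeline:
    """Full training path from labeled cohort reads to a trained ensemble."""
    regions = detect_regions(
        healthy_reads, tumor_reads, chrom_sizes,
        bin_size=bin_size, min_reads=min_reads,
        threshold=threshold, direction=direction,
    )
    if not regions:
        raise ValueError("no switching regions detected; nothing to train on")
    encoded = encode_region_reads(healthy_reads, regions, encoder_cfg, label=0)
    encoded += encode_region_reads(tumor_reads, regions, encoder_cfg, label=1)
    train_set, reserved = balance_and_split(encoded, seed=seed)
    ensemble, logs = train_ensemble(train_set, cfg=model_cfg, n_members=n_members)
    return TrainedPipeline(regions=regions, ensemble=ensemble,
                           encoder_cfg=encoder_cfg, reserved=reserved,
                           training_logs=logs)


def score_sample(
    pipeline: TrainedPipeline, reads: Sequence[MethylRead]
) -> np.ndarray:
    """Final (ensemble-averaged) d-scores of a sample's switching-region reads."""
    encoded = encode_region_reads(reads, pipeline.regions, pipeline.encoder_cfg)
    if not encoded:
        return np.empty(0)
    return ensemble_dscore(pipeline.ensemble, stack_matrices(encoded))


def estimate_sample(
    pipeline: TrainedPipeline,
    reads: Sequence[MethylRead],
    grid_step: float = 0.001,
) -> TumorFractionEstimate:
    """Tumor-fraction estimate for one sample from its d-scores."""
    dscores = score_sample(pipeline, reads)
    if dscores.size == 0:
        raise ValueError("sample has no qualifying reads in switching regions")
    return estimate_tumor_fraction(dscores, grid_step=grid_step)
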