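"""Model introspection: kernel PFMs, MEME export and delta d-scores.

Trains a small model on a scenario whose only class signal is a planted
8-mer motif in tumor reads, shows that a first-layer kernel recovers the
motif, then runs the methylation-perturbation analysis on a trained
methylation-signal model to expose super-additivity (the model reacts to
global demethylation more than the sum of single-site changes).
"""

import numpy as np

from dismir import (
    BetaParams,
    PlantedMotif,
    SimConfig,
    simulate_cohort,
    simulate_sample,
)
from dismir.encoding import (
    EncodedRead,
    EncoderConfig,
    balance_and_split,
    encode,
    stack_matrices,
    trim_read,
)
from dismir.interpretation import (
    delta_scores,
    kernel_pfm,
    motif_match_correlation,
    mwu_effect_size,
    write_meme,
)
from dismir.model import SMALL_CONFIG, build_model, ensemble_dscore, train_model
from dismir.pipeline import train_pipeline
from dismir.simulate import simulate_reference

# --- 1. motif recovery ------------------------------------------------------
MOTIF = "TACGTCAT"
cfg = SimConfig(seed=13,
                planted_motif=PlantedMotif(MOTIF, enrich_class="tumor",
                                           read_insert_prob=0.9),
                tumor_meth_switching=BetaParams(85, 15))  # methylation-neutral
reference = simulate_reference(cfg)
rng = np.random.default_rng(13)
t_reads, _ = simulate_sample(cfg, reference, "tumor_tissue", 1.0, rng, "t",
                             n_reads=4000)
h_reads, _ = simulate_sample(cfg, reference, "healthy_plasma", 0.0, rng, "h",
                             n_reads=4000)
ecfg = EncoderConfig()
encoded = []
for reads, label in ((h_reads, 0), (t_reads, 1)):
    for r in reads:
        trimmed = trim_read(r, ecfg)
        if trimmed is not None:
            encoded.append(EncodedRead(matrix=encode(trimmed, ecfg).matrix,
                                       label=label, read_ref=r.key))
train_set, reserved = balance_and_split(encoded, seed=0)
model = build_model(SMALL_CONFIG)
train_model(model, train_set)
pfms = kernel_pfm(model, stack_matrices(reserved), top_fraction=0.01)
corrs = [motif_match_correlation(p, MOTIF) for p in pfms]
best = int(np.argmax(corrs))
print(f"planted motif {MOTIF}: best kernel #{best} "
      f"PFM correlation {corrs[best]:.3f}")
write_meme([pfms[best]], "scratch_kernels.meme")
print("kernel exported to scratch_kernels.meme (MEME minimal format)")

# --- 2. delta d-score super-additivity --------------------------------------
cfg2 = SimConfig(seed=7)
design = ([("healthy_plasma", 0.0, 1500)] * 18
          + [("tumor_tissue", 1.0, 3000)] * 9)
ref2, samples = simulate_cohort(cfg2, design, seed=7)
healthy = [r for s in samples if s.meta.class_label == "healthy_plasma"
           for r in s.reads]
tumor = [r for s in samples if s.meta.class_label == "tumor_tissue"
         for r in s.reads]
pipe = train_pipeline(healthy, tumor, ref2.chrom_sizes,
                      model_cfg=SMALL_CONFIG, n_members=2, seed=1)
scorer = lambda x: ensemble_dscore(pipe.ensemble, x)
d_all, d_sum = [], []
for sr in pipe.regions[:3]:
    seq = ref2.sequences[sr.region.chrom][sr.region.start:sr.region.end]
    ds = delta_scores(scorer, sr.region, seq, L=66, stride=3)
    d_all += list(ds.delta_all)
    d_sum += list(ds.delta_sum)
es = mwu_effect_size(np.abs(d_sum), np.abs(d_all))
print(f"{len(d_all)} windows: mean |delta_all| {np.mean(np.abs(d_all)):.2f} "
      f"vs |delta_sum| {np.mean(np.abs(d_sum)):.2f}; "
      f"effect size {es:.2f} (> 0.5 = super-additive)")
# Demethylating all CpGs of a window moves the d-score far more than the
# summed single-site changes: the model filters single-CpG noise while
# reacting strongly to the global methylation switch tumors exhibit.
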