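# dismir

Read-level cancer detection from plasma cell-free DNA (cfDNA) whole-genome
bisulfite sequencing (WGBS) data.

Liquid-biopsy cancer detection must work at low sequencing depth, where
region-averaged methylation statistics drown in sampling noise.  This
package takes the opposite route: it classifies **every single read** and
aggregates the per-read calls into a sample-level tumor-fraction estimate.
It is aimed at computational biologists building or studying ctDNA
methylation classifiers, and at methodologists who want a fully synthetic,
ground-truthed test bed for read-resolution deconvolution.

## Method

1. **Switching regions.**  The genome is tiled into 500-bp bins; reads with
   ≥ 3 CpG calls are assigned to bins by their 5′ start.  In each
   sufficiently covered bin (≥ 25 pooled training reads) the per-read
   methylation-ratio extrema of the two training classes are compared: with
   H_min the minimum ratio over healthy-plasma reads and T_min over
   tumor-tissue reads, the bin is a *hypomethylated switching region* when

       H_min − T_min > t        (default t = 0.3)

   Reads in a switching region with ratio below H_min are *switching
   reads*; their fraction (FSR) is a model-free baseline statistic.
   Hypermethylated regions use the maxima (default t = 0.5).

2. **d-score model.**  Each qualifying read from a switching region is
   trimmed (5 bp off the 5′ end, cut to L = 66) and encoded as an L×5
   matrix — one-hot bases plus a binary CpG-methylation channel.  A hybrid
   network (1D convolution → max-pool → bidirectional LSTM → 1D
   convolution → flatten → three dense layers, sigmoid output) is trained
   to classify read origin (healthy plasma = 0, tumor tissue = 1) on a
   class-balanced pool with 20% reserved for kernel visualization.  The
   output d-score ∈ [0,1] is the probability the read is tumor-derived;
   by default 10 models are trained on the same data and their scores
   averaged.  The network is implemented in numpy with hand-written
   backpropagation and Adam (no GPU framework needed).

3. **Tumor fraction.**  For a test sample with d-scores d₁…dₙ the
   tumor-read fraction r maximizes the posterior

       P(r) = ∏ᵢ [ r·dᵢ + (1 − r)(1 − dᵢ) ]

   searched on a grid over [0,1] with step 0.001 (in log domain, d clipped
   to [10⁻⁶, 1−10⁻⁶]).  The maximizer r̂ is the sample's cancer-risk score.

4. **Interpretation.**  First-layer kernels are visualized as
   activation-weighted position frequency matrices (top 1% of windows over
   a reserved read set; 4-letter and 5-letter with methylated C as 'M'),
   exportable in MEME format.  Methylation-perturbation analysis rescoring
   windows with single CpGs (Δ_single), or all CpGs (Δ_all), demethylated
   quantifies whether the model attends to global rather than single-site
   methylation change (super-additivity: |Δ_all| > Σ|Δ_single|), with
   Mann–Whitney rank-AUC effect sizes and Fisher's combined test.

5. **Simulator.**  `dismir.simulate` generates reference genomes with
   planted CpG-island-like bins, class-dependent per-read Beta methylation
   levels, per-site flip noise, mixtures at known tumor fraction, optional
   planted sequence motifs, and full per-read/per-bin truth — so every
   stage is testable without controlled-access data.

## Worked example

```python
import numpy as np
from dismir import (SimConfig, simulate_cohort, simulate_sample,
                    train_pipeline, estimate_sample)
from dismir.model import SMALL_CONFIG

cfg = SimConfig(seed=7)
design = ([("healthy_plasma", 0.0, 1500)] * 18
          + [("tumor_tissue", 1.0, 3000)] * 9)
reference, samples = simulate_cohort(cfg, design, seed=7)
healthy = [r for s in samples if s.meta.class_label == "healthy_plasma"
           for r in s.reads]
tumor = [r for s in samples if s.meta.class_label == "tumor_tissue"
         for r in s.reads]
pipe = train_pipeline(healthy, tumor, reference.chrom_sizes,
                      model_cfg=SMALL_CONFIG, n_members=2, seed=1)
print(len(pipe.regions), "switching regions")
rng = np.random.default_rng(11)
for true_r in (0.0, 0.05, 0.1, 0.2, 0.3):
    reads, _ = simulate_sample(cfg, reference, "test_plasma", true_r, rng,
                               "s", n_reads=8000)
    est = estimate_sample(pipe, reads)
    print(f"true r = {true_r:.2f}  ->  r_hat = {est.r_hat:.3f} "
          f"({est.n_reads} reads)")
```

Output (about one minute on one CPU):

```
30 switching regions
true r = 0.00  ->  r_hat = 0.000 (692 reads)
true r = 0.05  ->  r_hat = 0.046 (705 reads)
true r = 0.10  ->  r_hat = 0.096 (717 reads)
true r = 0.20  ->  r_hat = 0.228 (699 reads)
true r = 0.30  ->  r_hat = 0.339 (728 reads)
```

The detected bins are the simulator's planted tumor-hypomethylated regions;
r̂ recovers the planted tumor-read fraction of each plasma mixture nearly
one-to-one, which is what makes it usable as a depth-robust cancer-risk
score.

The same workflow is available from the shell (`dismir simulate`,
`dismir regions`, `dismir train`, `dismir score`, `dismir estimate`,
`dismir pfm`); see `examples/` for narrative scripts covering each
capability, including kernel PFMs and the Δ d-score analysis.

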