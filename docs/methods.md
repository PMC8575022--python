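# Methods

## Model and assumptions

The package treats a plasma sample as a mixture of reads from two latent
sources, tumor and healthy tissue.  Three modelling commitments follow:

* **Read-level signal.**  Class information is carried by individual reads
  (their sequence plus per-CpG methylation calls), not by region-averaged
  statistics.  This is what preserves sensitivity at low depth: halving
  coverage halves the number of informative reads but does not blur each
  read's signal.
* **Switching-region selection.**  Informative loci are bins where the
  *extreme* per-read methylation ratios of the two classes separate
  (H_min − T_min > t for hypomethylation).  Extrema, not means: a region
  qualifies only if even the least-methylated healthy read stays clearly
  above the least-methylated tumor read, which suppresses outlier-driven
  false calls at read resolution.  Strict inequalities are used for both
  the threshold and the switching-read test.
* **Independent reads.**  The tumor-fraction posterior
  P(r) = ∏ᵢ [r·dᵢ + (1−r)(1−dᵢ)] treats d-scores as independent
  probabilities of tumor origin.  No correction is made for reads sharing
  a fragment or a region; with genome-wide sparse sampling at the depths
  targeted here the approximation is mild.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| bin size | 500 bp | region granularity; matches fragment-scale methylation blocks |
| min pooled reads per bin | 25 | extrema over fewer reads are too noisy to trust |
| min CpG calls per read | 3 | a 1–2-CpG read cannot express a ratio worth comparing |
| hypo / hyper threshold | 0.3 / 0.5 | separation required between class extrema |
| 5′ trim / input length L | 5 bp / 66 bp | adapter guard; fixed network input size |
| grid step for r̂ | 0.001 | resolution of the posterior search |
| d-score clip | 10⁻⁶ | keeps the log-posterior finite; the argmax is insensitive to the exact bound |
| ensemble size | 10 | averages out training stochasticity (tests and the acceptance script use 2 for CPU economy) |

Network defaults (conv 64×8 → pool 2 → BiLSTM 32/direction → conv 32×4 →
dense 64-16-1, dropout 0.2, Adam 10⁻³, batch 128, ≤ 20 epochs with early
stopping on a 10% validation split) are DanQ-scale values sized for a desk
CPU.  A reduced profile (`SMALL_CONFIG`: 16/8/8 filters-units-filters,
dense 32-8-1, 8 epochs) is used throughout the simulation studies, tests
and the acceptance script; on the synthetic scenarios it reaches the same
qualitative regime in a fraction of the time.

The engine behind the model is a compact numpy implementation of the
required layers with hand-written backpropagation (float32 training,
float64 available); gradients are verified against central finite
differences in the test suite, and training is reproducible from the
config seed.  Output logits are squashed by a sigmoid fused into the
binary-cross-entropy loss.

## What the simulator emulates — and what it does not

Emulated: non-overlapping bins with a designated tumor-hypomethylated
subset; CpG-island-like CpG density (~1 CpG per 8 bp — the default after
observing that extrema over reads carrying only ~3 coarse-grained CpG
ratios cannot support the 0.3 separation threshold, whereas real DMR-grade
regions are CpG-rich); per-read methylation levels drawn once per read
from tight Beta laws (healthy Beta(85,15), tumor-in-switching Beta(15,85);
means 0.85/0.15) then applied i.i.d. per site — reproducing the read-level
bimodality the switching-region definition exploits; 5% per-site flip
noise for bisulfite miscalls; plasma mixtures with each read tumor-origin
at probability r; optional planted motifs in one read class and/or in
switching bins of the reference; optional reverse-strand reads with
CpG-dyad methylation transfer.

Not emulated: real human sequence composition and repeats, fragment-length
biology, copy-number effects, batch and conversion-efficiency variation,
correlated methylation between neighbouring CpGs beyond the shared
per-read level.  Passing tests therefore demonstrate *mechanistic
correctness and recoverability under the stated statistical structure*,
not clinical performance; the published cohort-level numbers live on
controlled-access data and are out of reach here by design.

## Numerical choices

* Tumor-fraction search runs in the log domain; the log-posterior is a sum
  of logs of affine functions of r, hence concave, so the 0.001-grid
  argmax is a faithful maximizer (cross-checked against golden-section
  search).  Ties resolve to the smallest grid point — the conservative,
  lowest-risk call, relevant only for flat curves.
* PFM superposition and kernel activations are computed in float64 so the
  activation-weighted sums match a brute-force double loop to 1e-9
  regardless of training dtype; PFM weights are post-ReLU activations
  (non-negative by construction).
* Δ d-scores use the sign convention Δ = d(perturbed) − d(baseline);
  windows step by 1 by default (stride configurable), and only valid
  (unpadded) kernel offsets are scanned.
* N bases encode as all-zero one-hot rather than uniform 0.25, avoiding
  invented probability mass; reads shorter than trim5 + L are rejected,
  not padded.
* Reads stay in aligner-reported orientation; raw and reverse-complement
  reads are deliberately distinct model inputs.
* Read→bin assignment uses the 5′ start coordinate, making assignment
  unique and order-independent; the 25-read coverage filter is applied to
  the count pooled over all training samples (plus ≥ 1 read per class so
  both extrema exist) — the per-sample reading would discard nearly
  everything at the 1–3× depths this method targets.
* Paired-end mates, if present, are treated as independent segments.

## Design decisions that were genuinely open

* **Network sizes**: the exact original layer dimensions are not public;
  the defaults above are declared substitutes chosen at DanQ scale, not
  reconstructions.
* **Kernel activation reduction**: per-read ranking uses the maximum
  activation over offsets, while PFMs consume per-offset values; the
  reduction is unstated upstream and documented here as a choice.
* **E-values in Fisher's combination**: values above 1 error by default
  and are truncated to 1 (with a warning) only when explicitly requested.
* **"4th-quadrant" kernels**: operationalized as ES(Δ_all) > 0.5 and
  ES(Δ_sum) < 0.5.
* **Problem sizes** for simulation studies: training cohorts of 18 healthy
  plasma + 9 tumor tissue samples (~27k reads/class), test samples of
  3k–40k reads, 2-member ensembles and the reduced network profile — sized
  so the full pipeline study runs in minutes on one CPU while keeping all
  qualitative behaviour.

## Known limitations

* The depth-robustness experiment follows the repeated-sampling protocol:
  10 independently simulated mixtures per depth condition, compared by
  Mann–Whitney between the extreme depths.  A nested variant (resampling
  read subsets of one fixed sample) is deliberately not used for the
  significance test: the full-depth group is then a constant, and the
  maximum-posterior estimator's small positive skew at tens of reads makes
  the rank test flag a median offset that is ≪ the low-depth sampling
  spread.
* r̂ is a risk score, not a calibrated tumor burden; no confidence
  intervals are provided.
* Hypo- and hypermethylated regions are detected separately; no merged
  multi-direction model is built.
* The extrema-based region criterion is sensitive to per-read CpG count:
  with fewer than ~5 CpGs per read the ratio granularity makes H_min
  collapse, which is why the simulator's default density is CpG-island-like
  and why real usage should restrict to CpG-dense candidate regions.
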