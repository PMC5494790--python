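# Methods

This note documents the models, numerical choices and limitations of
`eegselm`: a three-class (normal / interictal / ictal) EEG classification
pipeline built from a lifting-scheme Daubechies-4 wavelet front end,
max/std subband features, and multiclass sparse extreme learning machines.

## Signal model and preprocessing

Input is single-channel EEG sampled at `fs` (default 173.61 Hz, the rate
of the standard public three-class benchmark), one segment per recording.
Segments are band-limited to 0–32 Hz before epoching because the
clinically discriminative rhythms (δ through β) lie below 32 Hz. The
filter is a low-pass Butterworth (the 0 Hz lower edge makes the band-pass
an ordinary low-pass), default order 4, applied forward–backward
(`filtfilt`) so that the output is zero-phase and the same length as the
input. At order 4 the two-pass magnitude at 60 Hz is below 1 % —
comfortably inside the stop-band bound asserted in the tests. Order and
cutoff are arguments; band-limiting can be disabled.

Band-limiting is applied to whole segments, then windows are cut — not
the other way round — so filter edge effects are shared across epochs
rather than repeated in each one.

## Epoching

Windows are 512 samples advanced by 256 (50 % overlap): 2.94 s windows
overlapping by 1.47 s at 173.61 Hz. A window is started at every multiple
of the hop that lies inside the segment, and a final window running past
the end is zero-padded to full length, so a segment of length L produces
`ceil(L / 256)` epochs and a 4096-sample segment produces exactly 16.
Strict full-window slicing (15 epochs per 4096 samples) is available via
`pad_final=False`. The padded convention is the default because it
reproduces the standard protocol counts for this benchmark (1600 epochs
per 100-segment class, 4800 over three classes).

## Wavelet decomposition

Each epoch is decomposed with three levels of the orthonormal 4-tap
Daubechies filter (two vanishing moments) into A3 (≈0–4 Hz), D3 (4–8 Hz),
D2 (8–16 Hz), D1 (16–32 Hz). The nominal band edges assume an effective
64 Hz rate; at fs = 173.61 Hz the true dyadic edges are higher
(e.g. D1 spans ≈21.7–43.4 Hz). We keep the nominal labels, as is
conventional for this pipeline, and note the discrepancy here.

The transform is computed by the lifting factorisation of the analysis
polyphase matrix rather than by convolution: split into even/odd
samples (even feeds the approximation branch — a fixed, documented
convention), then

1. update: `s_l = even_l + √3·odd_l`
2. predict: `d_l = odd_l − (√3/4)·s_l − ((√3−2)/4)·s_{l−1}`
3. update: `s_l ← s_l − d_{l+1}`
4. scale: `a_l = s_l·(√3−1)/√2`, `d_l ← d_l·(√3+1)/√2`.

Any sign/branch ambiguity in writing down this factorisation is resolved
empirically: the test suite asserts that the lifting output equals direct
circular convolution/decimation with the closed-form filter pair
(`h0 = (1+√3)/(4√2)` …, high-pass `(−h3, h2, −h1, h0)`) to 1e−10 on random
signals, with the detail channel at a two-sample circular delay. An
independent cross-check against PyWavelets (`db2`, periodization mode) is
also pinned, modulo that library's correlation convention (input rolled by
one sample; detail negated and rolled back by one).

**Boundary handling** is periodic (circular) by default: it preserves
dyadic lengths, exact energy conservation (Parseval to 1e−8 relative) and
exact invertibility (round-trip error ≤ 1e−10). A zero-extension mode
exists; it remains exactly invertible (each lifting step only adds a
function of the other channel) but breaks the Parseval identity near the
edges.

## Features

Per subband, two statistics: the **signed maximum** of the raw
coefficients and the **population standard deviation** (n denominator),
ordered (max A3, std A3, max D3, std D3, max D2, std D2, max D1, std D1).
Absolute-value maximum and the n−1 standard deviation are config switches;
"maximum" without modifier and the moment definition of the standard
deviation are the defaults. Features are **not** standardised: the
reference Gaussian width 2σ² = 500 was tuned on raw-µV-scale distances,
so z-scoring (available behind a flag) would silently invalidate it.

## Binary SELM

Training solves `min ½αᵀQα − 1ᵀα` over the box `[0, C]ᴺ`, with
`Q_ij = t_i t_j k(x_i, x_j)`. There is no equality constraint, hence no
bias term anywhere. Kernels: Gaussian `exp(−‖x−y‖²/2σ²)` (parameterised
directly by 2σ²), Laplacian `exp(−‖x−y‖/2σ)` (the denominator convention
is a switch, `2sigma` by default; this kernel is provided for completeness
and not used in the reference configuration), polynomial `(1 + x·y)^m`.

One multiplier is updated per iteration:

- **Selection**: `c = argmin_i J_i`, `J_i = g_i·d_i`, where `g = Qα − 1`
  and `d_i` is +1 at the lower bound, `−sign(g_i)` strictly inside, −1 at
  the upper bound. Ties break to the lowest index (determinism).
- **Step**: `α_c ← α_c − g_c` ("literal" mode) or
  `α_c ← α_c − g_c / k(x_c, x_c)` ("newton" mode, default). The two are
  identical for unit-diagonal kernels (Gaussian, Laplacian) — asserted in
  tests — but the literal step assumes a unit diagonal and can diverge
  for the polynomial kernel, so newton is the default.
- **Clip** to `[0, C]`, and propagate the **clipped** change into the
  gradient: `g_i ← g_i + t_i t_c k(x_i, x_c)(α_c^clip − α_c^old)`.
  Propagating the clipped (stored) value keeps `g` consistent with `α`;
  propagating the unclipped value would let the state drift from the
  iterate.
- **Stop** when `min_i J_i > −ε`; default ε = 0.001, which keeps the dual
  objective within about 1e−3 of the box-QP optimum on small random
  instances (checked against an exhaustive 1e−3 grid for N ≤ 2 and a
  multi-start bounded quasi-Newton oracle for N ≤ 4).

Whenever the selected coordinate has `J_c < −ε` the update strictly moves
`α_c`, so the iteration cannot stall. The default iteration cap is
`max(10 000, 50·N)`: the floor matters because ill-conditioned tiny
problems (near-duplicate points, polynomial kernels) can need a few
thousand iterations regardless of N, while for large N the 50·N term
dominates and is never reached in practice on separable EEG features. A
model that hits the cap is returned flagged `converged: False` with full
diagnostics rather than raising.

The trained model stores only rows with `α_i > 0` (support vectors) and
their signed weights `α_i t_i`; predictions are
`sign(Σ_i α_i t_i k(x, x_i))`, with `sign(0) → +1` as the documented tie
rule. The Gram matrix is formed densely (N ≤ a few thousand here; at
2400 training rows it is ~46 MB, well within reach of a laptop).

## Multiclass combination

Five strategies over a fixed class order (A, D, E):

- **OAA**: 3 one-vs-rest models; argmax of the raw (pre-sign) values.
- **OAO**: 3 pairwise models trained on the pair's samples only; majority
  vote; the only possible tie with 3 classes is 1-1-1 (asserted), resolved
  by the pairwise decision with the largest absolute value.
- **DAG**: OAO's models; sequential elimination from a root pair, exactly
  two evaluations. The root pair is a config (default (A, E)).
- **ECOC**: OAA's models; nearest target code among (1,−1,−1), (−1,1,−1),
  (−1,−1,1) in Hamming distance, ties to the lowest class index.
- **BT**: two models — root class vs rest, then the remaining pair. The
  root class is a config (default E, the most separable class).

The DAG and BT orderings are explicit configuration rather than fixed
constants because the optimal ordering is data-dependent; the grid/CV
machinery can score all three orderings of either strategy. On data where
every binary subproblem is solved exactly, all five strategies coincide —
a property the tests exercise on separable synthetic data.

## Evaluation protocol

The 3×3 confusion matrix is indexed [output][desired]. Sensitivity of a
class is its diagonal entry over its column sum. Specificity of class X
counts every non-X sample predicted as any non-X class as a true
negative — e.g. a true-D epoch predicted E still counts as a true
negative for A. Total accuracy is the trace over the grand total.

Cross-validation is k = 4 stratified folds with a seeded shuffle,
assigned at the epoch level by default (per-class fold sizes differ by at
most one). Because adjacent epochs of one segment overlap by 50 %,
epoch-level splitting leaks correlated samples across the train/test
boundary and flatters accuracy; a segment-level mode (whole segments
assigned to folds) is provided and recommended for realistic estimates.
Fold results are reported both pooled (confusions summed, then metrics)
and per fold; pooled accuracy is exactly total-correct / total-tested.

Grid search is exhaustive over C × kernel-parameter grids (defaults:
8 values of C ∈ {0.1 … 30}; 12 values of 2σ² ∈ {1 … 800}; 7 degrees
m ∈ {1 … 20}), scored by pooled CV accuracy; ties prefer smaller C, then
the smaller kernel parameter (smoother models, deterministically). The
reference configuration (OAO, Gaussian, C = 5, 2σ² = 500, ε = 0.001) ships
as `reference_settings.yaml`.

## Synthetic data generator

The generator emulates the qualitative structure the features exploit,
on a Bonn-like µV scale so the raw-scale kernel width 2σ² = 500 is usable
unchanged:

- **A (normal)**: 1/f-shaped background (σ = 10 µV) plus a 9–11 Hz rhythm
  of 10 µV amplitude — low-amplitude posterior-rhythm EEG.
- **D (interictal)**: the same background (σ = 12 µV) plus sparse biphasic
  spikes (derivative-of-Gaussian, ~70 ms, ≈4× background σ, 0.7 events/s).
- **E (ictal)**: high-amplitude 3–7 Hz rhythm with phase-locked 2nd/3rd
  harmonics (spike-wave morphology, 60 µV scale, σ = 15 µV background).

Per-segment frequencies, phases, spike times and amplitudes are drawn
from a seed-spawned generator tree: one integer seed determines the whole
dataset bit-for-bit, and distinct seeds give distinct data. Defaults are
100 segments of 4096 samples per class at 173.61 Hz, mirroring the public
benchmark's dimensions.

What the generator does **not** emulate: electrode artifacts, muscle and
eye-movement contamination, non-stationary background drift, inter-patient
variability, or realistic spike morphology diversity. The synthetic
classes are separable by construction in the 8-feature space, so passing
end-to-end tests demonstrates that the pipeline's machinery is correct and
that the published configuration is sensible on data of this scale — not
that clinical-grade accuracy transfers to real EEG, which must be checked
on the real recordings (see the README's Bonn section).

## Problem sizes used in the checks

The automated checks use sizes chosen to exercise every code path at
desk scale: protocol counts at the full 100 segments/class; wavelet oracle
equivalence on 200 random signals; QP optimality on 120 random instances
of N ≤ 4; and the end-to-end cross-validated run on 24 segments/class
(1152 epochs), where pooled OAO-Gaussian accuracy is ≈0.95–0.97 and a
shuffled-label control sits at chance (≈1/3). Larger runs (e.g. the full
96-point grid search at 100 segments/class) use the same code via the CLI.

## Known limitations

- Only three-class problems are tested; OAA/OAO/ECOC code paths accept k
  classes but make no guarantees beyond k = 3, and BT/DAG are 3-class.
- No probability calibration, ROC analysis or significance testing.
- The literal update mode is faithful to the single-multiplier rule it
  reproduces but is only safe for unit-diagonal kernels.
- Single-channel only; no EDF/BDF readers; no artifact rejection.
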