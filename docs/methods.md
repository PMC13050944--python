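# Methods

This note documents the models, defaults and numerical choices behind
`prestate`, in the spirit of a package methods appendix: what is computed,
why the defaults are what they are, and what the synthetic benchmarks do
and do not demonstrate.

## Synthetic data model

The generator emulates a within-subject graded-load motor experiment:
10 subjects × 5 load conditions (a no-load baseline plus four graded loads)
× 10 trials, each trial a 500 ms pre-movement epoch (125 samples at 250 Hz)
on a 32-channel 10-10 montage.

Each epoch is a concatenation of dwell segments. Segment lengths are
geometric with mean `segment_dwell` (default 10 samples = 40 ms, a typical
microstate duration), truncated at 1 — the simplest memoryless dwell model.
Each segment expresses one of K planted template maps, drawn independently
from the subject × condition prevalence table. Within a segment the
template is scaled by a positive half-sine envelope (so GFP peaks fall at
segment centers, one per segment) and multiplied by a random ±1 polarity
sign. The polarity flips are deliberate: they force every downstream stage
to honor the polarity invariance the microstate model assumes, and any
code path that forgets an absolute value fails loudly.

Planted templates are random orthonormal vectors in the average-reference
subspace (`random_orthonormal_maps`). Orthogonality is the cleanest
"well-separated clusters" condition for recovery benchmarks; real
microstate maps are correlated, so recovery numbers here are upper bounds
on real-data performance.

Background noise is spatially correlated pink noise: independent 1/f
channels mixed through a random near-identity matrix, then
average-referenced and scaled so that signal RMS / noise RMS equals `snr`
(default 2, a moderately clean evoked-scale regime). The generator does
**not** simulate ocular or muscle artifacts, volume-conducted focal
sources, inter-subject montage differences, or non-stationary noise —
passing benchmarks therefore demonstrate algorithmic correctness, not
robustness to real-world artifacts (the study's ICA/ASR cleaning steps are
out of scope here; a z-scored log-variance flagger plus 3-nearest-neighbor
inverse-distance interpolation keeps the bad-channel stage present and
testable).

A `map_jitter` parameter perturbs the planted templates per trial
(default 0): inter-trial topographic variability of true microstates is not
an empirically pinned quantity, so it is exposed rather than fixed.

Behavioral data follow the same design: reaction time = 450 ms base +
per-condition shift + subject effect + Gaussian noise; RMS EMG scales
multiplicatively with a per-condition `emg_scale`; movement duration and
pre-movement EMG carry no planted load effect, mirroring the null results
such experiments typically report for those measures. EMG traces are
20–450 Hz band-limited noise at 4 kHz with amplitude stepped up between
movement onset and offset; kinematic traces are trapezoids at 60 Hz with
0.5 s rise/fall.

## Preprocessing

- Band-pass: 0.5–30 Hz Butterworth of order 4, applied forward–backward
  (`sosfiltfilt`). Zero-phase filtering doubles the effective order but
  avoids phase distortion of pre-movement timing, which matters more here
  than matching a one-pass magnitude response.
- Downsampling: integer-ratio only (e.g. 500 → 250 Hz), order-8 Butterworth
  anti-alias low-pass at 0.8 × the new Nyquist, then decimation; output
  length is `floor(n·ratio)`. Filtering is applied after downsampling in
  the pipeline, matching the order in which the stages are listed.
- Epochs are half-open `[−500 ms, 0 ms)` windows before each onset: the
  onset sample itself is excluded because a "pre-movement" window must not
  contain movement.
- Baseline correction subtracts each channel's whole-epoch mean. With no
  pre-cue plateau in the epoch there is no privileged baseline interval;
  the whole-epoch mean is the neutral choice and makes baseline correction
  idempotent with average-referencing.
- The mains band-stop is configurable but a no-op inside a 0.5–30 Hz
  passband.

## Microstate machinery

Topographies are centered (average reference) and L2-normalized before
clustering. Similarity is absolute spatial correlation; distance is
`d = sqrt(1 − corr²)`, the sine of the angle between one-dimensional
subspaces — a proper metric on the projective space where polarity-free
maps live.

Modified k-means updates each template as the dominant eigenvector of the
within-cluster scatter `Σ x xᵀ` rather than a sign-aligned mean; both are
standard, but the eigenvector update is exactly the rank-one least-squares
solution of the polarity-free model. Template signs are fixed by making
the largest-magnitude channel positive — an arbitrary but deterministic
convention that commutes with channel permutations (this is what makes the
end-to-end permutation-equivariance tests exact). Assignment ties break to
the lower template index; empty clusters are reseeded from the worst-fit
map. Defaults: 100 restarts, tolerance 1e−6 on the GEV objective, explicit
seed required. The pipeline and benchmarks use 10–20 restarts, which on
the synthetic fixtures attain the same optimum at a fraction of the cost;
the restart count is a determinism-of-the-optimum vs. runtime dial, not a
correctness dial.

GEV is computed with GFP weights: `GEV_k = Σ_{label=k} (GFP_t·corr_t)² /
Σ_t GFP_t²`. In the clustering objective the weights are the peak maps'
original GFP values (the maps themselves are normalized). Per-condition
GEV is normalized within subject × condition over the labeled (GFP-peak)
samples.

No temporal smoothing or minimum-segment-duration constraint is applied to
segmentations; backfitting defaults to GFP-peak samples only (consistent
with the clustering input) with an all-samples option, and an optional
minimum-correlation rejection gate defaults to off. "Time frames" is
defined as the count of labeled GFP-peak samples per subject × condition —
when comparing with occurrence measures from other toolboxes, note that
those sometimes count all samples or segments instead.

### Cluster-number selection

Seven validity criteria are computed per K, each adapted to the
polarity-invariant distance, and the selected K is the median of their
per-criterion optima (lower median on even counts, i.e. ties to smaller K):

| criterion | optimum | note |
|---|---|---|
| silhouette | max | on the precomputed distance matrix |
| Davies–Bouldin | min | templates as cluster centers |
| Calinski–Harabasz | max | global center = dominant eigenvector of all maps |
| Dunn index | max | min inter-cluster / max intra-cluster distance |
| point-biserial | max | correlation of distance with same/different-cluster indicator |
| Krzanowski–Lai | max | needs K−1 and K+1 fits, so only interior K can win |
| cross-validation | min | residual variance × (p/(p−K))² with p = C−1 |

The battery is configurable by name; the median is robust to two or three
criteria preferring degenerate extremes. Criteria undefined at a given K
(empty clusters, range edges) are excluded with a logged note.

## Statistics

Friedman's statistic uses within-subject mid-ranks and the standard tie
correction; p-values come from the χ²(k−1) approximation, matching how
such tests are conventionally reported. A permutation option enumerates
all (k!)^n within-subject orderings when that count is ≤ 2×10⁶ (k = 3 with
n ≤ 8, k = 4 with n ≤ 5) and falls back to Monte Carlo otherwise — full
enumeration at k = 4, n = 8 (24⁸ ≈ 10¹¹) is not feasible.

Dunn's post hoc uses `z = (R̄_i − R̄_j)/sqrt(k(k+1)/(6n))` with two-sided
normal p-values, Bonferroni-adjusted over all k(k−1)/2 pairs by default
(Holm and unadjusted are selectable; all-pairs is the default family, a
versus-baseline family can be formed by filtering the pair table).

The null calibration benchmark (5000 Gaussian replicates at n = 10, k = 4)
measures the χ² approximation's type-I error at α = 0.05; it lands near
0.048 — the approximation is slightly conservative at this block count,
which is expected.

## Source analysis

The head is a 3-shell concentric sphere (radii 87/92/100 mm,
conductivities 0.33/0.0042/0.33 S/m). The forward solution is the
spherical-harmonic series for a current dipole in a layered conductor;
per-degree radial coefficients are obtained by solving the boundary
conditions numerically (5×5 system per degree), which reduces analytically
to the classical `(2n+1)/n` homogeneous-sphere series when all
conductivities are equal — the tests use that identity, plus the
closed-form infinite-medium dipole potential, as independent oracles for
the solver and the angular machinery respectively. Sixty series terms are
ample for sources at ≤ 72% of the brain radius.

Sources live on a regular Cartesian grid (default 12 mm spacing, ~590
voxels, eccentricity ≤ 0.72 of the brain radius). This deliberately
replaces an atlas-based cortical solution space: every algorithmic
property under test (inverse linearity, standardization, localization,
permutation inference) is preserved at desk scale, but voxels are reported
by grid coordinates, not anatomical labels.

sLORETA computes the minimum-norm current `j = Kᵀ(KKᵀ + αH)⁺φ` (H the
average-reference projector) and standardizes each voxel's 3-vector by the
corresponding 3×3 diagonal block of the resolution matrix `TK`. With
α = 0 (pseudo-inverse) the estimate has exactly zero localization error
for noiseless single grid dipoles, which the benchmark verifies over 25
random voxels; `alpha="auto"` (1e−2 × mean eigenvalue of the gain Gram
matrix) is the default for data with noise.

The SnPM contrast flips the signs of per-subject difference images. With
n = 10 subjects the complete sign-flip set (2¹⁰ = 1024) is smaller than
the conventional 5000 random draws, so it is enumerated exhaustively —
the test is then exact. The corrected threshold is the ⌈(1−α)M⌉-th
smallest max-|t|; because the attained level of a discrete permutation
test sits essentially at `floor(αM)/M ≈ α`, a finite simulation of the
familywise error is expected to fluctuate around 0.05, and the benchmark
accordingly tests the error count against its one-sided binomial bound
rather than the point value.

## Benchmark problem sizes

The validation benchmarks (test suite and `scripts/acceptance.py`) use:
template recovery — 10 seeds × (10 subjects × 5 conditions × 10 trials),
K range 2–12, 10 restarts; load-effect power — 200 replicates of
10 subjects × 4 conditions × 4 trials with K = 4 planted maps, clustering
at the planted K with the meta-criterion search disabled inside the
replicate loop (the K-search path is exercised by the recovery benchmark);
Friedman null — 5000 replicates; SnPM familywise error — 200 replicates on
a ~500-voxel null; determinism — a reduced 5-subject pipeline run twice
and hash-compared. These sizes are the package's chosen desk-scale
conditions; the per-condition load effect planted by
`load_sensitive_map` scales one map's prevalence linearly from 2× to 0.5×
its uniform share across conditions.

## Known limitations

- The synthetic generator's idealizations (orthogonal templates, one GFP
  peak per segment, artifact-free noise) make recovery benchmarks
  optimistic relative to real recordings.
- EDF files can be read (via MNE) but not written; the on-disk format is
  plain-text `.ep` matrices with JSON sidecars.
- The spherical head model supports no anatomical labeling; conclusions
  about specific cortical structures require a realistic forward model.
- Microstate syntax measures (transitions, durations per segment) and
  topographic ANOVA are out of scope; only time frames and GEV are
  computed.
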