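# Methods

`connmvpa` implements a connectome-based multivariate pattern analysis
(MVPA) for paired resting-state fMRI designs: the same subjects scanned
before and after an intervention, with the question of whether their
whole-brain functional-connectivity pattern carries enough information to
tell the two states apart, and which connections carry it.

## Pipeline

**Preprocessing.** Input is a regional time series (frames × regions), or a
4D volume plus an integer-label atlas that `parcellate` reduces to regional
means. The per-scan stages, in the default order *discard → nuisance
regression → band-pass → scrub*:

- `discard_initial` drops the first 5 frames (magnetic-saturation volumes);
  with 180 acquired frames this retains 175.
- `regress_nuisance` removes an intercept plus any supplied covariates
  (motion parameters, global/white-matter/CSF signals) by least squares.
- `bandpass` is a zero-phase Chebyshev type-I band-pass, order 4, 0.5 dB
  passband ripple, 0.01–0.08 Hz at TR = 2 s, applied forward–backward with
  `filtfilt`. The order/ripple are configurable; tests pin passband and
  stopband behaviour rather than coefficients.
- Motion scrubbing: frame-wise displacement is the sum of absolute
  backward differences of the six rigid-body parameters, rotations
  converted to arc length on a 50 mm sphere (a 1° step is 50·π/180 ≈
  0.8727 mm). FD at frame 1 is 0. Frames with FD > 0.5 mm are replaced by
  linear interpolation between the nearest clean neighbours; boundary runs
  take the nearest clean value, since one-sided interpolation is undefined.
  Motion files must declare their rotation unit (radians by default,
  degrees accepted and converted).

The stage order is a configuration knob recorded in every run log; the
default places regression before filtering so that filtered data are not
re-contaminated by unfiltered covariates, and scrubbing last so that
interpolation operates on the final signal.

**Connectivity features.** Pearson correlation between every pair of
regional series gives a symmetric R × R matrix; its upper triangle,
Fisher z-transformed (artanh, with |r| clipped at 1 − 1e−7), is the
feature vector. With the standard 116-region whole-brain parcellation this
is 6670 features. Edge k ↔ (i, j) follows one fixed convention — row-major
upper triangle, 1-based region IDs — used in every output.

**Kendall-tau feature selection.** Each feature is scored against the
class labels y ∈ {+1 post, −1 pre} by counting concordant and discordant
unordered sample pairs; pairs with a zero sign on either side
(within-class pairs, exact value ties) count for neither. The score is
τ = (n_c − n_d)/n². Only between-class pairs can contribute, so with
balanced classes |τ| ≤ 0.25 under this normalization; since the
denominator is constant within a call, the |τ| ranking used for selection
and the sign (connection stronger or weaker post-training) are what
matter, and both are invariant to the denominator convention. Selection
keeps the k largest |τ|, ties to the lower edge index.

**Classification.** A soft-margin SVM with the Gaussian RBF kernel
k(x_i, x_j) = exp(−‖x_i − x_j‖²/(2σ²)), σ = 2. Performance is estimated
by leave-one-out cross-validation with selection nested inside each fold:
the held-out sample never influences the ranking or the fit (verified by
mutating held-out features). Metrics: generalization rate (GR, overall
accuracy), sensitivity (post-training samples correct), specificity
(pre-training samples correct). The dual problem is delegated to libsvm
via scikit-learn with γ = 1/(2σ²); kernel form and parameters are the
contract, and dual feasibility is asserted in tests. Features enter on
the Fisher-z scale with no standardization by default (a flag exists and
is logged). A `sweep` utility runs full LOOCV over a (k, C) grid — C grid
in 0.005:0.05:2 colon notation, k from 40 to 300 — returning the GR
surface and its argmax (ties to smallest k, then smallest C).

**Consensus connections and region weights.** Because selection is
re-run per fold, the selected sets differ slightly across folds; the
consensus set is their intersection. Each consensus edge gets one sign
from τ computed on all samples (per-fold selections decide membership
only; per-fold sets are retained for audit). A region's weight is its
degree in the consensus graph, so weights sum to twice the number of
consensus edges.

**Permutation inference.** Significance of the observed GR comes from
re-running the *entire* pipeline — per-fold selection, SVM training,
LOOCV — on B label shuffles (default 1000), with the add-one estimator
p = (1 + #{GR* ≥ GR0})/(1 + B); ties count as extreme and p > 0 always.
Shuffle schemes: `free` (permute all labels; the default) and `paired`
(flip the two sessions within a subject), the latter offered because the
design is paired. A shuffle that would leave a training fold single-class
is redrawn and logged. Freezing the selection made on observed labels
while shuffling (`reselect_features=False`) is provided purely as a
negative control: on null data it inflates the rejection rate severalfold
(see `analysis/05_calibration.py`), which is the empirical argument for
keeping selection inside the loop.

## Synthetic studies

Real data for this design are not publicly available, so verification
rests on a generator whose defaults mirror the emulated study: 25
subjects × 2 sessions, 116 regions, 175 retained frames at TR = 2 s.
Frames are i.i.d. draws from a zero-mean multivariate Gaussian whose
correlation matrix is a constant-off-diagonal base (default 0.1, a
typical whole-brain mean), plus the planted shifts (default δr = 0.3 on
20 edges — the effect magnitude is this package's choice; the emulated
study reports none) on the post session, plus zero-mean subject-specific
jitter (SD 0.02) so LOOCV folds are not exchangeable copies. The summed
matrix is repaired to the nearest valid correlation matrix by clipping
eigenvalues at 1e−6 and rescaling to unit diagonal. Series are white by
default; an AR(1) option adds temporal smoothness without changing
zero-lag correlations (filter applied identically to all regions after
spatial mixing). What the generator does **not** emulate: spatial voxel
structure, physiological noise spectra, heavy-tailed motion artifacts,
site/session drifts — so passing tests demonstrate the statistical
machinery is sound, not that real fMRI of this design would classify at
any particular rate. Motion traces are a low-amplitude random walk with
step-change spikes at chosen frames; a feature-level shortcut generator
(Gaussian features, mean-shifted informative subset) supports classifier
and permutation tests without the time-series stage.

## Numerical and design choices

- **τ denominator.** The n² denominator (rather than tau-b's tie-corrected
  one) is kept because ranking and sign are all that downstream stages
  consume; equality of the induced ranking with an independent tau-b
  implementation on tie-free data is asserted in tests.
- **Consensus sign** comes from full-sample τ (a single well-defined sign
  per edge) rather than per-fold signs, which are stored for audit.
- **Analysis-scale C.** The package default configuration (σ = 2,
  C = 0.01, k = 160) mirrors the emulated study's reported optimum for its
  own data. At this package's synthetic scales that C is margin-infeasible:
  every dual coefficient sits at its bound, the intercept drifts to the
  training majority class, and under LOOCV (24-vs-25 folds) the classifier
  predicts the *opposite* of each held-out label — GR near 0 for observed
  and shuffled labels alike. The honest remedy is the procedure the method
  itself prescribes: sweep C for maximal GR. Run once on pilot replicates
  (seeds 777/888/999, disjoint from all test seeds; `analysis/06_sweep.py`
  reproduces it), the sweep fixes C = 0.105 for Fisher-z paired studies
  (k = 25, matching the planted-effect scale) and C = 0.755 for
  unit-variance feature-level studies (k = 10). These constants live in
  `connmvpa.experiments` and were not revisited afterwards.
- **Monte-Carlo problem sizes.** Calibration uses 200 null studies of 10
  subject pairs × 50 features with B = 99 shuffles; recovery uses 20
  replicates at the full 25-pair × 116-region scale with a B = 19 null
  (clearing all 19 nulls is the add-one p ≤ 0.05 criterion at that B).
  These sizes give binomial error bars tight enough for the checks they
  support while keeping the whole suite desk-scale.
- **Degenerate inputs.** Constant regional series are an error naming the
  region (correlation undefined); |r| → 1 is clipped with a warning before
  artanh; all-flagged scrubbing, single-class labels, rank-deficient
  nuisance designs, and out-of-range planted effects all raise errors
  naming the offending column/edge.

## Known limitations

- LOOCV-maximized sweep results are optimistic (no nested outer loop); the
  procedure is reproduced as specified and the optimism is inherent to it.
- The permutation default `free` ignores the pairing; `paired` is provided
  but the two can differ in power on strongly paired data.
- The generator's constant-off-diagonal base correlation is a deliberate
  simplification; real connectomes have modular structure that could make
  consensus precision easier or harder than the synthetic estimate.
- With heavy class imbalance the τ bound (0.25 for balanced classes)
  shrinks; selection still ranks correctly but |τ| magnitudes are not
  comparable across differently balanced studies.
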