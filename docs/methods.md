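# Methods

## Data model

All computations assume the instantaneous linear forward model
x = L s + η, with x ∈ ℝ^{N_x×T} the sensor data, L ∈ ℝ^{N_x×N_s} the scalar
leadfield (dipole orientations fixed), s the dipole current time courses
and η sensor noise. Inverse solutions are linear, ŝ = Φ x, and the whole
evaluation rests on that linearity: the resolution matrix R = Φ L relates
true to estimated activity exactly, and forward-mapping ŝ predicts held-out
sensors without further assumptions.

## Inverse operators

The minimum-norm family shares the kernel Φ = W Lᵀ (L W Lᵀ + λ²C)⁻¹ with a
diagonal source-covariance prior W and sensor-noise covariance C (identity
by default; an empty-room sample covariance is an opt-in alternative):

- **MNE**: W = I.
- **wMNE**: W_jj ∝ ‖L_j‖^(−p), default depth exponent p = 1 (configurable
  to 2), rescaled to unit mean so λ² stays on the MNE scale.
- **eLORETA**: W from the fixed point M = (L W Lᵀ + λ²C)⁻¹,
  W_jj = (l_jᵀ M l_j)^(−1/2), initialized at W = I, iterated until the
  maximum relative change in W falls below 1e-6 (at most 100 iterations;
  non-convergence sets a flag and warns rather than raising). Typical
  convergence on the synthetic study is 20–60 iterations.
- **sLORETA**: the MNE kernel with each row divided by
  sqrt([Φ (L Lᵀ + λ²C) Φᵀ]_jj); the output is in standardized, not
  current-density, units.

The beamformers compute each filter independently from the data covariance
C_x: Φ_j = (l_jᵀ C_reg⁻¹ l_j)⁻¹ l_jᵀ C_reg⁻¹ with diagonal loading
C_reg = C_x + γ (tr C_x / N_x) I (**LCMV**, unit gain Φ_j l_j = 1), and
**UNGMV** rescales each LCMV row to unit Euclidean norm.

One predicted-SNR parameter (dB, power scale) indexes every operator's
regularization: λ² = tr(L Lᵀ)/(tr C · 10^(SNR/10)) and γ = 10^(−SNR/10).
The default of 2.5 dB matches the generator's default sensor SNR. Whether
the SNR→λ mapping should use the amplitude rather than the power scale is
genuinely open; the power scale is implemented and the mapping is a single
function that can be swapped.

Two consequences are used as exact oracles throughout the tests: the
standardized solvers (sLORETA, eLORETA) have zero peak-localization error
at every dipole, and SECT is invariant under row rescaling, so UNGMV and
LCMV share it identically.

## Resolution metrics

From R = Φ L: PAD_i = ‖r_i − r_{argmax_j |PSF_ij|}‖ (absolute values in the
peak-pick — a sign-flipped peak is still a peak; a flag restores signed
peaks; ties break to the smallest dipole index). SEPS_i and SECT_i are the
PSF-/CTF-power-weighted RMS distances from the seed; the square root is
applied so both carry distance units, with a flag for the raw quadratic
ratio. Dipoles with an all-zero PSF column (or zero weight sum) are
reported as undefined, excluded from means, and counted — never silently
zeroed.

## Variance explained

Channels are randomly partitioned into k balanced folds (k = 27 for a
274-channel array; scaled as round(N_x/10.15) otherwise, e.g. k = 12 for
120 channels). The same partition is reused for every algorithm so per-fold
training sets are identical. Per fold, the operator is rebuilt from the
training-row submatrix of L — beamformer covariance comes from the training
channels of the same recording being analyzed, so no test-channel
information leaks — and the per-test-sensor squared Pearson correlation
between recorded and predicted series is averaged over all sensors and
folds. The empty-room score rER² runs through the identical code path with
only the input recording switched; the ratio rCV²/rER² is the headline
score. Correlation is invariant to per-channel affine rescalings, which is
what makes normalized solutions (sLORETA, UNGMV) comparable with
current-density ones.

The parcellated variant replaces ŝ, before forward mapping, with its
per-ROI rank-1 reconstruction: the first principal component time course
back-projected through its loading vector. PC1 loading signs follow a fixed
convention (sum of loadings positive; first nonzero entry positive on an
exact tie) purely for determinism — the squared correlation is
sign-invariant.

## Parcellated metrics and atlas reduction

fPAD_ω is the fraction of ROI ω's dipoles whose PSF peak falls outside ω;
the summary is the mean over ROIs (a mean over dipoles is equally
defensible; per-ROI values are exposed so either can be formed). Mean
neighbor correlation averages the signed zero-lag Pearson correlation over
adjacent ROI pairs (a flag switches to absolute values); pairs with a
constant time course are excluded and counted.

Atlas reduction allocates a target ROI total across anatomical clusters
proportionally to cluster influence ‖L_Ω‖ = Σ_ω ‖L_ω‖,
‖L_ω‖ = Σ_{j∈ω} ‖L_j‖, using largest-remainder apportionment with a floor
of one ROI per cluster and a cap at the cluster's current count — exact
sum, scale-invariant, deterministic. Within each cluster the
lowest-influence ROI is then merged with its lowest-influence adjacent
neighbor until the allocation is met. Real atlas reductions of this kind
are anatomy-guided and partly manual; the greedy rule is an automated
stand-in whose only objective is a more uniform influence distribution,
and it does not reproduce any published reduced atlas. Two ROIs are
adjacent iff some dipole of one neighbors a dipole of the other in the
source graph; influence is additive under merging, so total influence is
conserved exactly.

## Robustness and similarity

Noise injection adds i.i.d. Gaussian noise of variance σ²·tr(C_x)/N_x per
channel on a grid starting at σ² = 0 (default 0, 0.1, 0.25, 0.5, 1, 2, 4).
At each level the operator is rebuilt at the effective predicted SNR —
with prior power ratio ρ, the new ratio is ρ/(1 + σ²(1+ρ)), i.e. signal
variance fixed and noise variance incremented — and the reconstruction is
compared to the σ² = 0 solution by per-dipole temporal correlation averaged
over dipoles. The summary is the standard deviation of that mean across
levels. Child noise seeds are derived through a `SeedSequence` so they
cannot collide with seeds used for the recording itself.

Between-algorithm similarity uses the same mean-over-dipoles temporal
correlation (an alternative would concatenate dipoles × time into one
vector; averaging is the default for consistency with the robustness
metric). Cohort-level matrices are medians over simulations. Clustering is
recursive two-way spectral normalized cuts: the second-smallest generalized
eigenvector of (D − S, D), with the split chosen by an exact Ncut sweep
over every threshold of the eigenvector ordering; negative similarities
are floored at zero for clustering only (weights must be non-negative),
self-weights are dropped, disconnected components split at cost 0, and the
recorded cost of every split is the exact Ncut value of that bipartition.

## Group statistics

Metric tables (rows = seeded simulations standing in for subjects,
columns = algorithms) feed a Friedman test with within-row average ranks
(χ² = 12/(nk(k+1))·ΣR_j² − 3n(k+1), upper-tail χ²_{k−1} p; perfectly
consistent rankings give χ² = n(k−1) exactly), all C(k,2) two-sided
Wilcoxon signed-rank contrasts (zero differences dropped; exact null by
dynamic programming over sign assignments for n ≤ 25, tie-corrected normal
approximation above), and Benjamini–Hochberg step-up adjustment applied
within each metric family. These are implemented in-package so the exact
variants (zero-handling, tie correction, exactness threshold) are pinned;
the test suite cross-checks them against independent library
implementations and full enumeration.

## Synthetic data: what it emulates and what it does not

The generator emulates the structure the metrics depend on: a linear
instantaneous forward map from an analytic spherical conductor (radial
magnetometers, upper hemisphere, 0.12 m; tangential unit dipoles on a full
0.08 m sphere — tangential because radial dipoles are magnetically silent
in a sphere and would produce zero leadfield columns), band-limited (1–100
Hz, 4th-order two-pass Butterworth) Gaussian source dynamics with one
smoothing pass over a k-nearest-neighbor graph (k = 4) for the local
spatial correlation that drives leakage, sensor noise scaled against the
realized signal variance so the dB SNR is exact per realization, and
empty-room noise with a rank-3 common-mode component (3× the white-noise
amplitude) so its covariance is not perfectly diagonal.

It does not emulate: realistic cortical geometry or sulcal orientation
structure, gradiometer arrays or reference-channel noise cancellation,
1/f spectra, non-Gaussian or nonstationary dynamics, physiological
artifacts, or real environmental noise spectra. Passing tests therefore
establish the algorithmic and theoretical properties (exact zero PAD,
SECT invariance, saturation of unregularized MNE, monotone robustness
decay) and the correctness of every metric's implementation — not the
empirical group-level values a real cohort would produce.

Defaults mirror a desk-scale resting-state session: 30 s epochs at 256 Hz,
120 sensors, 600 dipoles, SNR 2.5 dB, cohorts of 11 seeded simulations,
and a −10…10 dB predicted-SNR sweep. Test and example workloads scale
down to 40–80 sensors and 100–300 dipoles with shorter epochs; the
robustness contract is checked at 80 sensors × 300 dipoles × 10 s over 10
seeds, sizes chosen so the properties under test are comfortably resolved.

## Numerical choices

- All pseudo-inverses use a relative cutoff of 1e-12 × the largest
  singular value, so rank-deficient toy problems are well-defined.
- The λ = 0 minimum-norm kernel is computed as W^{1/2}·pinv(L W^{1/2})
  (SVD of L, condition number κ) rather than forming (L W Lᵀ)⁻¹ (condition
  κ²): algebraically identical, and the reason in-sample saturation holds
  to 1e-10 rather than degrading with κ².
- The SNR-indexed λ² is evaluated with W = I at call time; solver-specific
  priors are rescaled to unit mean so λ² remains comparable across
  algorithms.
- Simulation child seeds are small fixed offsets of the master seed
  (documented in `pipeline.evaluate_subject`); robustness noise seeds are
  `SeedSequence`-derived.
- Degenerate inputs are flagged, not fudged: zero leadfield columns,
  zero-variance channels, constant ROI time courses and all-zero PSF
  columns are excluded from averages with counts reported.

## Known limitations

- The greedy atlas merge is a documented stand-in for anatomy-guided
  manual merging and targets only influence uniformity.
- Beamformer data covariance needs enough samples (the usual rule of thumb
  is ≥ 800–1000); the defaults (7680 samples) satisfy it, but very short
  user-supplied recordings will degrade LCMV/UNGMV silently in quality,
  not in code.
- Free-orientation (vector) solvers, nonlinear/Bayesian inverses and
  frequency-domain beamformers are out of scope.
- The empty-room common-mode structure is a stand-in for real hall noise
  and is exposed as a configuration knob.
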