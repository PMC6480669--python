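# Methods

This note records the models, conventions and numerical choices behind
the package, and what the simulation-based tests do and do not
establish.

## PLS1 engine

The calibration model is PLS1 fit by NIPALS on mean-centered data:
weight vectors `w_a ∝ Eᵀf` normalized to unit length, scores
`t_a = E w_a`, loadings `p_a = Eᵀt_a / tᵀt`, `q_a = fᵀt_a / tᵀt`,
with deflation of both `E` and `f` (for a single response the y
deflation does not change the solution). The regression vector is
`β = W (Pᵀ W)⁻¹ q`; predictions are `ȳ + (x − x̄)ᵀβ`. Channels are
centered but never autoscaled — the NIR convention, where all channels
share units and near-flat channels would otherwise have their noise
amplified. Scores of any block are obtained by the rotation
`R = W (Pᵀ W)⁻¹` applied to master-mean-centered spectra; on the
training data this reproduces the NIPALS score matrix exactly, and
prediction factorizes as `ŷ = T q + ȳ` at any truncation depth.

If the residual is rank-exhausted before the requested number of
components (weight norm below `1e-13` relative to the data scale),
fitting stops early with a warning rather than producing noise
components; cross-validated PRESS curves simply go flat beyond the
effective rank.

**Latent-variable count.** 10-fold cross-validation with a seeded fold
shuffle produces PRESS(A) for A = 1..A_max; the retained count is the
smallest A with `PRESS(A)/min_A' PRESS(A') ≤ F_{0.95}(n, n)` — the
PRESS-ratio F-test, which trades a small loss in raw CV error for
parsimony and stability. Defaults: 10 folds, α = 0.05, A_max = 15
capped by fold feasibility.

## Subspace transfer

Both standard blocks are projected through `R` (always centered with
the **master calibration mean** — the slave block is deliberately not
re-centered with its own mean inside `project_scores`, so the
projection is one fixed linear map for both instruments). The transfer
is the least-squares affine alignment on the first k factors

    T̃ ξ + 1bᵀ ≈ T̂ .

The intercept `b` matters: written on raw (uncentered) spectra, the
k×k map acts on scores that all share a large constant component, and
that constant supplies exactly one affine degree of freedom per
factor. Expressing the same model on centered scores therefore
requires an explicit intercept; without it (available as
`intercept=False`) a purely linear map cannot absorb an additive
baseline difference between instruments, and on the default simulated
conditions the transfer then recovers almost nothing of the
direct-transfer degradation (0.125 vs 0.132 RMSEP, against 0.0079 for
the affine solve). Rank-deficient standard sets fall back to the
minimum-norm least-squares solution with a warning.

**Factor count k.** Chosen by leave-one-out cross-validation over the
standard set, k = 1..min(A, n_std − 1). The held-out residual compares
the transfer-path prediction of the left-out *slave* standard with a
pseudo response: the full master model's prediction of the paired
*master* standard spectrum, computed once up front (the master model
is fixed throughout transfer; it is never refit). Ties are broken
toward the smallest k within 1e-10 relative RMSECV — parsimony again.
The projection, ξ, and q are all truncated to k consistently; k = A
gives the untruncated variant.

No slave reference value enters fitting, selection or prediction; the
interfaces do not even accept one. SBC is the single comparator that
requires standard-set reference values, and the benchmark harness
passes them only there.

## Comparators

* **PDS** — per master channel j, OLS with intercept of the master
  channel on the slave channels in a width-w window (w odd; clipped
  asymmetrically at the edges rather than zero-padded, so no signal is
  fabricated outside the measured range); coefficients form a banded
  p×p matrix. The corrected slave spectra are scored by the unchanged
  master model.
* **SBC** — OLS line `ŷ_std = slope·y_std + bias` between the master
  model's predictions of the slave standards and the reference values;
  test predictions are corrected by inverting the line.
* **GLSW** — difference matrix `D = X_std^m − X_std^s`, SVD `D = USVᵀ`,
  filter `G = I − V diag(1 − 1/√(s²/α + 1)) Vᵀ` (identity on the null
  space). The master model is refit on G-filtered calibration spectra
  and slave spectra are filtered before prediction. α defaults to
  0.02, the conventional choice; smaller α suppresses the difference
  directions harder.
* **CCACT** — canonical variates of the paired standard blocks,
  computed through rank-truncated SVDs of each centered block (which
  keeps the n ≪ p case well posed without explicit covariance
  inverses); per-pair OLS scaling of slave onto master variates on the
  standards; least-squares reconstruction from scaled variates back to
  master spectral space. The number of pairs c defaults to the
  minimizer of leave-one-out standard-reconstruction error.
* **MSC** — each spectrum regressed on the master calibration mean
  spectrum, corrected as `(x − b)/a`. It is treated as preprocessing:
  the master model is refit on corrected calibration spectra and slave
  spectra are corrected before prediction. Because the correction is a
  per-sample nonlinear transform, the MSC pipeline's no-transfer
  reference is its own master-side error, not the raw model's.

## Dataset division

Kennard–Stone max–min selection (first two picks = most distant pair;
ties broken toward the lowest index; distances on raw spectra). The
selection is incremental, so the first m picks of a longer run are the
m-sample selection — standard subsets are nested across sizes by
construction. The calibration/test division runs on the master
spectra with test size `round(0.2·n)` (round half up, which reproduces
64/16, 198/50 and 524/131 from 80, 248 and 655 samples); standards are
then ordered on the slave calibration spectra, mirroring which
instrument drives each choice in practice.

## Evaluation

RMSEP on the common test set; improvement
`h = (1 − RMSEP_plsct/RMSEP_other)·100 %` (negative when the transfer
is worse, reported as such); two-sided Wilcoxon signed-rank test on
paired per-sample **absolute** prediction errors — the only paired
quantity available to compare two methods on one test set. Zero
differences are dropped. The exact lattice distribution is used for
n ≤ 25 without midrank ties; with ties and n ≤ 13 the 2ⁿ sign
assignments are enumerated exactly; otherwise the normal approximation
with tie correction applies. This choice of error vector affects
p-values and is therefore stated prominently.

The benchmark harness additionally fits four references per run:
Calibration (master model on master test), Direct transfer (master
model on slave test, unmodified), Recalibration (fresh model on the
slave calibration set), and Recalibration2 (fresh model on the slave
standards only, LV count selected by the same CV + F-test capped by
the standard-set size).

## Synthetic paired spectra

Master spectra are Beer–Lambert mixtures: each of 4 (default)
components is a sum of 3 Gaussian peaks with widths of 30–90 channels
(wide enough that lag-1 channel autocorrelation exceeds 0.95, as in
real NIR), concentrations are Dirichlet compositions times a
per-sample scale drawn from U(0.7, 1.3) — positive spectra and a
full-rank concentration matrix — and the response is linear in one
component's concentration. The slave instrument measures the same
noise-free signal through, in order: Gaussian peak broadening,
fractional wavelength shift (linear interpolation, edge-clamped,
exact at zero shift), multiplicative gain, additive and sloped
baseline; then adds its own (optionally heteroscedastic) Gaussian
noise. Identity settings reproduce the master signal bit-for-bit
before noise.

Scenario defaults (`make_paper_like_scenario`): corn_like 80×700
(1100–2498 nm), wheat_like 248×741 (730–1100 nm), tablet_like 655×650
(600–1898 nm); inter-instrument difference smallest for wheat_like and
largest for corn_like (shift 1 channel, gain 1.05, baseline +0.02,
slave noise σ = 0.001 absorbance; master noise 5e-4; y noise 0.01
property units, which puts the corn-like calibration RMSEP near 0.009,
the realistic order for a moisture model).

**What the simulations do not show.** The distortion chain is affine
in the signal. Consequently every standard-based method — PLSCT, PDS,
SBC after its line fit — can correct it essentially completely, and
with 30 standards they all converge to the reference-noise floor:
under the default conditions PLSCT and PDS differ by ~0.2 % relative,
i.e. they tie, and the ordering of their means over 20 replicates is
seed noise. Real inter-instrument differences include effects outside
this model class (detector nonlinearity, scatter, wavelength-dependent
bandpass) and real master models carry many more latent variables than
the data's chemical rank, which is where feature-space transfer
separates from spectrum-space transfer in practice. The simulations
do establish: the direct-transfer degradation, its essentially
complete recovery by the subspace transfer without slave reference
values, the feature-gap contraction, factor-count recovery by LOO
selection, and the stabilization of error with standard-set size.

## Numerical conventions

* All least squares via `numpy.linalg.lstsq` (minimum-norm on rank
  deficiency, with a warning where it indicates a degenerate standard
  set).
* Fold assignment and every simulation draw flow from explicit integer
  seeds; identical seeds give byte-identical CLI reports.
* Degenerate inputs (constant X or y, zero-variance blocks, orthogonal
  MSC spectra) raise typed errors rather than propagating NaNs.
* Spectra CSVs are written with shortest round-trip float repr and read
  with round-trip parsing, so serialization is lossless.
* Test and acceptance problem sizes: oracle checks run on ~12×9
  instances (20 replicates), workflow checks on the full 80×700
  corn-like scenario (20 replicates), which keeps the whole suite
  around 15 s on one CPU.
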