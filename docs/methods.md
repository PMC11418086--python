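# Methods

## Model

A single-particle cryo-EM dataset supplies `n` projection images of one
molecule, each taken at an unknown rotation `R_i ∈ SO(3)`.  By the
Fourier slice theorem the 2-D transform of image `i` is the central
slice of the 3-D transform with frame `R_i`; two slices intersect in a
line with 3-D direction `d_ij = r_i × r_j`, where `r_m` is the third
row of `R_m` (the viewing axis).  In the plane of image `i` that line
has the canonical representative

    a_ij = Π R_i d_ij = J̃ R_i R_jᵀ e₃ ∈ R²,   J̃ = [[0,−1,0],[1,0,0]],

where `Π` drops the (identically zero) third coordinate.  Stacking the
`a_ij` as 2×1 blocks gives the 2n×n **pure common-lines matrix** `A`,
with zero diagonal blocks.  It factors exactly as `A = B C` with
`B_i = J̃ R_i` (2×3 blocks with orthonormal rows) and `c_j = R_jᵀ e₃`,
hence `rank A = 3` for generic rotations.  Beyond the rank law, purity
implies one norm equality per unordered pair,

    ‖a_ij‖ = ‖a_ji‖,

and, per unordered triple `{i<j<k}` with `d_i = det[a_ij a_ik]`,
`d_j = det[a_ji a_jk]`, `d_k = det[a_ki a_kj]`, the two determinant
equalities `d_i + d_j = 0` and `d_j + d_k = 0` (each `d` equals the
scalar triple product of the three viewing axes up to the alternating
sign `+,−,+`; the sign pattern is frozen by oracle tests on constructed
pure matrices).  That is `n(n−1)/2 + 2·C(n,3)` quadratic constraints:
5 at `n = 3`, 14 at `n = 4`.

Measured common lines come as *representatives known only up to a
nonzero scale and sign per block*.  The computational problem
throughout is therefore: given unit-normalized, noisy representatives,
recover per-block scales making the matrix pure, and from the pure
matrix the rotations.

## Identifiability: what the constraints can and cannot see

Two gauge facts shape the whole package:

* **Global scale and chirality.**  A pure matrix is recoverable from
  scale-corrupted data at best up to one global scale whose sign swaps
  the two mirror-handed rotation tuples (`R_i` versus `J R_i J` with
  `J = diag(1,1,−1)`).  Both candidates are always returned.
* **Per-image in-plane π rotations.**  Flipping the sign of one
  *block-row* of a pure matrix yields exactly the pure matrix of the
  rotations with `R_i` replaced by `diag(−1,−1,1) R_i` (verified
  symbolically and numerically).  Every constraint — rank, norms,
  determinants — is therefore invariant under per-block-row sign
  flips, and with independently sign-corrupted data no estimator can
  recover that gauge: the data distribution is invariant under the
  2^n-element orbit.  Recovery claims and tests are stated modulo this
  orbit; outputs are canonicalized by aligning each block-row's sign
  with the measured input (`align_row_signs`), which resolves the
  gauge correctly whenever the data's signs are consistent (e.g.
  positive scales, or detection-produced pairs).

Column signs, by contrast, are identifiable: the determinant
constraints are linear in signed column scales.

## Denoising (IRLS-ADMM with alternating-projection polish)

`irls_admm` minimizes the robust misfit `Σ ‖τ_ij a_ij − x_ij‖₂` over
per-block scales `τ` and a rank-3 matrix `X` with zero diagonal blocks,
where `a_ij` are the unit-normalized measured blocks.  IRLS converts
the mixed L1/Frobenius objective into weighted least squares with
weights `w_ij = 1/√(‖τ_ij a_ij − z_ij‖² + δ²)`; the weighted bilinear
problem is solved by ADMM with a consensus split `X = Z`, `Z` being the
top-3 SVD truncation:

1. `x_ij ← (w² τ a + ρ z − γ) / (w² + ρ)`, diagonal blocks zeroed;
2. `τ_ij ← ⟨a_ij, x_ij⟩`, then `‖T‖_F` renormalized to `√(n(n−1))`
   (the objective is scale-invariant; without a gauge `T → 0, X → 0`
   is a vacuous minimizer);
3. `Z ←` rank-3 truncation of `X + Γ/ρ`; `Γ ← Γ + ρ(X − Z)`.

Defaults: `ρ = 1`, `δ = 10⁻² ×` mean block residual at initialization,
20 IRLS rounds over up to 100 ADMM rounds of up to 10 inner
alternations, relative tolerance 1e−8, divergence cap 1e9.  The hot
loop is compiled with numba; a pure-Python reference of every update is
kept alongside and verified to 1e−15 agreement by tests.

Two regimes of the same iteration are exposed:

* **Robust averaging** (default): the weights are renormalized to unit
  mean each IRLS round, so that the ADMM penalty ρ stays commensurate
  with the data term and the rank-3 consensus can out-pull the fit on
  downweighted (outlier) blocks.  This is the right regime for noisy
  or outlier-laden data.
* **Interpolating** (`normalize_weights=False`): raw `1/δ`-scale
  weights pin every block, which is what exact scale recovery from
  consistent (but arbitrarily scaled/signed) data needs.

Initial scales are the measured block norms (`init="norms"`), making an
already-consistent matrix a fixed point; `init="ones"` starts agnostic.

After the ADMM loop an **alternating-projection polish** refines the
solution to machine precision: alternately project onto the per-block
scale-consistent set (`x_ij ← ⟨a_ij, x_ij⟩ a_ij`) and onto rank-3
matrices.  Exact interpolation is only appropriate when the data admits
a consistent scaling, so the polished iterate is kept only when it does
not increase the aggregate constraint error.

The non-convex landscape contains spurious basins, reached more often
under sign-corrupted data (at `n = 4` the per-block-scale rank-3
variety provably contains more than the separable-scale family).
`denoise_and_purify` handles this with restarts: attempt 0 runs the
solver as configured; later attempts switch to the interpolating
regime and randomize the block signs (a sign pattern is absorbed into
the unknown scales, so the underlying pure matrix is unchanged).
Failure is detectable without ground truth — the scaled output's
aggregate quadratic error stays large — and the best attempt by that
criterion is returned.

## Sinkhorn scaling

Rank-3 denoising leaves scale errors of the separable form
`τ_ij = λ_i μ_j`.  `sinkhorn` removes them by alternating homogeneous
least-squares solves: the row system stacks the norm rows
`λ_i‖a_ij‖ − λ_j‖a_ji‖` with the signed-square-root linearization of
the determinant rows (`sr(d_i)λ_i + sr(d_j)λ_j`, with
`sr(x) = sign(x)√|x|`), the column system stacks
`μ_j‖a_ij‖ − μ_i‖a_ji‖` with the division-linearized determinant rows
(`d_i μ_j + d_j μ_i`); each is solved by the right singular vector of
smallest singular value, sign-fixed to nonnegative entry sum, and
applied in place.  Because the norm rows are sign-blind and bias all
scales toward one sign, a **column-sign synchronization** step precedes
the alternation: the determinant-rows-only column system is solved
once and only the signs of its solution applied (its magnitudes scale
like squared row scales and can be poorly conditioned).  Divergence is
flagged when any scale entry falls below 1e−6 of the largest (the
vanishing-entries failure mode) or the residual grows tenfold; the
run stops when the aggregate quadratic error stops changing (tolerance
1e−10, at most 200 iterations).  Residuals are evaluated on the matrix
rescaled to a fixed Frobenius norm so the two constraint families stay
commensurate.

## Rotation recovery

From an estimated pure matrix: top-3 SVD factorization `A ≈ U V`; the
gauge `Q` with `B = U Q` satisfies `U_i (Q Qᵀ) U_iᵀ = I₂` per image, an
affine-linear least-squares problem in the six entries of the
symmetric `H = Q Qᵀ`, solved via its 6×6 normal equations.  From the
eigendecomposition `H = P D Pᵀ` (global sign flipped if two or more
eigenvalues are negative; singleton negatives clamped at 1e−12),
`B̂ = U P √D`; per image, row₁(R) = second row of `B̂_i`, row₂(R) =
−first row (from `B_i = J̃ R_i`), row₃ = row₁ × row₂, then projection
to the nearest rotation by SVD with determinant correction.  Running
the same pipeline on `−A` yields the mirror-handed candidate; both are
returned.

## Heterogeneity clustering

For a dataset holding several distinct molecules, within-population
blocks admit a consistent scaling while cross-population blocks are
meaningless.  `cluster_common_lines` scores random 4-subsets: extract
the 8×4 submatrix, run the denoiser (light caps: 5 IRLS rounds of 25
ADMM rounds), reject on divergence, on **vanishing fitted block
scales** (minimum off-diagonal |τ| below 0.2 of the median — an
inconsistent image can otherwise be "explained" by shrinking its
blocks to zero), or on a missing spectral gap of the scaled data
(σ₄/σ₃ > 0.1); otherwise run Sinkhorn and record the aggregate
quadratic error.  Four is the smallest sample size with a nontrivial
rank-3 constraint and keeps the subproblems fast and stable.

Accepted samples form a weighted 4-uniform hypergraph, flattened to a
graph whose pair weight is −log of the smallest error over hyperedges
containing the pair.  Weights are then **background-calibrated**: the
median accepted log-error is subtracted (and negatives clipped), so
that the inconsistent-sample background sits at zero — without this, a
noise floor common to all pairs swamps the community structure at
realistic angular noise.  Communities are found by the
local-fitness method of Lancichinetti, Fortunato and Kertész: fitness
`f(C) = s_in/(s_in + s_out)^α` on edge strengths, greedy growth from
the strongest unassigned seed with pruning of negative-fitness
members (incremental O(n) bookkeeping; an iteration cap guards
against add/prune oscillation on ties), `α = 1` by default.  Raw
communities may overlap; each node goes to the community where its
node fitness is largest, followed by a local refinement sweep of the
same rule over all communities, and nodes left in no community become
singletons.  Default budget is `50 n` samples with a warning below 80%
pair coverage.

## Synthetic data

`corrupt_matrix` emulates what detection hands downstream: per-block
scales `|τ| ~ U[scale_low, scale_high]` with sign flips, in-plane
angular noise (rotation of the representative by `N(0, σ²)` degrees —
detection errors are line-angle errors, so the norm is preserved), and
outright misdetections (replacement by a uniform random direction of
the same norm).  The default spec is the identity corruption; each
experiment opts into the dimensions it studies (`NoiseSpec.scaled` for
the scale-recovery conditions, `angle_sigma_deg` for detection-style
noise).  `heterogeneous_matrix` plants populations with consistent
within-blocks, i.i.d. uniform unit cross blocks, and one global
permutation.  What passing synthetic tests do *not* show: real class
averages have correlated detection errors, CTF effects and non-white
noise; none of these are modeled.

## Imaging and detection

Phantoms are sums of ≥5 isotropic Gaussian blobs with centers uniform
in a half-radius ball (generic position, hence no point-group
symmetry with probability one); their tomographic projections are
closed-form 2-D Gaussians centered at `Π R c`, so projection images
carry no quadrature error beyond grid sampling.  White Gaussian noise
is calibrated as `σ² = mean(clean²)/SNR`.  Detection samples both
images' centered FFTs (`fftshift∘fft2∘ifftshift`; without the inner
shift each image acquires a frame-dependent checkerboard phase that
destroys the common-line equality) along `n_theta = 180` central rays
with cubic-spline interpolation — bilinear resampling of the
oscillatory complex field was measured to cost several degrees of
argmax accuracy — over radii 3 to L/2−2 frequency pixels, after a
raised-cosine edge taper.  The normalized real correlation is
maximized over all ray pairs and both relative orientations (the ray
at θ+180° is the complex conjugate); the winning orientation is
encoded in the sign of the second representative.  Default grid:
L = 64 pixels at 3 Å (a desk-scale stand-in for the 129-pixel images
used with experimental data).

## Problem sizes and numerical choices

Test and acceptance runs use: rank law at n = 3…30 × 20 seeds; scale
recovery at n = 5…8 × 10 seeds (restarts ≤ 8); rotation recovery at
n = 10 × 10 seeds; noise robustness at n = 20 × 10 seeds with 5°
noise; clustering at 3×10 images × 5 seeds with budget 50 n; detection
at n = 6 phantoms on a 1° grid.  Degenerate inputs: viewing axes
parallel within 1e−10 raise a degenerate-pair error; zero blocks
cannot be normalized; the zero matrix has no defined constraint error;
σ₃ ≈ 0 aborts factorization.  Ties in community growth break toward
the lower node id; the global Sinkhorn sign is fixed by nonnegative
entry sums.

## Known limitations

* Per-image in-plane-π gauge: unrecoverable from independently
  sign-corrupted data (see above); plain-correlation recovery holds
  only under sign-consistent corruption.
* The clustering error signal degrades with angular noise roughly
  linearly; beyond ~2–3° of uniform per-line noise at budget 50 n the
  within/mixed separation thins and partitions fragment.
* Symmetric molecules are out of scope (common lines are then only
  defined up to the symmetry group).
* The solver is non-convex: single runs can land in spurious basins;
  restart-based selection is by observable constraint error only.
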