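# Methods

## Measurement model

A directional coupler with linear directivity *D* adds 1/*D* of the
reflected voltage wave to the measured forward wave, per channel:
a_meas = a_act + b/D. Directivity is specified in dB on the **voltage**
convention, D = 10^(dB/20), because the leakage adds voltage phasors; a
power convention (10^(dB/10)) would halve the modeled effect. For an
N-channel array the reflected waves follow from the scattering matrix,
y = (1/μ) e^{iφ} S x, where

* φ (rad) is the phase offset between the reference plane of the
  S-parameters and that of the coupler measurement. One global φ is used
  for all channels (cable lengths are assumed matched); the error is
  evaluated over a full sweep of φ, so only the *worst* offset matters.
* μ ≥ 1 is the linear voltage attenuation of the cable between the two
  planes. Default μ = 1 (coupler at the S-parameter plane): cable loss
  over sub-wavelength runs is negligible next to the directivity and is
  in any case equivalent to a slight directivity increase. The parameter
  is kept explicit because moving the coupler toward the amplifier
  (μ > 1) attenuates the reflected wave twice and demonstrably shrinks
  the error.
* A per-channel directivity vector is accepted (1/D becomes a diagonal
  matrix); real hardware varies, but the scalar default matches the
  common case of nominally identical couplers.

The measured excitation is x_meas = M x with the error matrix
M = (1/μ) e^{iφ} (1/D) S + I, and measured SAR is the quadratic form of
the congruence-transformed VOPs Q̃ⱼ = MᴴQⱼM. `custom_error_matrix`
accepts any square M (e.g. a sniffer-coil correlation matrix with unit
diagonal), so the worst-case machinery is not tied to the coupler model.

## Worst-case ratio

Per phase offset, the worst-case underestimation ratio is

r(φ) = max_j max_x x^H Q_j x subject to x^H Q̃_k x ≤ 1 for all k.

The outer maximization over j is an exhaustive loop (ties broken toward
the lowest index). The inner problem — a convex quadratic maximized over
an intersection of ellipsoids — is attacked through its semidefinite
relaxation. We solve the *dual* SDP, min Σλ_k s.t. Σλ_k Q̃_k ⪰ Q_j,
λ ≥ 0, by Kelley cutting planes: the matrix inequality is enforced
through scalar cuts generated from the most negative eigenvectors of the
slack matrix A(λ) = Σλ_k Q̃_k − Q_j at each LP iterate. The restricted
LPs are solved with HiGHS through an incremental handle so each re-solve
warm-starts from the previous simplex basis (a plain `linprog` fallback
exists).

Soundness does not rest on iterating to exact feasibility. At every
iterate the ε-infeasible λ is *certified* by the cheaper of two shifts —
additive along the all-ones direction (valid because ΣQ̃_k is positive
definite on the working subspace) or multiplicative along λ itself — and
the best certified value is the reported upper bound. A feasible
excitation is extracted from the near-null direction of the slack matrix
and improved by a deterministic projected ascent; its achieved ratio is
the lower bound, and `certificate_gap` records the relative distance.
Observed gaps are ~1e−7 on single-constraint instances and below ~1e−3 on
multi-VOP instances, i.e. the relaxation is numerically tight for this
problem family; the gap is reported rather than assumed away.

Numerical choices:

* Target convergence tolerance 1e−8 (relative, on the certified bound vs
  the LP objective), iteration cap 400, stall detection after 15
  non-improving iterations — the tail of a cutting-plane method is
  sublinear, and the certified bound makes early return sound.
* VOPs are normalized by the largest spectral norm in the set before
  solving; the ratio is scale-free, so this only conditions the solver.
* Degenerate directions: eigenvectors of ΣQ̃_k with (relatively) zero
  eigenvalue have zero measured SAR. If the actual SAR is nonzero along
  any of them the problem is reported UNBOUNDED (possible only with a
  singular custom error matrix or rank-deficient VOP sets — the coupler
  M is a small perturbation of the identity and safely invertible);
  otherwise the problem is restricted to the orthogonal complement.
* φ enters non-convexly (the error curves have multiple minima), so the
  sweep is an exhaustive uniform grid on [0, 2π), endpoint excluded,
  default 360 steps. Consecutive phase points warm-start each other's
  cut sets.

The total-forward-power error (actual ‖x‖² vs measured x^HMᴴMx) is
1/λ_min(MᴴM) in closed form; it equals the SAR solver run on a single
identity VOP, and the test suite holds the two code paths to 1e−4
agreement.

Reporting convention: the underestimation percentage is (1 − 1/r)·100,
i.e. the shortfall as a fraction of the *actual* SAR; the alternative
(r − 1)·100 is selectable and both columns are always written to the CSV
outputs, so either convention can be compared directly.

## Verification oracle

`oracle_max_ratio` is an independent lower-bound instrument sharing no
code with the solver. It samples isotropic complex Gaussian excitations
normalized onto the feasible boundary (max_k x^HQ̃_k x = 1, where the
maximum of a convex objective lives), keeps one running record per
actual-VOP branch x^HQ_j x, and at every record improvement starts a
deterministic constrained local maximization of that branch (SLSQP in the
real embedding [[Re x; Im x]], which tracks active sets and therefore
reaches corner maxima where several constraints are tight — plain
boundary-gradient ascent stalls there). Because polish starts are exactly
the record events of the sample stream, extending the stream only adds
starts: the bound is non-decreasing in the sample count for a fixed seed,
and bit-reproducible. The oracle is a test instrument for N ≤ 4–8;
sampling is exponentially inefficient in dimension and the production
path never depends on it. On 50 random small instances the solver bound
and the oracle agree to ~1e−6 relative.

The single-constraint case has the exact closed form
λ_max(Q̃^{−1}Q) (`generalized_eig_ratio`, Cholesky whitening), used as a
third, independent route in the tests.

## Real embedding

Hermitian quadratic forms are embedded as real symmetric 2N×2N blocks
[[Re Q, −Im Q], [Im Q, Re Q]] acting on z = (Re x; Im x); `real_embed`
exposes the construction and the solver-facing identity
zᵀQ_ℝz = x^HQx is property-tested. The cutting-plane solver itself works
directly in the complex domain (eigendecompositions of N×N Hermitian
matrices), which is equivalent and halves the matrix dimension.

## Synthetic data

Real transmit arrays span worst-case reflected powers
λ_max(SᴴS) from a few percent (intrinsically decoupled, heavily loaded
elements) to >0.8 (large-diameter arrays without effective decoupling).
The generator reproduces that spread:

* diagonal entries of magnitude `diag_reflection` with uniform random
  phase (element mismatch);
* off-diagonals complex Gaussian scaled by `coupling_scale` with
  exponential decay in circulant channel distance (ring-like arrays are
  nearest-neighbor dominated; decay factor 0.5 per step by default, and a
  dense mode with no decay for stress tests);
* passivity enforced by *global rescaling* — not spectral clipping — so
  the coupling structure keeps its shape; an optional exact target for
  λ_max(SᴴS) is hit by the same rescaling.

VOP sets are sums of `rank` random outer products, normalized so the
set's largest spectral norm is one. The bundled three-fixture suite
(low-coupling 8ch; high-coupling 8ch pinned at λ_max = 0.84;
high-coupling 32ch at 0.6, with 8/8/12 full-rank VOPs) spans the regimes
the analysis distinguishes.

What the generator does **not** emulate: electromagnetic realism — no
frequency dependence, no physical VOP compression structure (real VOP
sets come from field simulations and carry an overestimation margin), no
reciprocity constraints, no correlated element phases. Passing tests
therefore demonstrate the correctness and tightness of the worst-case
*computation* under controlled coupling, not the error magnitude of any
physical array; quantitative statements about a specific scanner require
its measured S-parameters and exported VOP set, which the Touchstone and
MAT v7.3 readers ingest directly.

## Problem sizes and determinism

Default test and acceptance runs use phase grids of 12–72 points for
multi-channel sweeps and the full 3600-point grid only for the cheap
single-channel case; instance counts are 20–50 per statistical check.
These sizes were chosen so that each check's statistic is stable at the
asserted tolerance. All randomness flows through explicit integer seeds
(NumPy `default_rng`); solver and oracle are deterministic given their
inputs, and report bundles are byte-stable apart from an isolated
timestamp field.

## Known limitations

* The SDR is an upper bound in principle; its tightness is certified per
  run via the extraction gap rather than proven for every error matrix.
  A large `certificate_gap` (not observed in practice) would mean the
  reported ratio is conservative — the safe direction for safety factors.
* The phase grid can in principle straddle a narrow peak in φ; the
  single-channel closed form suggests 1° resolution is ample for
  coupler-type error matrices, but pathological custom matrices may
  warrant a finer grid.
* Touchstone v2.0 files are rejected, not parsed; noise/digitization
  error sources and coupler frequency response are out of scope.
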