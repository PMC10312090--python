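# Methods

`cswater` implements a complete multi-compartment T2 relaxometry analysis
chain for brain water-fraction mapping: a digital phantom and cohort
simulator, non-central chi magnitude-bias correction, bounded three-pool
nonlinear least-squares fitting with optional spatial regularization,
CSF-distance ROI erosion, and the cohort-level age-association statistics.
This note records the models, the parameters that matter, the numerical
choices, and what the synthetic data do and do not establish.

## Signal model

Each voxel's magnitude at T2-prep time TE is modelled as the sum of three
exponentially decaying water pools,

    S(TE) = A_MW e^(-TE/T2_MW) + A_IEW e^(-TE/T2_IEW) + A_CSF e^(-TE/T2_CSF),

with nonnegative amplitudes and pool T2s boxed to [5, 20] ms (myelin
water), [20, 200] ms (intra/extra-cellular water) and [200, 2000] ms (CSF).
Water fractions are amplitude ratios to the total: MWF + IEWF + CSFF = 1.
Inter-compartment exchange and compartmental T1 weighting are deliberately
not modelled, and the first echo (preparation off) is taken as exactly
TE = 0 with no correction for preparation-pulse imperfection. The default
echo schedule is {0, 7.5, 17.5, 67.5, 147.5, 307.5} ms on a
1.3 × 1.3 × 5 mm³ grid.

With six echoes and six parameters the fit is exactly determined;
identifiability rests on the box constraints and the deterministic
initialization, and the per-voxel residual map lets users detect
problematic voxels. Because the last echo is ~300 ms, the CSF-pool T2 is
only weakly constrained — fractions are reliable well before T2_CSF is.

## Noise model and bias correction

Sum-of-squares combination of n coil channels makes magnitudes non-central
chi with 2n degrees of freedom: M = sqrt(Σ_k x_k² + y_k²), all channels
Gaussian with sd σ, the full signal placed on one channel's real part (any
split with the same noncentrality is equivalent in distribution; the
generator's moments are tested against closed forms). σ is estimated from
background air voxels of the two edge slices at the last echo via the
zero-signal chi mean E[M|0] = σ√2·Γ(n+½)/Γ(n); a single scalar σ is used
(no spatial noise map).

The correction tabulates the exact first moment

    E[M|A] = σ√2 · Γ(n+½)/Γ(n) · ₁F₁(−½; n; −A²/2σ²)

on 2000 points over A/σ ∈ [0, 50] and inverts it by monotone PCHIP
interpolation; measured magnitudes at or below the noise floor E[M|0] map
to 0 (amplitudes are physically nonnegative), and magnitudes beyond the
table use the high-SNR asymptote A = sqrt(m² − (2n−1)σ²). scipy's ₁F₁ has
isolated failure regions for large n; those entries are recomputed by
Gauss–Legendre quadrature of the noncentral-χ² density (the two routes
agree to machine precision elsewhere).

A point correction inverts the moment map, not the noise: below the
many-channel noise floor (≈ 8σ at 32 coils) the per-draw corrected mean
retains a negative residual bias of a few tenths of σ, which is
irreducible for any moment-inverting map. What the correction guarantees —
and what the tests assert — is (i) the corrected mean is strictly less
biased than the raw mean at every SNR and coil count, and (ii) the
tabulated moment is exact, so inverting it at an averaged magnitude
recovers the amplitude to within Monte-Carlo error.

## Fitting

Initialization follows the standard recipe: T2_MW = 10 ms, T2_CSF =
2000 ms, T2_IEW from an ordinary least-squares fit of ln S against the
first four TEs (T2 = −1/slope clamped into [20, 200] ms; nonpositive
signals or a rising slope fall back to 70 ms, a flat signal clamps to
200 ms); amplitudes start at 10% and 90% of S(TE₁) for the myelin and
intra/extra-cellular pools and at S(TE_last) for CSF. All-zero voxels are
flagged unfittable and excluded from maps rather than silently zeroed.

The bounded least-squares problem is solved by L-BFGS-B with analytic
gradients; T2s are optimized in log-space for conditioning (gradient-norm
tolerance 1e-8, at most 500 iterations, no random restarts). A solution is
never accepted uphill from the initialization, so the final objective is
bounded by the initial one by construction. Quality codes distinguish
outside-mask, fitted, unfittable and non-converged voxels, and the number
of voxels with a T2 binding at a pool bound is reported.

Volume fitting with `lambda_laplacian > 0` adds a squared-discrete-
Laplacian penalty over the 6-neighbourhood, computed on coil-normalized
amplitude maps (A divided by the mean first-echo signal in the mask) and
log-T2 maps, with per-axis 1/h² spacing weights in mm and Neumann
(replicate) boundaries — the penalty therefore vanishes exactly on
spatially constant maps. The joint problem is approximated by one
independent-fit pass followed by `n_sweeps` (default 2) Gauss–Seidel
sweeps, each re-solving one voxel with the penalty's exact local quadratic
(the stencils centred at the voxel and its in-mask neighbours). The weight
is unspecified in the source method; the shipped default λ = 100 was
chosen by an L-curve-style calibration on the default phantom (CSFF RMSE
0.061 → 0.023 going from λ = 0 to 100, with ≤10% further gain by λ = 1000)
and applies to all six maps. λ = 0 always reproduces independent per-voxel
fits exactly, which is what the oracle tests use. Because the misfit term
scales with squared signal while the normalized penalty does not, λ is
calibrated for data with S(TE₁) ≈ 1000; rescale λ proportionally to the
squared signal level for other units.

At realistic noise (first-echo SNR 100, 32 coils) the independent fit
shows a positive CSFF skew of roughly +0.03: the last-echo signal sits
near the noise floor and the nonnegativity constraint rectifies noise into
the CSF amplitude. The spatial constraint is the method's answer — with
λ = 100 the uniform-phantom CSFF bias falls below 0.01 after correction,
and stays strictly worse without it.

## ROI erosion

Tissue ROIs (cerebral WM, cortex, deep GM = cerebral GM minus cortex) are
eroded in two stages before averaging. Stage 1 is a 1 mm isotropic erosion
against the ROI's own complement, implemented with a structuring element
containing every voxel offset whose nearest-face distance is under 1 mm;
with 1.3 × 1.3 × 5 mm voxels this removes exactly the in-plane boundary
layer (faces at 0.65 mm) and nothing through-plane (faces at 2.5 mm).
Stage 2 removes voxels too close to any CSF-labelled voxel (ventricles or
subarachnoid space) under an ellipsoidal norm — offsets divided by the
in-plane minimum (1 mm) and through-plane minimum (5 mm) — evaluated with
an anisotropy-scaled Euclidean distance transform. Distances default to
voxel-centre-to-centre with a strict inequality, so a voxel exactly one
5 mm slice from a ventricle voxel is removed; a boundary-to-boundary
variant (subtracting half-voxel extents) is available and is strictly more
aggressive. Erosions that empty a mask warn rather than fail silently.

The erosion sweep reproduces the contamination experiment: cortical mean
CSFF under the uneroded mask and under 1 mm in-plane / {1, 3, 5, 7} mm
through-plane clearances. Note that at 5 mm slice thickness the 1 and
3 mm through-plane criteria cannot remove any voxel centre (the smallest
nonzero through-plane distance is 5 mm); demonstrations that need every
level to bite should use thinner-slice phantoms, as the test suite does
(0.8 mm slices with slice-direction partial-volume contamination).

## Cohort statistics

For each of the nine (ROI × water fraction) outcomes two nested OLS models
are fitted — WF = β₀ + β₁·Age + β₂·Sex + β₃·Volume + ε and the quadratic
variant adding an Age² term — and compared by the extra-sum-of-squares
F-test, F = (RSS_LM − RSS_QM)/(RSS_QM/(n−5)) on (1, n−5) df; the quadratic
model is selected iff p < α (default 0.05). When both models interpolate
exactly (RSS = 0) the parsimonious linear model is kept. The reported age
p-value is the ANOVA p of the Age² term under QM and the Wald p of the Age
coefficient under LM (the alternatives are also emitted); the nine
reported p-values are Benjamini–Hochberg adjusted. Sex is coded 0/1 with
female as reference. ROI volume enters as the externally normalized
(skull-size-scaled) value; the scaling factor is an input
(`normalize_volume` is a plain product), as head-size normalization itself
is external tooling. Repeatability uses Bland–Altman bias ± 1.96·sd limits
(sample sd, ddof = 1); the ventricle-volume/CSFF link uses Spearman rank
correlation with average ranks for ties.

Two scalar conversions connect signal fractions to volume terms:
V_CSF = water_content × CSFF (e.g. 0.83 × 4.0% = 3.3% in cortex,
0.70 × 5.0% = 3.5% in WM), and the compartment-shift arithmetic that
recomputes fractions after changing the intra/extra-cellular water content
alone — reducing 0.90 to 0.76 g/mL in a (0.05, 0.90, 0.05) g/mL voxel
moves IEWF by −1.6 and CSFF by +0.8 percentage points, illustrating that
relative fractions understate absolute water loss.

## Synthetic data: what it does and does not show

The phantom is a concentric six-label head (ventricles, deep GM, WM,
cortical ribbon, subarachnoid CSF, background) built from nested
ellipsoids in physical coordinates with a smooth seed-dependent boundary
ripple; shells are sized so the cortical ribbon survives the default
erosion on grids of 32 × 32 × 16 and larger. Tissue ground truth uses
literature-typical values (WM 10/85/5% at T2 10/70/1500 ms; cortex
5/91/4%; deep GM 6/89.5/4.5%; pure CSF at 2000 ms), configurable.

The cohort generator draws age uniform on [20, 80] y, sex Bernoulli(0.5),
normalized ROI volumes and nine outcomes from per-(ROI, WF) quadratic age
trends plus sex/volume effects and Gaussian residuals (default sd 0.8
percentage points, the order of between-subject scatter in regional WF
measurements), then clips to [0, 1] (warning if >1% of rows clip) and
renormalizes each row to sum to one. Default trends encode midlife-peaked
MWF in all regions, linearly declining IEWF (≈0.7 pp per six decades in
WM, 1.6 pp in cortex), linearly rising CSFF in WM and deep GM, and a
U-shaped cortical CSFF with minimum ≈4% near age 48 rising toward ≈7% at
80, with quadratically enlarging ventricles. A per-subject latent atrophy
factor (standard normal, loading 10 cm³ on ventricle volume and 1
percentage point on each CSFF outcome) couples organ-level and
tissue-level CSF beyond their shared age trends, giving ventricle-volume
versus regional-CSFF Spearman correlations around 0.6 as observed in
ageing cohorts; setting both loadings to zero makes residuals
independent.

What passing tests establish: the estimators are correct on their own
model (round-trip recovery, moment identities, distance semantics pinned
by brute-force oracles, F-test type-I rate at nominal α, ≥80% quadratic
detection under the encoded curvature at n = 60). What they do not
establish: behaviour under Gibbs ringing, B1/flip-angle errors, imperfect
registration, pathology, spatially varying noise, or any real-scanner
deviation from the three-pool model — the phantom contains none of these.
Problem sizes in the shipped tests (phantoms ≤ 32 × 32 × 16, 10⁵-draw
Monte Carlo, 2000 regression replicates) are the package's chosen
desk-scale defaults; all generators accept larger sizes.

## Known limitations

- The Gauss–Seidel smoothing approximates the joint penalized solve; it
  decreases the true joint objective monotonically per voxel update but is
  not run to global convergence.
- The CSF-pool T2 estimate saturates at its bounds frequently at realistic
  SNR (bound hits are counted and reported); interpret T2_CSF maps with
  care, fractions are the robust output.
- Noise estimation assumes a signal-free background; foreground-based
  estimation is out of scope.
- Gibbs correction and registration are accepted as pre-applied inputs.
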