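# Methods

## Model and procedure

The package analyses *graph dynamical systems*: multi-agent systems whose
observable at each frame is a symmetric weighted adjacency matrix
`A_t ∈ R^{m×m}`. The working assumption is Koopman-style: the sequence of
vectorised adjacency matrices evolves, to good approximation, under a
linear operator, so the data decompose as

```
A_t ≈ Σ_j  Z_j · λ_j^t · b_{j,0}
```

with complex eigenvalues `λ_j` (phase → oscillation frequency, modulus →
growth/decay rate), matrix-valued spatial modes `Z_j ∈ C^{m×m}` weighting
node-pair relations, and scalar amplitudes `b_{j,0}` fitted to the first
frame.

Graph DMD estimates this decomposition while preserving the node × node
structure of the snapshots. The order-3 tensor of forward snapshots
(frames `0..τ−1`) is factorised by a tensor-train decomposition — two
successive unfolding SVDs — whose matricised form is `X_mat = M Σ N` with
`M` column-orthonormal over node pairs and `N` row-orthonormal over time.
The shifted tensor (frames `1..τ`) gives `P` and `Q` the same way, with
`Q` absorbing its singular values so `P Q` matricises the shifted data.
The reduced operator

```
F̂ = (Mᵀ P)(Q N⁺) Σ⁻¹
```

is eigendecomposed; each eigenpair `(λ_j, w_j)` with `|λ_j| > 1e−10`
yields a mode `Z_j = unvec((1/λ_j) · P Q N⁺ Σ⁻¹ w_j)`. In exact
arithmetic with negligible truncation this is the compression of
`Y_mat X_mat⁺` onto the column space of `X_mat` in an orthonormal basis,
so the nonzero spectrum coincides with that of exact DMD on the
vectorised snapshots — the property the test suite uses as an independent
oracle. The value of the tensor-train route is that at practical
truncation (`ε = 1e−5`) the basis `M` respects the tensor structure of
the data rather than treating node pairs as anonymous coordinates.

Exact DMD (SVD-truncate `X`, `F̂ = U* Y V Σ⁻¹`, modes
`ψ_j = (1/λ_j) Y V Σ⁻¹ w_j`) is implemented independently as the
baseline feature family and as the oracle half of the dual-route checks.

## From trajectories to adjacency series

Agent positions (5 attackers, 5 defenders, a ball, a fixed goal/"ring";
2-D metres at 25 fps) are first low-pass filtered with a zero-phase
second-order Butterworth at 2 Hz — the analysis band of interest for
tactical motion; faster content is treated as measurement/limb noise. Edge weights are Gaussian kernels of pairwise
distance, `A_ij = exp(−d²/(2σ))`, calibrated through the half-weight
distance: `σ = d½²/(2 ln 2)` with `d½ = 1.5 m` between players (≈ contact
proximity) and `d½ = 6 m` to the ring (court-scale reference). The ball
is not a node; it anchors the slot ordering. Node identity is normalised
by a greedy ball-proximity rule: the two attackers nearest the ball take
slots A1–A2, each further attacker minimises the summed distance to the
attackers already placed, defenders fill D1–D5 identically, and the ring
is slot 11. Ties break on the lowest input agent index (deterministic).
Ordering is recomputed every frame by default; a per-segment variant
(frozen at frame 0) is available because per-frame reordering can inject
discontinuities into the matrix series.

## Windowing, validity and features

Decomposition runs on sliding windows of 50 frames (2 s) with a 25-frame
hop. Modes faster than 2 Hz are discarded *before* validity scoring, so
a window is judged only on the modes that can enter the features. Each
retained mode is scored by the VAF of its single-mode reconstruction,
`VAF_j = 1 − ‖A − Â_j‖_F² / ‖A‖_F²`; a window is valid iff
`max_j VAF_j ≥ 0.01`. Segments with no valid window are excluded and
logged.

Retained modes are normalised to max-abs 1 (amplitude lives in the time
dynamics), symmetrised with their transpose, and reduced to element-wise
moduli. Aggregation is an unweighted mean — within a window over modes
with `Im(λ) ≥ 0` (one representative per conjugate pair, avoiding double
counting), then across valid windows. Amplitude- or VAF-weighted
aggregation would be defensible alternatives; the unweighted mean was
chosen as the least-assuming default and is the only variant the tests
pin down.

Feature families: the aggregated-mode elements selected by a task mask
(defence: 10 D-D + 25 A-D + 5 D-R pairs = 40 features; offence: 10 A-A +
25 A-D = 35, ring excluded), graph-Laplacian eigenvalues of the
aggregated matrix (`L = D − W` on the zeroed-diagonal weights, ascending;
smallest is 0), raw-series summary statistics (mean/max/min per node
pair, 165 features at m = 11), and the exact-DMD spectrum variant, which
is the identical pipeline with exact DMD substituted for Graph DMD.

## Classification and inference

Unpenalised logistic regression (a vanishing ridge `1/C = 1e−8` for
solver stability) on z-scored features, so `exp(coef)` is an
interpretable odds ratio. Evaluation: accuracy and F = 2PR/(P+R) at the
0.5 threshold (P = R = F = 0 when no positives are predicted), ROC-AUC
and precision-recall curves over all thresholds, and five disjoint
stratified test folds from one seeded shuffle, summarised mean ± sd.
Odds ratios with Wald 95% CIs and p-values come from a statsmodels logit
on the standardised design (multivariate by default, univariate as an
option); exact collinearity and non-convergence are flagged per feature
rather than fatal. A thin helper runs the standard
Levene/Kruskal-Wallis/Bonferroni-Wilcoxon battery over per-fold metric
tables; it is deliberately outside the core method.

## Synthetic data: what it emulates and what it does not

`generate_linear_gds` produces tensors that are *exactly* representable
by `2·(#oscillatory) + (#static)` modes: each component contributes
`a ρ^t (S₁ cos(θt+φ) − S₂ sin(θt+φ))` with seeded symmetric `S₁, S₂`,
i.e. ground-truth eigenvalues `ρ e^{±iθ}`, modes `(S₁ ± iS₂)/2` and
amplitudes `a e^{±iφ}`. This is the model class the decomposition
assumes, so recovery there tests correctness, not robustness.

`generate_agent_segment` places teams at an asymmetric arc formation
(ring at origin, attackers at 6 m, defenders at 4 m, ball 0.5 m inside
attacker 1), lets designated pairs modulate their mutual distance
sinusoidally (anti-phase motion along the anchor line), and adds smooth
positional noise — white noise low-passed at 1 Hz and rescaled, so the
jitter lives inside the analysis band like real motion does. The default
dataset (40 segments, 10 s at 25 fps → 9 windows each) differs between
labels only in whether the two defenders nearest the ball (slots D1-D2
under the ordering) oscillate at 0.5 Hz with 0.6 m distance amplitude.
The 0.6 m amplitude keeps slot-ordering margins (~0.3–0.4 m) above the
noise scale so the discriminative pair stays in the same slots.

What passing these tests does *not* show: real tracking data is not a
low-rank linear GDS — formations drift, agents swap assignments, the
ordering changes slots mid-segment, and label-relevant dynamics are not
confined to one pair. Classification performance on the synthetic
dataset (AUC ≈ 1 at these settings) is a correctness check of the
pipeline's plumbing and of the qualitative mechanism (label-specific
pair oscillation → larger aggregated mode element → separable features),
not a performance claim about real collective motion.

## Numerical choices

- TT truncation: per-SVD relative rule, retain `σ_k/σ_1 > ε` (at least
  one direction); reconstruction error ≤ `√2 ε ‖X‖_F`. Rank is
  monotonically non-increasing in ε.
- `N⁺ = Nᵀ` when `N Nᵀ = I` within 1e−8 (true by construction), true
  pseudo-inverse as fallback.
- Eigenvalues with `|λ| ≤ 1e−10` are dropped before mode computation
  (the `1/λ` factor is undefined); exact DMD instead reports them with
  zeroed mode columns.
- Frequencies use the principal log branch: `|arg λ|/(2π Δt)` (one
  physical frequency per conjugate pair), growth `ln|λ|/Δt`.
- Mode ordering: ascending frequency, then descending `|b_{j,0}|`.
- Amplitudes are fitted to the first frame of the decomposed window.
- Vectorisation is column-major everywhere; symmetry of stored slices is
  enforced to 1e−9 and rounding asymmetry in the kernel builder is
  symmetrised away.
- Windows shorter than the window size at segment end are dropped, not
  padded; an all-zero tensor is a degenerate input, not a rank-0 result.

## Problem sizes

The bundled tests and the reproduction script run at desk scale: 11-node
graphs, 250-frame segments, 40-segment datasets, 50 random oracle
tensors with m ≤ 6 and T ≤ 20. The full suite takes well under a minute;
the reproduction script a few seconds. These sizes were chosen as the
smallest at which every property of interest (window arithmetic, 9
windows/segment, stratified 5-fold evaluation) is non-degenerate.

## Known limitations

- Per-frame reordering makes the adjacency series only piecewise smooth;
  occasional slot swaps act as structured noise on the features. The
  per-segment ordering avoids this at the cost of staleness.
- With 50-frame windows and m = 11, the operator is fitted from 49
  snapshot pairs in a 121-dimensional observable space; individual noise
  modes can reach VAF ≈ 0.02, so the 1% validity threshold is a weak
  filter at this window size (it is a calibrated pipeline constant, not
  a noise-optimal detector).
- Odds-ratio inference on 40 features from 40 segments is rank-deficient;
  the multivariate fit flags rather than resolves this. Use the
  univariate mode or larger n for interpretable inference.
- The Wald CIs assume asymptotic normality; separation is flagged, not
  corrected (no Firth penalty).
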