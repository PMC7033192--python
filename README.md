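# graphdmd

Spectral decomposition and classification of dynamic networks from
collective motion.

Many biological and social systems — flocks, pedestrian groups, sports
teams — are naturally described as *graph dynamical systems*: at each
frame the system is a weighted graph whose nodes are agents and whose
edge weights encode pairwise proximity, and the interesting structure
lives in how that graph oscillates, grows and decays over time.
`graphdmd` extracts those dynamics directly. It implements **graph
dynamic mode decomposition (Graph DMD)**: a Koopman-style spectral
analysis of adjacency-matrix time series that uses a tensor-train
decomposition (instead of a plain SVD) to preserve the node × node
structure of each snapshot, decomposing the series as

```
A_t ≈ Σ_{j=1..p}  Z_j · λ_j^t · b_{j,0}
```

where each complex eigenvalue `λ_j` carries a physical frequency
`|arg λ_j| / (2π Δt)` and growth rate `ln|λ_j| / Δt`, each matrix mode
`Z_j ∈ C^{m×m}` shows *which node pairs* participate in that dynamic,
and `b_{j,0}` is the mode's amplitude on the first frame.

Around the decomposition the package provides the full classification
pipeline for two-team trajectory data (ten players, ball, goal):

- **`graphdmd.adjacency`** — zero-phase 2 Hz Butterworth filtering,
  Gaussian-kernel adjacency series (`A_ij = exp(−d²/2σ)`, weight 0.5 at
  1.5 m between players and 6 m to the goal), and greedy ball-proximity
  node ordering into slots A1–A5, D1–D5, R.
- **`graphdmd.spectral`** — TT-SVD, Graph DMD, exact DMD (baseline and
  independent oracle), reconstruction and VAF.
- **`graphdmd.features`** — sliding-window decomposition (50-frame
  windows, 25-frame hop), 2 Hz mode cutoff, VAF-based window validity,
  mode normalisation/symmetrisation/averaging, and four feature
  families (Graph-DMD spectrum, exact-DMD spectrum, Laplacian
  eigenvalues, raw summary statistics).
- **`graphdmd.classify`** — unpenalised logistic regression, accuracy /
  ROC-AUC / F-measure with repeated stratified test folds, per-feature
  odds ratios with Wald intervals.
- **`graphdmd.synth`** — exactly-solvable linear graph dynamical systems
  and labelled two-team trajectory simulations with known discriminative
  structure.

## Worked example

Decompose a noiseless linear graph dynamical system with oscillations at
0.5 and 1.2 Hz, then run the end-to-end classification pipeline on a
synthetic dataset whose two labels differ only in whether the two
defenders nearest the ball oscillate their mutual distance at 0.5 Hz:

```python
import numpy as np
import graphdmd as g

spec = g.LinearGDSSpec(
    m=8,
    components=(g.GDSComponent(0.5), g.GDSComponent(1.2)),
    static_amplitude=1.0,
    dt=0.04, T=60, seed=7,
)
tensor, truth = g.generate_linear_gds(spec)
result = g.graph_dmd(tensor, eps=1e-9)
print("recovered frequencies (Hz):", np.round(result.frequencies_hz, 6))
print("eigenvalue moduli:        ", np.round(np.abs(result.eigenvalues), 6))
recon = g.reconstruct(result, range(tensor.n_frames))
print("reconstruction VAF:       ", round(g.vaf(tensor.values, recon), 9))

segments, _ = g.generate_dataset(20, base_seed=7)
out = g.run_end_to_end(segments, g.PipelineConfig(seed=7))
print(out["summary"])
```

prints

```
recovered frequencies (Hz): [0.  0.5 0.5 1.2 1.2]
eigenvalue moduli:         [1. 1. 1. 1. 1.]
reconstruction VAF:        1.0
               mean        sd
accuracy   0.950000  0.068465
auc        1.000000  0.000000
f_measure  0.955556  0.060858
```

The decomposition recovers the generator's frequencies exactly (0 Hz is
the static component; each oscillation appears once per conjugate pair),
all eigenvalues sit on the unit circle (no growth or decay), and the
five modes reconstruct the series perfectly. Downstream, the D1-D2
element of the aggregated mode matrix separates the two labels, and
held-out classification over five stratified folds is near-perfect.

The same pipeline is available from the shell:

```sh
graphdmd run-all --seed 7 --n-per-label 20 --outdir out/
```

which writes the trajectory CSV, feature table, per-fold metrics JSON,
ROC/PR curves, odds ratios and the fully-resolved configuration.

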