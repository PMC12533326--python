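# gpcca

Probabilistic canonical correlation analysis generalized to two or more
data modalities, with native missing-data handling.

Multi-modal studies — multi-omics cohorts, multi-view image features,
expression plus histology — measure several feature matrices on the same
samples, and in practice many samples lack entries or entire modalities.
`gpcca` integrates R ≥ 2 feature-by-sample matrices through a shared
latent factor model

    X = W Z + U + E,   z_k ~ N(0, I_d),   ε_k ~ N(0, Ψ),

where the stacked data X (m × n) load on d shared factors Z through W, and
the error covariance Ψ is block diagonal — errors may correlate within a
modality but not across modalities.  The model is fitted by an EM
algorithm that conditions on exactly the entries each sample has observed
(no pre-imputation), using the d × d Woodbury matrix
M̃ = (I + W̃ᵀΨ̃⁻¹W̃)⁻¹ and blockwise/Schur-complement inversion so the cost
is driven by the latent dimension and the number of *missing* rows.  The
package provides:

* **Fitting** with ridge shrinkage of the error correlations,
  Ψ_ridge = λΨ̂ + (1−λ)·diag(Ψ̂) (correlation matrix exactly
  λR̂ + (1−λ)I), λ ∈ (0, 1];
* **Embeddings** (posterior latent means, any missingness pattern) and
  **imputation** (observed entries pass through bit-exact);
* **Latent-dimension selection** by consensus over multiple EM starts:
  Louvain clustering (resolution 0.8) of each embedding on a
  shared-nearest-neighbor graph, consensus score
  H = Σ_{i<j} C_ij log₂ C_ij, best initialization by connectivity RMSE;
* **Synthetic benchmarks** (Gaussian/t₃, AR(1)-correlated informative
  features, MCAR and modality-wise MNAR, cross-modality violations) with
  ground truth;
* **ARI/NMI** evaluation and a CLI tying it together.

See `docs/methods.md` for the model, estimator and design details.

## Worked example

```python
import numpy as np
from gpcca import (SimulationSpec, generate_case, FitConfig,
                   fit_with_selection, adjusted_rand_index)

# Six clusters x 100 samples across modalities of 60/120/180 features;
# AR(1)-correlated informative features (rho = 0.7), 20% entries MCAR.
sd = generate_case(SimulationSpec(case="A", rho=0.7, missing_rate=0.2, seed=7))
print(sd.dataset.modality_dims, sd.dataset.n,
      round(1 - sd.dataset.observed_fraction(), 3))

cfg = FitConfig(d=4, lam=2/3, max_iter=150, tol=1e-5, seed=0)
model, labels, d_star, states = fit_with_selection(
    sd.dataset, candidates=[4, 6, 8], B=5, config=cfg)
print("selected d:", d_star)
print("consensus scores:", {d: round(s.score, 2) for d, s in states.items()})
print("ARI vs truth:", round(adjusted_rand_index(labels, sd.labels), 3))
```

Output:

```
(60, 120, 180) 600 0.2
selected d: 8
consensus scores: {4: -10753.29, 6: -96.57, 8: 0.0}
ARI vs truth: 0.996
```

The selector tries 4, 6 and 8 factors with five EM starts each.  At four
factors the five runs disagree wildly (a large negative consensus score);
at eight factors all five initializations produce the identical partition
(score 0), so d = 8 is selected, and the winning run's Louvain partition
recovers the six simulated clusters almost perfectly (ARI 0.996 against
the ground-truth labels).  The fitted model's `embedding` (8 × 600) and
`impute(...)` completions are then available for downstream analysis.

The same pipeline from the shell:

```sh
gpcca simulate --case A --rho 0.7 --missing-rate 0.2 --seed 7 --out-dir sim
gpcca select-d --modality sim/modality1.tsv --modality sim/modality2.tsv \
               --modality sim/modality3.tsv --candidates 4,6,8 --B 5 \
               --lam 0.667 --seed 0 --out-dir run
gpcca evaluate run/cluster_labels.tsv sim/labels.tsv
```

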