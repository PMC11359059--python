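# strokeclust

Federated consensus clustering of upper-limb motion features for
unsupervised post-stroke severity staging.

## The problem

Clinical stroke assessment scores such as the Fugl–Meyer Assessment for the
upper extremity (FMA-UE, 0–66, with scores below 29 denoting severe
impairment) require an expert rater. Motion recordings — 3-D positions of
the hand, arm and trunk captured by wearable IMUs or marker cameras while a
patient performs reach-and-grasp tasks — carry enough signal to stage
severity without labels: stroke survivors compensate for impaired arm
function with trunk motion, so *trunk displacement* increases with
severity. Patient recordings are also privacy-sensitive and scattered
across rehabilitation centers, which motivates a federated design where raw
data never leaves its center.

`strokeclust` implements that pipeline end to end for researchers in
rehabilitation analytics:

1. **Preprocessing** — zero-phase second-order Butterworth low-pass
   filtering (10 Hz default), optional double differentiation to linear
   acceleration, magnitude spectra of each channel/axis via the real DFT,
   per-subject pooling and column z-scoring.
2. **Base ensemble** — eight clustering methods (fuzzy c-means, k-means,
   a linear SOM, Gaussian mixtures, DBSCAN, Ward agglomerative, spectral,
   OPTICS) under one seeded contract.
3. **Consensus** — the co-association matrix CM (mean of the per-partition
   binary connectivity matrices) is factorized as

   CM ≈ N L Nᵀ,  N ∈ ℝ₊^{n×k}, L ∈ ℝ₊^{k×k}

   by alternating multiplicative updates
   N ← N ⊙ (CM N L) ⁄ (N NᵀCM N L) and
   L ← L ⊙ (NᵀCM N) ⁄ (NᵀN L NᵀN),
   with seeded restarts; hard consensus labels are the row argmax of N.
4. **Federation** — subjects are split across M clients; each client runs
   the full local pipeline and transmits only cluster centers, per-cluster
   mean trunk displacement, severity ranks and labels. The server aligns
   clusters by severity rank and aggregates centers with FedAvg
   (W_r = Σ_c n_c/N · center_{c,r}), then labels every subject by its
   nearest global center.
5. **Evaluation** — cluster-to-severity mapping by ascending trunk
   displacement (lowest = mildest), support-weighted
   accuracy/precision/recall/F against FMA-derived reference categories,
   and CompT (slowest client) + CmT (aggregation) timing bookkeeping.

A seeded synthetic cohort generator with known group structure makes every
stage testable without any external recordings.

## Worked example

```python
import numpy as np
from strokeclust import (
    CohortConfig, FederationConfig, assign_reference_fma, default_pipeline,
    fma_category, generate_cohort, run_federated, score,
    subject_trunk_displacement, to_frequency_features,
)

config = CohortConfig(n_subjects_per_group=20, seed=1)   # 3 groups, 60 subjects
trials, groups = generate_cohort(config)
trials = assign_reference_fma(trials, config)

features = to_frequency_features(trials)                  # 60 x 120, z-scored
td = subject_trunk_displacement(trials, config.trunk_channel)

fed = FederationConfig(n_clients=3, k=3,
                       pipeline=default_pipeline(3, seed=1, n_restarts=20),
                       partition_seed=1)
run = run_federated(features, td, fed)

reference = [fma_category(next(t.fma_score for t in trials if t.subject_id == s), 3)
             for s in features.row_ids]
report = score(run.labels, reference)
print(f"accuracy {report.accuracy:.3f}  F {report.f_score:.3f}")
print(f"CompT {run.timing.comp_time_s:.3f}s  CmT {run.timing.comm_time_s:.5f}s")
```

Output:

```
accuracy 0.917  F 0.915
CompT 0.306s  CmT 0.00006s
```

92% of the 60 subjects land in their FMA-consistent severity level (each
of the three clients sees only 20 subjects; accuracy rises toward 99% at
150 subjects — see the acceptance script below). The federation's cost is
dominated by the slowest client's local pipeline (CompT), with server
aggregation (CmT) negligible.

The same workflow is available from a shell via the `strokeclust` CLI
(`simulate`, `preprocess`, `cluster`, `consensus`, `federate`, `evaluate`);
run `strokeclust --help`.

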