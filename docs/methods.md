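# Methods

## Model and procedure

`strokeclust` stages post-stroke severity without labels by combining an
ensemble of clusterings of frequency-domain motion features into a single
consensus partition, running that pipeline independently on each of M
clients, and aggregating only cluster-level summaries on a server.

**Consensus model.** Given t base partitions of n subjects, each partition
b yields a binary connectivity matrix (entry 1 where two subjects share a
cluster); the co-association matrix CM is their element-wise mean, so
CM_ij is the fraction of methods that co-cluster i and j. CM is
approximated by the symmetric tri-factorization CM ≈ N L Nᵀ with N (n×k)
and L (k×k) nonnegative, minimizing ‖CM − N L Nᵀ‖²_F. In the ideal case N
is a cluster indicator matrix and L the cluster-interaction matrix; hard
consensus labels are the row argmax of N.

**Federation.** Horizontal: clients hold disjoint subjects with a shared
feature space. Each client transmits a `ClientSummary` — k cluster centers
in feature space, per-cluster mean trunk displacement, the implied severity
ranks, local labels, and its wall time — never raw feature rows (the
aggregation function accepts only these summaries, and a test asserts the
contract structurally). The server aligns cluster r on every client by
severity rank and computes FedAvg centers W_r = Σ_c (n_c/N) center_{c,r}
in a single aggregation round; the global centers then label every subject
by nearest Euclidean center. With M = 1 this reduces bit-for-bit to the
centralized pipeline, because the partition preserves canonical row order
and all clients share one pipeline configuration.

**Severity semantics.** Trunk displacement (TD) is the compensatory-motion
proxy: per step s past a 10-sample baseline window,
TD(s) = |x_s − x̄| + |y_s − ȳ| + |z_s − z̄| with (x̄, ȳ, z̄) the per-axis
baseline mean. Absolute deviations are used so opposite lean directions
cannot cancel and TD is a nonnegative magnitude; multi-marker trunks
(camera rigs) average TD across markers. The cluster with the lowest mean
TD of its members is the mildest level, ascending from there.

## Multiplicative updates, damping and the safeguard

The alternating ratio updates

    N ← N ⊙ (CM N L) / (N NᵀCM N L + ε)
    L ← L ⊙ (NᵀCM N) / (NᵀN L NᵀN + ε)

(the L step using the already-updated N) have the property that any point
where both ratios equal 1 — in particular an exact factorization with
orthonormal N — is stationary. The plain ratio step, however, is not a
guaranteed descent step for the *symmetric* factorization: on unstructured
random matrices it measurably overshoots and the objective can rise
transiently. `update_step` therefore exposes an `exponent` parameter: the
ratio is raised to `exponent` before multiplying, which leaves every fixed
point unchanged while shrinking the step. The fitter defaults to the
square-root step (`damping = 0.5`), the standard convergent choice for
symmetric factorizations, and additionally safeguards each iteration: if a
step still increases the objective, the exponent is halved and the step
retried (as the exponent → 0 the update tends to the identity along a
descent direction away from stationary points, so the backtracking
terminates); if no descent is found the run is declared converged. The
resulting objective traces are non-increasing, which the test suite asserts
at 1e−9 relative tolerance over 50 random matrices.

The orthogonality constraint NᵀN = I that characterizes the ideal
indicator solution is treated as soft: it is encouraged by the denominator
structure of the updates and reported as the diagnostic
`orthogonality_gap` = ‖NᵀN − I‖_F, never enforced by projection (any
projection scheme would change the update semantics).

**Initialization and restarts.** N starts from the indicator matrix of a
k-means partition of CM's rows (single random-init run per restart seed,
so restarts genuinely differ) plus a uniform 0.2 offset — multiplicative
updates can never revive an exactly-zero entry, so strict positivity at
the start matters; L starts from NᵀCM N normalized by the column-sum outer
product. `n_restarts` seeded restarts (default 100, the variance-reduction
protocol at study scale; smaller values are used in tests and the
acceptance script where the consensus structure is strong) keep the lowest
final objective. Empty clusters after argmax are repaired by donating the
point with the weakest assignment margin from a cluster with ≥ 2 members.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| filter order / cutoff | 2 / 10 Hz | Butterworth low-pass for 60 Hz wearable data (20 Hz for 200 Hz camera data); applied forward-backward (zero phase), which squares the magnitude response — movement analysis cannot tolerate phase lag |
| `n_bins` | 8 | DFT magnitude bins kept per channel-axis; with 5 channels × 3 axes this gives 120 features. One bin reproduces the 15 (wearable) / 27 (camera) channel-axis predictor counts |
| `k` | 2 or 3 | number of severity levels |
| MNMF `tol` / `max_iter` / `eps` | 1e−6 / 500 / 1e−10 | relative-objective stop, iteration cap, denominator stabilizer |
| `damping` | 0.5 | update-ratio exponent (see above); 1.0 recovers the plain rule |
| FMA boundaries | 29 (severe), 43 (mild/moderate) | 29 is the clinically anchored severe cutoff; 43 is an assumption, config-exposed |
| DBSCAN/OPTICS `eps` | 0.5 × median pairwise distance | data-scaled default; these methods ignore k, their noise points are absorbed into the nearest found cluster and heterogeneous cluster counts are tolerated by the consensus layer |

## Synthetic cohorts: what they emulate and what they do not

The generator emulates the statistical skeleton of reach-and-grasp
recordings: per-subject trials (4 tasks × 3 repetitions by default) of
multi-channel 3-D trajectories at 60 Hz, a dominant movement frequency
(1.5 Hz), additive Gaussian sensor noise (sd 0.05 length units), and —
the severity mechanism — trunk-channel oscillation whose amplitude is
strictly increasing across severity groups (defaults 1/2/4). Non-trunk
channels carry task-dependent motion *common to all groups*, so group
recovery must come through trunk-linked features, mirroring the
displacement-based labeling premise. Reference FMA-UE scores are drawn
per subject from group bands (severe < 29; for three groups, moderate
29–43 and mild 43–66, matching the default categorization boundaries).

It does **not** emulate biomechanically realistic limb kinematics, sensor
drift or soft-tissue artifacts, marker occlusion, inter-subject movement
idiosyncrasies, or any within-group distribution of compensation beyond
i.i.d. noise around a fixed amplitude. Passing recovery tests therefore
shows that the pipeline recovers severity structure *when trunk
compensation separates groups beyond the noise*, not that it would on any
particular clinical dataset.

Determinism: subject i draws all noise from `default_rng(seed + i)`, so
cohorts are reproducible and extensible without reshuffling existing
subjects; reference scores use an offset seed stream per subject.

## Numerical and design choices

- **Zero-phase filtering** (forward–backward) is used although the
  application mode is a free choice; effective attenuation is the squared
  single-pass response (−6 dB at cutoff).
- **Acceleration** is the central second difference
  (p_{t+1} − 2p_t + p_{t−1})·fs² — exact for quadratics — with one-sided
  second differences at the endpoints to keep time alignment.
- **Per-subject pooling**: trial feature vectors are averaged per subject
  before z-scoring, one row per subject. Zero-variance columns are left at
  0 after centering rather than raising.
- **Ties** everywhere resolve to the lowest index (argmax hardening of
  fuzzy memberships, consensus label argmax, severity ranking, global
  assignment — where the lower index is the milder cluster).
- **Client order**: FedAvg iterates summaries sorted by client id, so
  aggregation is exactly invariant to arrival order.
- **Timing**: CompT is the maximum per-client wall time (clients are
  logically parallel; execution is serial, which the purity and
  order-invariance contracts make equivalent), CmT the aggregation time,
  total = CompT + CmT.
- **Exhaustive method-subset search** enumerates all non-empty subsets of
  the pool (≤ 255), scoring each subset's consensus either by stability
  (mean adjusted Rand agreement between consensus labels and the subset's
  partitions) or against reference labels (Hungarian-aligned accuracy);
  ties prefer the smaller, then lexicographically earlier, subset.

## Problem sizes used in tests and the acceptance script

The test suite runs cohorts up to 300 subjects (100 per group, 5 clients,
20 seeds) for severity-group recovery, 50 random 30×30 matrices for descent
verification, and 60-point consensus-recovery problems over 10 seeds; the
acceptance script uses a 150-subject cohort with five clients and
20-restart consensus fits. These sizes give stable statistics at desk
scale; all accept a seed and scale linearly.

## Known limitations

- Severity-rank alignment before FedAvg assumes every client's clusters
  order consistently by trunk displacement; with very small clients or
  overlapping groups a client can rank a mixed cluster inconsistently,
  degrading the global centers.
- A single aggregation round is performed; there is no iterative
  federated refinement, client dropout handling, or secure aggregation.
- The factorization objective is non-convex; restarts mitigate but do not
  eliminate local minima.
- Density methods enter the consensus through an explicit noise-absorption
  rule; their hyperparameters are data-scaled heuristics, not tuned.
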