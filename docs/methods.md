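# Methods

## Scope and model

`brainstates` implements a four-stage analysis of parcellated resting-state
BOLD data: detection of recurring phase-locking states (LEiDA), per-subject
state-dynamics summaries (fractional occupancy, transition probabilities),
optimal-control energies of state transitions on structural connectomes,
and SVD-based PLS linking those features to behavior. All stages operate on
plain delimited-text matrices plus a subject manifest; a synthetic-cohort
generator with planted ground truth makes the whole chain testable without
any restricted data.

## LEiDA stage

**Filtering.** A 2nd-order Butterworth band-pass (default 0.01–0.1 Hz,
sampling interval 1.97 s) applied forward–backward (`sosfiltfilt`). The
band limits come from standard resting-state practice; zero-phase filtering
is essential because the next step extracts instantaneous phase. Series
shorter than the filter warm-up (3× the effective impulse-response length)
are rejected rather than padded.

**Phase and coherence.** Instantaneous phase is the angle of the analytic
signal (Hilbert transform). The phase-coherence matrix at time t has entries
cos(θᵢ − θⱼ); it is symmetric with unit diagonal and entries in [−1, 1] by
construction. Each frame is summarised by the unit eigenvector of its
largest eigenvalue.

**Sign convention.** Eigenvectors are flipped so that their mean is ≤ 0
(the majority of regions load negatively); an exactly zero mean is broken
by forcing the first element ≤ 0. This makes the positive entries the
minority "active community", which is what the state-naming rule inspects.
A degenerate top eigenvalue (multiplicity > 1 within 1e-10 relative) keeps
the deterministic LAPACK choice and emits a warning.

**Edge handling.** The analytic signal has endpoint transients, so pooling
discards each subject's first and last frame by default. `keep_edges=True`
retains all frames; the study-scale count of 197 × 261 = 51,417 pooled
eigenvectors is obtained under that flag. Both behaviours are first-class
because either convention is defensible and published counts imply no
discard.

**Clustering and model selection.** k-means (Euclidean distance, k-means++
initialisation, 50 restarts, 300 iterations, tolerance 1e-6, seeded) is run
for each k in the search range (default 2–20). Three validity indices are
computed per k — Dunn's index (min inter-cluster pair distance / max
intra-cluster diameter, zero diameters replaced by machine epsilon), mean
silhouette (singletons contribute 0), and Calinski–Harabasz. The indices
need not agree, so each ranks the candidate k values (rank 1 = best) and
the k with the lowest mean rank wins, ties going to the smallest k — a
symmetric aggregation that privileges no single index. Fitted states are
renumbered by descending pooled occupancy, matching the field convention
that state 1 is the most frequent (typically globally coherent) state.
Centroids are reported unit-normalised and sign-fixed like eigenvectors;
frame assignment (and `LeidaStates.predict`) uses the raw k-means centroids
so labels stay consistent with the fitted partition. Assignment ties go to
the lowest state index.

**State naming.** Each state is named for the reference network maximising
the sum of positive centroid values over its regions; a centroid with all
entries of one sign carries no community structure and is named "Global
Coherence". Ties break alphabetically.

## State dynamics

Fractional occupancy is the empirical state histogram divided by sequence
length (sums to 1 by construction). The transition-probability matrix is
the maximum-likelihood estimate from consecutive pairs within a subject —
pairs never span subjects, no pseudocounts. A source state a subject never
leaves from yields an all-zero row flagged `visited=False`; such subjects
are excluded listwise from downstream PLS unless uniform imputation
(row = 1/K) is explicitly requested, because imputation would fabricate
dynamics the data do not contain.

## Control energy

Connectomes are consensus-thresholded (edge kept iff nonzero in ≥ 50% of
subjects, boundary inclusive) and normalised as A_norm = A/(λ_max + c) − I
with c = 1, placing the top eigenvalue at −c/(λ_max + c) < 0 so free
dynamics decay. The optimal-control problem

minimise ∫₀ᵀ (xᵀ S x + ρ uᵀ u) dt  s.t.  ẋ = A_norm x + B u, x(0) = x0, x(T) = xf

with B = S = I (uniform full control set, full-trajectory penalty) and
defaults ρ = 1, T = 1 is solved through Pontryagin's conditions: u =
−Bᵀp/(2ρ) and the linear Hamiltonian system in (x, p). The unknown initial
costate follows from the partitioned matrix exponential of the Hamiltonian
over [0, T]; the boundary solve uses a pivoted factorisation and warns when
its condition number exceeds 1e10. Trajectories are rolled out on a uniform
grid (default 1001 points) by repeated application of the per-step matrix
exponential, and per-region energies ∫ u_i² dt are integrated by composite
Simpson quadrature. Solutions with terminal reconstruction error above
1e-6 raise instead of returning silently wrong energies.

Defaults c = 1 and T = 1 follow the conventions of widely used network
control toolboxes; both are parameters, as is an optional binarisation of
the source/target centroids (positive entries → 1) since either convention
appears in the literature. Tests verify agreement with an independent
discretized-control oracle (equality-constrained QP over piecewise-constant
controls, exact zero-order-hold discretization, trapezoid trajectory
quadrature; converges at O(dt²)) to 1e-4 relative on systems up to N = 4,
node-permutation equivariance to 1e-9, and stability of per-region energy
rankings across ρ ∈ {0.5, 1, 2}.

## PLS

Behavioral PLS decomposes the Q×P Pearson correlation matrix between the
behavior block and the brain block (correlation rather than covariance, the
standard behavioral variant). Mean-centered PLS decomposes the
column-centered matrix of group means (unweighted across groups).
Brainscores are z-scored (behavioral) or centered (mean-centered) data
projected on the brain saliences.

Inference: LV significance by permuting the behavior/group rows and
comparing singular values per LV directly (no rotation), with the +1
smoothed p-value (1 + #exceed)/(1 + n_perm), never exactly 0. Feature
reliability by bootstrap (resampling within groups when grouped): each
resample's saliences are aligned to the original by an orthogonal
Procrustes rotation before the standard error is taken, which removes axis
reflection/reordering artifacts; BSR = salience / bootstrap SE, flagged
reliable at |BSR| ≥ 2 (≈95% normal theory). A bootstrap SE of exactly 0
(possible when P = 1 or a feature is deterministic) yields an unbounded BSR
that is flagged reliable with a warning. Resamples that produce a
zero-variance column are redrawn (10 attempts, then error). Group
brainscore CIs are 95% percentile intervals over within-group bootstrap
resamples. Cross-model salience similarity is the cosine between salience
vectors with a permutation null built by refitting the comparison model
under permuted behavior. Resampling iteration defaults are 1000 each.

## Synthetic cohorts

The generator emulates exactly the statistical structure the pipeline
assumes: a Markov chain over K states, regional signals that are sinusoids
at a single carrier frequency (default 0.05 Hz, mid-passband) with a phase
offset of 0 or π according to the sign of the active state's pattern, and
additive white Gaussian noise (default sd 0.3 against unit signal
amplitude). The phase-coherence matrix of a noiseless frame is then the
rank-one outer product of the sign pattern, so the leading eigenvector
equals the planted pattern (entries ±1/√N, minority positive) exactly —
the planted sequence is a sharp oracle for the recovered one. State
switches land on sample boundaries.

Defaults mimic study scale — 218 regions, 261 timepoints, sampling
interval 1.97 s — and all are parameters. Two defaults were fixed by
simulation before the test suite was frozen:

* **Dwell time.** Self-transition probability 0.98 (mean dwell ≈ 50 TR,
  exchangeable chain). Filter ringing and Hilbert transients corrupt a few
  frames around each planted switch; this dwell keeps those frames a small
  fraction of the series so that recovered/planted agreement reflects the
  method rather than boundary effects. Real resting-state dwell times are
  considerably shorter; the generator is an oracle testbed, not an
  empirical model of dwell statistics.
* **Behavior noise.** behavior = FO · w + N(0, 0.8), giving LV1 detection
  power ≈ 0.8 at n = 100 under the default loadings. Default loadings are
  zero-mean across states because FO lives on the simplex: only the
  centered component of a loading vector is identifiable, and a zero-mean
  choice makes the planted direction exactly the detectable one.

Connectomes are modular Bernoulli graphs (4 modules, within-density 0.6,
between-density 0.15, uniform weights) redrawn until connected. What the
generator does **not** emulate: hemodynamics, 1/f and physiological noise
spectra, spatial autocorrelation, realistic dwell-time distributions, or
geometry-constrained connectomes. Passing tests therefore demonstrate
correctness of the estimators under their own assumptions, not performance
on real fMRI.

## Problem sizes in tests and the acceptance script

The study-scale pooled count (197 × 261 = 51,417) is computed at 60
regions, since the count depends only on subjects × timepoints. The
planted-state recovery run uses the full 20 × 218 × 261 default cohort with
k searched over 2–6 and 20 restarts; the library defaults (2–20, 50
restarts) are unchanged. PLS type-I calibration uses 200 null replicates ×
500 permutations in the acceptance script and 120 × 300 in the test suite.
Determinism is verified byte-for-byte on a 6-subject cohort.

## Known limitations

* The optimal-control solve uses a dense 2N×2N matrix exponential —
  comfortable at N ≈ 218, not intended for N ≫ 10³.
* Mean-centered PLS brainscore CIs are percentile bootstrap; no BCa
  correction.
* The validity-index search computes a full pairwise distance matrix once
  per fit (memory O(n²) in pooled frames); at the full 51,417-frame scale
  silhouette/Dunn evaluation would need a chunked implementation.
* Singular-value-based permutation tests are slightly conservative for
  later LVs; only LV1 calibration is asserted.
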