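"""Synthetic cohorts with planted ground truth.

Every downstream stage (state detection, occupancy/transition statistics,
control energy, PLS) is exercised on data generated here, where the latent
state sequence, the phase-locking patterns, the connectome and the
brain-behavior loadings are all known exactly.

Construction: regional signals are sinusoids at a single carrier frequency
inside the analysis passband, with a per-region phase offset of 0 or pi
according to the sign of the active state's planted pattern. The
phase-coherence matrix of such a frame is the rank-one outer product of the
sign vector, so its leading eigenvector equals the planted pattern up to
sign -- the planted sequence is an exact oracle for the recovered one.
State switches land on sample boundaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GroundTruth",
    "SubjectRecord",
    "BoldTimeSeries",
    "Cohort",
    "generate_state_patterns",
    "generate_state_sequence",
    "generate_bold",
    "generate_sc",
    "generate_behavior",
    "generate_cohort",
    "write_cohort",
    "default_markov",
]

#: Reference resting-state network names used to label synthetic regions.
NETWORK_NAMES = (
    "Visual",
    "Somatomotor",
    "DorsalAttention",
    "VentralAttention",
    "Limbic",
    "Frontoparietal",
    "DefaultMode",
)

# Calibrated defaults (see docs/methods.md): mean dwell ~50 TR keeps
# filter/Hilbert switch transients a small fraction of frames; behavior
# noise gives detection power ~0.8 at n=100.
DEFAULT_STAY_PROB = 0.98
DEFAULT_BEHAVIOR_NOISE_SD = 0.8


@dataclass
class BoldTimeSeries:
    """One subject's regions x timepoints signal with its sampling interval (s)."""

    subject_id: str
    data: np.ndarray
    sampling_interval: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D regions x timepoints matrix")
        if not np.isfinite(self.data).all():
            raise ValueError("data contains non-finite values")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass
class SubjectRecord:
    subject_id: str
    age: float
    behavior: float
    group: str

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError("age must be positive")


@dataclass
class GroundTruth:
    """Planted parameters of a synthetic cohort.

    state_patterns : (K, N) unit row vectors, the leading-eigenvector targets
    markov         : (K, K) row-stochastic state generator
    loadings       : linear coefficients mapping subject features to behavior
    noise_sd       : additive Gaussian noise sd on the BOLD channels
    seed           : master seed of the cohort
    """

    state_patterns: np.ndarray
    markov: np.ndarray
    loadings: np.ndarray
    noise_sd: float
    seed: int
    behavior_noise_sd: float = DEFAULT_BEHAVIOR_NOISE_SD

    def __post_init__(self) -> None:
        self.state_patterns = np.asarray(self.state_patterns, dtype=float)
        self.markov = _validate_markov(self.markov)
        self.loadings = np.asarray(self.loadings, dtype=float)
        norms = np.linalg.norm(self.state_patterns, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-10):
            raise ValueError("state_patterns rows must have unit Euclidean norm")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class Cohort:
    subjects: list[SubjectRecord]
    timeseries: dict[str, BoldTimeSeries]
    connectomes: dict[str, np.ndarray]
    state_sequences: dict[str, np.ndarray]
    region_networks: list[str]
    ground_truth: GroundTruth

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]


def _validate_markov(markov) -> np.ndarray:
    markov = np.asarray(markov, dtype=float)
    if markov.ndim != 2 or markov.shape[0] != markov.shape[1]:
        raise ValueError("markov must be a square matrix")
    if (markov < 0).any():
        raise ValueError("markov entries must be non-negative")
    if not np.allclose(markov.sum(axis=1), 1.0, atol=1e-12):
        raise ValueError("markov rows must sum to 1")
    return markov


def default_markov(n_states: int, stay_prob: float = DEFAULT_STAY_PROB) -> np.ndarray:
    """Exchangeable chain: stay with `stay_prob`, otherwise jump uniformly."""
    if not 0 <= stay_prob <= 1:
        raise ValueError("stay_prob must be in [0, 1]")
    if n_states == 1:
        return np.ones((1, 1))
    off = (1.0 - stay_prob) / (n_states - 1)
    markov = np.full((n_states, n_states), off)
    np.fill_diagonal(markov, stay_prob)
    return markov


def generate_state_patterns(
    n_regions: int,
    n_states: int,
    seed: int | np.random.Generator | None = None,
    positive_fraction: float = 0.3,
) -> np.ndarray:
    """Draw K well-separated sign patterns over N regions, unit-normalised.

    A minority of regions is positive in each state (the 'active community'),
    so the majority-negative eigenvector sign convention returns the pattern
    itself rather than its negation.
    """
    rng = np.random.default_rng(seed)
    if not 0 < positive_fraction < 0.5:
        raise ValueError("positive_fraction must be in (0, 0.5)")
    n_pos = max(1, int(round(positive_fraction * n_regions)))
    patterns = np.full((n_states, n_regions), -1.0)
    for k in range(n_states):
        # disjoint-leaning communities: cycle a block, then jitter
        idx = rng.permutation(n_regions)[:n_pos]
        patterns[k, idx] = 1.0
    patterns /= np.sqrt(n_regions)
    return patterns


def generate_state_sequence(
    markov,
    n_timepoints: int,
    seed: int | np.random.Generator | None = None,
    init: int | None = None,
) -> np.ndarray:
    """Simulate a Markov state sequence (integers 1..K).

    `init` is a 1-based start state; if omitted the start is drawn from the
    chain's stationary distribution.
    """
    markov = _validate_markov(markov)
    if n_timepoints < 1:
        raise ValueError("n_timepoints must be >= 1")
    rng = np.random.default_rng(seed)
    k = markov.shape[0]
    if init is None:
        stat = stationary_distribution(markov)
        state = rng.choice(k, p=stat)
    else:
        if not 1 <= init <= k:
            raise ValueError("init must be in 1..K")
        state = init - 1
    seq = np.empty(n_timepoints, dtype=int)
    seq[0] = state
    # draw all uniforms up front for speed; invert each row's CDF
    cdf = np.cumsum(markov, axis=1)
    u = rng.random(n_timepoints - 1)
    for t in range(1, n_timepoints):
        state = int(np.searchsorted(cdf[state], u[t - 1], side="right"))
        state = min(state, k - 1)  # guard against cdf[-1] = 1 - eps
        seq[t] = state
    return seq + 1


def stationary_distribution(markov) -> np.ndarray:
    markov = _validate_markov(markov)
    vals, vecs = np.linalg.eig(markov.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def generate_bold(
    sequence: np.ndarray,
    patterns: np.ndarray,
    sampling_interval: float = 1.97,
    carrier_freq: float = 0.05,
    noise_sd: float = 0.3,
    seed: int | np.random.Generator | None = None,
    subject_id: str = "synthetic",
) -> BoldTimeSeries:
    """Band-limited oscillatory signals realising a planted state sequence.

    Regions sharing the active pattern's sign oscillate in phase at
    `carrier_freq`; opposite-sign regions are in antiphase. Additive white
    Gaussian noise with sd `noise_sd` (signal amplitude is 1).
    """
    sequence = np.asarray(sequence, dtype=int)
    patterns = np.asarray(patterns, dtype=float)
    if patterns.ndim != 2:
        raise ValueError("patterns must be (K, N)")
    k, n = patterns.shape
    if sequence.min() < 1 or sequence.max() > k:
        raise ValueError("sequence states must be in 1..K")
    nyquist = 0.5 / sampling_interval
    if not 0 < carrier_freq < nyquist:
        raise ValueError(
            f"carrier_freq must lie in (0, {nyquist:.4g}) Hz for this sampling interval"
        )
    rng = np.random.default_rng(seed)
    t = np.arange(sequence.size) * sampling_interval
    phase = 2.0 * np.pi * carrier_freq * t  # global carrier
    signs = np.where(patterns[sequence - 1] >= 0, 1.0, -1.0)  # (T, N)
    data = signs.T * np.cos(phase)[None, :]
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, size=data.shape)
    return BoldTimeSeries(subject_id, data, sampling_interval)


def generate_sc(
    n_regions: int,
    modules: int | list[int] = 4,
    intra_density: float = 0.6,
    inter_density: float = 0.15,
    weight_scale: float = 1.0,
    seed: int | np.random.Generator | None = None,
    max_retries: int = 100,
) -> np.ndarray:
    """Modular weighted connectome: symmetric, non-negative, zero diagonal.

    Edges are Bernoulli with within-module probability `intra_density` and
    between-module probability `inter_density`; weights are uniform on
    (0, weight_scale] so present edges are strictly positive. Redraws until
    connected (up to `max_retries`).
    """
    if n_regions < 2:
        raise ValueError("n_regions must be >= 2")
    if not (0 <= intra_density <= 1 and 0 <= inter_density <= 1):
        raise ValueError("densities must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if isinstance(modules, int):
        assignment = np.repeat(np.arange(modules), int(np.ceil(n_regions / modules)))[:n_regions]
    else:
        assignment = np.asarray(modules)
        if assignment.size != n_regions:
            raise ValueError("module assignment length must equal n_regions")
    same = assignment[:, None] == assignment[None, :]
    p = np.where(same, intra_density, inter_density)
    iu = np.triu_indices(n_regions, k=1)
    for _ in range(max_retries):
        present = rng.random(iu[0].size) < p[iu]
        w = rng.uniform(0.0, weight_scale, size=iu[0].size)
        w = np.where(present, np.maximum(w, 1e-12 * weight_scale), 0.0)
        a = np.zeros((n_regions, n_regions))
        a[iu] = w
        a = a + a.T
        if _is_connected(a):
            return a
    raise RuntimeError(
        f"could not draw a connected graph in {max_retries} tries "
        f"(intra={intra_density}, inter={inter_density})"
    )


def _is_connected(a: np.ndarray) -> bool:
    from scipy.sparse.csgraph import connected_components

    n_comp, _ = connected_components(a > 0, directed=False)
    return n_comp == 1


def generate_behavior(
    features: np.ndarray | pd.DataFrame,
    loadings: np.ndarray,
    noise_sd: float = DEFAULT_BEHAVIOR_NOISE_SD,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """behavior = features @ loadings + N(0, noise_sd)."""
    x = np.asarray(features, dtype=float)
    w = np.asarray(loadings, dtype=float)
    if x.ndim != 2:
        raise ValueError("features must be 2-D (subjects x features)")
    if w.shape != (x.shape[1],):
        raise ValueError(
            f"loadings length {w.shape} does not match {x.shape[1]} feature columns"
        )
    rng = np.random.default_rng(seed)
    y = x @ w
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    return y


def _default_loadings(n_states: int, scale: float = 1.0) -> np.ndarray:
    """Zero-mean loadings on fractional occupancies.

    FO vectors live on the simplex, so only the centred component of a
    loading vector is identifiable; a zero-mean default makes the planted
    direction exactly the detectable one.
    """
    w = np.zeros(n_states)
    w[0] = 1.0
    w[1] = -1.0
    if n_states > 2:
        w -= w.mean()
    return scale * w / np.linalg.norm(w)


def generate_cohort(
    n_subjects: int = 20,
    n_regions: int = 218,
    n_timepoints: int = 261,
    n_states: int = 3,
    sampling_interval: float = 1.97,
    carrier_freq: float = 0.05,
    noise_sd: float = 0.3,
    stay_prob: float = DEFAULT_STAY_PROB,
    loadings: np.ndarray | None = None,
    behavior_noise_sd: float = DEFAULT_BEHAVIOR_NOISE_SD,
    sc_modules: int = 4,
    seed: int = 0,
) -> Cohort:
    """Full synthetic cohort mirroring the study's scale by default.

    Behavior is the planted linear function of each subject's true
    fractional occupancies plus noise; ages are uniform over 18-88 with the
    young/old split at 50 years.
    """
    master = np.random.SeedSequence(seed)
    s_patterns, s_seq, s_bold, s_sc, s_age, s_beh = master.spawn(6)
    patterns = generate_state_patterns(n_regions, n_states, np.random.default_rng(s_patterns))
    markov = default_markov(n_states, stay_prob)
    if loadings is None:
        loadings = _default_loadings(n_states)
    rng_age = np.random.default_rng(s_age)
    ages = rng_age.uniform(18.0, 88.0, size=n_subjects)

    seq_seeds = s_seq.spawn(n_subjects)
    bold_seeds = s_bold.spawn(n_subjects)
    sc_seeds = s_sc.spawn(n_subjects)
    sequences: dict[str, np.ndarray] = {}
    timeseries: dict[str, BoldTimeSeries] = {}
    connectomes: dict[str, np.ndarray] = {}
    fo = np.zeros((n_subjects, n_states))
    ids = [f"sub-{i:03d}" for i in range(n_subjects)]
    for i, sid in enumerate(ids):
        seq = generate_state_sequence(markov, n_timepoints, np.random.default_rng(seq_seeds[i]))
        sequences[sid] = seq
        timeseries[sid] = generate_bold(
            seq, patterns, sampling_interval, carrier_freq, noise_sd,
            np.random.default_rng(bold_seeds[i]), subject_id=sid,
        )
        connectomes[sid] = generate_sc(
            n_regions, modules=sc_modules, seed=np.random.default_rng(sc_seeds[i])
        )
        fo[i] = np.bincount(seq - 1, minlength=n_states) / seq.size

    behavior = generate_behavior(fo, loadings, behavior_noise_sd, np.random.default_rng(s_beh))
    subjects = [
        SubjectRecord(sid, float(ages[i]), float(behavior[i]), "YA" if ages[i] < 50 else "OA")
        for i, sid in enumerate(ids)
    ]
    region_networks = [NETWORK_NAMES[j % len(NETWORK_NAMES)] for j in range(n_regions)]
    truth = GroundTruth(patterns, markov, np.asarray(loadings, dtype=float), noise_sd, seed,
                        behavior_noise_sd)
    return Cohort(subjects, timeseries, connectomes, sequences, region_networks, truth)


def write_cohort(cohort: Cohort, outdir: str | Path) -> Path:
    """Persist a cohort: per-subject TSVs, manifest, region table, truth JSON.

    Returns the manifest path. Layout::

        outdir/
          manifest.tsv            subject_id  ts_path  sc_path  age  behavior  group
          regions.tsv             region_id  region_name  network_label
          ground_truth.json
          ts/<subject>.tsv        N x T, no header
          sc/<subject>.tsv        N x N, no header
          sequences/<subject>.tsv planted 1-based state per timepoint
    """
    outdir = Path(outdir)
    (outdir / "ts").mkdir(parents=True, exist_ok=True)
    (outdir / "sc").mkdir(exist_ok=True)
    (outdir / "sequences").mkdir(exist_ok=True)
    rows = []
    for rec in cohort.subjects:
        ts_path = outdir / "ts" / f"{rec.subject_id}.tsv"
        sc_path = outdir / "sc" / f"{rec.subject_id}.tsv"
        np.savetxt(ts_path, cohort.timeseries[rec.subject_id].data, fmt="%.17g", delimiter="\t")
        np.savetxt(sc_path, cohort.connectomes[rec.subject_id], fmt="%.17g", delimiter="\t")
        np.savetxt(
            outdir / "sequences" / f"{rec.subject_id}.tsv",
            cohort.state_sequences[rec.subject_id][None, :], fmt="%d", delimiter="\t",
        )
        rows.append(
            dict(subject_id=rec.subject_id, ts_path=str(ts_path.relative_to(outdir)),
                 sc_path=str(sc_path.relative_to(outdir)), age=rec.age,
                 behavior=rec.behavior, group=rec.group)
        )
    manifest = pd.DataFrame(rows)
    manifest_path = outdir / "manifest.tsv"
    manifest.to_csv(manifest_path, sep="\t", index=False, float_format="%.17g")
    regions = pd.DataFrame(
        dict(region_id=np.arange(len(cohort.region_networks)),
             region_name=[f"region_{j:03d}" for j in range(len(cohort.region_networks))],
             network_label=cohort.region_networks)
    )
    regions.to_csv(outdir / "regions.tsv", sep="\t", index=False)
    truth = cohort.ground_truth
    payload = {
        "state_patterns": truth.state_patterns.tolist(),
        "markov": truth.markov.tolist(),
        "loadings": truth.loadings.tolist(),
        "noise_sd": truth.noise_sd,
        "behavior_noise_sd": truth.behavior_noise_sd,
        "seed": truth.seed,
        "sampling_interval": next(iter(cohort.timeseries.values())).sampling_interval,
    }
    (outdir / "ground_truth.json").write_text(json.dumps(payload, indent=1))
    return manifest_path
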