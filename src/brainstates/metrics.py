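"""Fractional occupancy and transition probabilities of state sequences.

Sequences are 1-based integer vectors over K states. Fractional occupancy
is the empirical time share of each state; the transition-probability matrix
is the maximum-likelihood row-stochastic estimate from consecutive pairs
(row = source state, column = destination, diagonal = maintenance). Rows of
states a subject never leaves from are all-zero and flagged unvisited rather
than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FOVector",
    "TransitionMatrix",
    "fractional_occupancy",
    "transition_probability",
    "cohort_fo_table",
    "cohort_tp_table",
]


@dataclass
class FOVector:
    subject_id: str
    fo: np.ndarray

    def __post_init__(self) -> None:
        self.fo = np.asarray(self.fo, dtype=float)
        if abs(self.fo.sum() - 1.0) > 1e-12:
            raise ValueError("fractional occupancies must sum to 1")


@dataclass
class TransitionMatrix:
    subject_id: str
    tp: np.ndarray
    visited: np.ndarray

    def __post_init__(self) -> None:
        self.tp = np.asarray(self.tp, dtype=float)
        self.visited = np.asarray(self.visited, dtype=bool)
        rowsum = self.tp.sum(axis=1)
        if not np.allclose(rowsum[self.visited], 1.0, atol=1e-12):
            raise ValueError("visited rows must sum to 1")
        if rowsum[~self.visited].any():
            raise ValueError("unvisited rows must be all-zero")


def _check_sequence(states: np.ndarray, n_states: int) -> np.ndarray:
    seq = np.asarray(states, dtype=int)
    if seq.ndim != 1 or seq.size < 1:
        raise ValueError("state sequence must be a non-empty 1-D vector")
    if seq.min() < 1 or seq.max() > n_states:
        raise ValueError(f"states must lie in 1..{n_states}")
    return seq


def fractional_occupancy(states, n_states: int, subject_id: str = "") -> FOVector:
    """fo[s] = count(s) / length."""
    seq = _check_sequence(states, n_states)
    fo = np.bincount(seq - 1, minlength=n_states) / seq.size
    return FOVector(subject_id, fo)


def transition_probability(states, n_states: int, subject_id: str = "") -> TransitionMatrix:
    """ML transition estimate from consecutive pairs of one subject's sequence.

    tp[i, j] = #(i -> j) / #(pairs starting in i). A source state with no
    outgoing pairs yields an all-zero row with visited[i] = False.
    """
    seq = _check_sequence(states, n_states)
    if seq.size < 2:
        raise ValueError("transition estimation needs a sequence of length >= 2")
    counts = np.zeros((n_states, n_states))
    np.add.at(counts, (seq[:-1] - 1, seq[1:] - 1), 1.0)
    outgoing = counts.sum(axis=1)
    visited = outgoing > 0
    tp = np.zeros_like(counts)
    tp[visited] = counts[visited] / outgoing[visited, None]
    return TransitionMatrix(subject_id, tp, visited)


def cohort_fo_table(sequences: dict[str, np.ndarray], n_states: int) -> pd.DataFrame:
    """Subjects x K table of fractional occupancies, columns fo_1..fo_K."""
    rows = {sid: fractional_occupancy(seq, n_states, sid).fo
            for sid, seq in sequences.items()}
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=[f"fo_{s}" for s in range(1, n_states + 1)])


def cohort_tp_table(sequences: dict[str, np.ndarray], n_states: int
                    ) -> tuple[pd.DataFrame, pd.Series]:
    """Subjects x K^2 table of flattened transition matrices (row-major,
    columns tp_i_j) plus a per-subject flag for fully-visited sequences."""
    cols = [f"tp_{i}_{j}" for i in range(1, n_states + 1) for j in range(1, n_states + 1)]
    rows, complete = {}, {}
    for sid, seq in sequences.items():
        tm = transition_probability(seq, n_states, sid)
        rows[sid] = tm.tp.ravel()
        complete[sid] = bool(tm.visited.all())
    table = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    return table, pd.Series(complete, name="all_states_visited")
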