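"""Per-run occupancy summaries derived from state label sequences.

Dwell time is the mean number of consecutive windows spent in a state per
visit; fraction of time is the proportion of a run's windows assigned to
the state.  States never entered contribute zeros (not missing values) so
they enter group statistics, matching the treatment of subjects who never
visit a state.
"""
from __future__ import annotations

from fractions import Fraction

import numpy as np
import pandas as pd

from .containers import StateSequence


def _check_labels(labels: np.ndarray, k: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("empty state sequence")
    if labels.min() < 1 or labels.max() > k:
        raise ValueError(f"labels must lie in 1..{k}")
    return labels


def run_lengths(labels: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of identical labels as (state, length) pairs, in order."""
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        return []
    change = np.flatnonzero(np.diff(labels) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [len(labels)]])
    return [(int(labels[s]), int(e - s)) for s, e in zip(starts, ends)]


def fraction_of_time(seq: StateSequence | np.ndarray, k: int) -> np.ndarray:
    """Proportion of windows in each state (exact count ratios)."""
    labels = _check_labels(seq.labels if isinstance(seq, StateSequence) else seq, k)
    counts = np.bincount(labels, minlength=k + 1)[1:]
    total = labels.size
    return np.array([float(Fraction(int(c), total)) for c in counts])


def mean_dwell_time(seq: StateSequence | np.ndarray, k: int) -> np.ndarray:
    """Mean consecutive-window visit length per state (0 for states never entered)."""
    labels = _check_labels(seq.labels if isinstance(seq, StateSequence) else seq, k)
    sums = np.zeros(k)
    visits = np.zeros(k, dtype=int)
    for state, length in run_lengths(labels):
        sums[state - 1] += length
        visits[state - 1] += 1
    out = np.zeros(k)
    entered = visits > 0
    out[entered] = sums[entered] / visits[entered]
    return out


def state_entry_indicator(seq: StateSequence | np.ndarray, k: int) -> np.ndarray:
    """Boolean per state: was the state entered at least once."""
    labels = _check_labels(seq.labels if isinstance(seq, StateSequence) else seq, k)
    return np.bincount(labels, minlength=k + 1)[1:] > 0


def count_transitions(seq: StateSequence | np.ndarray) -> int:
    """Number of window-to-window label changes in the run."""
    labels = np.asarray(seq.labels if isinstance(seq, StateSequence) else seq, dtype=int)
    if labels.size == 0:
        raise ValueError("empty state sequence")
    return int(np.sum(np.diff(labels) != 0))


def metrics_table(
    sequences: list[StateSequence],
    k: int,
    tr_seconds: float = 2.0,
    step: int = 1,
) -> pd.DataFrame:
    """Tidy per-(run, state) metrics table.

    Dwell time is reported in windows, with a seconds conversion column
    (windows x step x TR) alongside.
    """
    rows = []
    for seq in sequences:
        frac = fraction_of_time(seq, k)
        dwell = mean_dwell_time(seq, k)
        visited = state_entry_indicator(seq, k)
        n_trans = count_transitions(seq)
        for s in range(k):
            rows.append(
                {
                    "subject_id": seq.subject_id,
                    "condition": seq.condition,
                    "state": s + 1,
                    "dwell_time": dwell[s],
                    "dwell_time_seconds": dwell[s] * step * tr_seconds,
                    "fraction": frac[s],
                    "visited": bool(visited[s]),
                    "n_transitions": n_trans,
                }
            )
    return pd.DataFrame(rows)
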