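"""Brute-force reference for 1-D disjoint-interval class assignment.

Given a fixed activity direction, the pathway MILP reduces to a 1-D problem:
place one interval per class on the activity axis, intervals pairwise
separated by at least ε, maximising the number of samples whose activity
falls inside their own class interval.  That 1-D problem is solved here
exactly by dynamic programming over sorted distinct activity values, which
makes it an independent check on the MILP: for a single gene the MILP
objective must equal the oracle's, and for any candidate weight vector the
oracle value is an upper bound on the MILP objective.

The implementation shares no code with the MILP path.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Sequence

import numpy as np

__all__ = [
    "best_enclosed_count",
    "min_misclassified_1d",
    "oracle_single_gene",
    "grid_search_directions",
]


def best_enclosed_count(
    activities: Sequence[float],
    labels: Sequence,
    class_names: Sequence,
    epsilon: float = 1e-3,
) -> int:
    """Maximum own-class enclosures achievable by ε-separated class intervals.

    Each class receives at most one interval; intervals of different classes
    must be disjoint with a gap of at least *epsilon* between the last
    enclosed value of one and the first enclosed value of the next.  Samples
    sharing an activity value stand or fall together: all of them lie inside
    whichever interval covers that value.
    """
    act = np.asarray(activities, dtype=float)
    labels = np.asarray(labels)
    classes = list(class_names)
    cindex = {c: i for i, c in enumerate(classes)}
    order = np.argsort(act, kind="stable")
    values, starts = np.unique(act[order], return_index=True)
    V, C = len(values), len(classes)
    # counts[j, c] = samples with the j-th distinct value and class c
    counts = np.zeros((V, C), dtype=int)
    pos = np.searchsorted(values, act)
    for p, lab in zip(pos, labels):
        counts[p, cindex[lab]] += 1
    # run_score[a, b, c] = enclosed samples when values a..b go to class c
    csum = np.concatenate([np.zeros((1, C), dtype=int), np.cumsum(counts, axis=0)])

    @lru_cache(maxsize=None)
    def best(prev_end: int, used_mask: int) -> int:
        # prev_end: index of the last distinct value covered by the previous
        # interval (−1 for none); the next interval must start at a value
        # ≥ values[prev_end] + epsilon.
        if prev_end >= 0:
            a_min = int(np.searchsorted(values, values[prev_end] + epsilon))
        else:
            a_min = 0
        out = 0
        for a in range(a_min, V):
            for b in range(a, V):
                for c in range(C):
                    if used_mask >> c & 1:
                        continue
                    gain = int(csum[b + 1, c] - csum[a, c])
                    out = max(out, gain + best(b, used_mask | (1 << c)))
        return out

    result = best(-1, 0)
    best.cache_clear()
    return result


def min_misclassified_1d(
    activities: Sequence[float],
    labels: Sequence,
    class_names: Sequence,
    epsilon: float = 1e-3,
) -> int:
    """Minimum samples left outside their class interval for this direction."""
    return len(list(labels)) - best_enclosed_count(
        activities, labels, class_names, epsilon
    )


def oracle_single_gene(
    g: Sequence[float],
    labels: Sequence,
    class_names: Sequence,
    epsilon: float = 1e-3,
) -> int:
    """Optimal objective for a single-gene pathway: best over weight ±1."""
    g = np.asarray(g, dtype=float)
    return min(
        min_misclassified_1d(sign * g, labels, class_names, epsilon)
        for sign in (1.0, -1.0)
    )


def grid_search_directions(
    G: np.ndarray,
    labels: Sequence,
    class_names: Sequence,
    epsilon: float = 1e-3,
    n_grid: int = 41,
) -> int:
    """Best 1-D objective over a signed weight grid for a two-gene pathway.

    Candidate weights (w1, w2) are taken on an n_grid × n_grid lattice over
    [−1, 1]², rescaled to |w1| + |w2| = 1, de-duplicated, and each direction
    is scored with the exact 1-D dynamic programme.  The MILP optimum can
    only improve on (never exceed) this grid minimum.
    """
    G = np.asarray(G, dtype=float)
    if G.shape[1] != 2:
        raise ValueError("grid search is defined for two-gene pathways")
    axis = np.linspace(-1.0, 1.0, n_grid)
    w1, w2 = np.meshgrid(axis, axis)
    w = np.column_stack([w1.ravel(), w2.ravel()])
    norm = np.abs(w).sum(axis=1)
    w = w[norm > 0] / norm[norm > 0, None]
    w = np.unique(np.round(w, 12), axis=0)
    best = len(list(labels))
    for row in w:
        obj = min_misclassified_1d(G @ row, labels, class_names, epsilon)
        best = min(best, obj)
        if best == 0:
            break
    return best
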