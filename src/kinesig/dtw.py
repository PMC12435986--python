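"""Dependent multivariate dynamic time warping of paired trajectories.

Each communicative trajectory (the *query*) is aligned onto its paired
non-communicative trajectory (the *reference*) in home-centered 2D space.
The DP uses the symmetric step pattern with diagonal weight 2, so the
accumulated Euclidean error can be normalized by N + M; this normalized
distance is the spatial dissimilarity of the pair. The temporal statistic is
the *warping cost*: the mean over the optimal path of (query index −
reference index), positive when the query had to be stretched in time to fit
the reference and negative when it had to be compressed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .trajectory import DataError, IntegrityError, TrialRecord, Trajectory

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def _accumulate(cost: np.ndarray) -> np.ndarray:
    """Accumulated-cost matrix for the symmetric-2 step pattern.

    D[i, j] = min(D[i-1, j] + c, D[i, j-1] + c, D[i-1, j-1] + 2c); the first
    cell enters with weight 1.
    """
    n, m = cost.shape
    acc = np.empty((n, m))
    acc[0, 0] = cost[0, 0]
    for j in range(1, m):
        acc[0, j] = acc[0, j - 1] + cost[0, j]
    for i in range(1, n):
        acc[i, 0] = acc[i - 1, 0] + cost[i, 0]
        for j in range(1, m):
            c = cost[i, j]
            best = acc[i - 1, j - 1] + 2.0 * c
            up = acc[i - 1, j] + c
            if up < best:
                best = up
            left = acc[i, j - 1] + c
            if left < best:
                best = left
            acc[i, j] = best
    return acc


@dataclass
class WarpPath:
    """Monotone alignment path as an (L, 2) array of (query, reference) indices."""

    pairs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.pairs, dtype=int)
        if p.ndim != 2 or p.shape[1] != 2:
            raise DataError("path must be an (L, 2) index array")
        steps = np.diff(p, axis=0)
        if p.size and (
            np.any(steps < 0)
            or np.any(steps > 1)
            or np.any((steps == 0).all(axis=1))
        ):
            raise DataError("path steps must be from {(1,0),(0,1),(1,1)}")
        self.pairs = p


@dataclass
class DtwResult:
    """Alignment outcome of one trial pair."""

    normalized_distance: float
    warping_cost: float
    path: WarpPath
    n_query: int
    n_reference: int


def warping_cost(path: WarpPath, per_reference: bool = False) -> float:
    """Mean difference of aligned sample indices (query − reference), in samples.

    With ``per_reference=True`` the differences are first averaged within
    each reference sample, then across reference samples — a sensitivity
    variant that weights every reference instant equally instead of every
    path step.
    """
    p = path.pairs
    diff = p[:, 0] - p[:, 1]
    if not per_reference:
        return float(np.mean(diff))
    sums = np.bincount(p[:, 1], weights=diff)
    counts = np.bincount(p[:, 1])
    return float(np.mean(sums / counts))


def _backtrack(acc: np.ndarray, cost: np.ndarray) -> np.ndarray:
    """Optimal path by backtracking; ties prefer the diagonal, then the step
    that advanced the reference index."""
    i, j = acc.shape[0] - 1, acc.shape[1] - 1
    rev = [(i, j)]
    tol = 1e-10
    while i > 0 or j > 0:
        c = cost[i, j]
        here = acc[i, j]
        if i > 0 and j > 0 and abs(acc[i - 1, j - 1] + 2.0 * c - here) <= tol * (1 + abs(here)):
            i, j = i - 1, j - 1
        elif j > 0 and abs(acc[i, j - 1] + c - here) <= tol * (1 + abs(here)):
            j = j - 1
        elif i > 0 and abs(acc[i - 1, j] + c - here) <= tol * (1 + abs(here)):
            i = i - 1
        elif i > 0 and j > 0:
            i, j = i - 1, j - 1  # numerical fallback
        elif j > 0:
            j = j - 1
        else:
            i = i - 1
        rev.append((i, j))
    return np.array(rev[::-1], dtype=int)


def dtw_align(reference: Trajectory, query: Trajectory) -> DtwResult:
    """Align ``query`` onto ``reference`` in home-centered 2D space.

    Returns the (N+M)-normalized accumulated Euclidean distance, the optimal
    path and the signed warping cost.
    """
    if reference.n_samples < 2 or query.n_samples < 2:
        raise DataError("DTW needs at least 2 samples per trajectory")
    q = query.xy_home_centered()
    r = reference.xy_home_centered()
    if not (np.all(np.isfinite(q)) and np.all(np.isfinite(r))):
        raise DataError("trajectories must be gap-free before DTW")
    cost = cdist(q, r)  # rows: query, cols: reference
    acc = _accumulate(cost)
    path = WarpPath(_backtrack(acc, cost))
    n, m = cost.shape
    return DtwResult(
        normalized_distance=float(acc[-1, -1] / (n + m)),
        warping_cost=warping_cost(path),
        path=path,
        n_query=n,
        n_reference=m,
    )


def pair_and_align(trials: list[TrialRecord]) -> pd.DataFrame:
    """Align every communicative trial onto its non-communicative partner.

    Expects a balanced post-exclusion collection; an unpaired trial raises an
    integrity error. Returns one row per pair with labels and DTW outcomes.
    """
    by_pair: dict = {}
    for tr in trials:
        by_pair.setdefault(tr.pair_key, {})[tr.condition] = tr
    rows = []
    for key in by_pair:
        pair = by_pair[key]
        if set(pair) != {"non_communicative", "communicative"}:
            have = next(iter(pair.values()))
            raise IntegrityError(f"unpaired trial {have.uid} in pair_and_align")
        ref = pair["non_communicative"]
        qry = pair["communicative"]
        res = dtw_align(ref.trajectory, qry.trajectory)
        pid, group, item, session, trial_idx = key
        rows.append(
            {
                "participant_id": pid,
                "group": group,
                "item_id": item,
                "session": session,
                "trial_index": trial_idx,
                "normalized_distance": res.normalized_distance,
                "warping_cost": res.warping_cost,
                "n_query": res.n_query,
                "n_reference": res.n_reference,
            }
        )
    return pd.DataFrame(rows)
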