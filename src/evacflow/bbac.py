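"""Bregman block-average co-clustering with I-divergence (BBAC_I).

Rows (grid cells) and columns (hours) of a non-negative matrix are
partitioned simultaneously; each block of the co-clustered approximation
Ô is the arithmetic mean of its entries (the Bregman-optimal block
representative), and the fit criterion is the I-divergence

    F_loss = D_I(O ‖ Ô) = Σ [ O log(O/Ô) − O + Ô ].

With a single temporal cluster (tc = 1, the configuration used for the
spatial comparison against EOF) the algorithm reduces to 1-D clustering of
the rows. Alternating block-mean updates and per-row (per-column) argmin
reassignments never increase the loss; multiple random restarts guard
against local minima.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

#: Floor applied to block means inside logarithms (min-max scaled data
#: contain exact zeros).
EPS = 1e-10


@dataclass
class CoClusterResult:
    """Best-of-restarts co-clustering solution."""

    row_labels: np.ndarray  # (G,) ints in 0..gc-1
    col_labels: np.ndarray  # (T,) ints in 0..tc-1
    block_means: np.ndarray  # (gc, tc)
    approximation: np.ndarray  # (G, T) blockwise-constant Ô
    loss_trajectory: np.ndarray  # per-iteration loss, non-increasing
    n_iter: int
    converged: bool
    seed: int
    restart_index: int
    loss: float = field(init=False)

    def __post_init__(self) -> None:
        self.loss = float(self.loss_trajectory[-1])


def scale_minmax(matrix: np.ndarray) -> np.ndarray:
    """Global (whole-matrix) min-max scaling to [0, 1].

    A constant matrix maps to all zeros (with a warning): the degenerate
    case carries no structure to cluster.
    """
    m = np.asarray(matrix, dtype=float)
    if not np.all(np.isfinite(m)):
        raise ValueError("matrix must be finite")
    lo, hi = m.min(), m.max()
    if hi == lo:
        warnings.warn("constant matrix: min-max scaling returns all zeros", stacklevel=2)
        return np.zeros_like(m)
    return (m - lo) / (hi - lo)


def i_divergence(x: np.ndarray, y: np.ndarray) -> float:
    """Generalized KL divergence Σ [x log(x/y) − x + y], with 0·log 0 = 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if np.any(x < 0):
        raise ValueError("x must be non-negative")
    if np.any(y <= 0):
        raise ValueError("y must be strictly positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        # log(x) - log(y) rather than log(x/y): x/y can underflow to 0 for
        # subnormal x, sending the summand to -inf instead of ~0.
        xlog = np.where(x > 0, x * (np.log(x) - np.log(y)), 0.0)
    return float(np.sum(xlog - x + y))


def block_approximation(
    matrix: np.ndarray, row_labels: np.ndarray, col_labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Block means and the blockwise-constant approximation Ô.

    Blocks that happen to be empty (an empty row or column cluster) get
    mean 0; the fitting loop's empty-cluster repair keeps them out of
    returned solutions.
    """
    m = np.asarray(matrix, dtype=float)
    row_labels = np.asarray(row_labels, dtype=int)
    col_labels = np.asarray(col_labels, dtype=int)
    gc = int(row_labels.max()) + 1
    tc = int(col_labels.max()) + 1
    r_ind = np.eye(gc)[row_labels]  # (G, gc) indicators
    c_ind = np.eye(tc)[col_labels]  # (T, tc)
    sums = r_ind.T @ m @ c_ind
    counts = np.outer(r_ind.sum(axis=0), c_ind.sum(axis=0))
    means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return means, means[row_labels][:, col_labels]


def _item_contrib(matrix: np.ndarray, approx: np.ndarray) -> np.ndarray:
    """Per-row I-divergence contribution under a fixed approximation."""
    y = np.maximum(approx, EPS)
    x = matrix
    with np.errstate(divide="ignore", invalid="ignore"):
        xlog = np.where(x > 0, x * np.log(x / y), 0.0)
    return (xlog - x + y).sum(axis=1)


def _reassign(matrix: np.ndarray, reps: np.ndarray) -> np.ndarray:
    """Per-row argmin of Σ_t d_I(x_t, reps[c, t]); ties go to the lowest index."""
    y = np.maximum(reps, EPS)  # (C, T)
    x = matrix  # (G, T)
    with np.errstate(divide="ignore", invalid="ignore"):
        xlogx = np.where(x > 0, x * np.log(x), 0.0)
    cost = (
        xlogx.sum(axis=1, keepdims=True)
        - x @ np.log(y).T
        - x.sum(axis=1, keepdims=True)
        + y.sum(axis=1)
    )
    return np.argmin(cost, axis=1)


def _repair_empty(labels: np.ndarray, n_clusters: int, contrib: np.ndarray) -> np.ndarray:
    """Fill each empty cluster with the worst-fitting item from a non-singleton."""
    labels = labels.copy()
    for c in range(n_clusters):
        if not np.any(labels == c):
            counts = np.bincount(labels, minlength=n_clusters)
            movable = counts[labels] > 1
            if not movable.any():
                continue
            labels[int(np.argmax(np.where(movable, contrib, -np.inf)))] = c
    return labels


def _partition_objective(S: np.ndarray, N: np.ndarray) -> float:
    """Σ_b S_b log(S_b / n_b): the partition-dependent part of the loss.

    For block means the I-divergence collapses to
    F = Σ x log x − Σ_b S_b log(S_b / n_b), so comparing partitions only
    needs block sums S and sizes N. Returned with sign such that larger is
    better (F = const − objective).
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        return float(np.where(S > 0, S * np.log(S / np.maximum(N, 1)), 0.0).sum())


def _hartigan_rows(
    rs: np.ndarray, rows: np.ndarray, gc: int, col_sizes: np.ndarray
) -> bool:
    """One sequential best-move pass over rows with exact loss changes.

    ``rs[g, d]`` is row g's sum over the columns of column-cluster d.
    Each row is moved to the cluster that most improves the exact
    objective (ties keep the current cluster); moves that would empty a
    cluster are skipped. Returns whether any move was made. Escapes local
    minima of the batch update because the candidate evaluation accounts
    for the block-mean shift the move itself causes.
    """
    G = rs.shape[0]
    S = np.zeros((gc, rs.shape[1]))
    counts = np.zeros(gc, dtype=int)
    for g in range(G):
        S[rows[g]] += rs[g]
        counts[rows[g]] += 1

    def term(vec: np.ndarray, cnt: int) -> float:
        if cnt == 0:
            return 0.0
        return _partition_objective(vec, cnt * col_sizes)

    moved = False
    for g in range(G):
        a = rows[g]
        if counts[a] <= 1:
            continue
        base = term(S[a], counts[a])
        best_gain, best_b = 1e-12, -1
        sa_new = S[a] - rs[g]
        base_a_removed = term(sa_new, counts[a] - 1)
        for b in range(gc):
            if b == a:
                continue
            gain = (
                base_a_removed
                + term(S[b] + rs[g], counts[b] + 1)
                - base
                - term(S[b], counts[b])
            )
            if gain > best_gain:
                best_gain, best_b = gain, b
        if best_b >= 0:
            S[a] = sa_new
            S[best_b] += rs[g]
            counts[a] -= 1
            counts[best_b] += 1
            rows[g] = best_b
            moved = True
    return moved


def _means_full(matrix, rows, cols, gc, tc) -> tuple[np.ndarray, np.ndarray]:
    means, approx = block_approximation(matrix, rows, cols)
    if means.shape != (gc, tc):  # trailing clusters empty
        full = np.zeros((gc, tc))
        full[: means.shape[0], : means.shape[1]] = means
        means = full
        approx = means[rows][:, cols]
    return means, approx


def fit_coclustering(
    matrix: np.ndarray,
    gc: int,
    tc: int = 1,
    max_iterations: int = 100,
    tol: float = 1e-6,
    n_restarts: int = 10,
    seed: int | np.random.Generator = 0,
) -> CoClusterResult:
    """Fit BBAC_I by alternating minimization with random restarts.

    ``matrix`` must be min-max scaled (non-negative). Each restart draws
    random initial row (and, when tc > 1, column) labels, alternates
    block-mean updates with per-row/per-column argmin reassignment, and
    stops when the loss improvement drops below ``tol`` or after
    ``max_iterations``. The restart with the lowest final loss is
    returned; its loss trajectory is non-increasing.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("matrix must be 2-D")
    G, T = m.shape
    if not 1 <= gc <= G:
        raise ValueError(f"gc must lie in [1, {G}]")
    if not 1 <= tc <= T:
        raise ValueError(f"tc must lie in [1, {T}]")
    if np.any(m < 0):
        raise ValueError("matrix must be non-negative (min-max scaled)")
    if m.max() == m.min():
        warnings.warn(
            "all-equal matrix: a single effective cluster fits exactly", stacklevel=2
        )

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_repr = -1 if isinstance(seed, np.random.Generator) else int(seed)

    best: CoClusterResult | None = None
    for restart in range(n_restarts):
        rows = rng.integers(0, gc, size=G)
        cols = np.zeros(T, dtype=int) if tc == 1 else rng.integers(0, tc, size=T)
        means, approx = _means_full(m, rows, cols, gc, tc)
        rows = _repair_empty(rows, gc, _item_contrib(m, approx))
        if tc > 1:
            cols = _repair_empty(cols, tc, _item_contrib(m.T, approx.T))

        traj: list[float] = []
        converged = False
        it = 0
        for it in range(1, max_iterations + 1):
            means, approx = _means_full(m, rows, cols, gc, tc)
            loss = i_divergence(m, np.maximum(approx, EPS))
            traj.append(loss)
            if len(traj) > 1 and traj[-2] - loss < tol:
                converged = True
                break

            rows = _reassign(m, means[:, cols])
            rows = _repair_empty(rows, gc, _item_contrib(m, means[rows][:, cols]))
            if tc > 1:
                means, _ = _means_full(m, rows, cols, gc, tc)
                cols = _reassign(m.T, means[rows].T)
                cols = _repair_empty(cols, tc, _item_contrib(m.T, means[rows][:, cols].T))

        # Sequential per-item refinement on the exact objective; the batch
        # update can stall in local minima the single-move landscape escapes.
        for _ in range(50):
            improved = False
            csize = np.bincount(cols, minlength=tc)
            rs = np.stack([m[:, cols == d].sum(axis=1) for d in range(tc)], axis=1)
            improved |= _hartigan_rows(rs, rows, gc, csize)
            if tc > 1:
                rsize = np.bincount(rows, minlength=gc)
                cs = np.stack([m[rows == c].sum(axis=0) for c in range(gc)], axis=1)
                improved |= _hartigan_rows(cs, cols, tc, rsize)
            if not improved:
                break

        means, approx = _means_full(m, rows, cols, gc, tc)
        final_loss = i_divergence(m, np.maximum(approx, EPS))
        if not traj or final_loss < traj[-1]:
            traj.append(final_loss)

        result = CoClusterResult(
            row_labels=rows,
            col_labels=cols,
            block_means=means,
            approximation=approx,
            loss_trajectory=np.array(traj),
            n_iter=it,
            converged=converged,
            seed=seed_repr,
            restart_index=restart,
        )
        if best is None or result.loss < best.loss:
            best = result
    assert best is not None
    return best
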