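"""Empirical orthogonal function (EOF) decomposition of the anomaly field.

The G×T anomaly matrix is centered per grid (each row's temporal mean is
removed) and the spatial covariance C = O'O'ᵀ/(T−1) is eigendecomposed.
Eigenvectors are the spatial modes (EOFs); projecting the centered field
onto them gives the temporal principal components (PCs); each eigenvalue's
share of the trace is the fraction of variance the mode explains.

Computation goes through a thin SVD of the centered matrix, which is the
same decomposition (λ_j = s_j²/(T−1), modes = left singular vectors) and
avoids forming the G×G covariance when G ≫ T.

Mode/PC sign pairs are mathematically arbitrary; :func:`orient_signs`
applies the convention that each mode's largest-|loading| cell is positive.
Interpretation rule for a cell: loading sign × PC sign > 0 means the
population there moves above its mean (inflow/increase), < 0 below
(outflow/decrease).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .panel import AnomalyMatrix

#: Relative eigenvalue gap below which mode ordering/rotation is unstable.
DEGENERACY_RTOL = 1e-10


@dataclass
class EOFResult:
    """Spatial modes, temporal PCs, eigenvalues and variance fractions.

    ``modes`` is G×K with orthonormal columns; ``pcs`` is T×K, the raw
    projection O'ᵀ·modes (no unit-variance rescaling), so the sample
    variance of PC k equals eigenvalue k. ``row_means`` is the per-grid
    temporal mean removed during centering; ``modes @ pcs.T + row_means``
    reconstructs the anomaly field exactly at full rank.
    """

    modes: np.ndarray
    pcs: np.ndarray
    eigenvalues: np.ndarray
    explained_fraction: np.ndarray
    row_means: np.ndarray
    grid_index: np.ndarray

    @property
    def k(self) -> int:
        return self.modes.shape[1]


def eof_decompose(anom: AnomalyMatrix, k: int) -> EOFResult:
    """Leading-k EOF decomposition of the anomaly matrix.

    Raises if the centered matrix has no variance or k is out of range.
    """
    G, T = anom.values.shape
    if G < 2 or T < 2:
        raise ValueError("need at least 2 grids and 2 hours")
    if not 1 <= k <= min(G, T):
        raise ValueError(f"k must lie in [1, {min(G, T)}]")

    row_means = anom.values.mean(axis=1, keepdims=True)
    centered = anom.values - row_means
    if not np.any(centered):
        raise ValueError("no variance to decompose: anomaly matrix is constant per grid")

    u, s, _ = linalg.svd(centered, full_matrices=False)
    eigenvalues = s**2 / (T - 1)
    total = eigenvalues.sum()

    gaps = np.abs(np.diff(eigenvalues[:k])) if k > 1 else np.array([])
    if gaps.size and np.any(gaps < DEGENERACY_RTOL * eigenvalues[0]):
        warnings.warn(
            "near-degenerate leading eigenvalues: mode ordering/rotation is unstable",
            stacklevel=2,
        )

    modes = u[:, :k]
    return EOFResult(
        modes=modes,
        pcs=centered.T @ modes,
        eigenvalues=eigenvalues[:k],
        explained_fraction=eigenvalues[:k] / total,
        row_means=row_means.ravel(),
        grid_index=np.asarray(anom.grid_index, dtype=object),
    )


def orient_signs(result: EOFResult) -> EOFResult:
    """Flip each (mode, PC) pair so the largest-|loading| cell is positive.

    Reconstruction is unchanged (each pair is negated jointly); idempotent.
    """
    modes = result.modes.copy()
    pcs = result.pcs.copy()
    for j in range(result.k):
        peak = np.argmax(np.abs(modes[:, j]))
        if modes[peak, j] < 0:
            modes[:, j] = -modes[:, j]
            pcs[:, j] = -pcs[:, j]
    return EOFResult(
        modes=modes,
        pcs=pcs,
        eigenvalues=result.eigenvalues.copy(),
        explained_fraction=result.explained_fraction.copy(),
        row_means=result.row_means.copy(),
        grid_index=result.grid_index,
    )


def select_top_loadings(
    result: EOFResult, mode_index: int, q: float = 0.2
) -> tuple[np.ndarray, float]:
    """The ⌈qG⌉ strongest-|loading| cells of one mode, and their variance share.

    The share is Σ selected loading² / Σ all loading² for that mode
    (loadings are unit-norm, so this is the fraction of the mode's spatial
    variance the selected cells carry). Ties are broken by grid order.
    """
    if not 0.0 < q <= 1.0:
        raise ValueError("q must lie in (0, 1]")
    if not 0 <= mode_index < result.k:
        raise ValueError(f"mode_index must lie in [0, {result.k})")
    loadings = result.modes[:, mode_index]
    g = loadings.size
    m = int(np.ceil(q * g))
    # Stable sort on (-|loading|, position): ties go to the earlier grid id.
    order = np.argsort(-np.abs(loadings), kind="stable")[:m]
    selected = np.zeros(g, dtype=bool)
    selected[order] = True
    share = float(np.sum(loadings[selected] ** 2) / np.sum(loadings**2))
    return result.grid_index[selected], share


def select_top_loadings_union(
    result: EOFResult, mode_indices: tuple[int, ...] = (0, 1), q: float = 0.2
) -> np.ndarray:
    """Cells in the top-q fraction of *any* of the given modes."""
    ids: set[str] = set()
    for j in mode_indices:
        sel, _ = select_top_loadings(result, j, q)
        ids.update(str(g) for g in sel)
    return result.grid_index[np.isin(result.grid_index.astype(str), sorted(ids))]


def classify_flow(loading_sign: float, pc_value: float, dead_band: float = 0.0) -> str:
    """Flow class of a cell from its loading sign and a PC value.

    Positive loading with positive PC means the cell sits above its mean
    (increase); negative loading with positive PC, below (decrease); both
    reverse when the PC is negative. |PC| <= ``dead_band`` is neutral.
    """
    if abs(pc_value) <= dead_band or loading_sign == 0:
        return "neutral"
    product = np.sign(loading_sign) * np.sign(pc_value)
    return "increase" if product > 0 else "decrease"
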