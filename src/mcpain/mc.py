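"""Morphological connectivity (MC) networks.

The MC between two ROIs of one participant is the symmetrised
Kullback-Leibler divergence (J-divergence) between their KDE-estimated
gray-matter intensity densities,

    KL(p, q) = ∫ p(x) log(p(x)/q(x)) + q(x) log(q(x)/p(x)) dx,

evaluated by trapezoid quadrature on a shared uniform grid. A participant's
MC matrix is symmetric with a zero diagonal; its strictly-lower-triangle
vectorisation (row-major, 4005 entries for 90 ROIs) is the participant's MC
feature vector.

All pairwise divergences of a participant are computed on a single shared
grid spanning the pooled range of that participant's ROI samples, so every
pairwise integral uses a consistent support.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .density import (
    DEFAULT_GRID_POINTS,
    DEFAULT_PADDING,
    DensityEstimate,
    estimate_density,
    make_grid,
    scott_bandwidth,
)
from .errors import DegenerateSampleError, GridMismatchError, InvalidParameterError
from .parcellation import Parcellation

#: ASCII separator used in ROI-pair feature names ("ROI_i-ROI_j", i after j).
PAIR_SEP = "-"


@dataclass(frozen=True)
class MCMatrix:
    """Symmetric ROI x ROI divergence matrix for one participant."""

    values: np.ndarray
    roi_names: tuple[str, ...]

    def __post_init__(self) -> None:
        v = self.values
        n = len(self.roi_names)
        if v.shape != (n, n):
            raise InvalidParameterError(f"matrix shape {v.shape} != ({n}, {n})")
        if not np.all(np.isfinite(v)):
            raise InvalidParameterError("MC matrix contains non-finite entries")


def lower_triangle_pairs(n_rois: int) -> list[tuple[int, int]]:
    """Strictly-lower-triangle (i, j) index pairs, i > j, row-major order."""
    rows, cols = np.tril_indices(n_rois, k=-1)
    return list(zip(rows.tolist(), cols.tolist()))


def pair_names(roi_names: Iterable[str]) -> list[str]:
    names = list(roi_names)
    return [f"{names[i]}{PAIR_SEP}{names[j]}" for i, j in lower_triangle_pairs(len(names))]


def symmetric_kl(p: DensityEstimate, q: DensityEstimate) -> float:
    """Symmetrised KL divergence of two densities on a shared grid.

    The integrand is written as (p - q)(log p - log q), which is pointwise
    non-negative, so the trapezoid quadrature is non-negative by construction
    and exactly symmetric in its arguments.
    """
    if p.grid.shape != q.grid.shape or not np.array_equal(p.grid, q.grid):
        raise GridMismatchError(
            "density estimates are on different grids; re-evaluate on a shared grid"
        )
    integrand = (p.density - q.density) * (np.log(p.density) - np.log(q.density))
    return float(np.trapezoid(integrand, p.grid))


def _pairwise_symmetric_kl(dens: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """All pairwise J-divergences between rows of a density matrix."""
    n = dens.shape[0]
    logd = np.log(dens)
    out = np.zeros((n, n))
    for i in range(n):
        integrand = (dens[i] - dens) * (logd[i] - logd)
        out[i] = np.trapezoid(integrand, grid, axis=1)
    # enforce exact symmetry and zero diagonal against rounding
    out = 0.5 * (out + out.T)
    np.fill_diagonal(out, 0.0)
    return out


def build_mc_matrix(
    roi_samples: Mapping[int, np.ndarray],
    parc: Parcellation,
    n_points: int = DEFAULT_GRID_POINTS,
    padding: float = DEFAULT_PADDING,
) -> MCMatrix:
    """One participant's MC matrix from a mapping roi_id -> intensity vector.

    A single uniform grid is built from the pooled samples of all ROIs
    (pooled min/max padded by ``padding`` pooled Scott bandwidths); every ROI
    density is evaluated on it, then all pairwise symmetric-KL divergences
    are taken by trapezoid quadrature.
    """
    missing = [r for r in parc.roi_ids if r not in roi_samples]
    if missing:
        raise InvalidParameterError(f"missing ROI samples for roi_ids {missing}")
    vectors = [np.asarray(roi_samples[r], dtype=float).ravel() for r in parc.roi_ids]
    pooled = np.concatenate(vectors)
    h_pool = scott_bandwidth(pooled)
    grid = make_grid(pooled.min(), pooled.max(), h_pool, n_points, padding)

    dens = np.empty((parc.n_rois, n_points))
    for k, (roi_id, name, x) in enumerate(zip(parc.roi_ids, parc.names, vectors)):
        try:
            dens[k] = estimate_density(x, grid=grid).density
        except DegenerateSampleError as exc:
            raise DegenerateSampleError(
                f"degenerate samples for ROI {name} (roi_id={roi_id}): {exc}"
            ) from exc
    values = _pairwise_symmetric_kl(dens, grid)
    return MCMatrix(values=values, roi_names=tuple(parc.names))


def vectorize_lower_triangle(
    mc: MCMatrix, symmetry_tol: float = 1e-8
) -> pd.Series:
    """Strictly-lower-triangle entries as a named feature vector.

    Row-major order; entry names are ``"ROI_i-ROI_j"`` with i after j in
    parcellation order. Length is n(n-1)/2.
    """
    v = mc.values
    if np.max(np.abs(v - v.T)) > symmetry_tol:
        raise InvalidParameterError("MC matrix is asymmetric beyond tolerance")
    rows, cols = np.tril_indices(v.shape[0], k=-1)
    return pd.Series(v[rows, cols], index=pair_names(mc.roi_names), name="mc")


def matrix_from_vector(vector: pd.Series, roi_names: Iterable[str]) -> MCMatrix:
    """Reconstruct the symmetric MC matrix from its lower-triangle vector."""
    names = tuple(roi_names)
    n = len(names)
    values = np.zeros((n, n))
    rows, cols = np.tril_indices(n, k=-1)
    values[rows, cols] = np.asarray(vector, dtype=float)
    values = values + values.T
    return MCMatrix(values=values, roi_names=names)


def cohort_mc_features(
    sample_set,
    parc: Parcellation,
    n_points: int = DEFAULT_GRID_POINTS,
    padding: float = DEFAULT_PADDING,
) -> pd.DataFrame:
    """MC feature table (participants x ROI pairs) for a whole cohort.

    ``sample_set`` is an :class:`~mcpain.samples.ROISampleSet`. Row order
    follows the sample set's participant ordering; column order is the stable
    lower-triangle pair order of the parcellation.
    """
    rows = {}
    for pid in sample_set.participants:
        mc = build_mc_matrix(sample_set.participant_samples(pid), parc, n_points, padding)
        rows[pid] = vectorize_lower_triangle(mc)
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "participant_id"
    return table.loc[list(sample_set.participants)]


def write_mc_matrix_csv(mc: MCMatrix, path: str | Path) -> None:
    """Square CSV with ROI-name header and index."""
    pd.DataFrame(mc.values, index=mc.roi_names, columns=mc.roi_names).to_csv(path)


def write_edge_list(mc: MCMatrix, path: str | Path) -> None:
    """Lower-triangle edge list as TSV (roi_a, roi_b, value)."""
    rows = [
        {"roi_a": mc.roi_names[i], "roi_b": mc.roi_names[j], "value": mc.values[i, j]}
        for i, j in lower_triangle_pairs(len(mc.roi_names))
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
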