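"""Multi-resolution 2D Haar wavelet features with one-step frameshifts.

Each expression grid is zero-padded to even dimensions, divided into
disjoint 2x2 sections, and every section yields four features combining
row-wise means and differences (low-pass through high-pass).  The section
means form a half-size grid that is decomposed again, down to a single
cell, so features span fine-grained local switches up to whole-pathway
shifts.  Because the rigid 2x2 tiling splits some neighboring cell pairs,
the transform is repeated on the grid shifted by one row, one column, and
both ("frameshift" variants), which restores every 2x2 neighborhood of
the original grid inside some section.

Feature values follow the plain mean/difference convention (means divide
by 2, differences are unscaled) rather than orthonormal Haar scaling; the
two differ by a constant factor per (level, kind) and give identical
permutation statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .expression import ExpressionGrid

__all__ = [
    "KINDS",
    "SHIFTS",
    "WaveletFeature",
    "WaveletFeatureSet",
    "pad_to_even",
    "block_features",
    "decompose",
    "frameshift_variants",
    "feature_vector",
    "feature_index",
    "feature_matrix",
    "extract_all",
]

KINDS = ("mean_of_means", "diff_of_means", "mean_of_diffs", "diff_of_diffs")
SHIFTS = ("none", "row", "col", "both")


@dataclass(frozen=True)
class WaveletFeature:
    """One Haar feature: its grid variant, resolution, section and kind."""

    pathway_id: str
    shift: str
    level: int
    section: tuple[int, int]
    kind: str
    value: float


@dataclass
class WaveletFeatureSet:
    """All Haar features of one sample on one pathway, canonically ordered.

    The ordering (shift, level, section row-major, kind) is a function of
    the grid shape only, so features are comparable position-wise across
    samples of the same pathway.
    """

    pathway_id: str
    sample_id: str
    features: list[WaveletFeature]

    def values(self) -> np.ndarray:
        return np.array([f.value for f in self.features])


def pad_to_even(grid: np.ndarray) -> np.ndarray:
    """Append zero rows (bottom) / columns (right) until both dims are even."""
    grid = np.asarray(grid, dtype=float)
    r, c = grid.shape
    return np.pad(grid, ((0, r % 2), (0, c % 2)))


def block_features(block: np.ndarray) -> tuple[float, float, float, float]:
    """The four Haar features of a 2x2 section [[a, b], [c, d]].

    With row means mu = (a+b)/2, ml = (c+d)/2 and row differences
    du = a-b, dl = c-d: mean of means (mu+ml)/2, difference of means
    mu-ml, mean of differences (du+dl)/2, difference of differences du-dl.
    """
    (a, b), (c, d) = np.asarray(block, dtype=float)
    mu, ml = (a + b) / 2, (c + d) / 2
    du, dl = a - b, c - d
    return ((mu + ml) / 2, mu - ml, (du + dl) / 2, du - dl)


def _level_features(grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All four feature planes of one (even-sized) grid plus the f1 plane.

    Returns (features, f1) where features has shape (nr, nc, 4) over the
    nr x nc sections in row-major order.
    """
    a = grid[0::2, 0::2]
    b = grid[0::2, 1::2]
    c = grid[1::2, 0::2]
    d = grid[1::2, 1::2]
    mu, ml = (a + b) / 2, (c + d) / 2
    du, dl = a - b, c - d
    f1 = (mu + ml) / 2
    planes = np.stack([f1, mu - ml, (du + dl) / 2, du - dl], axis=-1)
    return planes, f1


def decompose(grid: np.ndarray, pathway_id: str = "", shift: str = "none") -> list[WaveletFeature]:
    """Full multi-resolution decomposition of one grid.

    Level 0 is the finest resolution; the level l+1 grid consists of the
    level-l mean-of-means values (padded to even when odd).  Recursion
    stops once the averaged grid is a single cell; a 1x1 input therefore
    yields no features.
    """
    out: list[WaveletFeature] = []
    current = np.asarray(grid, dtype=float)
    level = 0
    while current.shape != (1, 1):
        current = pad_to_even(current)
        planes, f1 = _level_features(current)
        nr, nc, _ = planes.shape
        for r in range(nr):
            for c in range(nc):
                for k, kind in enumerate(KINDS):
                    out.append(WaveletFeature(pathway_id, shift, level, (r, c),
                                              kind, float(planes[r, c, k])))
        current = f1
        level += 1
    return out


def frameshift_variants(grid: np.ndarray) -> dict[str, np.ndarray]:
    """The four one-step frameshift variants of a grid.

    A zero row and/or column is prepended so that the 2x2 tiling of each
    variant cuts the original grid at shifted boundaries; together the
    variants cover every 2x2 neighborhood of the original.
    """
    grid = np.asarray(grid, dtype=float)
    return {
        "none": grid,
        "row": np.pad(grid, ((1, 0), (0, 0))),
        "col": np.pad(grid, ((0, 0), (1, 0))),
        "both": np.pad(grid, ((1, 0), (1, 0))),
    }


def _shape_index(shape: tuple[int, int], shift: str) -> list[tuple[str, int, int, int, str]]:
    """Canonical (shift, level, sec_row, sec_col, kind) order for one variant."""
    rows, cols = shape
    out = []
    level = 0
    while (rows, cols) != (1, 1):
        rows += rows % 2
        cols += cols % 2
        nr, nc = rows // 2, cols // 2
        for r in range(nr):
            for c in range(nc):
                for kind in KINDS:
                    out.append((shift, level, r, c, kind))
        rows, cols = nr, nc
        level += 1
    return out


def feature_index(shape: tuple[int, int]) -> list[tuple[str, int, int, int, str]]:
    """Canonical feature ordering for a grid shape, over all four shifts."""
    rows, cols = shape
    out = []
    for shift in SHIFTS:
        dr = 1 if shift in ("row", "both") else 0
        dc = 1 if shift in ("col", "both") else 0
        out.extend(_shape_index((rows + dr, cols + dc), shift))
    return out


def feature_vector(grid: np.ndarray) -> np.ndarray:
    """All Haar features of a grid across the four shifts, canonical order."""
    parts = []
    variants = frameshift_variants(grid)
    for shift in SHIFTS:
        current = variants[shift]
        while current.shape != (1, 1):
            current = pad_to_even(current)
            planes, f1 = _level_features(current)
            parts.append(planes.reshape(-1))
            current = f1
    if not parts:
        return np.empty(0)
    return np.concatenate(parts)


def feature_matrix(grids: list[ExpressionGrid]) -> tuple[list, np.ndarray]:
    """Feature vectors of all samples of one pathway, stacked row-wise.

    Returns the shared canonical index and a (n_samples, n_features)
    matrix; all grids must share dimensions.
    """
    if not grids:
        return [], np.empty((0, 0))
    shape = grids[0].grid.shape
    for g in grids:
        if g.grid.shape != shape:
            raise ValueError(
                f"grid shape mismatch: {g.sample_id} has {g.grid.shape}, expected {shape}"
            )
    index = feature_index(shape)
    mat = np.vstack([feature_vector(g.grid) for g in grids]) if index else np.empty((len(grids), 0))
    return index, mat


def extract_all(grids: list[ExpressionGrid]) -> list[WaveletFeatureSet]:
    """Per-sample feature sets over all shifts, levels and sections."""
    index, mat = feature_matrix(grids)
    out = []
    for g, row in zip(grids, mat):
        feats = [
            WaveletFeature(g.pathway_id, shift, level, (r, c), kind, float(v))
            for (shift, level, r, c, kind), v in zip(index, row)
        ]
        out.append(WaveletFeatureSet(pathway_id=g.pathway_id, sample_id=g.sample_id,
                                     features=feats))
    return out
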