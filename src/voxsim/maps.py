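"""Per-gene expression maps and map-derived features.

One gene's spatial expression pattern is a vector of log2-ratio values over
the occupied cells of a :class:`~voxsim.mask.GridMask`.  Four feature
families are extracted per gene:

* multilevel 2-D wavelet coefficients of the hemisphere-averaged map
  (spatial-frequency content; bilateral averaging suppresses noise by
  exploiting the brain's left/right symmetry),
* the raw per-voxel values,
* the mean of each adjacent voxel pair, and
* the absolute difference of each adjacent voxel pair (local gradients).

Neighbor-pair features are computed on the full un-averaged map; wavelet
features on the averaged half-map.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt

from .layout import FeatureLayout, gene_layout
from .mask import GridMask, MaskError, NeighborPairs, enumerate_neighbor_pairs


@dataclass(frozen=True)
class ExpressionMap:
    """One gene's log2-ratio values, one per occupied mask cell, mask order."""

    gene_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("expression map values must be 1-D")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite expression value for gene {self.gene_id}")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class AveragedMap:
    """Hemisphere-averaged map over the reduced (half + midline) cell set."""

    gene_id: str
    values: np.ndarray


@dataclass(frozen=True)
class MapDescriptor:
    """Per-gene flat feature vector with its segment layout."""

    gene_id: str
    values: np.ndarray
    layout: FeatureLayout

    def segment(self, name: str) -> np.ndarray:
        return self.layout.extract(self.values, name)


# ---------------------------------------------------------------------------
# I/O


def read_expression_matrix(path, mask: GridMask, sep: str | None = None) -> list[ExpressionMap]:
    """Read a gene x voxel matrix (first column gene id, columns cell labels).

    Columns are matched to the mask's occupied-cell labels and reordered to
    mask order; missing or extra columns raise :class:`MaskError`.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    wanted = list(mask.labels)
    missing = [c for c in wanted if c not in df.columns]
    if missing:
        raise MaskError(f"expression matrix lacks voxel columns: {missing[:5]}")
    df = df[wanted]
    return [ExpressionMap(str(gene), row.to_numpy(dtype=float)) for gene, row in df.iterrows()]


def write_expression_matrix(maps: list[ExpressionMap], mask: GridMask, path) -> None:
    df = pd.DataFrame(
        np.array([m.values for m in maps]),
        index=pd.Index([m.gene_id for m in maps], name="gene_id"),
        columns=list(mask.labels),
    )
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Filtering and averaging


def filter_noisy_genes(
    maps: list[ExpressionMap], lo: float = -1.0, hi: float = 1.0
) -> list[ExpressionMap]:
    """Drop genes whose whole profile lies inside [lo, hi].

    A gene with no voxel outside the band carries no signal above the
    microarray noise floor; a single strong value anywhere retains it.
    """
    if not lo < hi:
        raise ValueError("lo must be < hi")
    return [m for m in maps if not np.all((m.values >= lo) & (m.values <= hi))]


def average_hemispheres(expr: ExpressionMap, mask: GridMask) -> AveragedMap:
    """Average each mirror cell pair; midline cells pass through unchanged."""
    if expr.values.size != mask.n_voxels:
        raise MaskError(
            f"map of {expr.gene_id} has {expr.values.size} values, mask has {mask.n_voxels} cells"
        )
    value_at = {c: expr.values[i] for i, c in enumerate(mask.occupied)}
    out = {}
    for left, right in mask.mirror_pairs:
        out[min(left, right)] = 0.5 * (value_at[left] + value_at[right])
    for cell in mask.center_cells:
        out[cell] = value_at[cell]
    return AveragedMap(expr.gene_id, np.array([out[c] for c in mask.reduced_cells]))


def embed_half_grid(avg: AveragedMap, mask: GridMask) -> np.ndarray:
    """Place averaged values into their half-grid rectangle (zeros elsewhere).

    Rows span the full mask; columns span up to the right-most representative
    cell.  Unoccupied cells inside the rectangle are zero-filled so the
    rectangle is well defined for the wavelet transform.
    """
    cells = mask.reduced_cells
    if avg.values.size != len(cells):
        raise MaskError("averaged map not aligned to mask")
    n_cols = max(c for _, c in cells)
    grid = np.zeros((mask.n_rows, n_cols))
    for value, (r, c) in zip(avg.values, cells):
        grid[r - 1, c - 1] = value
    return grid


# ---------------------------------------------------------------------------
# Feature extraction


def wavelet_features(
    avg: AveragedMap,
    mask: GridMask,
    level: int = 3,
    wavelet_name: str = "haar",
    mode: str = "symmetric",
) -> np.ndarray:
    """Multilevel 2-D DWT coefficients of the embedded averaged map.

    Coefficients are concatenated coarsest-first: the level-``level``
    approximation, then per level the horizontal, vertical and diagonal
    detail sub-bands, each flattened row-major.  The output length is a
    deterministic function of (grid shape, wavelet, level, mode).
    """
    if level < 1:
        raise ValueError("level must be >= 1")
    grid = embed_half_grid(avg, mask)
    wavelet = pywt.Wavelet(wavelet_name)
    # too large = the approximation collapses to 1x1 before the last level
    shape = grid.shape
    for lev in range(level):
        if lev > 0 and shape == (1, 1):
            raise MaskError(f"level {level} too large for {grid.shape} half-grid")
        shape = tuple(pywt.dwt_coeff_len(n, wavelet.dec_len, mode) for n in shape)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # pywt warns near the boundary level
        coeffs = pywt.wavedec2(grid, wavelet, level=level, mode=mode)
    parts = [np.asarray(coeffs[0]).ravel()]
    for detail in coeffs[1:]:
        parts.extend(np.asarray(band).ravel() for band in detail)
    return np.concatenate(parts)


def wavelet_feature_count(
    mask: GridMask, level: int = 3, wavelet_name: str = "haar", mode: str = "symmetric"
) -> int:
    """Wavelet-segment length implied by a mask geometry and DWT config."""
    probe = AveragedMap("_probe", np.zeros(len(mask.reduced_cells)))
    return wavelet_features(probe, mask, level, wavelet_name, mode).size


def neighbor_features(
    expr: ExpressionMap, mask: GridMask, pairs: NeighborPairs
) -> tuple[np.ndarray, np.ndarray]:
    """Per adjacent pair (A, B): mean (A+B)/2 and absolute difference |A-B|.

    Computed on the full un-averaged map; ordering follows the pair
    enumeration (horizontal, then vertical, then diagonal).
    """
    if expr.values.size != mask.n_voxels:
        raise MaskError("map not aligned to mask")
    idx = np.array(
        [(mask.index_of(a), mask.index_of(b)) for a, b in pairs.all_pairs], dtype=int
    ).reshape(-1, 2)
    a = expr.values[idx[:, 0]] if idx.size else np.empty(0)
    b = expr.values[idx[:, 1]] if idx.size else np.empty(0)
    return 0.5 * (a + b), np.abs(a - b)


def map_descriptor(
    expr: ExpressionMap,
    mask: GridMask,
    pairs: NeighborPairs | None = None,
    level: int = 3,
    wavelet_name: str = "haar",
    mode: str = "symmetric",
) -> MapDescriptor:
    """Assemble the per-gene descriptor: wavelet | voxels | pair_avg | pair_absdiff."""
    if pairs is None:
        pairs = enumerate_neighbor_pairs(mask)
    wav = wavelet_features(average_hemispheres(expr, mask), mask, level, wavelet_name, mode)
    pair_avg, pair_absdiff = neighbor_features(expr, mask, pairs)
    layout = gene_layout(wav.size, mask.n_voxels, len(pairs))
    vector = layout.concat(
        {
            "wavelet": wav,
            "voxels": expr.values,
            "pair_avg": pair_avg,
            "pair_absdiff": pair_absdiff,
        }
    )
    return MapDescriptor(expr.gene_id, vector, layout)


def write_descriptors(descriptors: list[MapDescriptor], path, sidecar_path=None) -> None:
    """Export descriptors as TSV with a JSON layout sidecar."""
    if not descriptors:
        raise ValueError("no descriptors to write")
    layout = descriptors[0].layout
    df = pd.DataFrame(
        np.array([d.values for d in descriptors]),
        index=pd.Index([d.gene_id for d in descriptors], name="gene_id"),
    )
    df.to_csv(path, sep="\t")
    if sidecar_path is not None:
        with open(sidecar_path, "w") as fh:
            json.dump(layout.to_dict(), fh, indent=1)
            fh.write("\n")
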