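"""Reports: feature importance mapped back onto voxels, and curve export.

The ensemble's cumulated feature weights live on flat feature indices; for
interpretation they are mapped through the layout onto voxel labels (the
``voxels`` segment), voxel-pair labels (the two neighbor-pair segments)
and positional wavelet/statistic labels, then ranked.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .layout import FeatureLayout, LayoutError, feature_name
from .mask import GridMask, NeighborPairs


def voxel_significance(
    weights: np.ndarray,
    layout: FeatureLayout,
    mask: GridMask | None = None,
    pairs: NeighborPairs | None = None,
) -> pd.DataFrame:
    """Rank non-zero cumulated weights with spatial labels.

    Returns rows (feature_index, segment, label, weight) sorted by weight
    descending, ties by feature index.  Wavelet slots are reported under
    the ``wavelet`` segment without a spatial mapping.
    """
    weights = np.asarray(weights, dtype=float)
    if weights.size != layout.total:
        raise LayoutError(f"{weights.size} weights for a {layout.total}-slot layout")
    rows = []
    for index in np.flatnonzero(weights > 0):
        segment, label = feature_name(int(index), layout, mask, pairs)
        rows.append((int(index), segment, label, float(weights[index])))
    frame = pd.DataFrame(rows, columns=["feature_index", "segment", "label", "weight"])
    return frame.sort_values(
        ["weight", "feature_index"], ascending=[False, True], ignore_index=True
    )


def write_voxel_significance(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def write_curve(curve: pd.DataFrame, path) -> None:
    curve.to_csv(path, sep="\t", index=False)
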