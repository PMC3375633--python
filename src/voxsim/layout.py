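"""Feature-vector layouts.

Per-gene map descriptors and pair descriptors are flat vectors whose
segments must be addressable by name (for reporting feature importance
back onto brain voxels) and whose offsets must be reproducible.  The
reference layout used throughout is::

    wavelet (42) | voxels (68) | stats (3: R, P, dE) | pair_avg (171) | pair_absdiff (171)

for a pair descriptor of 455 slots; the per-gene descriptor is the same
without the 3 pair-level statistic slots (452 slots).  Segment lengths are
configuration, not constants: any mask geometry produces its own lengths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mask import GridMask, NeighborPairs, cell_label, pair_label

STAT_NAMES = ("R", "P", "dE")


class LayoutError(ValueError):
    """Raised on inconsistent or mismatched feature layouts."""


@dataclass(frozen=True)
class FeatureLayout:
    """Ordered named segments of a flat feature vector."""

    segments: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [name for name, _ in self.segments]
        if len(set(names)) != len(names):
            raise LayoutError("duplicate segment name")
        if any(length < 0 for _, length in self.segments):
            raise LayoutError("negative segment length")

    @property
    def total(self) -> int:
        return sum(length for _, length in self.segments)

    def offset(self, name: str) -> int:
        pos = 0
        for seg, length in self.segments:
            if seg == name:
                return pos
            pos += length
        raise LayoutError(f"no segment named {name!r}")

    def length(self, name: str) -> int:
        for seg, length in self.segments:
            if seg == name:
                return length
        raise LayoutError(f"no segment named {name!r}")

    def slice(self, name: str) -> slice:
        off = self.offset(name)
        return slice(off, off + self.length(name))

    def extract(self, vector: np.ndarray, name: str) -> np.ndarray:
        vector = np.asarray(vector)
        if vector.shape[-1] != self.total:
            raise LayoutError(f"vector length {vector.shape[-1]} != layout total {self.total}")
        return vector[..., self.slice(name)]

    def concat(self, parts: dict[str, np.ndarray]) -> np.ndarray:
        """Assemble a vector from per-segment arrays (validating lengths)."""
        chunks = []
        for name, length in self.segments:
            part = np.asarray(parts[name], dtype=float).ravel()
            if part.size != length:
                raise LayoutError(f"segment {name!r} expects {length} values, got {part.size}")
            chunks.append(part)
        return np.concatenate(chunks) if chunks else np.empty(0)

    def segment_of(self, index: int) -> tuple[str, int]:
        """Map a flat feature index to ``(segment name, index within segment)``."""
        if not 0 <= index < self.total:
            raise LayoutError(f"feature index {index} outside 0..{self.total - 1}")
        pos = 0
        for name, length in self.segments:
            if index < pos + length:
                return name, index - pos
            pos += length
        raise AssertionError("unreachable")

    def to_dict(self) -> dict:
        return {"segments": [[name, length] for name, length in self.segments]}

    @classmethod
    def from_dict(cls, spec: dict) -> "FeatureLayout":
        return cls(tuple((str(n), int(l)) for n, l in spec["segments"]))


def gene_layout(n_wavelet: int, n_voxels: int, n_pairs: int) -> FeatureLayout:
    """Layout of a per-gene map descriptor (no pair-level statistics)."""
    return FeatureLayout(
        (
            ("wavelet", n_wavelet),
            ("voxels", n_voxels),
            ("pair_avg", n_pairs),
            ("pair_absdiff", n_pairs),
        )
    )


def pair_layout(n_wavelet: int, n_voxels: int, n_pairs: int) -> FeatureLayout:
    """Layout of a gene-pair descriptor: R, P and dE sit after the voxels."""
    return FeatureLayout(
        (
            ("wavelet", n_wavelet),
            ("voxels", n_voxels),
            ("stats", len(STAT_NAMES)),
            ("pair_avg", n_pairs),
            ("pair_absdiff", n_pairs),
        )
    )


def paper_pair_layout() -> FeatureLayout:
    """The reference 455-slot layout (42 wavelet, 68 voxels, 171 pairs)."""
    return pair_layout(42, 68, 171)


def pair_layout_of(gene: FeatureLayout) -> FeatureLayout:
    """Insert the 3 pair-statistic slots into a per-gene layout."""
    segs: list[tuple[str, int]] = []
    for name, length in gene.segments:
        segs.append((name, length))
        if name == "voxels":
            segs.append(("stats", len(STAT_NAMES)))
    if ("stats", len(STAT_NAMES)) not in segs:
        raise LayoutError("per-gene layout lacks a 'voxels' segment")
    return FeatureLayout(tuple(segs))


def feature_name(
    index: int,
    layout: FeatureLayout,
    mask: GridMask | None = None,
    pairs: NeighborPairs | None = None,
) -> tuple[str, str]:
    """Human-readable ``(segment, label)`` of a flat feature index.

    Voxel slots map to cell labels and neighbor-pair slots to pair labels
    when the mask geometry is supplied; wavelet and statistic slots carry
    positional labels (wavelet coefficients have no single-voxel support).
    """
    segment, k = layout.segment_of(index)
    if segment == "wavelet":
        return segment, f"w{k + 1}"
    if segment == "stats":
        return segment, STAT_NAMES[k]
    if segment == "voxels":
        return segment, cell_label(mask.occupied[k]) if mask is not None else f"v{k + 1}"
    if segment in ("pair_avg", "pair_absdiff"):
        if pairs is not None:
            a, b = pairs.all_pairs[k]
            return segment, pair_label(a, b)
        return segment, f"p{k + 1}"
    return segment, str(k)
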