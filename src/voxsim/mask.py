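"""Grid masks for voxelated expression maps.

A coronal tissue slice is diced into a rectangular grid of 1 mm^3 voxels;
only a subset of grid cells actually carries tissue ("occupied" cells).
Cells are addressed by a letter row and a 1-based column, e.g. ``"D7"``.
The mask records which cells are occupied, how left/right hemisphere cells
pair up across the vertical midline, and which cells sit on the midline.

Cell ordering everywhere in the package is row-major (``A1, A2, ..., B1,
...``) over the occupied cells, so feature indices are reproducible.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field
from typing import Iterable, Sequence

Cell = tuple[int, int]  # (row, col), both 1-based


class MaskError(ValueError):
    """Raised for malformed or inconsistent mask declarations."""


def cell_label(cell: Cell) -> str:
    """Return the ``"D7"``-style label of a (row, col) cell."""
    row, col = cell
    if not 1 <= row <= 26:
        raise MaskError(f"row {row} outside supported range 1..26")
    return f"{string.ascii_uppercase[row - 1]}{col}"


def parse_label(label: str) -> Cell:
    """Parse a ``"D7"``-style label into a (row, col) cell."""
    label = label.strip().upper()
    if len(label) < 2 or label[0] not in string.ascii_uppercase or not label[1:].isdigit():
        raise MaskError(f"malformed cell label {label!r}")
    return (string.ascii_uppercase.index(label[0]) + 1, int(label[1:]))


def pair_label(a: Cell, b: Cell) -> str:
    """Label of an unordered cell pair, e.g. ``"(F3,E3)"`` in mask order."""
    a, b = sorted((a, b))
    return f"({cell_label(a)},{cell_label(b)})"


@dataclass(frozen=True)
class NeighborPairs:
    """Unordered pairs of adjacent occupied cells, grouped by direction.

    ``horizontal`` pairs differ by one column, ``vertical`` by one row and
    ``diagonal`` by one of each; both diagonal directions of a 2x2 block
    contribute, one pair each.
    """

    horizontal: tuple[tuple[Cell, Cell], ...]
    vertical: tuple[tuple[Cell, Cell], ...]
    diagonal: tuple[tuple[Cell, Cell], ...]

    @property
    def all_pairs(self) -> tuple[tuple[Cell, Cell], ...]:
        return self.horizontal + self.vertical + self.diagonal

    def __len__(self) -> int:
        return len(self.horizontal) + len(self.vertical) + len(self.diagonal)

    def counts(self) -> dict[str, int]:
        return {
            "horizontal": len(self.horizontal),
            "vertical": len(self.vertical),
            "diagonal": len(self.diagonal),
        }


@dataclass(frozen=True)
class GridMask:
    """Occupancy mask of the voxel grid plus hemisphere mirror pairing.

    Parameters
    ----------
    n_rows, n_cols
        Grid rectangle dimensions.
    occupied
        Occupied cells in row-major order.
    mirror_pairs
        ``(left, right)`` cell pairs averaged during hemisphere averaging.
    center_cells
        Occupied cells mapped to themselves (midline cells, plus any cell
        whose mirror is unoccupied under an asymmetric occupancy).
    """

    n_rows: int
    n_cols: int
    occupied: tuple[Cell, ...]
    mirror_pairs: tuple[tuple[Cell, Cell], ...]
    center_cells: tuple[Cell, ...]
    _index: dict[Cell, int] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        occ = set(self.occupied)
        if len(occ) != len(self.occupied):
            raise MaskError("duplicate occupied cells")
        if list(self.occupied) != sorted(self.occupied):
            raise MaskError("occupied cells must be in row-major order")
        for r, c in self.occupied:
            if not (1 <= r <= self.n_rows and 1 <= c <= self.n_cols):
                raise MaskError(f"cell {cell_label((r, c))} outside the {self.n_rows}x{self.n_cols} grid")
        seen: set[Cell] = set()
        for left, right in self.mirror_pairs:
            if left[0] != right[0]:
                raise MaskError(f"mirror pair {cell_label(left)}/{cell_label(right)} spans rows")
            for cell in (left, right):
                if cell not in occ:
                    raise MaskError(f"mirror pair references unoccupied cell {cell_label(cell)}")
                if cell in seen:
                    raise MaskError(f"cell {cell_label(cell)} appears in two mirror pairs")
                seen.add(cell)
        for cell in self.center_cells:
            if cell not in occ:
                raise MaskError(f"center cell {cell_label(cell)} is unoccupied")
            if cell in seen:
                raise MaskError(f"cell {cell_label(cell)} is both mirrored and center")
            seen.add(cell)
        if seen != occ:
            missing = sorted(occ - seen)
            raise MaskError(
                "mirror_pairs and center_cells must partition occupied; missing "
                + ", ".join(cell_label(c) for c in missing)
            )
        object.__setattr__(self, "_index", {c: i for i, c in enumerate(self.occupied)})

    # -- basic queries ---------------------------------------------------

    @property
    def n_voxels(self) -> int:
        return len(self.occupied)

    def index_of(self, cell: Cell) -> int:
        """Position of an occupied cell in mask order."""
        try:
            return self._index[cell]
        except KeyError:
            raise MaskError(f"cell {cell_label(cell)} is not occupied") from None

    def is_occupied(self, cell: Cell) -> bool:
        return cell in self._index

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(cell_label(c) for c in self.occupied)

    @property
    def reduced_cells(self) -> tuple[Cell, ...]:
        """Representative cells of the averaged (half + midline) map.

        One cell per mirror pair (the lower-column member) plus every center
        cell, in row-major order.  This is the cell ordering of
        :class:`~voxsim.maps.AveragedMap`.
        """
        reps = [min(pair) for pair in self.mirror_pairs] + list(self.center_cells)
        return tuple(sorted(reps))

    # -- construction ----------------------------------------------------

    @classmethod
    def from_cells(
        cls,
        n_rows: int,
        n_cols: int,
        occupied: Iterable[Cell],
        mirror_pairs: Sequence[tuple[Cell, Cell]] | None = None,
    ) -> "GridMask":
        """Build a mask, deriving the mirror pairing if not supplied.

        The default pairing reflects column *j* onto column ``n_cols+1-j``
        within each row.  An occupied cell whose mirror is itself is a
        center cell; a cell whose mirror is unoccupied passes through
        unchanged (treated as center) so that the partition invariant holds
        on asymmetric masks.
        """
        occ = tuple(sorted(set(occupied)))
        occ_set = set(occ)
        if mirror_pairs is None:
            pairs: list[tuple[Cell, Cell]] = []
            centers: list[Cell] = []
            for r, c in occ:
                mc = n_cols + 1 - c
                if c < mc and (r, mc) in occ_set:
                    pairs.append(((r, c), (r, mc)))
                elif c == mc or (r, mc) not in occ_set:
                    centers.append((r, c))
                # c > mc and mirror occupied: covered by its left partner
        else:
            pairs = [tuple(sorted(p)) for p in mirror_pairs]
            paired = {cell for p in pairs for cell in p}
            centers = [c for c in occ if c not in paired]
        return cls(n_rows, n_cols, occ, tuple(sorted(pairs)), tuple(sorted(centers)))

    @classmethod
    def full(cls, n_rows: int, n_cols: int) -> "GridMask":
        """Fully occupied rectangular mask with default mirror pairing."""
        return cls.from_cells(
            n_rows, n_cols, [(r, c) for r in range(1, n_rows + 1) for c in range(1, n_cols + 1)]
        )

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "occupied": [cell_label(c) for c in self.occupied],
            "mirror_pairs": [[cell_label(a), cell_label(b)] for a, b in self.mirror_pairs],
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
            fh.write("\n")


def load_mask(path) -> GridMask:
    """Read a mask declaration from JSON.

    The file must declare ``n_rows``, ``n_cols`` and ``occupied`` (cell
    labels); ``mirror_pairs`` overrides the default column-reflection
    pairing, and ``expected_neighbor_counts`` (keys ``horizontal`` /
    ``vertical`` / ``diagonal`` / ``total``), when present, is validated
    against the enumerated adjacency and a :class:`MaskError` is raised on
    mismatch.
    """
    with open(path) as fh:
        spec = json.load(fh)
    labels = [str(x) for x in spec["occupied"]]
    if len(set(labels)) != len(labels):
        raise MaskError("duplicate occupied cell label in mask file")
    occupied = [parse_label(x) for x in labels]
    mirror = spec.get("mirror_pairs")
    if mirror is not None:
        mirror = [(parse_label(a), parse_label(b)) for a, b in mirror]
    mask = GridMask.from_cells(int(spec["n_rows"]), int(spec["n_cols"]), occupied, mirror)
    expected = spec.get("expected_neighbor_counts")
    if expected:
        counts = enumerate_neighbor_pairs(mask).counts()
        counts["total"] = sum(counts.values())
        for key, want in expected.items():
            if key not in counts:
                raise MaskError(f"unknown neighbor-count key {key!r}")
            if counts[key] != int(want):
                raise MaskError(
                    f"declared {key} neighbor count {want} != enumerated {counts[key]}"
                )
    return mask


def enumerate_neighbor_pairs(mask: GridMask) -> NeighborPairs:
    """Enumerate adjacent occupied cell pairs by direction.

    Ordering is deterministic: row-major over the anchor cell, with the
    down-right diagonal of a cell listed before its down-left diagonal.
    """
    occ = set(mask.occupied)
    horizontal: list[tuple[Cell, Cell]] = []
    vertical: list[tuple[Cell, Cell]] = []
    diagonal: list[tuple[Cell, Cell]] = []
    for r, c in mask.occupied:
        if (r, c + 1) in occ:
            horizontal.append(((r, c), (r, c + 1)))
        if (r + 1, c) in occ:
            vertical.append(((r, c), (r + 1, c)))
        if (r + 1, c + 1) in occ:
            diagonal.append(((r, c), (r + 1, c + 1)))
        if (r + 1, c - 1) in occ:
            diagonal.append(((r, c), (r + 1, c - 1)))
    return NeighborPairs(tuple(horizontal), tuple(vertical), tuple(diagonal))
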