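"""Synthetic expression maps, ontologies and annotations.

No public accession exists for the voxelated expression dataset the method
was developed on, so every pipeline stage is exercised on generated data
that emulates its statistical structure: a ~68-voxel bilaterally symmetric
brain-slice mask; archetype groups of genes sharing a smooth spatial
expression profile (the analogue of a multiple functional expression
profile, MFEP) plus per-voxel Gaussian noise; and term annotations whose
pairwise Lin similarity is coupled to map similarity with a tunable
coupling strength.  ``coupling`` is the probability that a gene draws its
terms from its archetype's dedicated subtree rather than at random: at 1
map similarity and functional similarity are tightly linked, at 0 they are
independent.

Everything is driven by a single integer seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .maps import ExpressionMap
from .mask import Cell, GridMask
from .ontology import AnnotationSet, OntologyGraph


class SynthError(ValueError):
    """Raised for infeasible generator configurations."""


@dataclass
class SynthConfig:
    """Study conditions for a synthetic run.

    Defaults mirror the analysis subset the method targets: 345 genes in a
    small number of archetype profiles on a 68-voxel slice mask, moderate
    per-voxel noise, and a strong (but not perfect) coupling between a
    gene's map archetype and its functional annotations.
    """

    n_genes: int = 345
    n_archetypes: int = 5
    mask: GridMask | None = None
    noise_sd: float = 0.5
    coupling: float = 0.8
    ontology_depth: int = 4
    branching: int = 5  # >= n_archetypes so each profile owns a subtree
    terms_per_gene: int = 3
    base_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.coupling <= 1:
            raise SynthError("coupling must lie in [0, 1]")
        if self.n_archetypes > self.n_genes:
            raise SynthError("more archetypes than genes")
        if self.noise_sd < 0:
            raise SynthError("noise_sd must be non-negative")


def generate_mask(n_rows: int, n_cols: int, n_occupied: int, seed: int = 0) -> GridMask:
    """A connected occupied region, symmetric about the vertical midline.

    Starts from the full rectangle and removes mirror-symmetric cells
    (border-first) while keeping the occupied set 4-connected, so the
    result always supports hemisphere averaging and is deterministic per
    seed.
    """
    total = n_rows * n_cols
    if not 1 <= n_occupied <= total:
        raise SynthError(f"cannot occupy {n_occupied} of {total} cells")
    deficit = total - n_occupied
    if n_cols % 2 == 0 and deficit % 2 == 1:
        raise SynthError("even-column grid admits only even removal counts")
    rng = np.random.default_rng(seed)
    occupied: set[Cell] = {(r, c) for r in range(1, n_rows + 1) for c in range(1, n_cols + 1)}

    def connected(cells: set[Cell]) -> bool:
        if not cells:
            return False
        stack = [next(iter(cells))]
        seen = {stack[0]}
        while stack:
            r, c = stack.pop()
            for nb in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                if nb in cells and nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return len(seen) == len(cells)

    attempts = 0
    while deficit > 0:
        attempts += 1
        if attempts > 50 * total:
            raise SynthError("could not carve a symmetric connected mask")
        # bias removals toward the rectangle corners, like a slice outline
        cells = sorted(occupied)
        weights = np.array(
            [
                max(abs(2 * r - n_rows - 1) / max(n_rows - 1, 1), 0.05)
                * max(abs(2 * c - n_cols - 1) / max(n_cols - 1, 1), 0.05)
                for r, c in cells
            ]
        )
        pick = cells[rng.choice(len(cells), p=weights / weights.sum())]
        mirror = (pick[0], n_cols + 1 - pick[1])
        group = {pick, mirror}
        if len(group) > deficit or not group <= occupied:
            continue
        remaining = occupied - group
        if connected(remaining):
            occupied = remaining
            deficit -= len(group)
    return GridMask.from_cells(n_rows, n_cols, occupied)


def default_slice_mask(seed: int = 0) -> GridMask:
    """A 68-voxel symmetric slice-like mask on a 7x11 grid."""
    return generate_mask(7, 11, 68, seed)


def generate_ontology(
    depth: int,
    branching: int,
    n_corpus_genes: int,
    seed: int = 0,
    namespace: str = "biological_process",
) -> OntologyGraph:
    """A rooted is-a tree with a random background annotation corpus.

    ``depth`` counts term levels including the root; every internal term
    has ``branching`` children.  Each corpus gene is annotated to one
    random leaf, so annotation counts are consistent by construction
    (child sums <= parent, root = corpus size).
    """
    if depth < 2:
        raise SynthError("ontology depth must be >= 2")
    parents = _term_tree(depth, branching)
    leaves = sorted(set(parents) - {p for ps in parents.values() for p in ps})
    rng = np.random.default_rng(seed)
    annotations = {
        f"bg{i:05d}": {leaves[rng.integers(len(leaves))]} for i in range(n_corpus_genes)
    }
    return OntologyGraph(parents, namespace, annotations)


def _term_tree(depth: int, branching: int) -> dict[str, set[str]]:
    """Complete ``branching``-ary is-a tree of ``depth`` levels of terms."""
    parents: dict[str, set[str]] = {"T:root": set()}
    frontier = ["T:root"]
    for level in range(1, depth):
        nxt = []
        for parent in frontier:
            for k in range(branching):
                child = f"{parent}.{k}" if parent != "T:root" else f"T:{level}.{k}"
                parents[child] = {parent}
                nxt.append(child)
        frontier = nxt
    return parents


def _leaf_blocks(parents: dict[str, set[str]]) -> list[list[str]]:
    """Leaves grouped by the root child they descend from (disjoint blocks)."""
    children: dict[str, list[str]] = {}
    for term, ps in parents.items():
        for p in ps:
            children.setdefault(p, []).append(term)
    leaves = {t for t in parents if t not in children}

    def descend(term: str) -> list[str]:
        if term in leaves:
            return [term]
        return [leaf for child in sorted(children[term]) for leaf in descend(child)]

    return [sorted(descend(c)) for c in sorted(children.get("T:root", []))]


def generate_genes(
    config: SynthConfig,
) -> tuple[list[ExpressionMap], dict[str, AnnotationSet], OntologyGraph, np.ndarray]:
    """Generate maps, annotations, the ontology and the archetype assignment.

    Each archetype owns a smooth base map (a Gaussian field smoothed with a
    3x3 box kernel, so the wavelet features carry signal) and a disjoint
    block of leaf terms.  A gene's map is its archetype base plus i.i.d.
    Gaussian voxel noise; its annotations come from the archetype block
    with probability ``coupling`` and from all leaves otherwise.  The
    returned assignment array is the recovery ground truth.
    """
    rng = np.random.default_rng(config.seed)
    mask = config.mask if config.mask is not None else default_slice_mask(config.seed)
    n_vox = mask.n_voxels

    parents = _term_tree(config.ontology_depth, config.branching)
    blocks = _leaf_blocks(parents)
    if len(blocks) < config.n_archetypes:
        raise SynthError(
            f"{len(blocks)} top-level subtrees cannot host {config.n_archetypes} archetypes"
        )
    all_leaves = sorted(leaf for block in blocks for leaf in block)

    # smooth archetype base maps on the full grid rectangle
    bases = np.empty((config.n_archetypes, n_vox))
    for a in range(config.n_archetypes):
        field_ = rng.normal(0.0, config.base_sd, size=(mask.n_rows, mask.n_cols))
        smooth = ndimage.uniform_filter(field_, size=3, mode="nearest")
        bases[a] = np.array([smooth[r - 1, c - 1] for r, c in mask.occupied])

    assignment = np.arange(config.n_genes) % config.n_archetypes
    maps: list[ExpressionMap] = []
    annotations: dict[str, set[str]] = {}
    width = max(4, len(str(config.n_genes)))
    for i in range(config.n_genes):
        gene = f"g{i:0{width}d}"
        a = int(assignment[i])
        values = bases[a] + rng.normal(0.0, config.noise_sd, size=n_vox)
        maps.append(ExpressionMap(gene, values))
        pool = blocks[a] if rng.random() < config.coupling else all_leaves
        k = min(config.terms_per_gene, len(pool))
        annotations[gene] = set(rng.choice(pool, size=k, replace=False))

    graph = OntologyGraph(parents, "biological_process", annotations)
    sets = {g: AnnotationSet(g, frozenset(ts)) for g, ts in annotations.items()}
    return maps, sets, graph, assignment
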