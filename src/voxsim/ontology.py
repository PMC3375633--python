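"""Term information content, Lin similarity and gene-pair functional similarity.

Gene function labels come from an ontology of terms related by ``is_a``
edges (a DAG, one namespace per analysis: cellular component, molecular
function or biological process).  A term's information content is

    IC(t) = -ln( n(t) / n(root) )

where ``n(t)`` counts corpus genes annotated to ``t`` or any descendant.
Lin similarity between two terms is ``2 IC(MICA) / (IC(t1) + IC(t2))``
with MICA the common ancestor of maximal IC.  A gene pair's functional
similarity is the mean of the *non-zero* term-pair similarities across the
two genes' annotation sets (Gamma counts those non-zero pairs); if no pair
has positive similarity, the gene-pair similarity is 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

NAMESPACES = ("cellular_component", "molecular_function", "biological_process")


class OntologyError(ValueError):
    """Raised for malformed graphs or undefined similarity queries."""


@dataclass(frozen=True)
class AnnotationSet:
    """The ontology terms annotated to one gene (single namespace)."""

    gene_id: str
    terms: frozenset[str]


class OntologyGraph:
    """An is-a DAG with per-term annotation counts and information content.

    Parameters
    ----------
    parents
        Mapping term -> set of is-a parents; roots have an empty set.
    namespace
        The GO namespace this graph models.
    annotations
        Mapping gene id -> iterable of annotated terms.  Annotations are
        propagated to all ancestors; the corpus is the set of annotated
        genes, so the root's count equals the corpus size.
    """

    def __init__(
        self,
        parents: Mapping[str, Iterable[str]],
        namespace: str,
        annotations: Mapping[str, Iterable[str]],
    ) -> None:
        if namespace not in NAMESPACES:
            raise OntologyError(f"unknown namespace {namespace!r}")
        self.namespace = namespace
        self.parents: dict[str, frozenset[str]] = {
            term: frozenset(p) for term, p in parents.items()
        }
        for term, par in self.parents.items():
            unknown = par - self.parents.keys()
            if unknown:
                raise OntologyError(f"term {term} has undeclared parent(s) {sorted(unknown)}")
        dag = nx.DiGraph((t, p) for t, ps in self.parents.items() for p in ps)
        dag.add_nodes_from(self.parents)
        if not nx.is_directed_acyclic_graph(dag):
            raise OntologyError("is-a relation contains a cycle")
        # ancestor closure (term -> ancestors incl. itself), computed once
        order = list(nx.topological_sort(dag))  # parents after children
        closure: dict[str, frozenset[str]] = {}
        for term in reversed(order):  # roots first
            anc = {term}
            for p in self.parents[term]:
                anc |= closure[p]
            closure[term] = frozenset(anc)
        self._ancestors = closure

        self.annotation_count: dict[str, int] = dict.fromkeys(self.parents, 0)
        genes = 0
        for gene, terms in annotations.items():
            terms = set(terms)
            unknown = terms - self.parents.keys()
            if unknown:
                raise OntologyError(f"gene {gene} annotated to unknown term(s) {sorted(unknown)}")
            if not terms:
                continue
            genes += 1
            reached: set[str] = set()
            for t in terms:
                reached |= self._ancestors[t]
            for t in reached:
                self.annotation_count[t] += 1
        self.corpus_size = genes
        self._ic_cache: dict[str, float] = {}

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self.parents)

    def ancestors(self, term: str) -> frozenset[str]:
        """All is-a ancestors of a term, including the term itself."""
        try:
            return self._ancestors[term]
        except KeyError:
            raise OntologyError(f"unknown term {term!r}") from None

    def roots(self) -> frozenset[str]:
        return frozenset(t for t, p in self.parents.items() if not p)

    def leaves(self) -> frozenset[str]:
        has_child = {p for ps in self.parents.values() for p in ps}
        return frozenset(self.parents.keys() - has_child)


def information_content(graph: OntologyGraph, term: str) -> float:
    """IC(t) = -ln(n(t) / corpus size), in nats; 0 at the root."""
    cached = graph._ic_cache.get(term)
    if cached is not None:
        return cached
    count = graph.annotation_count.get(term)
    if count is None:
        raise OntologyError(f"unknown term {term!r}")
    if count < 1 or graph.corpus_size < 1:
        raise OntologyError(f"IC undefined: term {term} has no annotations")
    ic = max(0.0, -math.log(count / graph.corpus_size))
    graph._ic_cache[term] = ic
    return ic


def lin_similarity(graph: OntologyGraph, f1: str, f2: str) -> float:
    """Lin similarity 2 IC(MICA) / (IC(f1)+IC(f2)), in [0, 1].

    MICA is the annotated common ancestor of maximal IC (ties broken by
    term id for determinism).  When both terms are roots (IC sum 0) the
    similarity is 0 by convention.
    """
    ic1 = information_content(graph, f1)
    ic2 = information_content(graph, f2)
    if ic1 + ic2 == 0.0:
        return 0.0
    common = graph.ancestors(f1) & graph.ancestors(f2)
    best = 0.0
    for anc in sorted(common):
        if graph.annotation_count.get(anc, 0) >= 1:
            best = max(best, information_content(graph, anc))
    return 2.0 * best / (ic1 + ic2)


def positive_mean(values: Iterable[float]) -> float:
    """Mean of the strictly positive entries; 0 when there are none."""
    pos = [v for v in values if v > 0]
    return sum(pos) / len(pos) if pos else 0.0


def gene_pair_similarity(F1: AnnotationSet, F2: AnnotationSet, graph: OntologyGraph) -> float:
    """Gamma-averaged Lin similarity over the two genes' term sets.

    Averages ``lin_similarity`` over all cross pairs with similarity > 0;
    returns 0 when every cross pair has similarity 0 or either gene has no
    annotations.
    """
    if not F1.terms or not F2.terms:
        logger.warning(
            "gene pair (%s, %s): empty annotation set, similarity 0", F1.gene_id, F2.gene_id
        )
        return 0.0
    return positive_mean(
        lin_similarity(graph, f1, f2) for f1 in sorted(F1.terms) for f2 in sorted(F2.terms)
    )


def binarize_label(d: float, threshold: float) -> int:
    """+1 iff the similarity strictly exceeds the threshold, else -1."""
    if not 0.0 <= d <= 1.0:
        raise ValueError(f"similarity {d} outside [0, 1]")
    return 1 if d > threshold else -1


# ---------------------------------------------------------------------------
# I/O


def load_obo(path, namespace: str) -> dict[str, set[str]]:
    """Read is-a parent relations for one namespace from an OBO file."""
    graph = obonet.read_obo(path)
    parents: dict[str, set[str]] = {}
    for term, data in graph.nodes(data=True):
        if data.get("namespace", namespace) != namespace:
            continue
        parents[term] = set(data.get("is_a", []))
    for term in parents:
        parents[term] &= parents.keys()  # drop cross-namespace parents
    return parents


def load_annotations(path, namespace: str) -> dict[str, set[str]]:
    """Read a GAF-like TSV (gene_id, term_id, namespace) for one namespace."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("gene_id"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise OntologyError(f"malformed annotation line: {line!r}")
            gene, term, ns = fields[0], fields[1], fields[2]
            if ns != namespace:
                continue
            out.setdefault(gene, set()).add(term)
    return out


def build_graph(obo_path, annotation_path, namespace: str) -> tuple[OntologyGraph, dict[str, AnnotationSet]]:
    """Load ontology + annotations and return the graph and per-gene sets."""
    parents = load_obo(obo_path, namespace)
    raw = load_annotations(annotation_path, namespace)
    known = {g: ts & parents.keys() for g, ts in raw.items()}
    graph = OntologyGraph(parents, namespace, known)
    sets = {g: AnnotationSet(g, frozenset(ts)) for g, ts in known.items() if ts}
    return graph, sets


def write_obo(parents: Mapping[str, Iterable[str]], namespace: str, path) -> None:
    """Write an is-a term graph as minimal OBO."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        fh.write(f"ontology: {namespace}\n")
        for term in sorted(parents):
            fh.write(f"\n[Term]\nid: {term}\nname: {term}\nnamespace: {namespace}\n")
            for parent in sorted(parents[term]):
                fh.write(f"is_a: {parent}\n")


def write_annotations(annotations: Mapping[str, Iterable[str]], namespace: str, path) -> None:
    """Write gene -> term annotations as GAF-like TSV."""
    with open(path, "w") as fh:
        fh.write("gene_id\tterm_id\tnamespace\n")
        for gene in sorted(annotations):
            for term in sorted(annotations[gene]):
                fh.write(f"{gene}\t{term}\t{namespace}\n")
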