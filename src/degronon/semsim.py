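"""Graph-based GO semantic similarity (Wang measure), implemented from its
recursive definition.

The Wang measure scores the similarity of two ontology terms from their
positions in the GO graph.  Each term ``t`` defines semantic contributions
(S-values) over its ancestor closure: ``S_t(t) = 1`` and, for an ancestor
``a``, ``S_t(a) = max over child edges (c -> a)`` of ``w_rel * S_t(c)``,
where the edge weight ``w_rel`` depends on the relation (0.8 for is_a, 0.6
for part_of by default).  The similarity of two terms is

    sim(t1, t2) = sum_{a in common ancestors} (S_t1(a) + S_t2(a))
                  / (SV(t1) + SV(t2)),

with ``SV(t)`` the sum of all of ``t``'s S-values.  Gene-level similarity
combines the pairwise term matrix by best-match averaging (BMA).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

logger = logging.getLogger(__name__)

IS_A = "is_a"
PART_OF = "part_of"

DEFAULT_EDGE_WEIGHTS = {IS_A: 0.8, PART_OF: 0.6}

#: Evidence codes retained by default: direct assay and physical interaction.
DEFAULT_EVIDENCE_CODES = frozenset({"IDA", "IPI"})

BP_NAMESPACE = "biological_process"


@dataclass(frozen=True)
class SemSimParams:
    edge_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EDGE_WEIGHTS)
    )
    combine: str = "best_match_average"

    def __post_init__(self) -> None:
        for rel, w in self.edge_weights.items():
            if not (0.0 < w < 1.0):
                raise ValueError(f"edge weight for {rel} must be in (0,1), got {w}")


class GoDag:
    """A typed, acyclic ontology graph restricted to is_a / part_of edges.

    ``edges`` are (child, parent, relation) triples; ``namespace`` maps each
    term to its ontology namespace.  Other relations (regulates, ...) should
    be dropped by the caller: the similarity measure defines weights only for
    is_a and part_of.
    """

    def __init__(
        self,
        terms: Iterable[str],
        edges: Iterable[tuple[str, str, str]],
        namespace: Optional[Mapping[str, str]] = None,
    ) -> None:
        self.terms: set[str] = set(terms)
        self.parents: dict[str, list[tuple[str, str]]] = {t: [] for t in self.terms}
        self.children: dict[str, list[tuple[str, str]]] = {t: [] for t in self.terms}
        for child, parent, rel in edges:
            if rel not in (IS_A, PART_OF):
                continue
            if child not in self.terms or parent not in self.terms:
                raise ValueError(f"edge references unknown term: {child} -> {parent}")
            self.parents[child].append((parent, rel))
            self.children[parent].append((child, rel))
        self.namespace: dict[str, str] = dict(namespace or {})
        self._assert_acyclic()

    @classmethod
    def from_obo(cls, path: str) -> "GoDag":
        """Load an OBO v1.2 ontology via obonet, keeping is_a/part_of edges."""
        import obonet

        graph = obonet.read_obo(path)
        terms = [n for n, d in graph.nodes(data=True) if not d.get("is_obsolete")]
        term_set = set(terms)
        edges = []
        for child, parent, rel in graph.edges(keys=True):
            if rel in (IS_A, PART_OF) and child in term_set and parent in term_set:
                edges.append((child, parent, rel))
        ns = {
            n: graph.nodes[n].get("namespace", "")
            for n in terms
        }
        return cls(terms, edges, ns)

    def _assert_acyclic(self) -> None:
        # Kahn's algorithm over child->parent edges
        indeg = {t: len(self.parents[t]) for t in self.terms}
        stack = [t for t, d in indeg.items() if d == 0]
        seen = 0
        while stack:
            t = stack.pop()
            seen += 1
            for child, _ in self.children[t]:
                indeg[child] -= 1
                if indeg[child] == 0:
                    stack.append(child)
        if seen != len(self.terms):
            raise ValueError("ontology graph contains a cycle")

    def ancestors(self, term: str) -> set[str]:
        """All ancestors of ``term`` (excluding the term itself)."""
        out: set[str] = set()
        stack = [term]
        while stack:
            t = stack.pop()
            for parent, _ in self.parents[t]:
                if parent not in out:
                    out.add(parent)
                    stack.append(parent)
        return out

    def descendants(self, term: str) -> set[str]:
        out: set[str] = set()
        stack = [term]
        while stack:
            t = stack.pop()
            for child, _ in self.children[t]:
                if child not in out:
                    out.add(child)
                    stack.append(child)
        return out


def compute_s_values(
    term: str, dag: GoDag, params: Optional[SemSimParams] = None
) -> dict[str, float]:
    """S-values of ``term`` over its ancestor closure.

    ``S(term) = 1``; for each ancestor ``a``, ``S(a)`` is the maximum over
    edges ``(c -> a)`` with ``c`` inside the closure of ``w_rel * S(c)``.
    Processing terms in topological order (children before parents within the
    closure) makes the recursion a single dynamic-programming pass.
    """
    if term not in dag.terms:
        raise ValueError(f"unknown term: {term}")
    params = params or SemSimParams()
    closure = dag.ancestors(term) | {term}
    # topological order within the closure: process a term once all its
    # in-closure children are done
    pending_children = {
        t: sum(1 for c, _ in dag.children[t] if c in closure) for t in closure
    }
    order: list[str] = [t for t in closure if pending_children[t] == 0]
    s: dict[str, float] = {}
    i = 0
    queue = list(order)
    while i < len(queue):
        t = queue[i]
        i += 1
        if t == term:
            s[t] = 1.0
        else:
            s[t] = max(
                params.edge_weights[rel] * s[c]
                for c, rel in dag.children[t]
                if c in closure
            )
        for parent, _ in dag.parents[t]:
            if parent in closure:
                pending_children[parent] -= 1
                if pending_children[parent] == 0:
                    queue.append(parent)
    return s


def term_similarity(
    t1: str, t2: str, dag: GoDag, params: Optional[SemSimParams] = None
) -> float:
    """Wang similarity of two terms in the same namespace, in [0, 1]."""
    params = params or SemSimParams()
    ns1 = dag.namespace.get(t1)
    ns2 = dag.namespace.get(t2)
    if ns1 is not None and ns2 is not None and ns1 != ns2:
        raise ValueError(f"cross-namespace comparison: {t1} ({ns1}) vs {t2} ({ns2})")
    s1 = compute_s_values(t1, dag, params)
    s2 = compute_s_values(t2, dag, params)
    common = set(s1) & set(s2)
    if not common:
        return 0.0
    return sum(s1[a] + s2[a] for a in common) / (sum(s1.values()) + sum(s2.values()))


def gene_similarity(
    terms1: set[str],
    terms2: set[str],
    dag: GoDag,
    params: Optional[SemSimParams] = None,
) -> Optional[float]:
    """Best-match-average similarity of two genes' term sets.

    BMA is the arithmetic mean of (mean of row maxima, mean of column maxima)
    of the pairwise term-similarity matrix.  Returns ``None`` when either
    gene has no annotation.
    """
    if not terms1 or not terms2:
        return None
    params = params or SemSimParams()
    t1 = sorted(terms1)
    t2 = sorted(terms2)
    matrix = [[term_similarity(a, b, dag, params) for b in t2] for a in t1]
    row_max = [max(row) for row in matrix]
    col_max = [max(matrix[i][j] for i in range(len(t1))) for j in range(len(t2))]
    return 0.5 * (sum(row_max) / len(row_max) + sum(col_max) / len(col_max))


class PairwiseSemSim:
    """Gene-pair similarity with per-term S-value caching.

    Precomputing each annotated term's S-values once makes all-pairs
    similarity over a network's node set tractable.
    """

    def __init__(
        self,
        annotations: Mapping[str, set[str]],
        dag: GoDag,
        params: Optional[SemSimParams] = None,
    ) -> None:
        self.annotations = annotations
        self.dag = dag
        self.params = params or SemSimParams()
        self._s: dict[str, dict[str, float]] = {}
        self._sv: dict[str, float] = {}

    def _term(self, t: str) -> tuple[dict[str, float], float]:
        if t not in self._s:
            s = compute_s_values(t, self.dag, self.params)
            self._s[t] = s
            self._sv[t] = sum(s.values())
        return self._s[t], self._sv[t]

    def term_sim(self, t1: str, t2: str) -> float:
        s1, sv1 = self._term(t1)
        s2, sv2 = self._term(t2)
        common = s1.keys() & s2.keys()
        if not common:
            return 0.0
        return sum(s1[a] + s2[a] for a in common) / (sv1 + sv2)

    def gene_sim(self, g1: str, g2: str) -> Optional[float]:
        terms1 = sorted(self.annotations.get(g1, ()))
        terms2 = sorted(self.annotations.get(g2, ()))
        if not terms1 or not terms2:
            return None
        matrix = [[self.term_sim(a, b) for b in terms2] for a in terms1]
        row_max = [max(row) for row in matrix]
        col_max = [max(matrix[i][j] for i in range(len(terms1))) for j in range(len(terms2))]
        return 0.5 * (sum(row_max) / len(row_max) + sum(col_max) / len(col_max))

    def all_pairs(self, genes: Iterable[str]) -> dict[frozenset, float]:
        genes = sorted(set(genes) & set(self.annotations))
        out: dict[frozenset, float] = {}
        for i, g1 in enumerate(genes):
            for g2 in genes[i + 1 :]:
                sim = self.gene_sim(g1, g2)
                if sim is not None:
                    out[frozenset((g1, g2))] = sim
        return out


def filter_annotations(
    records: Iterable[tuple[str, str, str]],
    dag: GoDag,
    codes: frozenset[str] = DEFAULT_EVIDENCE_CODES,
    namespace: str = BP_NAMESPACE,
) -> dict[str, set[str]]:
    """Evidence- and namespace-filter GAF-like (gene, term, evidence) records.

    Keeps only records with a retained evidence code whose term belongs to
    ``namespace``; terms absent from the DAG (e.g. obsolete) are dropped with
    a warning.  Genes losing every term are logged and omitted.
    """
    raw: dict[str, set[str]] = {}
    kept: dict[str, set[str]] = {}
    for gene, term, code in records:
        raw.setdefault(gene, set()).add(term)
        if code not in codes:
            continue
        if term not in dag.terms:
            logger.warning("dropping annotation to unknown/obsolete term %s", term)
            continue
        if dag.namespace and dag.namespace.get(term) != namespace:
            continue
        kept.setdefault(gene, set()).add(term)
    lost = set(raw) - set(kept)
    if lost:
        logger.info("%d genes lost all annotations after filtering", len(lost))
    return kept
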