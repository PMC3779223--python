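"""Wang-method GO semantic similarity and its superfamily aggregation.

Similarity between two GO terms follows the Wang (G-SESAME) scheme: each
term's contribution is propagated up the DAG as an *S-value* — 1 at the
term itself, and for every ancestor the maximum over child paths of the
child's S-value times an edge factor (0.8 for ``is_a``, 0.6 for
``part_of`` by default).  Two terms are compared through their shared
ancestors::

    sim(t1, t2) = sum_{u in common} (S1(u) + S2(u))
                  / (sum_u S1(u) + sum_u S2(u))

Aggregation proceeds in two levels: the similarity of a *pair of domains*
is the plain mean of all cross term pairs between their annotation sets,
and each member's score is the grand average of its pair means against
every other annotated member.  Outlier and non-outlier group means are
then compared directly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import networkx as nx
import obonet
import pandas as pd

from .errors import OntologyCycleError, UndefinedTermError

logger = logging.getLogger(__name__)

#: Edge types with a Wang contribution factor; anything else is ignored.
EDGE_TYPES = ("is_a", "part_of")


@dataclass(frozen=True)
class WangWeights:
    """Semantic contribution factors per edge type, each in (0, 1)."""

    w_is_a: float = 0.8
    w_part_of: float = 0.6

    def __post_init__(self) -> None:
        for w in (self.w_is_a, self.w_part_of):
            if not 0.0 < w < 1.0:
                raise ValueError("contribution factors must lie in (0, 1)")

    def factor(self, edge_type: str) -> float:
        return self.w_is_a if edge_type == "is_a" else self.w_part_of


@dataclass(frozen=True)
class GOOntology:
    """A GO DAG: term ids with names, typed child->parent edges."""

    graph: nx.MultiDiGraph = field(repr=False)  # edges child -> parent

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise OntologyCycleError("term graph contains a cycle")
        for child, parent, rel in self.graph.edges(keys=True):
            if rel not in EDGE_TYPES:
                raise ValueError(f"unexpected edge type {rel!r}")

    @property
    def terms(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def roots(self) -> set[str]:
        return {t for t in self.graph.nodes
                if self.graph.out_degree(t) == 0}

    def name(self, term: str) -> str:
        return self.graph.nodes[term].get("name", term)

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    @classmethod
    def from_edges(cls, terms: Mapping[str, str],
                   edges: Iterable[tuple[str, str, str]]) -> "GOOntology":
        """Build from {term: name} and (child, parent, type) triples."""
        g = nx.MultiDiGraph()
        for t, name in terms.items():
            g.add_node(t, name=name)
        for child, parent, rel in edges:
            for t in (child, parent):
                if t not in g:
                    raise UndefinedTermError(f"edge references {t!r} which "
                                             "is not a defined term")
            g.add_edge(child, parent, key=rel)
        return cls(g)


def parse_obo(path) -> GOOntology:
    """Parse an OBO 1.2 file into a :class:`GOOntology`.

    Obsolete terms are skipped; relationship types other than ``part_of``
    are dropped with a warning; a term referenced as a parent but never
    defined, or a cyclic graph, is an error.
    """
    raw = obonet.read_obo(path, ignore_obsolete=True)
    g = nx.MultiDiGraph()
    for node, data in raw.nodes(data=True):
        if "name" not in data:
            raise UndefinedTermError(
                f"term {node!r} is referenced but has no stanza")
        g.add_node(node, name=data["name"])
    for child, parent, rel in raw.edges(keys=True):
        if rel not in EDGE_TYPES:
            logger.warning("ignoring relationship %r (%s -> %s)",
                           rel, child, parent)
            continue
        g.add_edge(child, parent, key=rel)
    return GOOntology(g)


def write_obo(path, onto: GOOntology, header: str = "format-version: 1.2"
              ) -> None:
    """Serialize deterministically (sorted stanzas, sorted parents)."""
    blocks = [header]
    for t in onto.terms:
        lines = [f"[Term]", f"id: {t}", f"name: {onto.name(t)}"]
        edges = sorted(onto.graph.edges(t, keys=True))
        for _, parent, rel in edges:
            if rel == "is_a":
                lines.append(f"is_a: {parent} ! {onto.name(parent)}")
            else:
                lines.append(f"relationship: part_of {parent} "
                             f"! {onto.name(parent)}")
        blocks.append("\n".join(lines))
    with open(path, "w") as fh:
        fh.write("\n\n".join(blocks) + "\n")


# ---------------------------------------------------------------------------
# Wang similarity
# ---------------------------------------------------------------------------

def svalues(term: str, onto: GOOntology,
            w: WangWeights | None = None) -> dict[str, float]:
    """S-values of *term* over itself and all its ancestors.

    ``S(term) = 1``; for each ancestor ``u``,
    ``S(u) = max over children c of u on paths from term of w(c->u) * S(c)``,
    evaluated by dynamic programming in topological order.
    """
    w = w or WangWeights()
    if term not in onto:
        raise UndefinedTermError(f"unknown term {term!r}")
    g = onto.graph
    reach = {term} | nx.descendants(g, term)  # edges point to parents
    sub = g.subgraph(reach)
    S = {term: 1.0}
    for u in nx.topological_sort(sub):
        if u == term:
            continue
        S[u] = max(w.factor(rel) * S[c]
                   for c, _, rel in sub.in_edges(u, keys=True))
    return S


def term_similarity(t1: str, t2: str, onto: GOOntology,
                    w: WangWeights | None = None) -> float:
    """Wang similarity of two terms, in [0, 1].

    Terms with no shared ancestor (e.g. different GO namespaces) score 0.
    """
    S1 = svalues(t1, onto, w)
    S2 = svalues(t2, onto, w)
    common = set(S1) & set(S2)
    if not common:
        return 0.0
    num = math.fsum(S1[u] + S2[u] for u in sorted(common))
    den = math.fsum(S1.values()) + math.fsum(S2.values())
    return num / den


def domain_pair_similarity(terms_a: Iterable[str], terms_b: Iterable[str],
                           onto: GOOntology | None = None,
                           w: WangWeights | None = None,
                           method: str = "all-pairs",
                           skip_disjoint: bool = False,
                           sim_func: Callable[[str, str], float] | None = None
                           ) -> float:
    """Mean similarity between two domains' annotation sets.

    The default aggregation averages ``term_similarity`` over all
    ``|A| x |B|`` cross pairs — every GO term pair that *could* be
    compared.  ``method="best-match"`` instead averages each term's best
    match in the other set (both directions); it is offered as an
    alternative aggregation, not the default.  ``skip_disjoint`` drops
    zero-ancestry (cross-namespace) pairs from the mean instead of
    counting them as 0.

    *sim_func* overrides the term-level similarity (e.g. to aggregate
    published per-pair values); otherwise the Wang similarity over *onto*
    is used.
    """
    A = sorted(set(terms_a))
    B = sorted(set(terms_b))
    if not A or not B:
        raise ValueError("both annotation sets must be non-empty")
    if sim_func is None:
        if onto is None:
            raise ValueError("an ontology is required without sim_func")
        sim_func = lambda x, y: term_similarity(x, y, onto, w)  # noqa: E731

    sims = {(x, y): sim_func(x, y) for x in A for y in B}
    if skip_disjoint:
        sims = {k: v for k, v in sims.items() if v > 0.0}
        if not sims:
            return 0.0
    if method == "all-pairs":
        return math.fsum(sims.values()) / len(sims)
    if method == "best-match":
        fwd = [max(sims[(x, y)] for y in B if (x, y) in sims)
               for x in A if any((x, y) in sims for y in B)]
        rev = [max(sims[(x, y)] for x in A if (x, y) in sims)
               for y in B if any((x, y) in sims for x in A)]
        return math.fsum(fwd + rev) / (len(fwd) + len(rev))
    raise ValueError(f"unknown aggregation method {method!r}")


def member_semantic_score(member: str,
                          annotations: Mapping[str, Iterable[str]],
                          onto: GOOntology,
                          w: WangWeights | None = None,
                          method: str = "all-pairs",
                          skip_disjoint: bool = False) -> float | None:
    """Grand average of a member's pair means against all other annotated
    members; ``None`` when the member (or everyone else) is unannotated."""
    ann = {m: set(ts) for m, ts in annotations.items() if ts}
    if member not in ann:
        return None
    others = sorted(m for m in ann if m != member)
    if not others:
        return None
    vals = [domain_pair_similarity(ann[member], ann[m], onto, w,
                                   method=method, skip_disjoint=skip_disjoint)
            for m in others]
    return math.fsum(vals) / len(vals)


@dataclass
class SemanticReport:
    """Two-level GO aggregation results for one superfamily."""

    pair_means: dict[tuple[str, str], float]
    member_scores: dict[str, float]
    group_means: tuple[float | None, float | None] = (None, None)

    @property
    def outlier_mean(self) -> float | None:
        return self.group_means[0]

    @property
    def non_outlier_mean(self) -> float | None:
        return self.group_means[1]


def semantic_report(annotations: Mapping[str, Iterable[str]],
                    onto: GOOntology,
                    w: WangWeights | None = None,
                    method: str = "all-pairs",
                    skip_disjoint: bool = False) -> SemanticReport:
    """Pair means and grand averages for every annotated member."""
    ann = {m: set(ts) for m, ts in sorted(annotations.items()) if ts}
    members = sorted(ann)
    pair_means: dict[tuple[str, str], float] = {}
    for i, a in enumerate(members):
        for b in members[i + 1:]:
            v = domain_pair_similarity(ann[a], ann[b], onto, w,
                                       method=method,
                                       skip_disjoint=skip_disjoint)
            pair_means[(a, b)] = pair_means[(b, a)] = v
    scores = {}
    for m in members:
        vals = [pair_means[(m, x)] for x in members if x != m]
        if vals:
            scores[m] = math.fsum(vals) / len(vals)
    return SemanticReport(pair_means=pair_means, member_scores=scores)


def semantics_vs_deviation(report, sem: SemanticReport) -> pd.DataFrame:
    """Per-member table joining mean RMSD, GO score and outlier flag.

    Also fills ``sem.group_means`` with the outlier and non-outlier group
    averages (``None`` for an empty group).  Members missing from the
    semantic report are an error — the two reports must cover the same
    members (unannotated members are excluded upstream by dropping them
    from the annotation table, not silently here).
    """
    missing = [m for m in report.member_ids if m not in sem.member_scores]
    if missing:
        raise ValueError(f"no semantic score for members: {missing}")
    rows = []
    for m in report.member_ids:
        rows.append({"member_id": m,
                     "mean_rmsd": report.mean_rmsd[m],
                     "go_semantics": sem.member_scores[m],
                     "is_outlier": m in report.outliers})
    df = pd.DataFrame(rows)
    grp = []
    for flag in (True, False):
        vals = df.loc[df.is_outlier == flag, "go_semantics"]
        grp.append(float(vals.mean()) if len(vals) else None)
    sem.group_means = (grp[0], grp[1])
    return df
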