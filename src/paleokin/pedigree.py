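"""Rule-based pedigree reconstruction from pairwise kinship evidence.

The engine consumes gated :class:`~paleokin.kinstats.PairKinship` records
plus per-individual metadata (sex, age class, uniparental haplogroups)
and emits a typed kin graph: directed parent-of edges, sibling edges,
and second-degree edges with a candidate-type set. The rule order is
fixed: uniparental/age rules before k-based evidence, the two sibling
triangulation rules applied to fixpoint, and X-chromosome theta last as
a pruner. Unresolvable choices carry ambiguity flags rather than
guesses; contradictory hard evidence flags the edge instead of dropping
it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .core import IndividualRecord
from .kinstats import AUTO_OVERLAP_GATE, X_OVERLAP_GATE, PairKinship

SECOND_DEGREE_CANDIDATES = ("grandparental", "avuncular", "half-sibling")


@dataclass
class FirstDegreeThresholds:
    """Evidence cutoffs for parent-offspring vs sibling typing."""

    k1_parent_offspring: float = 0.75
    k2_sibling: float = 0.15
    r0_parent_offspring_max: float = 0.05
    theta_x_low: float = 0.10       # male-male: compatible with father-son
    theta_x_high: float = 0.25      # male-male: maternal-line sharing


@dataclass
class KinEdge:
    id1: str
    id2: str
    kind: str                       # parent-of / sibling / second-degree
    role: str | None = None         # mother / father for parent-of
    subtype: str | None = None      # typed second-degree relation
    candidates: tuple = ()
    basis: str = ""
    ambiguous: bool = False
    inconsistent: bool = False
    conflict: bool = False
    notes: list = field(default_factory=list)


class PedigreeGraph:
    """Typed kin graph with determinism and acyclicity guarantees."""

    def __init__(self, records: Sequence[IndividualRecord]):
        self.records = {r.id: r for r in records}
        self.parent_edges: list[KinEdge] = []
        self.sibling_edges: list[KinEdge] = []
        self.second_edges: list[KinEdge] = []
        self.annotations: list[str] = []
        self._dag = nx.DiGraph()
        self._dag.add_nodes_from(self.records)

    def add_parent(self, parent: str, child: str, **kw) -> KinEdge:
        edge = KinEdge(parent, child, "parent-of", **kw)
        self._dag.add_edge(parent, child)
        if not nx.is_directed_acyclic_graph(self._dag):
            self._dag.remove_edge(parent, child)
            edge.inconsistent = True
            edge.notes.append("rejected: would create an ancestry cycle")
        self.parent_edges.append(edge)
        return edge

    def add_sibling(self, a: str, b: str, **kw) -> KinEdge:
        a, b = sorted((a, b))
        edge = KinEdge(a, b, "sibling", **kw)
        self.sibling_edges.append(edge)
        return edge

    def add_second(self, a: str, b: str, **kw) -> KinEdge:
        a, b = sorted((a, b))
        kw.setdefault("candidates", SECOND_DEGREE_CANDIDATES)
        edge = KinEdge(a, b, "second-degree", **kw)
        self.second_edges.append(edge)
        return edge

    # -- views ---------------------------------------------------------------
    def sibling_pairs(self) -> list[tuple[str, str]]:
        return [(e.id1, e.id2) for e in self.sibling_edges if not e.inconsistent]

    def parent_of(self) -> set[tuple[str, str]]:
        return {(e.id1, e.id2) for e in self.parent_edges if not e.inconsistent}

    def to_edge_table(self):
        import pandas as pd
        rows = []
        for e in (*self.parent_edges, *self.sibling_edges, *self.second_edges):
            rows.append({
                "id1": e.id1, "id2": e.id2, "kind": e.kind, "role": e.role,
                "subtype": e.subtype, "candidates": "|".join(e.candidates),
                "basis": e.basis, "ambiguous": e.ambiguous,
                "inconsistent": e.inconsistent, "conflict": e.conflict,
                "notes": "; ".join(e.notes)})
        df = pd.DataFrame(rows, columns=["id1", "id2", "kind", "role",
                                         "subtype", "candidates", "basis",
                                         "ambiguous", "inconsistent",
                                         "conflict", "notes"])
        return df.sort_values(["kind", "id1", "id2"]).reset_index(drop=True)

    def to_dot(self) -> str:
        lines = ["digraph pedigree {"]
        for name in sorted(self.records):
            r = self.records[name]
            shape = {"XY": "box", "XX": "ellipse"}.get(r.genetic_sex, "diamond")
            lines.append(f'  "{name}" [shape={shape}];')
        for e in sorted(self.parent_edges, key=lambda e: (e.id1, e.id2)):
            style = ' style=dashed' if e.ambiguous or e.inconsistent else ""
            lines.append(f'  "{e.id1}" -> "{e.id2}" [label="{e.role or "parent"}"'
                         f'{style}];')
        for e in sorted(self.sibling_edges, key=lambda e: (e.id1, e.id2)):
            lines.append(f'  "{e.id1}" -> "{e.id2}" [dir=none label="sib"];')
        for e in sorted(self.second_edges, key=lambda e: (e.id1, e.id2)):
            lab = e.subtype or "2nd"
            lines.append(f'  "{e.id1}" -> "{e.id2}" [dir=none style=dotted '
                         f'label="{lab}"];')
        lines.append("}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Gates
# ---------------------------------------------------------------------------

def gate_pairs(pairs: Iterable[PairKinship],
               auto_gate: int = AUTO_OVERLAP_GATE,
               x_gate: int = X_OVERLAP_GATE) -> list[PairKinship]:
    """Admit only pairs whose autosomal evidence clears the overlap gate.

    X evidence is flagged per pair (``gate_x``); a pair gated on
    autosomes but not on X keeps its degree while theta_X rules are
    skipped. Sub-gate evidence never enters the rule engine.
    """
    out = []
    for pk in pairs:
        pk.gate_auto = pk.n_overlap_auto >= auto_gate
        pk.gate_x = pk.n_overlap_x >= x_gate
        if pk.gate_auto:
            out.append(pk)
    return out


# ---------------------------------------------------------------------------
# First-degree typing
# ---------------------------------------------------------------------------

def type_first_degree(pk: PairKinship, rec1: IndividualRecord,
                      rec2: IndividualRecord,
                      thresholds: FirstDegreeThresholds | None = None):
    """Distinguish parent-offspring from siblings for a first-degree pair.

    Rule order: (a) two juveniles are siblings; (b) two males sharing a
    mitochondrial haplogroup are siblings; (c) adult female + juvenile
    with shared mito is mother-child; (d) k-coefficients (k1 near 1 with
    no opposite homozygotes is parent-offspring, appreciable k2 is
    siblings); (e) male-male theta_X near zero as a father-son
    tiebreaker. Returns ``(kind, parent_id_or_None, basis, ambiguous,
    inconsistent)``.
    """
    t = thresholds or FirstDegreeThresholds()
    same_mito = (rec1.mito_haplogroup and rec1.mito_haplogroup
                 == rec2.mito_haplogroup)
    males = rec1.genetic_sex == "XY" and rec2.genetic_sex == "XY"
    juv1, juv2 = rec1.age_class == "juvenile", rec2.age_class == "juvenile"

    po_supported = (np.isfinite(pk.k1) and pk.k1 >= t.k1_parent_offspring
                    and (not np.isfinite(pk.r0)
                         or pk.r0 <= t.r0_parent_offspring_max))
    sib_supported = np.isfinite(pk.k2) and pk.k2 >= t.k2_sibling

    if juv1 and juv2:
        return ("sibling", None, "both juveniles", False,
                bool(po_supported and not sib_supported))
    if males and same_mito:
        return ("sibling", None, "males sharing mito haplogroup", False,
                bool(po_supported and not sib_supported))
    if same_mito and (juv1 != juv2):
        adult, child = (rec1, rec2) if juv2 else (rec2, rec1)
        if adult.genetic_sex == "XX":
            # shared mito is expected either way; k-evidence arbitrates
            if sib_supported and not po_supported:
                return ("sibling", None,
                        "shared mito but sibling-like k2", False, False)
            return ("parent-offspring", adult.id,
                    "adult female + juvenile, shared mito", False,
                    bool(sib_supported and po_supported))
    if po_supported and not sib_supported:
        parent = None
        ambiguous = False
        if juv1 != juv2:
            parent = rec2.id if juv1 else rec1.id
        elif same_mito and {rec1.genetic_sex, rec2.genetic_sex} == {"XX", "XY"}:
            # a father-daughter pair would not share mito: female is mother
            parent = rec1.id if rec1.genetic_sex == "XX" else rec2.id
        elif rec1.age_class == rec2.age_class:
            ambiguous = True        # direction undecidable from age
        if parent is None and not ambiguous:
            parent = rec1.id if rec1.age_class == "adult" else rec2.id
        return ("parent-offspring", parent, "k1 ~ 1, no opposite homozygotes",
                ambiguous, False)
    if sib_supported and not po_supported:
        return ("sibling", None, "appreciable k2", False, False)
    if males and pk.gate_x and np.isfinite(pk.theta_x):
        if pk.theta_x <= t.theta_x_low:
            parent = None
            if juv1 != juv2:
                parent = rec2.id if juv1 else rec1.id
            return ("parent-offspring", parent,
                    "male-male theta_X ~ 0 (father-son)", parent is None, False)
    if po_supported and sib_supported:
        return ("first-ambiguous", None,
                "conflicting k evidence (k1 and k2 both high)", True, True)
    return ("first-ambiguous", None, "insufficient evidence", True, False)


# ---------------------------------------------------------------------------
# Second-degree triangulation
# ---------------------------------------------------------------------------

def triangulate_second_degree(graph: PedigreeGraph,
                              pairs: Sequence[PairKinship],
                              thresholds: FirstDegreeThresholds | None = None
                              ) -> None:
    """Apply the sibling-pair triangulation rules to fixpoint.

    Rule 1: an individual first-degree to one of two known siblings and
    second-degree to the other is the first sibling's child and the
    second's niece/nephew. Rule 2: second-degree to only one sibling
    (the other genotyped and unrelated) means grandchild of that
    sibling. Remaining second-degree edges keep the full candidate set;
    male-male pairs with gated X evidence get theta_X-based candidate
    pruning notes.
    """
    t = thresholds or FirstDegreeThresholds()
    degree = {}
    by_pair = {}
    for pk in pairs:
        key = tuple(sorted((pk.id1, pk.id2)))
        degree[key] = pk.degree_final
        by_pair[key] = pk

    def deg(a, b):
        return degree.get(tuple(sorted((a, b))))

    second_keys = sorted(k for k, d in degree.items() if d == "second")
    typed: dict[tuple, KinEdge] = {}
    untouched = set(second_keys)
    changed = True
    while changed:
        changed = False
        for key in second_keys:
            a, b = key
            for x, s2 in ((a, b), (b, a)):
                # x is 2nd-degree to s2; look for a typed sibling of s2
                for e in graph.sibling_edges:
                    if s2 not in (e.id1, e.id2) or e.inconsistent:
                        continue
                    s1 = e.id2 if e.id1 == s2 else e.id1
                    if x in (s1, s2):
                        continue
                    if deg(x, s1) == "first":
                        subtype, basis = "avuncular", (
                            f"first-degree to sibling {s1}, second-degree to "
                            f"{s2}: child of {s1}, niece/nephew of {s2}")
                        po = (s1, x)
                    elif deg(x, s1) in ("unrelated", None) and \
                            any(s1 in k and x in k for k in degree):
                        subtype, basis = "grandparental", (
                            f"second-degree to {s2} only (sibling {s1} "
                            f"unrelated): grandchild of {s2}")
                        po = None
                    else:
                        continue
                    prev = typed.get(key)
                    if prev is not None:
                        if prev.subtype != subtype:
                            prev.conflict = True
                            prev.notes.append(f"also typed {subtype}: {basis}")
                        continue
                    edge = graph.add_second(a, b, subtype=subtype, basis=basis,
                                            candidates=(subtype,))
                    typed[key] = edge
                    untouched.discard(key)
                    if po is not None and po not in graph.parent_of():
                        role = ("mother" if graph.records[po[0]].genetic_sex
                                == "XX" else
                                "father" if graph.records[po[0]].genetic_sex
                                == "XY" else None)
                        graph.add_parent(po[0], po[1], role=role,
                                         basis=f"triangulated via siblings "
                                               f"{s1}/{s2}")
                    changed = True
    for key in sorted(untouched):
        a, b = key
        pk = by_pair[key]
        edge = graph.add_second(a, b, basis="untyped second degree",
                                ambiguous=True)
        ra, rb = graph.records[a], graph.records[b]
        if ra.genetic_sex == "XY" and rb.genetic_sex == "XY" and pk.gate_x \
                and np.isfinite(pk.theta_x):
            if pk.theta_x <= t.theta_x_low:
                edge.notes.append(
                    "theta_X ~ 0: excludes maternal-line grandfather and "
                    "maternal uncle")
            elif pk.theta_x >= t.theta_x_high:
                edge.notes.append(
                    "theta_X elevated: maternal-line relationship favoured")


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def _first_degree_ids(pairs: Sequence[PairKinship], who: str) -> set[str]:
    out = set()
    for pk in pairs:
        if pk.degree_final == "first":
            if pk.id1 == who:
                out.add(pk.id2)
            elif pk.id2 == who:
                out.add(pk.id1)
    return out


def build_pedigree(pairs: Sequence[PairKinship],
                   records: Sequence[IndividualRecord],
                   thresholds: FirstDegreeThresholds | None = None
                   ) -> PedigreeGraph:
    """Run gates, first-degree typing, direction resolution via sibling
    co-parentage, triangulation, and graph-consistency subtype labelling.

    Deterministic: pairs are processed in sorted order and every rule is
    a pure function of the gated evidence.
    """
    graph = PedigreeGraph(records)
    recs = graph.records
    gated = gate_pairs(list(pairs))
    gated.sort(key=lambda pk: (pk.id1, pk.id2))
    firsts = [pk for pk in gated if pk.degree_final == "first"]
    pending_po: list[tuple[PairKinship, str, bool]] = []
    for pk in firsts:
        kind, parent, basis, ambiguous, inconsistent = type_first_degree(
            pk, recs[pk.id1], recs[pk.id2], thresholds)
        if kind == "sibling":
            e = graph.add_sibling(pk.id1, pk.id2, basis=basis,
                                  ambiguous=ambiguous)
            e.inconsistent = inconsistent
        elif kind == "parent-offspring":
            if parent is not None:
                child = pk.id2 if parent == pk.id1 else pk.id1
                role = ("mother" if recs[parent].genetic_sex == "XX" else
                        "father" if recs[parent].genetic_sex == "XY" else None)
                e = graph.add_parent(parent, child, role=role, basis=basis,
                                     ambiguous=ambiguous)
                e.inconsistent = e.inconsistent or inconsistent
            else:
                pending_po.append((pk, basis, inconsistent))
        else:
            e = graph.add_sibling(pk.id1, pk.id2, basis=basis, ambiguous=True)
            e.subtype = "sibling-or-parent-offspring"
            e.inconsistent = inconsistent
    # direction resolution: a candidate who is first-degree to BOTH
    # members of a typed sibling pair (one of them being the partner)
    # must be their shared parent — a child of one sibling would be
    # second-degree to the other
    for pk, basis, inconsistent in pending_po:
        parent = None
        for cand, other in ((pk.id1, pk.id2), (pk.id2, pk.id1)):
            neigh = _first_degree_ids(gated, cand)
            for x, y in graph.sibling_pairs():
                if other in (x, y) and x in neigh and y in neigh:
                    parent = cand
                    break
            if parent:
                break
        if parent is not None:
            child = pk.id2 if parent == pk.id1 else pk.id1
            role = ("mother" if recs[parent].genetic_sex == "XX" else
                    "father" if recs[parent].genetic_sex == "XY" else None)
            graph.add_parent(parent, child, role=role,
                             basis=basis + "; direction via first-degree "
                                           "kinship to both of a sibling pair")
        else:
            e = graph.add_sibling(pk.id1, pk.id2,
                                  basis=basis + "; direction unresolved",
                                  ambiguous=True)
            e.subtype = "parent-offspring-undirected"
            e.inconsistent = inconsistent
    triangulate_second_degree(graph, gated, thresholds)
    _label_second_from_graph(graph)
    return graph


def _label_second_from_graph(graph: PedigreeGraph) -> None:
    """Type remaining second-degree edges that the reconstructed parent
    graph already explains (grandparental / avuncular / half-sibling)."""
    parents: dict[str, set[str]] = {}
    for p, c in graph.parent_of():
        parents.setdefault(c, set()).add(p)
    sibs = {frozenset(p) for p in graph.sibling_pairs()}

    def grandparent(a, b):             # a grandparent of b?
        return any(a in parents.get(p, ()) for p in parents.get(b, ()))

    def avuncular(a, b):               # a sibling of one of b's parents?
        return any(frozenset((a, p)) in sibs for p in parents.get(b, ()))

    for e in graph.second_edges:
        if e.subtype is not None:
            continue
        a, b = e.id1, e.id2
        if grandparent(a, b) or grandparent(b, a):
            e.subtype, e.ambiguous = "grandparental", False
            e.notes.append("implied by reconstructed parent-of chain")
        elif avuncular(a, b) or avuncular(b, a):
            e.subtype, e.ambiguous = "avuncular", False
            e.notes.append("implied by reconstructed sibling + parent-of edges")
        elif parents.get(a) and parents.get(b) \
                and len(parents[a] & parents[b]) == 1:
            e.subtype, e.ambiguous = "half-sibling", False
            e.notes.append("implied by a single shared reconstructed parent")
        if e.subtype:
            e.candidates = (e.subtype,)


# ---------------------------------------------------------------------------
# Social-structure summary
# ---------------------------------------------------------------------------

def haplotype_diversity(labels: Sequence[str]) -> float:
    """h = (n/(n-1)) (1 - sum p_i^2); NaN for fewer than 2 haplotypes."""
    labels = [x for x in labels if x]
    n = len(labels)
    if n < 2:
        return float("nan")
    _, counts = np.unique(labels, return_counts=True)
    p = counts / n
    return float(n / (n - 1) * (1.0 - (p ** 2).sum()))


def summarize_social_structure(graph: PedigreeGraph,
                               records: Sequence[IndividualRecord]) -> dict:
    """Kin-fraction by sex plus mito vs Y haplotype diversity.

    Reports counts of adult males/females with at least one detected kin
    edge, the mitochondrial haplotype diversity over everyone and the Y
    diversity over males, and nothing beyond these numbers (statistical
    patrilocality contrasts live in the D-statistic machinery).
    """
    recs = {r.id: r for r in records}
    with_kin = set()
    for e in (*graph.parent_edges, *graph.sibling_edges, *graph.second_edges):
        if not e.inconsistent:
            with_kin.update((e.id1, e.id2))
    out: dict = {"n_individuals": len(recs)}
    for sex, key in (("XY", "male"), ("XX", "female")):
        adults = [r for r in recs.values()
                  if r.genetic_sex == sex and r.age_class == "adult"]
        n_kin = sum(1 for r in adults if r.id in with_kin)
        out[f"n_adult_{key}"] = len(adults)
        out[f"n_adult_{key}_with_kin"] = n_kin
        out[f"kin_fraction_{key}"] = (n_kin / len(adults) if adults
                                      else float("nan"))
    mito = [r.mito_haplogroup for r in recs.values() if r.mito_haplogroup]
    ys = [r.y_haplogroup for r in recs.values()
          if r.genetic_sex == "XY" and r.y_haplogroup]
    if len(mito) >= 2:
        out["h_mito"] = haplotype_diversity(mito)
    else:
        out["h_mito_note"] = "not computable: missing mito haplogroups"
    if len(ys) >= 2:
        out["h_y"] = haplotype_diversity(ys)
    else:
        out["h_y_note"] = "not computable: missing Y haplogroups"
    if len(recs) < 2:
        out["note"] = "single-individual site: comparisons not computable"
    return out
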