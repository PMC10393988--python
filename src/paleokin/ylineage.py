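"""Y-chromosome haplogroup assignment against an ISOGG-style branch tree.

Markers live on branches of a rooted haplogroup tree (TSV dialect:
name, haplogroup, position, ancestral, derived; parent links either
explicit or derived from hierarchical label nesting). Calls are first
passed through the ancient-DNA recoding rules — low-quality (GQ < 50)
transition calls are kept only when they show C or G, and T/A calls at
transversion sites whose panel alleles exclude them are relabelled as
their deamination sources C/G — then the root-to-leaf lineage with the
highest cumulative derived support is chosen and the individual assigned
to the deepest node on it carrying derived support.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import mutation_class

GQ_TRANSITION_MIN = 50


@dataclass
class Marker:
    name: str
    haplogroup: str
    position: int
    ancestral: str
    derived: str


@dataclass
class Assignment:
    haplogroup: str
    n_derived_support: int
    n_path_conflicts: int
    n_off_path_derived: int
    tie: bool = False
    tie_candidates: list = field(default_factory=list)


class HaplogroupTree:
    """Rooted haplogroup tree with branch-defining SNPs."""

    def __init__(self, parent: dict[str, str | None],
                 markers: list[Marker]):
        self.parent = dict(parent)
        roots = [n for n, p in self.parent.items() if p is None]
        if len(roots) != 1:
            raise ValueError(f"tree must have a single root, found {roots}")
        self.root = roots[0]
        self.children: dict[str, list[str]] = {n: [] for n in self.parent}
        for n, p in self.parent.items():
            if p is not None:
                if p not in self.parent:
                    raise ValueError(f"parent {p!r} of {n!r} is not a node")
                self.children[p].append(n)
        self.markers_by_node: dict[str, list[Marker]] = {n: [] for n in self.parent}
        self.marker_at: dict[int, Marker] = {}
        for m in markers:
            if m.haplogroup not in self.parent:
                raise ValueError(f"marker {m.name} on unknown branch "
                                 f"{m.haplogroup!r}")
            if m.position in self.marker_at:
                raise ValueError(f"position {m.position} carries two markers")
            if len(m.ancestral) != 1 or len(m.derived) != 1:
                raise ValueError(f"indel marker {m.name} not allowed")
            self.markers_by_node[m.haplogroup].append(m)
            self.marker_at[m.position] = m
        self.depth: dict[str, int] = {}
        for n in self.parent:
            d, p = 0, self.parent[n]
            while p is not None:
                d, p = d + 1, self.parent[p]
            self.depth[n] = d

    # -- construction --------------------------------------------------------
    @classmethod
    def from_table(cls, df: pd.DataFrame,
                   parents: dict[str, str | None] | None = None,
                   panel_positions=None) -> "HaplogroupTree":
        """Build from a marker table; infer parents from label nesting
        when not given (longest proper prefix present among labels).

        Markers at multiple positions (comma-separated) are split;
        markers at positions absent from ``panel_positions`` (when
        provided) are dropped with a count stored on the tree.
        """
        markers = []
        n_dropped = 0
        keep = set(panel_positions) if panel_positions is not None else None
        for _, row in df.iterrows():
            for pos in str(row["position"]).split(","):
                pos = int(pos)
                if keep is not None and pos not in keep:
                    n_dropped += 1
                    continue
                markers.append(Marker(str(row["name"]), str(row["haplogroup"]),
                                      pos, str(row["ancestral"]).upper(),
                                      str(row["derived"]).upper()))
        labels = sorted({m.haplogroup for m in markers})
        if parents is None:
            parents = {}
            for lab in labels:
                cands = [o for o in labels if o != lab and lab.startswith(o)]
                parents[lab] = max(cands, key=len) if cands else None
            roots = [n for n, p in parents.items() if p is None]
            if len(roots) > 1:
                # synthesize a root above multiple top-level clades
                parents = {**parents, "ROOT": None}
                for r in roots:
                    parents[r] = "ROOT"
        tree = cls(parents, markers)
        tree.n_markers_dropped = n_dropped
        return tree

    def path_to(self, node: str) -> list[str]:
        path = []
        while node is not None:
            path.append(node)
            node = self.parent[node]
        return path[::-1]

    def leaves(self) -> list[str]:
        return [n for n, c in self.children.items() if not c]


def read_isogg_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t",
                       dtype={"name": str, "haplogroup": str, "position": str,
                              "ancestral": str, "derived": str})


# ---------------------------------------------------------------------------
# Recoding
# ---------------------------------------------------------------------------

def recode_y_calls(calls: pd.DataFrame, tree: HaplogroupTree) -> pd.DataFrame:
    """Apply the ancient-DNA usability rules to raw Y-site calls.

    ``calls`` columns: position, allele (called base), gq. Returns the
    usable call set with columns position, allele, state
    (ancestral/derived), recoded (bool); calls at non-marker positions,
    GQ-filtered transition calls, and alleles matching neither panel
    allele are dropped.
    """
    rows = []
    for _, row in calls.iterrows():
        pos = int(row["position"])
        marker = tree.marker_at.get(pos)
        if marker is None:
            continue
        allele = str(row["allele"]).upper()
        gq = float(row["gq"])
        site_alleles = {marker.ancestral, marker.derived}
        mclass = mutation_class(marker.ancestral, marker.derived)
        recoded = False
        if mclass == "transition":
            # low-quality transitions only trusted when they show C or G
            # (a T/A there is indistinguishable from deamination)
            if gq < GQ_TRANSITION_MIN and allele not in ("C", "G"):
                continue
        else:
            if allele == "T" and "T" not in site_alleles:
                allele, recoded = "C", True
            elif allele == "A" and "A" not in site_alleles:
                allele, recoded = "G", True
        if allele == marker.derived:
            state = "derived"
        elif allele == marker.ancestral:
            state = "ancestral"
        else:
            continue
        rows.append({"position": pos, "allele": allele, "state": state,
                     "recoded": recoded, "haplogroup": marker.haplogroup})
    return pd.DataFrame(rows, columns=["position", "allele", "state",
                                       "recoded", "haplogroup"])


def merge_udg_calls(primary: pd.DataFrame, udg: pd.DataFrame,
                    tree: HaplogroupTree) -> pd.DataFrame:
    """Merge damage-repaired (UDG) transition calls over non-UDG ones."""
    if udg is None or not len(udg):
        return primary
    trans_pos = {p for p, m in tree.marker_at.items()
                 if mutation_class(m.ancestral, m.derived) == "transition"}
    udg_trans = udg[udg["position"].isin(trans_pos)]
    keep = primary[~primary["position"].isin(set(udg_trans["position"]))]
    return pd.concat([keep, udg_trans], ignore_index=True)


# ---------------------------------------------------------------------------
# Assignment
# ---------------------------------------------------------------------------

def assign_haplogroup(usable: pd.DataFrame, tree: HaplogroupTree,
                      mode: str = "deepest_supported") -> Assignment:
    """Assign the lowest-level haplogroup on the best-supported lineage.

    Every root-to-leaf path is scored by its cumulative count of derived
    calls; on the winning path the assigned label is the deepest node
    with >= 1 derived supporting call (``mode="deepest_supported"``) or
    the node maximizing cumulative support (``mode="max_count"``, which
    differs only when deeper branches add no support). Ties between
    lineages prefer fewer conflicting ancestral calls; a remaining tie
    reports the deepest common ancestor with a flag. Derived calls off
    the chosen lineage are counted but ignored.
    """
    derived_on = {n: 0 for n in tree.parent}
    ancestral_on = {n: 0 for n in tree.parent}
    for _, row in usable.iterrows():
        if row["state"] == "derived":
            derived_on[row["haplogroup"]] += 1
        else:
            ancestral_on[row["haplogroup"]] += 1
    total_derived = sum(derived_on.values())
    if total_derived == 0:
        return Assignment(tree.root, 0, 0, 0)

    best_score, best = -1, []
    for leaf in tree.leaves():
        path = tree.path_to(leaf)
        score = sum(derived_on[n] for n in path)
        conflicts = sum(ancestral_on[n] for n in path if derived_on[n] > 0)
        if score > best_score:
            best_score, best = score, [(leaf, path, conflicts)]
        elif score == best_score:
            best.append((leaf, path, conflicts))
    if len(best) > 1:                       # tie-break on path conflicts
        min_c = min(b[2] for b in best)
        best = [b for b in best if b[2] == min_c]
    tie = len(best) > 1

    def assigned_on(path):
        supported = [n for n in path if derived_on[n] > 0]
        if mode == "deepest_supported":
            return supported[-1] if supported else tree.root
        # max_count: node whose cumulative support equals the path total
        # at minimal depth beyond which no support accrues
        cum, best_n = 0, tree.root
        for n in path:
            cum += derived_on[n]
            if derived_on[n] > 0:
                best_n = n
        return best_n

    if tie:
        # deepest common ancestor of the tied lineages
        paths = [b[1] for b in best]
        dca = tree.root
        for nodes in zip(*paths):
            if len(set(nodes)) == 1:
                dca = nodes[0]
            else:
                break
        path = tree.path_to(dca)
        label = assigned_on(path)
        support = sum(derived_on[n] for n in path)
        conflicts = sum(ancestral_on[n] for n in path if derived_on[n] > 0)
        return Assignment(label, support, conflicts,
                          total_derived - support, tie=True,
                          tie_candidates=[b[0] for b in best])
    leaf, path, conflicts = best[0]
    label = assigned_on(path)
    sup_path = tree.path_to(label)
    support = sum(derived_on[n] for n in sup_path)
    return Assignment(label, support, conflicts, total_derived - best_score)


# ---------------------------------------------------------------------------
# Synthetic trees (test/bench support)
# ---------------------------------------------------------------------------

def random_tree(n_nodes: int, seed: int, markers_per_branch: int = 3,
                positions_start: int = 2_650_000) -> HaplogroupTree:
    """A random rooted haplogroup tree with SNP markers on every branch."""
    rng = np.random.default_rng(seed)
    parent: dict[str, str | None] = {"HG0": None}
    names = ["HG0"]
    for k in range(1, n_nodes):
        parent[f"HG{k}"] = names[int(rng.integers(0, len(names)))]
        names.append(f"HG{k}")
    bases = "ACGT"
    markers, pos = [], positions_start
    for node in names:
        if parent[node] is None:
            continue
        for j in range(markers_per_branch):
            anc, der = rng.choice(list(bases), 2, replace=False)
            markers.append(Marker(f"M_{node}_{j}", node, pos, str(anc), str(der)))
            pos += 137
    return HaplogroupTree(parent, markers)
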