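"""Haplotype genealogy graphs via Fitch parsimony.

Given a rooted tree and the alignment of its tips, ancestral sequences are
reconstructed per site with the Fitch small-parsimony algorithm (bottom-up
state sets, then a fully deterministic top-down resolution: the root takes
the lexicographically smallest state of its set, children inherit the
parent state when possible, otherwise their lexicographically smallest
state).  Branches whose endpoint sequences are identical on comparable
sites are contracted, identical haplotypes are merged with their
multiplicities accumulated, and the remaining branches are weighted by the
substitution count between their endpoint haplotypes.  Sites with gaps or N
contribute no state and are treated as compatible during merging.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import networkx as nx

from .io import SequenceAlignment

_MISSING = frozenset("N-?")


@dataclass
class HaplotypeNode:
    hap_id: str
    sequence: str
    multiplicity: int
    members: list[str]


@dataclass
class HaplotypeGraph:
    """Distinct haplotypes (sampled and inferred) with substitution-weighted
    edges; backed by a networkx graph for connectivity queries."""

    nodes: list[HaplotypeNode]
    edges: list[tuple[str, str, int]]

    @property
    def inferred_nodes(self) -> list[HaplotypeNode]:
        return [n for n in self.nodes if n.multiplicity == 0]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for n in self.nodes:
            g.add_node(n.hap_id, multiplicity=n.multiplicity, members=tuple(n.members))
        for u, v, w in self.edges:
            g.add_edge(u, v, weight=w)
        return g

    @property
    def total_multiplicity(self) -> int:
        return sum(n.multiplicity for n in self.nodes)

    @property
    def total_edge_weight(self) -> int:
        return sum(w for _, _, w in self.edges)


def fitch_ancestral(
    tree: dendropy.Tree, alignment: SequenceAlignment
) -> tuple[dict, int]:
    """Fitch ancestral reconstruction: per-node sequences and parsimony score.

    Tips must be bijective with alignment rows.  Returns a mapping from tree
    node to its sequence (tips keep their observed row, internal nodes get
    reconstructed states; a site missing in an entire subtree inherits the
    resolved parent state, or N at the root) and the parsimony score counted
    over sites with at least one observed state.
    """
    rows = dict(alignment.records)
    tips = [leaf for leaf in tree.leaf_node_iter()]
    for leaf in tips:
        if leaf.taxon is None:
            raise ValueError("tree has an unlabelled tip")
        if leaf.taxon.label not in rows:
            raise ValueError(f"tip {leaf.taxon.label!r} has no alignment row")
    if len(tips) != len(rows):
        raise ValueError(
            f"{len(tips)} tips but {len(rows)} alignment rows; ids must match 1:1"
        )
    ncol = alignment.columns
    post = list(tree.postorder_node_iter())
    pre = list(tree.preorder_node_iter())
    state_sets: dict = {id(n): [None] * ncol for n in post}
    score = 0
    for site in range(ncol):
        for node in post:
            if node.is_leaf():
                b = rows[node.taxon.label][site]
                state_sets[id(node)][site] = frozenset() if b in _MISSING else frozenset(b)
            else:
                child_sets = [
                    state_sets[id(c)][site]
                    for c in node.child_nodes()
                    if state_sets[id(c)][site]
                ]
                if not child_sets:
                    state_sets[id(node)][site] = frozenset()
                else:
                    inter = frozenset.intersection(*child_sets)
                    if inter:
                        state_sets[id(node)][site] = inter
                    else:
                        state_sets[id(node)][site] = frozenset.union(*child_sets)
                        score += len(child_sets) - 1
    sequences: dict = {}
    resolved: dict = {id(n): [None] * ncol for n in pre}
    for site in range(ncol):
        for node in pre:
            ss = state_sets[id(node)][site]
            parent = node.parent_node
            parent_state = resolved[id(parent)][site] if parent is not None else None
            if not ss:
                resolved[id(node)][site] = parent_state  # may be None at root
            elif parent_state is not None and parent_state in ss:
                resolved[id(node)][site] = parent_state
            else:
                resolved[id(node)][site] = min(ss)
    for node in pre:
        if node.is_leaf():
            sequences[node] = rows[node.taxon.label]
        else:
            sequences[node] = "".join(b if b else "N" for b in resolved[id(node)])
    return sequences, score


def _comparable_equal(a: str, b: str) -> bool:
    return all(x == y for x, y in zip(a, b) if x not in _MISSING and y not in _MISSING)


def _substitutions(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x not in _MISSING and y not in _MISSING and x != y)


def _merge_seq(a: str, b: str) -> str:
    """Combine two compatible sequences, preferring definite bases."""
    return "".join(x if x not in _MISSING else y for x, y in zip(a, b))


def build_graph(tree: dendropy.Tree, sequences: dict) -> HaplotypeGraph:
    """Collapse zero-change branches of an ancestrally labelled tree.

    Adjacent nodes whose sequences agree on comparable sites are merged
    (union-find over tree edges); merged classes with identical resolved
    sequences are merged again; tip multiplicities accumulate.  Edge weights
    are the substitution counts between class sequences.
    """
    nodes = list(tree.preorder_node_iter())
    parent_of = {id(n): n.parent_node for n in nodes}
    cls = {id(n): id(n) for n in nodes}

    def find(x):
        while cls[x] != x:
            cls[x] = cls[cls[x]]
            x = cls[x]
        return x

    def union(x, y):
        cls[find(x)] = find(y)

    for n in nodes:
        p = parent_of[id(n)]
        if p is not None and _comparable_equal(sequences[n], sequences[p]):
            union(id(n), id(p))
    # resolve a representative sequence per class (fill Ns from members)
    class_nodes: dict = {}
    for n in nodes:
        class_nodes.setdefault(find(id(n)), []).append(n)
    class_seq = {
        c: _reduce_merge([sequences[n] for n in members])
        for c, members in class_nodes.items()
    }
    # second merge: classes with equal resolved sequences
    seq_to_class: dict[str, list] = {}
    for c, s in class_seq.items():
        seq_to_class.setdefault(s, []).append(c)
    canon = {c: group[0] for group in seq_to_class.values() for c in group}
    final_nodes: dict = {}
    for c, members in class_nodes.items():
        final_nodes.setdefault(canon[c], []).extend(members)
    final_seq = {
        cc: _reduce_merge([class_seq[c] for c in class_nodes if canon[c] == cc])
        for cc in final_nodes
    }
    # stable haplotype ids: sampled classes by first member tip label, then inferred
    entries = []
    for c, members in final_nodes.items():
        tips = sorted(m.taxon.label for m in members if m.is_leaf())
        entries.append((c, tips))
    entries.sort(key=lambda e: (len(e[1]) == 0, e[1][0] if e[1] else ""))
    hap_ids = {}
    n_inferred = 0
    for i, (c, tips) in enumerate(entries):
        if tips:
            hap_ids[c] = f"H{i + 1}"
        else:
            n_inferred += 1
            hap_ids[c] = f"inferred{n_inferred}"
    node_objs = []
    for c, tips in entries:
        node_objs.append(
            HaplotypeNode(
                hap_id=hap_ids[c],
                sequence=final_seq[c],
                multiplicity=len(tips),
                members=tips,
            )
        )
    # edges: tree edges between distinct final classes
    edge_set: dict[tuple[str, str], int] = {}
    for n in nodes:
        p = parent_of[id(n)]
        if p is None:
            continue
        cu, cv = canon[find(id(n))], canon[find(id(p))]
        if cu == cv:
            continue
        u, v = sorted((hap_ids[cu], hap_ids[cv]))
        w = _substitutions(final_seq[cu], final_seq[cv])
        edge_set[(u, v)] = max(w, 1)
    edges = sorted((u, v, w) for (u, v), w in edge_set.items())
    return HaplotypeGraph(node_objs, edges)


def _reduce_merge(seqs: list[str]) -> str:
    out = seqs[0]
    for s in seqs[1:]:
        out = _merge_seq(out, s)
    return out


def haplotype_graph(
    tree: dendropy.Tree, alignment: SequenceAlignment
) -> tuple[HaplotypeGraph, int]:
    """Fitch reconstruction followed by zero-branch collapsing; returns the
    graph and the parsimony score."""
    sequences, score = fitch_ancestral(tree, alignment)
    return build_graph(tree, sequences), score


def root_unrooted(tree: dendropy.Tree) -> dendropy.Tree:
    """Root an unrooted tree at the first tip's pendant edge (the collapsed
    graph is root-invariant, so the choice only fixes traversal order)."""
    first = next(tree.leaf_node_iter())
    tree.reroot_at_edge(first.edge, update_bipartitions=False)
    return tree


def export_graph(g: HaplotypeGraph, path: str | Path, format: str = "dot") -> None:
    """Serialise as DOT (node size ∝ multiplicity) or JSON."""
    path = Path(path)
    if format == "dot":
        lines = ["graph haplotypes {", "  node [shape=circle];"]
        for n in g.nodes:
            size = max(0.3, 0.3 * (n.multiplicity**0.5))
            label = f"{n.hap_id} ({n.multiplicity})"
            style = ' style=dashed' if n.multiplicity == 0 else ""
            lines.append(
                f'  "{n.hap_id}" [label="{label}" width={size:.2f}{style}];'
            )
        for u, v, w in g.edges:
            lines.append(f'  "{u}" -- "{v}" [label="{w}"];')
        lines.append("}")
        path.write_text("\n".join(lines) + "\n")
    elif format == "json":
        payload = {
            "nodes": [
                {
                    "id": n.hap_id,
                    "sequence": n.sequence,
                    "multiplicity": n.multiplicity,
                    "members": n.members,
                }
                for n in g.nodes
            ],
            "edges": [{"source": u, "target": v, "substitutions": w} for u, v, w in g.edges],
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
    else:
        raise ValueError(f"unknown format {format!r} (use 'dot' or 'json')")


def load_graph_json(path: str | Path) -> HaplotypeGraph:
    payload = json.loads(Path(path).read_text())
    nodes = [
        HaplotypeNode(d["id"], d["sequence"], d["multiplicity"], list(d["members"]))
        for d in payload["nodes"]
    ]
    edges = [(d["source"], d["target"], d["substitutions"]) for d in payload["edges"]]
    return HaplotypeGraph(nodes, edges)
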