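"""Parsimony mapping of per-codon meanings onto a phylogeny.

Unordered-state (Fitch) parsimony generalized to multifurcating rooted
trees via Sankoff dynamic programming with unit change costs.  Tips with
unknown state impose no constraint.

Besides the minimum number of state changes, the module computes, for each
state, the minimum number of independent origins of that state — the
quantity behind statements like "at least three independent events turned
AGG into an alanine codon".  Origins are counted under an asymmetric
Sankoff cost: an edge entering the state costs one gain, an edge leaving
it is disallowed (once a lineage has acquired the derived decoding
machinery, counting it as silently un-acquired would let a single
ancestral origin plus free reversions explain any distribution, collapsing
the count to 1), and all other transitions are free.  The root taking the
state counts as one origin.  Under this cost the count equals the minimal
number of gains needed to cover all tips carrying the state, with
unknown-state tips free to join either side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy

UNKNOWN_STATE = "?"
_INF = float("inf")


@dataclass
class Node:
    label: str
    children: list["Node"] = field(default_factory=list)

    @property
    def is_tip(self) -> bool:
        return not self.children

    def preorder(self) -> Iterable["Node"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterable["Node"]:
        return reversed(list(self.preorder()))


@dataclass
class Phylogeny:
    root: Node

    def tips(self) -> list[Node]:
        return [n for n in self.root.preorder() if n.is_tip]

    def tip_labels(self) -> list[str]:
        return [t.label for t in self.tips()]

    def find_clade(self, label: str) -> Node | None:
        for node in self.root.preorder():
            if node.label == label:
                return node
        return None

    def clade_tips(self, label: str) -> list[str]:
        node = self.find_clade(label)
        if node is None:
            raise KeyError(f"no node labeled {label!r}")
        return [n.label for n in node.preorder() if n.is_tip]

    def to_newick(self) -> str:
        def fmt(node: Node) -> str:
            if node.is_tip:
                return node.label
            inner = ",".join(fmt(c) for c in node.children)
            return f"({inner}){node.label or ''}"

        return fmt(self.root) + ";"


def parse_newick(text: str) -> Phylogeny:
    """Parse a newick string; branch lengths are ignored for parsimony."""
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=False
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"newick parse error: {exc}") from exc

    def convert(dnode) -> Node:
        label = ""
        if dnode.taxon is not None and dnode.taxon.label:
            label = dnode.taxon.label.replace(" ", "_")
        elif dnode.label:
            label = dnode.label.replace(" ", "_")
        return Node(label=label, children=[convert(c) for c in dnode.child_nodes()])

    root = convert(tree.seed_node)
    phy = Phylogeny(root=root)
    labels = phy.tip_labels()
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate tip labels: {dupes}")
    return phy


@dataclass
class StateAssignment:
    codon: str
    tip_states: dict[str, str]
    ancestral_states: dict[int, frozenset[str]]  # node id (preorder index) → optimal states
    min_changes: int
    min_gains_of: dict[str, int]


def _state_universe(tip_states: Mapping[str, str]) -> list[str]:
    return sorted({s for s in tip_states.values() if s and s != UNKNOWN_STATE})


def fitch_map(
    tree: Phylogeny, tip_states: Mapping[str, str], codon: str = ""
) -> StateAssignment:
    """Minimum-change ancestral mapping of unordered states on a rooted tree.

    ``tip_states`` maps taxon → state; taxa mapped to ``"?"`` (or absent) are
    unconstrained.  ``ancestral_states[i]`` (i = preorder index) is the set
    of states the node takes in at least one maximally parsimonious
    labeling.  ``min_gains_of[s]`` is the minimum number of independent
    origins of s (edges entering s, plus a root origin) under the
    irreversible-gain cost described in the module docstring.
    """
    tips = set(tree.tip_labels())
    extra = set(tip_states) - tips
    if extra:
        raise ValueError(f"tip states for taxa absent from tree: {sorted(extra)}")
    states = _state_universe(tip_states)
    nodes = list(tree.root.preorder())
    index = {id(n): i for i, n in enumerate(nodes)}
    if not states:
        return StateAssignment(
            codon=codon,
            tip_states=dict(tip_states),
            ancestral_states={i: frozenset() for i in range(len(nodes))},
            min_changes=0,
            min_gains_of={},
        )
    k = len(states)
    sidx = {s: j for j, s in enumerate(states)}

    # -- up pass: up[i][j] = min changes in subtree of node i, node i in state j
    up = [[0] * k for _ in nodes]
    for node in tree.root.postorder():
        i = index[id(node)]
        if node.is_tip:
            obs = tip_states.get(node.label, UNKNOWN_STATE)
            if obs and obs != UNKNOWN_STATE:
                for j in range(k):
                    up[i][j] = 0 if j == sidx[obs] else _INF
            continue
        for j in range(k):
            total = 0
            for child in node.children:
                ci = index[id(child)]
                total += min(up[ci][jj] + (jj != j) for jj in range(k))
            up[i][j] = total

    min_changes = int(min(up[0]))

    # -- down pass: down[i][j] = min changes outside subtree i, node i in state j
    down = [[0] * k for _ in nodes]
    for node in tree.root.preorder():
        i = index[id(node)]
        if node is tree.root:
            down[i] = [0] * k
        child_costs = []
        for child in node.children:
            ci = index[id(child)]
            # cost contributed by this child's subtree given parent state j
            child_costs.append([min(up[ci][jj] + (jj != j) for jj in range(k)) for j in range(k)])
        for c_pos, child in enumerate(node.children):
            ci = index[id(child)]
            for j in range(k):  # child state
                best = _INF
                for pj in range(k):  # parent state
                    others = sum(
                        child_costs[o][pj] for o in range(len(node.children)) if o != c_pos
                    )
                    cand = down[i][pj] + others + (pj != j)
                    if cand < best:
                        best = cand
                down[ci][j] = best

    ancestral = {
        i: frozenset(
            states[j] for j in range(k) if up[i][j] + down[i][j] == min_changes
        )
        for i in range(len(nodes))
    }

    # -- asymmetric Sankoff for minimum independent origins of each state:
    # entering s costs 1, leaving s is disallowed, all else is free
    min_gains: dict[str, int] = {}
    for s in states:
        sj = sidx[s]
        up2: list[list[float]] = [[0.0] * k for _ in nodes]
        for node in tree.root.postorder():
            i = index[id(node)]
            if node.is_tip:
                obs = tip_states.get(node.label, UNKNOWN_STATE)
                if obs and obs != UNKNOWN_STATE:
                    up2[i] = [0.0 if j == sidx[obs] else _INF for j in range(k)]
                continue
            for j in range(k):
                total = 0.0
                for child in node.children:
                    ci = index[id(child)]
                    best = _INF
                    for jj in range(k):
                        if j == sj and jj != sj:
                            continue  # loss of the derived state disallowed
                        cost = up2[ci][jj] + (1.0 if jj == sj and j != sj else 0.0)
                        if cost < best:
                            best = cost
                    total += best
                up2[i][j] = total
        min_gains[s] = int(min(up2[0][j] + (j == sj) for j in range(k)))

    return StateAssignment(
        codon=codon,
        tip_states=dict(tip_states),
        ancestral_states=ancestral,
        min_changes=min_changes,
        min_gains_of=min_gains,
    )


def brute_force_parsimony(
    tree: Phylogeny, tip_states: Mapping[str, str]
) -> tuple[int, dict[str, int]]:
    """Exhaustive-enumeration oracle for small trees: returns
    (min_changes, min_gains_of) by trying every ancestral labeling.

    min_changes minimizes unit-cost changes over all labelings; each
    min_gains_of[s] minimizes origins of s (edges entering s plus a root
    origin) over labelings with no edge leaving s.  Intended for trees of
    at most ~10 internal nodes over ~4 states.
    """
    from itertools import product

    states = _state_universe(tip_states)
    if not states:
        return 0, {}
    k = len(states)
    sidx = {s: j for j, s in enumerate(states)}
    nodes = list(tree.root.preorder())
    index = {id(n): i for i, n in enumerate(nodes)}
    edges = [
        (index[id(p)], index[id(c)]) for p in nodes for c in p.children
    ]
    fixed = [-1] * len(nodes)
    free: list[int] = []
    for i, n in enumerate(nodes):
        obs = tip_states.get(n.label, UNKNOWN_STATE) if n.is_tip else UNKNOWN_STATE
        if n.is_tip and obs not in ("", UNKNOWN_STATE):
            fixed[i] = sidx[obs]
        else:
            free.append(i)
    best_changes = None
    best_gains = [None] * k
    label = list(fixed)
    for combo in product(range(k), repeat=len(free)):
        for pos, j in zip(free, combo):
            label[pos] = j
        changes = 0
        gains = [0] * k
        lost = [False] * k  # did any edge leave state j?
        for pi, ci in edges:
            ps, cs = label[pi], label[ci]
            if ps != cs:
                changes += 1
                gains[cs] += 1
                lost[ps] = True
        gains[label[0]] += 1  # root origin
        if best_changes is None or changes < best_changes:
            best_changes = changes
        for j in range(k):
            if not lost[j] and (best_gains[j] is None or gains[j] < best_gains[j]):
                best_gains[j] = gains[j]
    return int(best_changes), {s: int(best_gains[sidx[s]]) for s in states}


def gains_report(
    tree: Phylogeny, tip_states_by_codon: Mapping[str, Mapping[str, str]]
) -> "pd.DataFrame":
    """TSV-ready report: codon, min_changes, and per-state minimum origins."""
    import pandas as pd

    rows = []
    for codon, tip_states in sorted(tip_states_by_codon.items()):
        sa = fitch_map(tree, tip_states, codon=codon)
        rows.append(
            {
                "codon": codon,
                "min_changes": sa.min_changes,
                "min_gains": ";".join(
                    f"{s}={g}" for s, g in sorted(sa.min_gains_of.items())
                ),
            }
        )
    return pd.DataFrame(rows, columns=["codon", "min_changes", "min_gains"])
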