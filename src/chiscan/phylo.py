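"""Presence/absence of candidate motifs on a phylogeny.

Formalizes verbal ancestor/loss narratives ("present in the ancestor,
lost in this genus") as small-parsimony reconstruction with equal gain
and loss costs.  The per-node result is the full set of states
appearing in at least one most-parsimonious reconstruction, so equally
parsimonious gain-versus-loss scenarios are reported, not resolved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import dendropy
import pandas as pd

__all__ = [
    "read_newick",
    "parse_newick",
    "fitch_presence_absence",
    "annotate_tree",
    "AncestralStates",
    "AnnotationResult",
]

STATES = ("present", "absent")
_INF = float("inf")


def parse_newick(newick: str) -> dendropy.Tree:
    """Parse a Newick string into a rooted tree (polytomies accepted)."""
    try:
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            preserve_underscores=True,
        )
    except Exception as exc:
        raise ValueError(f"Newick parse failure: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) < 2:
        raise ValueError("tree needs at least 2 tips")
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ValueError(f"duplicate tip labels: {dupes}")
    return tree


def read_newick(path) -> dendropy.Tree:
    """Load a rooted tree from a Newick file; labels kept verbatim."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    return parse_newick(path.read_text())


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


@dataclass
class AncestralStates:
    """Most-parsimonious presence/absence reconstruction summary.

    node_states maps every node to the frozenset of states that node
    takes in at least one reconstruction achieving min_changes.
    """

    min_changes: int
    node_states: dict
    tree: dendropy.Tree

    @property
    def root_states(self) -> frozenset:
        return self.node_states[self.tree.seed_node]

    def tip_state(self, label: str) -> str:
        for leaf in self.tree.leaf_node_iter():
            if leaf.taxon.label == label:
                (state,) = self.node_states[leaf]
                return state
        raise KeyError(label)


def fitch_presence_absence(
    tree: dendropy.Tree, tip_states: dict[str, str]
) -> AncestralStates:
    """Unit-cost small parsimony for a binary character.

    Bottom-up and top-down dynamic programming over {present, absent}
    with unit change cost (handles polytomies); min_changes is the
    parsimony score and each node's state set contains exactly the
    states achievable in some most-parsimonious reconstruction.
    """
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        if label not in tip_states:
            raise KeyError(f"missing state for tip {label!r}")
        if tip_states[label] not in STATES:
            raise ValueError(
                f"state for {label!r} must be one of {STATES}"
            )

    # bottom-up: cost_below[node][s] = min changes within the subtree
    # given the node has state s
    below: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            s = tip_states[node.taxon.label]
            below[node] = [
                0.0 if st == s else _INF for st in STATES
            ]
        else:
            costs = [0.0, 0.0]
            for child in node.child_nodes():
                cb = below[child]
                for si in range(2):
                    costs[si] += min(
                        cb[ti] + (0.0 if ti == si else 1.0)
                        for ti in range(2)
                    )
            below[node] = costs

    root = tree.seed_node
    best = min(below[root])

    # top-down: cost_above[node][s] = min changes outside the subtree
    # given the node has state s
    above: dict = {root: [0.0, 0.0]}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        children = node.child_nodes()
        # per-child contribution of the other children, by parent state
        child_contrib = {
            c: [
                min(
                    below[c][ti] + (0.0 if ti == si else 1.0)
                    for ti in range(2)
                )
                for si in range(2)
            ]
            for c in children
        }
        for child in children:
            sib_cost = [
                sum(
                    child_contrib[c][si]
                    for c in children
                    if c is not child
                )
                for si in range(2)
            ]
            above[child] = [
                min(
                    above[node][si]
                    + sib_cost[si]
                    + (0.0 if si == ci else 1.0)
                    for si in range(2)
                )
                for ci in range(2)
            ]

    node_states: dict = {}
    for node in tree.preorder_node_iter():
        states = frozenset(
            STATES[si]
            for si in range(2)
            if below[node][si] + above[node][si] == best
        )
        node_states[node] = states
    return AncestralStates(
        min_changes=int(best), node_states=node_states, tree=tree
    )


@dataclass
class AnnotationResult:
    """Tip-level motif annotation plus per-motif parsimony summaries."""

    tips: pd.DataFrame
    motif_summary: pd.DataFrame


def annotate_tree(
    tree: dendropy.Tree, per_species_motifs: dict[str, list[str]]
) -> AnnotationResult:
    """Annotate tips with candidate motifs and summarise each motif.

    Tips absent from the calls are marked "no data" (distinct from
    tips evaluated but without candidates, marked "none"); species in
    the calls but not on the tree trigger a warning listing them.
    """
    labels = tip_labels(tree)
    orphans = sorted(set(per_species_motifs) - set(labels))
    if orphans:
        warnings.warn(
            f"species in calls but not on the tree: {orphans}"
        )
    rows = []
    for label in labels:
        if label not in per_species_motifs:
            rows.append((label, "", "no data"))
        else:
            motifs = sorted(per_species_motifs[label])
            rows.append(
                (label, ";".join(motifs), "candidate" if motifs else "none")
            )
    tips = pd.DataFrame(rows, columns=["tip", "motifs", "status"])

    all_motifs = sorted(
        {m for ms in per_species_motifs.values() for m in ms}
    )
    summary_rows = []
    for motif in all_motifs:
        tip_states = {
            label: (
                "present"
                if motif in per_species_motifs.get(label, [])
                else "absent"
            )
            for label in labels
        }
        anc = fitch_presence_absence(tree, tip_states)
        summary_rows.append(
            (
                motif,
                sum(1 for s in tip_states.values() if s == "present"),
                anc.min_changes,
                "/".join(sorted(anc.root_states)),
            )
        )
    motif_summary = pd.DataFrame(
        summary_rows,
        columns=["motif", "n_tips_present", "min_changes", "root_states"],
    )
    return AnnotationResult(tips=tips, motif_summary=motif_summary)
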