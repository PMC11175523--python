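"""Binary-character parsimony on rooted trees (Fitch and Dollo).

Dollo parsimony allows a single gain and any number of losses — the model for
irreversible characters such as chromosome fusion-with-mixing.  Fitch allows
both gains and losses.  Trees are dendropy trees; nodes are identified by
their leaf taxon label or internal node label.
"""

from __future__ import annotations

import dendropy

__all__ = ["node_name", "fitch_binary", "dollo_binary", "dollo_gain_edge"]


def node_name(node: dendropy.Node) -> str:
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    return node.label or ""


def _leaf_state(node: dendropy.Node, leaf_values: dict[str, int]) -> int:
    name = node_name(node)
    if name not in leaf_values:
        raise KeyError(f"leaf {name!r} has no character state")
    return int(bool(leaf_values[name]))


def fitch_binary(tree: dendropy.Tree, leaf_values: dict[str, int],
                 root_pref: int = 0) -> dict[str, int]:
    """Fitch small parsimony for one binary character.

    Ambiguities are resolved deterministically: the root takes ``root_pref``
    when ambiguous; below the root, a node ambiguous in the up-pass copies its
    parent's state.
    """
    up: dict[int, set[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            up[id(node)] = {_leaf_state(node, leaf_values)}
        else:
            children = [up[id(c)] for c in node.child_nodes()]
            inter = set.intersection(*children)
            up[id(node)] = inter if inter else set.union(*children)
    states: dict[str, int] = {}
    down: dict[int, int] = {}
    for node in tree.preorder_node_iter():
        s = up[id(node)]
        if node.parent_node is None:
            val = next(iter(s)) if len(s) == 1 else root_pref
        else:
            p = down[id(node.parent_node)]
            val = p if p in s else min(s)
        down[id(node)] = val
        states[node_name(node)] = val
    return states


def dollo_binary(tree: dendropy.Tree, leaf_values: dict[str, int]) -> dict[str, int]:
    """Dollo reconstruction: present at a node iff the node lies in the clade
    of the most recent common ancestor of all 1-leaves and still has a
    1-leaf descendant (i.e. one gain on the MRCA's stem, losses on the
    maximal 0-subtrees)."""
    has_one: dict[int, bool] = {}
    n_ones: dict[int, int] = {}
    total = 0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            v = _leaf_state(node, leaf_values)
            has_one[id(node)] = bool(v)
            n_ones[id(node)] = int(v)
            total += int(v)
        else:
            cs = node.child_nodes()
            has_one[id(node)] = any(has_one[id(c)] for c in cs)
            n_ones[id(node)] = sum(n_ones[id(c)] for c in cs)
    states: dict[str, int] = {node_name(n): 0 for n in tree.preorder_node_iter()}
    if total == 0:
        return states
    # MRCA of the 1-leaves: deepest node whose subtree holds every 1-leaf
    mrca = tree.seed_node
    while not mrca.is_leaf():
        carriers = [c for c in mrca.child_nodes() if n_ones[id(c)] == total]
        if not carriers:
            break
        mrca = carriers[0]
    stack = [mrca]
    while stack:
        node = stack.pop()
        states[node_name(node)] = int(has_one[id(node)])
        stack.extend(node.child_nodes())
    return states


def dollo_gain_edge(tree: dendropy.Tree, leaf_values: dict[str, int]) -> str | None:
    """Name of the node whose stem edge carries the single Dollo gain."""
    ones = {name for name, v in leaf_values.items() if v}
    if not ones:
        return None
    mrca = tree.mrca(taxon_labels=sorted(ones)) if len(ones) > 1 else None
    if mrca is None:
        for leaf in tree.leaf_node_iter():
            if node_name(leaf) in ones:
                return node_name(leaf)
    return node_name(mrca)
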