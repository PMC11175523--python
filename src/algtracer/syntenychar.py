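"""Synteny-based character phylogenetics.

Each of the 24 ancestral linkage groups (BALGs) is scored per species with
the *categories* of rearrangement it suffered (intact; fused with X by a
given geometry; split; dispersed).  Earlier nested fusions are recorded as
their own categories, mirroring the stepwise nature of chromosome evolution.
The category table is binarized (one column per category; nested duplicates
of the same event under several BALGs are collapsed), compared with the
asymmetric binary (Jaccard) distance, clustered hierarchically, and used for
Bayesian tree sampling under a two-state symmetric Markov model (Mk2) with
an exponential(10) branch-length prior and uniform topology prior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .algebra import ROOT_ALG_LABELS, AlgState

__all__ = [
    "CategoryTable",
    "encode_categories",
    "binarize",
    "binary_distance",
    "cluster",
    "dendrogram_clades",
    "McmcConfig",
    "McmcResult",
    "sample_trees",
    "check_monophyly",
    "splits_contain",
]


@dataclass
class CategoryTable:
    """Per-BALG rearrangement categories across species."""

    balg_order: tuple[str, ...]
    species: tuple[str, ...]
    # balg -> species -> set of category names
    memberships: dict[str, dict[str, frozenset]] = field(default_factory=dict)

    def categories(self, balg: str) -> tuple[str, ...]:
        cats: set[str] = set()
        for sp_cats in self.memberships[balg].values():
            cats |= sp_cats
        return tuple(sorted(cats))

    def category_counts(self) -> dict[str, int]:
        return {b: len(self.categories(b)) for b in self.balg_order}


def _leaf_categories(state: AlgState, lab: str) -> frozenset:
    for src_name, (labels, records) in state.dispersed.items():
        if lab in labels:
            cats = {name for kind, name, ls in records if lab in ls}
            cats.add(f"dispersed:{src_name}")
            return frozenset(cats)
    homes = state.chromosome_of(lab)
    if not homes:
        raise KeyError(f"label {lab!r} absent from state")
    cats = set()
    for h in homes:
        cats |= {name for kind, name, ls in state.chromosomes[h].records if lab in ls}
    if not cats:
        return frozenset({f"intact:{lab}"})
    return frozenset(cats)


def encode_categories(leaf_states: dict[str, AlgState],
                      root_labels=ROOT_ALG_LABELS) -> CategoryTable:
    """Canonical rearrangement categories per (BALG, species).

    Identical event descriptions across species share one category; a species
    whose chromosome carries nested earlier fusions is a member of each nested
    category (the stepwise record).  Output is invariant to species order.
    """
    species = tuple(sorted(leaf_states))
    table = CategoryTable(tuple(root_labels), species)
    for lab in root_labels:
        table.memberships[lab] = {
            sp: _leaf_categories(leaf_states[sp], lab) for sp in species}
    return table


def binarize(table: CategoryTable, deduplicate: bool = True) -> pd.DataFrame:
    """Species x category binary matrix.

    Without de-duplication there is one column per (BALG, category) cell; a
    fusion joining k BALGs therefore appears k times with identical
    membership.  De-duplication keeps one column per distinct category name
    (no double counting of a single event).
    """
    columns: list[tuple[str, str]] = []
    seen: set[str] = set()
    for balg in table.balg_order:
        for cat in table.categories(balg):
            if deduplicate and cat in seen:
                continue
            seen.add(cat)
            columns.append((balg, cat))
    data = np.zeros((len(table.species), len(columns)), dtype=int)
    for j, (balg, cat) in enumerate(columns):
        for i, sp in enumerate(table.species):
            member = any(cat in table.memberships[b].get(sp, frozenset())
                         for b in table.balg_order) if deduplicate else \
                cat in table.memberships[balg].get(sp, frozenset())
            data[i, j] = int(member)
    return pd.DataFrame(data, index=list(table.species),
                        columns=[f"{b}|{c}" for b, c in columns])


def binary_distance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Asymmetric binary distance: mismatches / columns where either is 1.

    Pairs with no informative column get NaN (reported, not invented).
    """
    if len(matrix) < 2:
        raise ValueError("need >=2 species")
    x = matrix.values.astype(bool)
    d = squareform(pdist(x, metric="jaccard"))
    informative = (x[:, None, :] | x[None, :, :]).sum(axis=2)
    d = np.where(informative == 0, np.nan, d)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)


def cluster(dist: pd.DataFrame, method: str = "complete") -> np.ndarray:
    """Agglomerative hierarchical clustering on a distance table.

    Returns the scipy linkage matrix; leaf order follows ``dist.index``.
    """
    condensed = squareform(dist.values, checks=False)
    return hierarchy.linkage(condensed, method=method)


def dendrogram_clades(linkage: np.ndarray, labels: list[str]) -> list[frozenset]:
    """Leaf sets of every internal node of a dendrogram."""
    tree = hierarchy.to_tree(linkage)
    clades: list[frozenset] = []

    def walk(node) -> frozenset:
        if node.is_leaf():
            return frozenset([labels[node.id]])
        s = walk(node.left) | walk(node.right)
        clades.append(s)
        return s

    walk(tree)
    return clades


# ---------------------------------------------------------------------------
# Mk2 MCMC tree sampling


@dataclass(frozen=True)
class McmcConfig:
    n_samples: int = 10000
    burnin_frac: float = 0.25
    seed: int = 0
    thin: int = 5
    branch_prior_rate: float = 10.0

    def __post_init__(self) -> None:
        if not 0 <= self.burnin_frac < 1:
            raise ValueError("burnin_frac must lie in [0, 1)")


@dataclass
class McmcResult:
    taxa: tuple[str, ...]
    split_freqs: dict[frozenset, float]
    consensus_splits: list[frozenset]
    n_kept: int
    acceptance: float


class _UnrootedTree:
    """Unrooted binary tree over n>=4 leaves, adjacency-list based."""

    def __init__(self, n_leaves: int, rng: np.random.Generator, prior_rate: float):
        # random stepwise-addition start topology
        self.adj: dict[int, dict[int, float]] = {}
        nxt = n_leaves  # internal node ids
        order = list(rng.permutation(n_leaves))
        a, b, c = order[0], order[1], order[2]
        hub = nxt
        nxt += 1
        for leaf in (a, b, c):
            self._link(hub, leaf, rng.exponential(1 / prior_rate))
        for leaf in order[3:]:
            edges = self.edges()
            u, v = edges[rng.integers(len(edges))]
            self._unlink(u, v)
            mid = nxt
            nxt += 1
            self._link(u, mid, rng.exponential(1 / prior_rate))
            self._link(mid, v, rng.exponential(1 / prior_rate))
            self._link(mid, leaf, rng.exponential(1 / prior_rate))
        self.n_leaves = n_leaves

    def _link(self, u: int, v: int, t: float) -> None:
        self.adj.setdefault(u, {})[v] = t
        self.adj.setdefault(v, {})[u] = t

    def _unlink(self, u: int, v: int) -> None:
        del self.adj[u][v]
        del self.adj[v][u]

    def edges(self) -> list[tuple[int, int]]:
        return sorted((u, v) for u in self.adj for v in self.adj[u] if u < v)

    def internal_edges(self) -> list[tuple[int, int]]:
        return [(u, v) for u, v in self.edges()
                if u >= self.n_leaves and v >= self.n_leaves]

    def loglik(self, leaf_partials: np.ndarray) -> float:
        """Felsenstein pruning; stationary root frequencies (1/2, 1/2)."""
        root = self.n_leaves  # any internal node
        partial = None
        for nbr in self.adj[root]:
            msg = self._message(nbr, root, leaf_partials)
            partial = msg if partial is None else partial * msg
        col_lik = 0.5 * partial.sum(axis=0)
        return float(np.log(np.clip(col_lik, 1e-300, None)).sum())

    def _message(self, node: int, parent: int, leaf_partials: np.ndarray) -> np.ndarray:
        """Partial likelihood message passed along the edge node -> parent."""
        if node < self.n_leaves:
            partial = leaf_partials[node]
        else:
            partial = None
            for child in self.adj[node]:
                if child == parent:
                    continue
                msg = self._message(child, node, leaf_partials)
                partial = msg if partial is None else partial * msg
        t = self.adj[node][parent]
        psame = 0.5 * (1 + math.exp(-2 * t))
        pdiff = 1 - psame
        out = np.empty_like(partial)
        out[0] = psame * partial[0] + pdiff * partial[1]
        out[1] = pdiff * partial[0] + psame * partial[1]
        return out

    def log_prior(self, rate: float) -> float:
        return sum(math.log(rate) - rate * t for _, t in self._edge_lengths())

    def _edge_lengths(self):
        for u, v in self.edges():
            yield (u, v), self.adj[u][v]

    def nni(self, rng: np.random.Generator) -> tuple | None:
        """Apply a random NNI; returns an undo token, or None if no internal edge."""
        internal = self.internal_edges()
        if not internal:
            return None
        u, v = internal[rng.integers(len(internal))]
        u_nbrs = [x for x in self.adj[u] if x != v]
        v_nbrs = [x for x in self.adj[v] if x != u]
        a = u_nbrs[rng.integers(len(u_nbrs))]
        b = v_nbrs[rng.integers(len(v_nbrs))]
        ta, tb = self.adj[u][a], self.adj[v][b]
        self._unlink(u, a)
        self._unlink(v, b)
        self._link(u, b, tb)
        self._link(v, a, ta)
        return (u, v, a, b, ta, tb)

    def undo_nni(self, token: tuple) -> None:
        u, v, a, b, ta, tb = token
        self._unlink(u, b)
        self._unlink(v, a)
        self._link(u, a, ta)
        self._link(v, b, tb)

    def splits(self, taxa: tuple[str, ...]) -> frozenset:
        """Canonical splits: for each edge, the leaf-name set on the side away
        from leaf 0; trivial splits excluded."""
        out = set()
        for u, v in self.edges():
            side = self._leaves_beyond(v, u)
            if 0 in side:
                side = set(range(self.n_leaves)) - side
            if 1 < len(side) < self.n_leaves - 1:
                out.add(frozenset(taxa[i] for i in side))
        return frozenset(out)

    def _leaves_beyond(self, node: int, parent: int) -> set[int]:
        if node < self.n_leaves:
            return {node}
        out: set[int] = set()
        for child in self.adj[node]:
            if child != parent:
                out |= self._leaves_beyond(child, node)
        return out


def sample_trees(matrix: pd.DataFrame, cfg: McmcConfig = McmcConfig()) -> McmcResult:
    """MCMC over unrooted topologies and branch lengths under Mk2.

    Metropolis–Hastings with alternating branch-length multiplier proposals
    and nearest-neighbour-interchange topology moves; majority-rule consensus
    splits after discarding ``burnin_frac``.  Seed-reproducible.
    """
    vals = matrix.values
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("matrix cells must be binary")
    taxa = tuple(matrix.index)
    n = len(taxa)
    if n < 4:
        raise ValueError("need >=4 species for tree sampling")
    rng = np.random.default_rng(cfg.seed)
    leaf_partials = np.zeros((n, 2, vals.shape[1]))
    leaf_partials[:, 0, :] = (vals == 0).astype(float)
    leaf_partials[:, 1, :] = (vals == 1).astype(float)
    tree = _UnrootedTree(n, rng, cfg.branch_prior_rate)
    rate = cfg.branch_prior_rate
    ll = tree.loglik(leaf_partials)
    lp = tree.log_prior(rate)
    split_counts: dict[frozenset, int] = {}
    kept = 0
    accepted = proposed = 0
    burn = int(cfg.burnin_frac * cfg.n_samples)
    for it in range(cfg.n_samples):
        for _ in range(cfg.thin):
            # branch-length multiplier move
            edges = tree.edges()
            u, v = edges[rng.integers(len(edges))]
            t_old = tree.adj[u][v]
            factor = math.exp(0.5 * (rng.random() - 0.5) * 2)
            t_new = t_old * factor
            tree._link(u, v, t_new)
            ll_new = tree.loglik(leaf_partials)
            lp_new = tree.log_prior(rate)
            log_acc = (ll_new + lp_new) - (ll + lp) + math.log(factor)
            proposed += 1
            if math.log(rng.random() + 1e-300) < log_acc:
                ll, lp = ll_new, lp_new
                accepted += 1
            else:
                tree._link(u, v, t_old)
            # NNI move (symmetric proposal, uniform topology prior)
            token = tree.nni(rng)
            if token is not None:
                ll_new = tree.loglik(leaf_partials)
                proposed += 1
                if math.log(rng.random() + 1e-300) < ll_new - ll:
                    ll = ll_new
                    accepted += 1
                else:
                    tree.undo_nni(token)
        if it >= burn:
            kept += 1
            for s in tree.splits(taxa):
                split_counts[s] = split_counts.get(s, 0) + 1
    freqs = {s: c / kept for s, c in split_counts.items()}
    consensus = sorted((s for s, f in freqs.items() if f > 0.5), key=sorted)
    return McmcResult(taxa, freqs, consensus, kept, accepted / max(1, proposed))


def splits_contain(result: McmcResult, taxa: set[str]) -> bool:
    """Whether the consensus splits isolate exactly ``taxa``."""
    target = frozenset(taxa)
    if result.taxa[0] in target:
        target = frozenset(result.taxa) - target
    return target in set(result.consensus_splits)


def check_monophyly(tree, taxa: set[str]) -> bool:
    """True iff some edge bipartition of a (dendropy) tree isolates ``taxa``."""
    from .parsimony import node_name

    leaves = {node_name(l) for l in tree.leaf_node_iter()}
    unknown = set(taxa) - leaves
    if unknown:
        raise KeyError(f"unknown taxa {sorted(unknown)}")
    target = frozenset(taxa)
    for node in tree.preorder_node_iter():
        below = frozenset(node_name(l) for l in node.leaf_iter())
        if below == target or leaves - below == target:
            return True
    return False
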