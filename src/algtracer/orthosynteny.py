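"""Reciprocal-best-hit ortholog pairing with a C-score filter, and collinear
synteny-block chaining in gene-rank space.

The C-score of a hit (q, t) is score(q,t) / max(best(q), best(t)); at the
default threshold of 0.99 this admits only (near-)reciprocal best hits.
Blocks are chained greedily in rank space: anchors sorted by rank on genome A
are extended while the rank gap on *both* genomes stays within ``max_gap`` and
rank order on genome B is monotone (increasing, or decreasing for inverted
blocks).  Defaults follow common macrosynteny practice: a display block needs
>=4 anchor pairs within a gap of 75 genes; chromosome-assignment mode uses
min_pairs=1 with no gap limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .genomeio import GeneMap, OrthologPairSet

__all__ = [
    "SimilarityTable",
    "RbhParams",
    "ChainParams",
    "SyntenyBlock",
    "read_similarity_table",
    "compute_rbh",
    "chain_blocks",
    "dotplot_table",
    "write_blocks",
]


@dataclass
class SimilarityTable:
    """Alignment-score triples (query_gene, target_gene, score>0)."""

    genome_a: str
    genome_b: str
    hits: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(s <= 0 for _, _, s in self.hits):
            raise ValueError("similarity scores must be strictly positive")


@dataclass(frozen=True)
class RbhParams:
    c_score_min: float = 0.99

    def __post_init__(self) -> None:
        if not 0 < self.c_score_min <= 1:
            raise ValueError("c_score_min must lie in (0, 1]")


@dataclass(frozen=True)
class ChainParams:
    min_pairs: int = 4
    max_gap: int | None = 75  # None = unlimited

    @classmethod
    def assignment_mode(cls) -> "ChainParams":
        return cls(min_pairs=1, max_gap=None)


@dataclass
class SyntenyBlock:
    chrom_a: str
    chrom_b: str
    anchors: list[tuple[str, str]]
    orientation: str  # {"same", "inverted"}

    def __len__(self) -> int:
        return len(self.anchors)


def read_similarity_table(path: str | Path, genome_a: str = "A", genome_b: str = "B",
                          columns: tuple[int, int, int] = (0, 1, 2)) -> SimilarityTable:
    """Read a 3-column TSV (or BLAST/LAST tabular via a column map)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    qc, tc, sc = columns
    hits = [(str(r[qc]), str(r[tc]), float(r[sc])) for r in df.itertuples(index=False)]
    return SimilarityTable(genome_a, genome_b, hits)


def compute_rbh(table: SimilarityTable, params: RbhParams = RbhParams()) -> OrthologPairSet:
    """Mutual-best-hit pairs passing the C-score filter.

    A pair is kept iff its score is the unique maximum among the query's hits
    and among the target's hits; ties for best are dropped entirely (no
    arbitrary orthology).  Output is one-to-one by construction and invariant
    under row permutation of the input.
    """
    if not table.hits:
        raise ValueError("empty similarity table")
    best_q: dict[str, float] = {}
    best_t: dict[str, float] = {}
    for q, t, s in table.hits:
        best_q[q] = max(best_q.get(q, 0.0), s)
        best_t[t] = max(best_t.get(t, 0.0), s)
    # count how many hits attain each best score (tie detection)
    nbest_q: dict[str, int] = {}
    nbest_t: dict[str, int] = {}
    for q, t, s in table.hits:
        if s == best_q[q]:
            nbest_q[q] = nbest_q.get(q, 0) + 1
        if s == best_t[t]:
            nbest_t[t] = nbest_t.get(t, 0) + 1
    pairs = []
    for q, t, s in table.hits:
        if s < best_q[q] or s < best_t[t]:
            continue
        if nbest_q[q] > 1 or nbest_t[t] > 1:
            continue
        if s / max(best_q[q], best_t[t]) < params.c_score_min:
            continue
        pairs.append((q, t))
    pairs.sort()
    return OrthologPairSet(table.genome_a, table.genome_b, pairs, provenance="rbh")


def _ranked_anchors(pairs: OrthologPairSet, map_a: GeneMap, map_b: GeneMap):
    for a, b in pairs.pairs:
        if a not in map_a:
            raise KeyError(f"gene {a!r} missing from map of {map_a.genome_id!r}")
        if b not in map_b:
            raise KeyError(f"gene {b!r} missing from map of {map_b.genome_id!r}")
        ga, gb = map_a.gene(a), map_b.gene(b)
        yield (ga.chrom, gb.chrom, ga.rank, gb.rank, a, b)


def _best_chain(anchors: list[tuple[int, int, str, str]], gap: float,
                direction: int) -> list[int]:
    """Longest collinear chain (indices) by dynamic programming.

    Consecutive anchors must advance by 1..gap ranks on genome A and by
    1..gap ranks on genome B in the given direction.  Ties break toward the
    earliest anchors, so extraction is deterministic.
    """
    n = len(anchors)
    best_len = [1] * n
    parent = [-1] * n
    for j in range(n):
        ra_j, rb_j = anchors[j][0], anchors[j][1]
        for i in range(j):
            ra_i, rb_i = anchors[i][0], anchors[i][1]
            if not 0 < ra_j - ra_i <= gap:
                continue
            step = direction * (rb_j - rb_i)
            if not 0 < step <= gap:
                continue
            if best_len[i] + 1 > best_len[j]:
                best_len[j] = best_len[i] + 1
                parent[j] = i
    end = max(range(n), key=lambda j: (best_len[j], -j))
    chain = []
    while end != -1:
        chain.append(end)
        end = parent[end]
    return chain[::-1]


def chain_blocks(pairs: OrthologPairSet, map_a: GeneMap, map_b: GeneMap,
                 params: ChainParams = ChainParams()) -> list[SyntenyBlock]:
    """Chain collinear anchors per chromosome pair into synteny blocks.

    The longest collinear chain (either orientation) is found exactly by
    dynamic programming, removed, and the search repeats on the remaining
    anchors until the best chain falls below ``min_pairs``.  Every anchor
    ends up in at most one block.
    """
    by_pair: dict[tuple[str, str], list[tuple[int, int, str, str]]] = {}
    for ca, cb, ra, rb, a, b in _ranked_anchors(pairs, map_a, map_b):
        by_pair.setdefault((ca, cb), []).append((ra, rb, a, b))
    blocks: list[SyntenyBlock] = []
    gap = params.max_gap if params.max_gap is not None else float("inf")
    for (ca, cb), anchors in sorted(by_pair.items()):
        anchors.sort()
        remaining = list(anchors)
        while remaining:
            candidates = []
            for direction, orient in ((1, "same"), (-1, "inverted")):
                idx = _best_chain(remaining, gap, direction)
                candidates.append((len(idx), direction == 1, idx, orient))
            _, _, idx, orient = max(candidates, key=lambda c: (c[0], c[1]))
            if len(idx) < params.min_pairs:
                break
            blocks.append(SyntenyBlock(
                ca, cb, [(remaining[j][2], remaining[j][3]) for j in idx], orient))
            picked = set(idx)
            remaining = [a for j, a in enumerate(remaining) if j not in picked]
    return blocks


def dotplot_table(pairs: OrthologPairSet, map_a: GeneMap, map_b: GeneMap,
                  chrom_order_a: list[str] | None = None,
                  chrom_order_b: list[str] | None = None) -> pd.DataFrame:
    """One row per ortholog pair with genome-wide cumulative ranks.

    Global rank = offset of the chromosome (in the given order, default the
    map's first-appearance order) + within-chromosome rank.
    """
    order_a = chrom_order_a or map_a.chromosomes
    order_b = chrom_order_b or map_b.chromosomes
    sizes_a, sizes_b = map_a.chrom_sizes(), map_b.chrom_sizes()
    off_a, off_b, acc = {}, {}, 0
    for c in order_a:
        off_a[c] = acc
        acc += sizes_a.get(c, 0)
    acc = 0
    for c in order_b:
        off_b[c] = acc
        acc += sizes_b.get(c, 0)
    rows = []
    for ca, cb, ra, rb, a, b in _ranked_anchors(pairs, map_a, map_b):
        rows.append((off_a[ca] + ra, off_b[cb] + rb, ca, cb, a, b))
    return pd.DataFrame(rows, columns=[
        "rank_a_global", "rank_b_global", "chrom_a", "chrom_b", "gene_a", "gene_b"])


def write_blocks(blocks: list[SyntenyBlock], path: str | Path) -> None:
    """MCscan-style anchors text; '#' lines separate blocks."""
    with open(path, "w") as fh:
        for i, blk in enumerate(blocks):
            fh.write(f"### block {i} {blk.chrom_a} {blk.chrom_b} {blk.orientation}\n")
            for a, b in blk.anchors:
                fh.write(f"{a}\t{b}\n")
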