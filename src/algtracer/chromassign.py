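"""Chromosome homology assignment from ortholog placement.

For every chromosome pair (i of genome A, j of genome B) the ortholog pairs
are split into a 2x2 table

    a = pairs on (i, j)        b = pairs on (i, not j)
    c = pairs on (not i, j)    d = pairs on (not i, not j)

and tested with a two-sided Fisher's exact test, Bonferroni-corrected over the
m = nA x nB tested pairs.  The enrichment direction is enforced separately by
the risk difference rd = a/(a+b) - c/(c+d) > 0.  A pair is a *strong*
correspondence when p_adj < 1e-10 (homologous chromosomes) and *weak* when
1e-10 <= p_adj < 1e-2 (small-scale rearrangement signal only).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import hypergeom

from .genomeio import GeneMap, OrthologPairSet

__all__ = [
    "ContingencyTable",
    "AssignmentResult",
    "build_contingency",
    "fisher_exact",
    "risk_difference",
    "assign_all",
    "write_assignments",
]

#: tolerance when deciding whether a table is "as extreme" as the observed one
POINT_PROB_TOL = 1e-12


@dataclass(frozen=True)
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class AssignmentResult:
    chrom_a: str
    chrom_b: str
    table: ContingencyTable
    p_raw: float
    p_adj: float
    rd: float | None
    tier: str  # {"strong", "weak", "none"}


def build_contingency(pairs: OrthologPairSet, map_a: GeneMap, map_b: GeneMap,
                      chrom_a: str, chrom_b: str) -> ContingencyTable:
    """Count ortholog pairs into the 2x2 table for one chromosome pair."""
    if chrom_a not in map_a.chromosomes:
        raise KeyError(f"chromosome {chrom_a!r} absent from {map_a.genome_id!r}")
    if chrom_b not in map_b.chromosomes:
        raise KeyError(f"chromosome {chrom_b!r} absent from {map_b.genome_id!r}")
    a = b = c = d = 0
    for ga, gb in pairs.pairs:
        on_a = map_a.gene(ga).chrom == chrom_a
        on_b = map_b.gene(gb).chrom == chrom_b
        if on_a and on_b:
            a += 1
        elif on_a:
            b += 1
        elif on_b:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def fisher_exact(table: ContingencyTable) -> float:
    """Two-sided Fisher's exact probability of a 2x2 table.

    Sums hypergeometric point probabilities, with the table's margins fixed,
    of all tables whose point probability does not exceed the observed one
    (up to POINT_PROB_TOL, guarding against float misclassification at the
    boundary).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.total
    if n == 0:
        raise ValueError("all-zero contingency table")
    row1, col1 = a + b, a + c
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, col1, row1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1 + POINT_PROB_TOL)].sum())
    return min(1.0, p)


def risk_difference(table: ContingencyTable) -> float | None:
    """a/(a+b) - c/(c+d); None (reported as missing) when a row is empty."""
    if table.a + table.b == 0 or table.c + table.d == 0:
        return None
    return table.a / (table.a + table.b) - table.c / (table.c + table.d)


def _tier(p_adj: float, rd: float | None, alpha_strong: float, alpha_weak: float) -> str:
    if rd is None or rd <= 0:
        return "none"
    if p_adj < alpha_strong:
        return "strong"
    if p_adj < alpha_weak:
        return "weak"
    return "none"


def assign_all(pairs: OrthologPairSet, map_a: GeneMap, map_b: GeneMap,
               alpha_strong: float = 1e-10, alpha_weak: float = 1e-2,
               exclude_b: set[str] | None = None) -> list[AssignmentResult]:
    """Test every chromosome pair; Bonferroni m = nA x nB.

    ``exclude_b`` drops chromosomes (e.g. unplaced scaffolds) from the tested
    chrom_b candidates; their orthologs still count in the b/c/d totals.
    """
    chroms_a = map_a.chromosomes
    chroms_b = [c for c in map_b.chromosomes if not exclude_b or c not in exclude_b]
    if not chroms_a or not chroms_b:
        raise ValueError("both genomes need at least one chromosome")
    # vectorized counting: per-pair chromosome labels
    placed = [(map_a.gene(a).chrom, map_b.gene(b).chrom) for a, b in pairs.pairs]
    total = len(placed)
    from collections import Counter

    joint = Counter(placed)
    marg_a = Counter(ca for ca, _ in placed)
    marg_b = Counter(cb for _, cb in placed)
    m = len(chroms_a) * len(chroms_b)
    results: list[AssignmentResult] = []
    for ca in chroms_a:
        for cb in chroms_b:
            a = joint.get((ca, cb), 0)
            b = marg_a.get(ca, 0) - a
            c = marg_b.get(cb, 0) - a
            d = total - a - b - c
            tab = ContingencyTable(a, b, c, d)
            p_raw = fisher_exact(tab) if tab.total else 1.0
            p_adj = min(1.0, p_raw * m)
            rd = risk_difference(tab)
            results.append(AssignmentResult(ca, cb, tab, p_raw, p_adj, rd,
                                            _tier(p_adj, rd, alpha_strong, alpha_weak)))
    results.sort(key=lambda r: (chroms_a.index(r.chrom_a), r.p_adj, r.chrom_b))
    return results


def read_assignments(path: str | Path) -> list[AssignmentResult]:
    """Read a TSV previously written by :func:`write_assignments`."""
    out: list[AssignmentResult] = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        ca, cb, a, b, c, d, p_raw, p_adj, rd, tier = line.split("\t")
        out.append(AssignmentResult(
            ca, cb, ContingencyTable(int(a), int(b), int(c), int(d)),
            float(p_raw), float(p_adj), None if rd == "NA" else float(rd), tier))
    return out


def write_assignments(results: list[AssignmentResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# chrom_a\tchrom_b\ta\tb\tc\td\tp_raw\tp_adj\trd\ttier\n")
        for r in results:
            rd = "NA" if r.rd is None else f"{r.rd:.6g}"
            fh.write(f"{r.chrom_a}\t{r.chrom_b}\t{r.table.a}\t{r.table.b}\t{r.table.c}"
                     f"\t{r.table.d}\t{r.p_raw:.6g}\t{r.p_adj:.6g}\t{rd}\t{r.tier}\n")
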