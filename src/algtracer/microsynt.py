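"""Microsyntenic-block analysis for small gene clusters.

Two members of a declared gene family set (e.g. the pharyngeal cluster
complement xrn2, nkx2.1, nkx2.2, msx, cnga, pax1/9, slc25a21, mipol1, foxa,
egln3) are *linked* in a genome when they sit on the same chromosome with at
most ``max_intervening`` non-family genes between them.  Same-chromosome but
distant pairs are reported separately, never silently merged into linkage.
Linkage presence across species forms a binary matrix whose ancestral states
are inferred on a guide tree under Dollo or Fitch parsimony.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import dendropy
import pandas as pd

from . import parsimony
from .genomeio import GeneMap

__all__ = [
    "FamilyTable",
    "LinkageRule",
    "LinkageReport",
    "read_family_table",
    "find_linked_pairs",
    "block_matrix",
    "ancestral_blocks",
]


@dataclass
class FamilyTable:
    """gene_id -> family assignments for one or more genomes."""

    families: tuple[str, ...]
    members: dict[str, dict[str, str]] = field(default_factory=dict)  # genome -> gene -> family

    def for_genome(self, genome_id: str) -> dict[str, str]:
        return self.members.get(genome_id, {})


@dataclass(frozen=True)
class LinkageRule:
    max_intervening: int = 3

    def __post_init__(self) -> None:
        if self.max_intervening < 0:
            raise ValueError("max_intervening must be >= 0")


@dataclass
class LinkageReport:
    genome_id: str
    linked: set[frozenset] = field(default_factory=set)
    same_chrom_unlinked: set[frozenset] = field(default_factory=set)
    cross_chrom: set[frozenset] = field(default_factory=set)
    missing: set[str] = field(default_factory=set)


def read_family_table(path: str | Path) -> FamilyTable:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    members: dict[str, dict[str, str]] = {}
    fams: list[str] = []
    for genome, gene, fam in zip(df[0], df[1], df[2]):
        if gene in members.setdefault(genome, {}):
            raise ValueError(f"gene {gene!r} mapped to more than one family")
        members[genome][gene] = fam
        if fam not in fams:
            fams.append(fam)
    return FamilyTable(tuple(fams), members)


def find_linked_pairs(gmap: GeneMap, fam: FamilyTable,
                      rule: LinkageRule = LinkageRule()) -> LinkageReport:
    """Classify every family pair of one genome as linked, same-chromosome-
    but-unlinked, or cross-chromosome; absent members are recorded, not
    errors.  Symmetric in pair order and invariant to record order."""
    assignment = fam.for_genome(gmap.genome_id)
    located: dict[str, list] = {}
    for gene_id, family in assignment.items():
        if gene_id in gmap:
            located.setdefault(family, []).append(gmap.gene(gene_id))
    report = LinkageReport(gmap.genome_id,
                           missing={f for f in fam.families if f not in located})
    family_gene_ids = {g for g in assignment if g in gmap}
    for fa, fb in combinations(sorted(located), 2):
        pair = frozenset((fa, fb))
        best: str | None = None
        for ga in located[fa]:
            for gb in located[fb]:
                if ga.chrom != gb.chrom:
                    best = best or "cross"
                    continue
                lo, hi = sorted((ga.rank, gb.rank))
                between = [g for g in gmap.genes_on(ga.chrom)[lo + 1:hi]
                           if g.gene_id not in family_gene_ids]
                if len(between) <= rule.max_intervening:
                    best = "linked"
                elif best != "linked":
                    best = "same_chrom"
        if best == "linked":
            report.linked.add(pair)
        elif best == "same_chrom":
            report.same_chrom_unlinked.add(pair)
        elif best == "cross":
            report.cross_chrom.add(pair)
    return report


def block_matrix(reports: dict[str, LinkageReport],
                 tier: str = "linked") -> pd.DataFrame:
    """Species x family-pair binary presence matrix for one linkage tier."""
    if not reports:
        raise ValueError("need >=1 genome")
    all_pairs = sorted({p for r in reports.values()
                        for p in getattr(r, tier if tier != "linked" else "linked")},
                       key=sorted)
    rows = {}
    for genome, rep in reports.items():
        present = rep.linked if tier == "linked" else getattr(rep, tier)
        rows[genome] = [int(p in present) for p in all_pairs]
    cols = ["--".join(sorted(p)) for p in all_pairs]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def ancestral_blocks(matrix: pd.DataFrame, tree: dendropy.Tree,
                     mode: str = "dollo") -> pd.DataFrame:
    """Per-node presence of each linkage under Dollo or Fitch parsimony."""
    leaves = {parsimony.node_name(l) for l in tree.leaf_node_iter()}
    unknown = set(matrix.index) - leaves
    if unknown:
        raise KeyError(f"species missing from tree: {sorted(unknown)}")
    recon: dict[str, dict[str, int]] = {}
    for col in matrix.columns:
        lv = {sp: int(matrix.loc[sp, col]) for sp in matrix.index}
        for leaf in leaves - set(matrix.index):
            lv[leaf] = 0
        if mode == "dollo":
            recon[col] = parsimony.dollo_binary(tree, lv)
        elif mode == "fitch":
            recon[col] = parsimony.fitch_binary(tree, lv)
        else:
            raise ValueError(f"unknown parsimony mode {mode!r}")
    nodes = [parsimony.node_name(n) for n in tree.preorder_node_iter()]
    return pd.DataFrame({col: [recon[col][n] for n in nodes] for col in recon},
                        index=nodes)
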