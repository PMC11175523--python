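"""Turn pairwise chromosome assignments into rearrangement calls.

The strong-tier assignment results between two genomes form a bipartite
correspondence graph.  Degree patterns classify each chromosome: one-to-one
(degree 1 on both sides), fusion candidate (a chromosome matching >=2 partner
chromosomes), split candidate (the mirror pattern), and dispersal (a
chromosome whose orthologs scatter with no enriched partner).  Fusions are
subtyped by a runs statistic along the fused chromosome's gene order: two
runs of source labels mean an unmodified end-end fusion (t1), three runs with
the minority source internal mean centric insertion or a single
translocation (t2), and heavily interleaved labels mean fusion-with-mixing
(t_s).  Events are polarized against an outgroup: the lineage whose state
differs from the outgroup carries the derived event.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .chromassign import AssignmentResult
from .genomeio import GeneMap

__all__ = [
    "CorrespondenceGraph",
    "MixingProfile",
    "RearrangementCall",
    "build_graph",
    "classify_pattern",
    "mixing_profile",
    "polarize",
    "detect_dispersal",
]

#: default index above which a 3+-run fused chromosome counts as mixed
MIX_THRESHOLD = 0.2
#: minority-label share above which three runs are read as a translocated
#: end-end fusion rather than a centric insertion
CENTRIC_MINORITY_MAX = 0.4
#: a chromosome holding >= this fraction of a source's orthologs blocks a
#: dispersal call (so a 2-way split is not misread as dispersal)
DISPERSAL_MAX_FRAC = 0.3


@dataclass
class CorrespondenceGraph:
    genome_a: str
    genome_b: str
    graph: nx.Graph

    def partners(self, chrom: str) -> list[str]:
        if chrom not in self.graph:
            raise KeyError(f"chromosome {chrom!r} not in graph")
        return sorted(self.graph.neighbors(chrom))


@dataclass(frozen=True)
class MixingProfile:
    runs: int
    index: float  # (runs-1)/(n_anchors-1) in [0, 1]
    state: str    # {t1_end_end, t2_centric_or_translocated, ts_mixed}


@dataclass
class RearrangementCall:
    pattern: str  # {one_to_one, fusion, split, dispersal}
    chrom: str
    operands: tuple[str, ...]
    subtype: str | None = None  # fusions only: {end_end, centric_insertion, mixing}
    polarity: str = "unpolarized"
    support: dict = field(default_factory=dict)


def build_graph(results: list[AssignmentResult], genome_a: str = "A",
                genome_b: str = "B", tiers: set[str] = frozenset({"strong"}),
                chroms_a: list[str] | None = None,
                chroms_b: list[str] | None = None) -> CorrespondenceGraph:
    """Bipartite graph with one edge per kept assignment, weighted by rd.

    Chromosome node names are namespaced with the genome id so that equal
    labels in the two genomes never collide.
    """
    g = nx.Graph()
    for r in results:
        g.add_node((genome_a, r.chrom_a), genome=genome_a)
        g.add_node((genome_b, r.chrom_b), genome=genome_b)
    for extra, gid in ((chroms_a, genome_a), (chroms_b, genome_b)):
        for c in extra or []:
            g.add_node((gid, c), genome=gid)
    for r in results:
        if r.tier in tiers:
            g.add_edge((genome_a, r.chrom_a), (genome_b, r.chrom_b),
                       rd=r.rd, p_adj=r.p_adj, tier=r.tier)
    return CorrespondenceGraph(genome_a, genome_b, g)


def classify_pattern(cg: CorrespondenceGraph, genome: str, chrom: str,
                     results: list[AssignmentResult] | None = None,
                     ortholog_targets: dict[str, int] | None = None,
                     max_frac: float = DISPERSAL_MAX_FRAC) -> RearrangementCall:
    """Classify one chromosome by its degree pattern in the strong-tier graph.

    ``ortholog_targets`` (target chromosome -> ortholog count for this
    chromosome's genes) is needed only to distinguish dispersal from a simple
    lack of data when the degree is zero.
    """
    node = (genome, chrom)
    if node not in cg.graph:
        raise KeyError(f"chromosome {chrom!r} of {genome!r} not in graph")
    partners = sorted(cg.graph.neighbors(node))
    if len(partners) >= 2:
        return RearrangementCall("fusion", chrom, tuple(p[1] for p in partners))
    if len(partners) == 1:
        partner = partners[0]
        back = sorted(cg.graph.neighbors(partner))
        if len(back) >= 2:
            return RearrangementCall("split", chrom, tuple(b[1] for b in back))
        return RearrangementCall("one_to_one", chrom, (partners[0][1],))
    if ortholog_targets:
        total = sum(ortholog_targets.values())
        if total and max(ortholog_targets.values()) / total < max_frac:
            return RearrangementCall("dispersal", chrom, ())
    return RearrangementCall("dispersal", chrom, (), support={"note": "degree 0"})


def _runs_of(labels: list[str]) -> list[list[str]]:
    runs: list[list[str]] = []
    for lab in labels:
        if runs and runs[-1][0] == lab:
            runs[-1].append(lab)
        else:
            runs.append([lab])
    return runs


def _drop_stray_singletons(labels: list[str], tol: float) -> list[str]:
    """Remove isolated single-gene runs while they make up less than ``tol``
    of the anchors — stray ortholog misassignments, not rearrangement signal.
    A genuinely interleaved sequence (singleton share >= tol) is untouched."""
    runs = _runs_of(labels)
    singles = sum(1 for r in runs if len(r) == 1)
    if singles == 0 or singles / max(1, len(labels)) >= tol:
        return labels
    return [lab for r in runs if len(r) > 1 for lab in r]


def mixing_profile(labels: list[str], mix_threshold: float = MIX_THRESHOLD,
                   centric_minority_max: float = CENTRIC_MINORITY_MAX,
                   singleton_tol: float = 0.1) -> MixingProfile:
    """Runs statistic over the source-label sequence of a fused chromosome.

    ``labels`` is the per-gene source assignment in gene-rank order (unlabeled
    genes already dropped).  Rare isolated singleton runs are discounted as
    annotation noise first.  runs <= 2 is an untouched end-end fusion; exactly
    3 runs with the minority source internal and rare (share <=
    ``centric_minority_max``) is the centric-insertion signature; otherwise
    the normalized runs index (runs-1)/(n-1) >= ``mix_threshold`` means mixed.
    """
    if len(set(labels)) < 2:
        raise ValueError("need >=2 distinct source labels")
    cleaned = _drop_stray_singletons(list(labels), singleton_tol)
    if len(set(cleaned)) >= 2:
        labels = cleaned
    runs = 1 + sum(1 for i in range(1, len(labels)) if labels[i] != labels[i - 1])
    index = (runs - 1) / (len(labels) - 1)
    if runs <= 2:
        state = "t1_end_end"
    elif runs == 3:
        from collections import Counter

        counts = Counter(labels)
        minority = min(counts, key=counts.get)
        internal = labels[0] != minority and labels[-1] != minority
        if internal and counts[minority] / len(labels) <= centric_minority_max:
            state = "t2_centric_or_translocated"
        elif index >= mix_threshold:
            state = "ts_mixed"
        else:
            state = "t2_centric_or_translocated"
    else:
        state = "ts_mixed" if index >= mix_threshold else "t2_centric_or_translocated"
    return MixingProfile(runs, index, state)


def profile_subtype(profile: MixingProfile) -> str:
    return {"t1_end_end": "end_end",
            "t2_centric_or_translocated": "centric_insertion",
            "ts_mixed": "mixing"}[profile.state]


def source_label_sequence(fused_map: GeneMap, chrom: str,
                          source_of: dict[str, str]) -> list[str]:
    """Source labels of a chromosome's genes in rank order (unlabeled dropped)."""
    return [source_of[g.gene_id] for g in fused_map.genes_on(chrom)
            if g.gene_id in source_of]


def polarize(call: RearrangementCall, outgroup_results: list[AssignmentResult],
             lineage: str = "ingroup", other: str = "partner",
             tiers: set[str] = frozenset({"strong"})) -> RearrangementCall:
    """Assign the derived lineage of a fusion/split call using an outgroup.

    ``outgroup_results`` compare the genome carrying ``call.operands`` (for a
    fusion: the partner genome holding the unfused pieces; the operand labels
    are its chromosomes) against the outgroup.  If the outgroup holds the
    operands on distinct chromosomes the fusion is derived in the fused
    lineage; if on one chromosome, the *split* is derived in the split
    lineage; anything else is unresolved.  Polarity is never assigned without
    outgroup edges.
    """
    og_partner: dict[str, set[str]] = {}
    for r in outgroup_results:
        if r.tier in tiers and r.chrom_a in call.operands:
            og_partner.setdefault(r.chrom_a, set()).add(r.chrom_b)
    if not og_partner or any(op not in og_partner for op in call.operands):
        call.polarity = "unresolved"
        return call
    sets = [og_partner[op] for op in call.operands]
    if all(len(s) == 1 for s in sets):
        flat = [next(iter(s)) for s in sets]
        if len(set(flat)) == len(flat):
            call.polarity = f"derived_in_{lineage}" if call.pattern == "fusion" else \
                f"ancestral_in_{lineage}"
        elif len(set(flat)) == 1:
            call.polarity = f"derived_in_{other}" if call.pattern == "fusion" else \
                f"derived_in_{lineage}"
        else:
            call.polarity = "unresolved"
    else:
        call.polarity = "unresolved"
    return call


def detect_dispersal(results: list[AssignmentResult], source_chrom: str,
                     ortholog_targets: dict[str, int],
                     max_frac: float = DISPERSAL_MAX_FRAC) -> bool:
    """True iff no target reaches the strong tier for ``source_chrom`` and no
    target chromosome holds >= ``max_frac`` of its mapped orthologs."""
    total = sum(ortholog_targets.values())
    if total == 0:
        raise ValueError(f"no mapped orthologs for {source_chrom!r}")
    if any(r.chrom_a == source_chrom and r.tier == "strong" for r in results):
        return False
    return max(ortholog_targets.values()) / total < max_frac
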