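"""Synthetic genome evolution with known truth.

A root genome of ``n_alg`` ancestral linkage groups x ``genes_per_alg`` genes
evolves along a species tree under the chromosome-scale event vocabulary:
end-end fusion, centric insertion, fusion-with-mixing (fusion followed by
rounds of intrachromosomal inversions and reciprocal translocations),
fission, and whole-group dispersal, plus per-branch gene loss and ortholog
misannotation noise at the leaves.  Every emitted gene map comes with the
true per-branch event list, the gene -> ancestral-group labels, and the true
ortholog pairs, so each downstream inference stage can be scored exactly.

TE landscapes are simulated separately as a Poisson process whose rate drops
by ``cluster_factor`` inside a declared exclusion zone, emulating the TE
depletion observed in conserved gene clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genomeio import GeneMap, Gene, OrthologPairSet, TETrack, TE_CLASSES, read_species_tree
from .parsimony import node_name
from .tedensity import ClusterRegion

__all__ = ["SimConfig", "SimEvent", "SimResult", "simulate", "simulate_te"]

#: synthetic gene length and spacing (bp); ranks, not positions, drive synteny
GENE_LEN = 500
GENE_SPACING = 1000


@dataclass(frozen=True)
class SimEvent:
    kind: str
    operands: tuple[str, ...]  # chromosome names at the time of application
    branch: str = ""


@dataclass
class SimConfig:
    seed: int = 0
    n_alg: int = 24
    genes_per_alg: int = 150
    tree: str = "(A,B);"
    events: dict[str, list[SimEvent]] = field(default_factory=dict)  # branch -> events
    mixing_rounds: int = 200
    noise_frac: float = 0.02
    loss_frac: float = 0.05

    def __post_init__(self) -> None:
        if not (0 <= self.noise_frac < 1 and 0 <= self.loss_frac < 1):
            raise ValueError("fractions must lie in [0, 1)")
        if self.n_alg < 1 or self.genes_per_alg < 1:
            raise ValueError("counts must be >= 1")


@dataclass
class TruthEvent:
    branch: str
    kind: str
    operand_labels: tuple[frozenset, ...]  # root-ALG labels per operand

    @property
    def all_labels(self) -> frozenset:
        return frozenset().union(*self.operand_labels)


@dataclass
class SimResult:
    maps: dict[str, GeneMap]
    truth_events: list[TruthEvent]
    gene_alg: dict[str, dict[str, str]]  # leaf -> gene_id -> root ALG label
    true_pairs: dict[tuple[str, str], list[tuple[str, str]]]
    pairs: dict[tuple[str, str], OrthologPairSet]
    alg_labels: tuple[str, ...]

    def pairs_between(self, a: str, b: str) -> OrthologPairSet:
        if (a, b) in self.pairs:
            return self.pairs[(a, b)]
        flipped = self.pairs[(b, a)]
        return OrthologPairSet(a, b, [(y, x) for x, y in flipped.pairs],
                               flipped.provenance)


def _alg_labels(n: int) -> tuple[str, ...]:
    return tuple(f"c{i + 1:02d}" for i in range(n))


def _mix(genes: list, rounds: int, rng: np.random.Generator) -> list:
    """In-place style scrambling: random inversions and reciprocal
    translocations with uniform endpoints, local to the chromosome."""
    genes = list(genes)
    n = len(genes)
    for _ in range(rounds):
        if n < 4:
            break
        if rng.random() < 0.5:
            i, j = sorted(rng.integers(0, n, size=2))
            genes[i:j + 1] = genes[i:j + 1][::-1]
        else:
            cuts = np.sort(rng.choice(np.arange(1, n), size=3, replace=False))
            i, j, k = (int(c) for c in cuts)
            genes = genes[:i] + genes[j:k] + genes[i:j] + genes[k:]
    return genes


def _apply_sim_event(genome: dict[str, list], e: SimEvent, cfg: SimConfig,
                     rng: np.random.Generator) -> None:
    for op in e.operands:
        if op not in genome:
            raise KeyError(f"event {e.kind}{e.operands} references absent chromosome {op!r}")
    if e.kind == "fusion_end_end":
        merged = [g for op in e.operands for g in genome.pop(op)]
        genome["●".join(e.operands)] = merged
    elif e.kind == "fusion_centric":
        host, insert = e.operands[0], e.operands[1]
        hg, ig = genome.pop(host), genome.pop(insert)
        pos = int(rng.integers(1, max(2, len(hg))))
        genome["↘".join(e.operands)] = hg[:pos] + ig + hg[pos:]
    elif e.kind == "fusion_mixing":
        merged = [g for op in e.operands for g in genome.pop(op)]
        genome["⊗".join(e.operands)] = _mix(merged, cfg.mixing_rounds, rng)
    elif e.kind == "fission":
        src = genome.pop(e.operands[0])
        # centric fission: the breakpoint sits in the central (centromeric)
        # span, so both products are viable chromosomes
        lo = max(1, int(0.2 * len(src)))
        hi = max(lo + 1, int(0.8 * len(src)))
        pos = int(rng.integers(lo, hi))
        genome[f"{e.operands[0]}-a"] = src[:pos]
        genome[f"{e.operands[0]}-b"] = src[pos:]
    elif e.kind == "dispersal":
        src = genome.pop(e.operands[0])
        targets = list(genome)
        for g in src:
            t = targets[int(rng.integers(len(targets)))]
            pos = int(rng.integers(0, len(genome[t]) + 1))
            genome[t].insert(pos, g)
    else:
        raise ValueError(f"unknown event kind {e.kind!r}")


def _labels_of(genome: dict[str, list], name: str) -> frozenset:
    return frozenset(lab for lab, _ in genome[name])


def simulate(cfg: SimConfig) -> SimResult:
    """Evolve the root genome along the tree; identical seeds give identical
    output."""
    rng = np.random.default_rng(cfg.seed)
    labels = _alg_labels(cfg.n_alg)
    root = {lab: [(lab, i) for i in range(cfg.genes_per_alg)] for lab in labels}
    tree = read_species_tree(cfg.tree)
    truth_events: list[TruthEvent] = []
    leaf_genomes: dict[str, dict[str, list]] = {}

    def descend(node, genome):
        name = node_name(node)
        genome = {k: list(v) for k, v in genome.items()}
        for e in cfg.events.get(name, []):
            op_labels = tuple(_labels_of(genome, op) for op in e.operands)
            _apply_sim_event(genome, e, cfg, rng)
            truth_events.append(TruthEvent(name, e.kind, op_labels))
        if cfg.loss_frac > 0 and name:
            for chrom in list(genome):
                keep = rng.random(len(genome[chrom])) >= cfg.loss_frac
                genome[chrom] = [g for g, k in zip(genome[chrom], keep) if k]
        if node.is_leaf():
            leaf_genomes[name] = genome
        for child in node.child_nodes():
            descend(child, genome)

    descend(tree.seed_node, root)

    maps: dict[str, GeneMap] = {}
    gene_alg: dict[str, dict[str, str]] = {}
    ancestral: dict[str, dict[tuple, str]] = {}  # leaf -> (alg, idx) -> gene_id
    for leaf, genome in sorted(leaf_genomes.items()):
        genes: list[Gene] = []
        gene_alg[leaf] = {}
        ancestral[leaf] = {}
        for chrom in sorted(genome):
            for i, (alg, idx) in enumerate(genome[chrom]):
                gid = f"{leaf}_{alg}_{idx}"
                genes.append(Gene(gid, chrom, i * GENE_SPACING, i * GENE_SPACING + GENE_LEN))
                gene_alg[leaf][gid] = alg
                ancestral[leaf][(alg, idx)] = gid
        maps[leaf] = GeneMap(leaf, genes)

    leaves = sorted(leaf_genomes)
    true_pairs: dict[tuple[str, str], list[tuple[str, str]]] = {}
    pairs: dict[tuple[str, str], OrthologPairSet] = {}
    for i, a in enumerate(leaves):
        for b in leaves[i + 1:]:
            shared = sorted(set(ancestral[a]) & set(ancestral[b]))
            plist = [(ancestral[a][k], ancestral[b][k]) for k in shared]
            true_pairs[(a, b)] = list(plist)
            if cfg.noise_frac > 0 and len(plist) > 3:
                n_noise = int(round(cfg.noise_frac * len(plist)))
                if n_noise >= 2:
                    idx = rng.choice(len(plist), size=n_noise, replace=False)
                    bs = [plist[j][1] for j in idx]
                    rolled = bs[1:] + bs[:1]  # cyclic partner swap keeps 1-to-1
                    for j, nb in zip(idx, rolled):
                        plist[j] = (plist[j][0], nb)
            pairs[(a, b)] = OrthologPairSet(a, b, plist, provenance="given")
    return SimResult(maps, truth_events, gene_alg, true_pairs, pairs, labels)


def simulate_te(chrom_lengths: dict[str, int], background_rate: float,
                cluster: ClusterRegion | None = None, cluster_factor: float = 1.0,
                seed: int = 0) -> TETrack:
    """Poisson TE landscape: ``background_rate`` starts per 10 kb, multiplied
    by ``cluster_factor`` inside the cluster region; classes uniform over the
    four TE types."""
    if background_rate <= 0:
        raise ValueError("background rate must be positive")
    if cluster is not None:
        if cluster.chrom not in chrom_lengths:
            raise KeyError(f"cluster chromosome {cluster.chrom!r} unknown")
        if cluster.end > chrom_lengths[cluster.chrom]:
            raise ValueError("cluster region extends past chromosome end")
    rng = np.random.default_rng(seed)
    intervals: list[tuple[str, int, int, str]] = []
    for chrom, length in chrom_lengths.items():
        segments = [(0, length, background_rate)]
        if cluster is not None and cluster.chrom == chrom:
            segments = [(0, cluster.start, background_rate),
                        (cluster.start, cluster.end, background_rate * cluster_factor),
                        (cluster.end, length, background_rate)]
        for lo, hi, rate in segments:
            if hi <= lo or rate <= 0:
                continue
            n = rng.poisson(rate * (hi - lo) / 10_000)
            starts = np.sort(rng.integers(lo, hi, size=n))
            classes = rng.integers(0, len(TE_CLASSES), size=n)
            for s, c in zip(starts, classes):
                intervals.append((chrom, int(s), int(s) + 100, TE_CLASSES[c]))
    return TETrack("sim", intervals)
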