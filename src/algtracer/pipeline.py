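"""End-to-end orchestration: assignments -> leaf ALG states -> ancestral
reconstruction -> recovered event set, plus replay/census/character reports
from the shipped history fixtures.

The leaf-state inference mirrors the comparative workflow: each ingroup
genome is compared against an event-free outgroup genome whose chromosomes
stand proxy for the ancestral linkage groups; strong-tier assignment edges
give each ingroup chromosome its composition, the runs statistic over the
gene-order source labels gives the fusion geometry, and group dispersal is
called when a proxy group's orthologs scatter with no enriched partner.
"""

from __future__ import annotations

import hashlib
import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

from . import algebra, rearrange, syntenychar
from .algebra import AlgState, Chromosome, Unit
from .chromassign import assign_all
from .genomeio import GeneMap, OrthologPairSet, read_species_tree
from .parsimony import dollo_binary, node_name
from .rearrange import mixing_profile, profile_subtype, source_label_sequence
from .simgenome import SimResult

__all__ = [
    "infer_leaf_state",
    "recover_events",
    "replay_report",
    "run_all",
]

_SUBTYPE_KIND = {"end_end": "fusion_end_end", "centric_insertion": "fusion_centric",
                 "mixing": "fusion_mixing"}


def infer_leaf_state(leaf_map: GeneMap, outgroup_map: GeneMap,
                     pairs: OrthologPairSet, alpha_strong: float = 1e-10,
                     alpha_weak: float = 1e-2,
                     mix_threshold: float = rearrange.MIX_THRESHOLD,
                     max_frac: float = rearrange.DISPERSAL_MAX_FRAC) -> AlgState:
    """Compose a leaf's ALG state from its assignment against the outgroup.

    Outgroup chromosome names are used as the linkage-group labels, so the
    outgroup must itself be rearrangement-free relative to the ancestor.
    """
    results = assign_all(pairs, leaf_map, outgroup_map, alpha_strong, alpha_weak)
    partners: dict[str, list[str]] = {}
    for r in results:
        if r.tier == "strong":
            partners.setdefault(r.chrom_a, []).append(r.chrom_b)
    # source label of each leaf gene = outgroup chromosome of its partner
    source_of = {a: outgroup_map.gene(b).chrom for a, b in pairs.pairs}
    # how many leaf chromosomes carry each outgroup group (split detection)
    homes: dict[str, list[str]] = {}
    for chrom, ps in partners.items():
        for p in ps:
            homes.setdefault(p, []).append(chrom)

    state = AlgState()
    for chrom in leaf_map.chromosomes:
        ps = sorted(partners.get(chrom, []))
        if not ps:
            continue  # handled by dispersal scan below
        split = any(len(homes[p]) > 1 for p in ps)
        if len(ps) == 1:
            lab = ps[0]
            records: tuple = ()
            if split:
                records = (("fission", f"split:{lab}", frozenset([lab])),)
            unit = Unit(chrom if split else lab, frozenset([lab]), split=split)
            state.chromosomes[chrom if split else lab] = Chromosome(
                chrom if split else lab, (unit,), records)
            continue
        seq = [s for s in source_label_sequence(leaf_map, chrom, source_of) if s in ps]
        prof = mixing_profile(seq, mix_threshold)
        subtype = profile_subtype(prof)
        kind = _SUBTYPE_KIND[subtype]
        sym = algebra.FUSION_SYMBOL[kind]
        name = sym.join(ps)
        records = ((kind, name, frozenset(ps)),)
        if split:
            records += (("fission", f"split:{name}", frozenset(ps)),)
        if subtype == "mixing":
            units: tuple = (Unit(name, frozenset(ps), mixed=True, split=split),)
        else:
            units = tuple(Unit(p, frozenset([p]), split=split) for p in ps)
        state.chromosomes[chrom if split else name] = Chromosome(
            chrom if split else name, units, records)
    # dispersal: outgroup groups with no strong-tier home anywhere
    placed = set().union(*(set(v) for v in partners.values())) if partners else set()
    for og_chrom in outgroup_map.chromosomes:
        if og_chrom in placed:
            continue
        targets = Counter(leaf_map.gene(a).chrom for a, b in pairs.pairs
                          if outgroup_map.gene(b).chrom == og_chrom and a in leaf_map)
        if targets and max(targets.values()) / sum(targets.values()) < max_frac:
            state.dispersed[og_chrom] = (frozenset([og_chrom]),
                                         (("dispersal", f"dispersed:{og_chrom}",
                                           frozenset([og_chrom])),))
    return state


@dataclass(frozen=True)
class RecoveredEvent:
    kind: str
    labels: frozenset

    def __repr__(self) -> str:
        return f"{self.kind}({','.join(sorted(self.labels))})"


def recover_events(leaf_states: dict[str, AlgState], tree, outgroup: str,
                   labels) -> set[RecoveredEvent]:
    """Infer the rearrangement event set from leaf states by parsimony.

    Fusions appear as co-residency characters gained on an edge (Dollo for
    mixed pairs, Fitch for unmixed); fissions as ">=2 chromosomes share a
    label" characters; dispersals as per-label dispersal characters (both
    Dollo — a split or dispersed group never reassembles).
    """
    recon = algebra.parsimony_reconstruct(leaf_states, tree, outgroup, labels)
    events: set[RecoveredEvent] = set()
    leaf_names = {node_name(l) for l in tree.leaf_node_iter()}

    def gained(rec: dict[str, int]) -> list[str]:
        out = []
        for node in tree.preorder_node_iter():
            name = node_name(node)
            parent = node.parent_node
            pv = rec.get(node_name(parent), 0) if parent is not None else 0
            if rec.get(name, 0) and not pv:
                out.append(name)
        return out

    # fusions from pair characters, merged per (edge, connected operand set)
    import networkx as nx

    for kind_chars, mixed in ((recon.mixed_pairs, True), (recon.unmixed_pairs, False)):
        per_edge: dict[str, list[tuple[str, str]]] = {}
        for pair, rec in kind_chars.items():
            for edge in gained(rec):
                per_edge.setdefault(edge, []).append(pair)
        for edge, prs in per_edge.items():
            g = nx.Graph(prs)
            for comp in nx.connected_components(g):
                comp = frozenset(comp)
                if mixed:
                    events.add(RecoveredEvent("fusion_mixing", comp))
                else:
                    kind = _leaf_subtype(leaf_states, edge, comp, leaf_names, tree)
                    events.add(RecoveredEvent(kind, comp))

    # fissions and dispersals as Dollo characters
    split_chars: dict[frozenset, dict[str, int]] = {}
    disp_chars: dict[str, dict[str, int]] = {}
    for lab in labels:
        lv_d = {leaf: int(lab in st.dispersed_labels) for leaf, st in leaf_states.items()}
        if any(lv_d.values()):
            disp_chars[lab] = dollo_binary(tree, lv_d)
    seen_groups: set[frozenset] = set()
    for leaf, st in leaf_states.items():
        for lab in labels:
            if len(st.chromosome_of(lab)) > 1:
                grp = frozenset().union(
                    *(st.chromosomes[h].labels for h in st.chromosome_of(lab)))
                seen_groups.add(grp)
    # overlapping groups describe the same fission; merge to their union
    merged: list[set] = []
    for grp in sorted(seen_groups, key=sorted):
        for m in merged:
            if m & grp:
                m |= grp
                break
        else:
            merged.append(set(grp))
    seen_groups = {frozenset(m) for m in merged}
    for grp in seen_groups:
        lv = {leaf: int(any(len(st.chromosome_of(lab)) > 1 for lab in grp))
              for leaf, st in leaf_states.items()}
        split_chars[grp] = dollo_binary(tree, lv)
    for grp, rec in split_chars.items():
        if any(rec.values()):
            events.add(RecoveredEvent("fission", grp))
    for lab, rec in disp_chars.items():
        if any(rec.values()):
            events.add(RecoveredEvent("dispersal", frozenset([lab])))
    return events


def _leaf_subtype(leaf_states, edge, comp, leaf_names, tree) -> str:
    """Fusion kind for an unmixed co-residency gain, read from the recorded
    geometry of a leaf below the gain edge."""
    for leaf in sorted(leaf_names):
        st = leaf_states[leaf]
        for chrom in st.chromosomes.values():
            for kind, name, ls in chrom.records:
                if kind in _SUBTYPE_KIND.values() and comp <= ls:
                    return kind
    return "fusion_end_end"


def recover_from_simulation(sim: SimResult, outgroup: str, tree_str: str,
                            **kwargs) -> tuple[set[RecoveredEvent], dict[str, AlgState]]:
    """Full pipeline on simulator output: leaf states against the outgroup
    leaf, then event recovery on the tree."""
    tree = read_species_tree(tree_str)
    og_map = sim.maps[outgroup]
    leaf_states: dict[str, AlgState] = {}
    for leaf, lmap in sim.maps.items():
        if leaf == outgroup:
            leaf_states[leaf] = algebra.root_state(og_map.chromosomes)
            continue
        leaf_states[leaf] = infer_leaf_state(
            lmap, og_map, sim.pairs_between(leaf, outgroup), **kwargs)
    events = recover_events(leaf_states, tree, outgroup, tuple(og_map.chromosomes))
    return events, leaf_states


def truth_event_set(sim: SimResult) -> set[RecoveredEvent]:
    """Canonical (kind, labels) set of the simulator's true events."""
    return {RecoveredEvent(t.kind, t.all_labels) for t in sim.truth_events}


# ---------------------------------------------------------------------------
# fixture reports


def replay_report(fixture: str = "deuterostome") -> dict:
    """Replay a shipped history fixture: per-node chromosome counts and, for
    the deuterostome fixture, the intact/changed census over the five extant
    deuterostome leaves."""
    hist = algebra.load_history(fixture)
    states = algebra.replay(hist)
    counts = {node: len(st) for node, st in states.items()}
    leaves = [node_name(l) for l in hist.tree.leaf_node_iter()]
    report = {"fixture": hist.name, "counts": counts, "leaves": leaves}
    if hist.name == "deuterostome":
        census_leaves = {l: states[l] for l in ("BFL", "PFL", "SCA", "SPU", "POC")}
        intact, changed = algebra.census_intact(census_leaves, hist.root_labels)
        report["census"] = {"intact": intact, "changed": changed}
    return report


def ten_species_states() -> dict[str, AlgState]:
    """Leaf ALG states of the ten bilaterian species, replayed from the
    deuterostome and spiralian history fixtures."""
    states: dict[str, AlgState] = {}
    for fixture, leaves in (("deuterostome", ("BFL", "PFL", "SCA", "SPU", "POC")),
                            ("spiralian", ("RPH", "SCO", "PYE", "PEC", "SBE"))):
        hist = algebra.load_history(fixture)
        replayed = algebra.replay(hist)
        for leaf in leaves:
            states[leaf] = replayed[leaf]
    return states


def character_report() -> dict:
    """Category table, binary matrix and distances for the ten-species set."""
    states = ten_species_states()
    table = syntenychar.encode_categories(states)
    matrix = syntenychar.binarize(table)
    dist = syntenychar.binary_distance(matrix)
    return {"table": table, "matrix": matrix, "dist": dist,
            "category_counts": table.category_counts()}


def run_all(seed: int = 0, out_dir: str | Path | None = None) -> dict:
    """Fixture-driven full report: replayed counts, census, category counts,
    distances and dendrogram clades; deterministic given the seed."""
    report: dict = {"seed": seed}
    for fixture in ("deuterostome", "sea_urchin", "spiralian"):
        report[fixture] = replay_report(fixture)
    chars = character_report()
    report["category_counts"] = chars["category_counts"]
    matrix = chars["matrix"]
    linkage = syntenychar.cluster(chars["dist"])
    clades = syntenychar.dendrogram_clades(linkage, list(matrix.index))
    report["deuterostomes_cluster"] = frozenset(
        {"BFL", "PFL", "SCA", "SPU", "POC"}) in set(clades)
    payload = json.dumps(
        {k: v for k, v in report.items() if isinstance(v, (int, float, str, bool))},
        sort_keys=True)
    report["config_hash"] = hashlib.sha256(payload.encode()).hexdigest()[:12]
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        matrix.to_csv(out_dir / "binary_matrix.tsv", sep="\t")
        chars["dist"].to_csv(out_dir / "binary_distance.tsv", sep="\t")
        with open(out_dir / "report.json", "w") as fh:
            json.dump({k: v for k, v in report.items()
                       if isinstance(v, (dict, int, float, str, bool))
                       and k not in ("table",)}, fh, indent=2, default=str)
    return report
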