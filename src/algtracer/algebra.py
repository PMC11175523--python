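"""Ancestral-linkage-group (ALG) state algebra.

An :class:`AlgState` describes one genome as a set of chromosomes, each a
head-to-tail sequence of *units*.  A unit is an irreducible stretch of the
chromosome: either a single ancestral linkage group, a mixed amalgam of
several (after fusion-with-mixing), or a declared split part of a former
composite.  Rearrangement events transform states:

* ``fusion_end_end``   — concatenate two (or more) chromosomes (symbol ●);
* ``fusion_centric``   — insert one chromosome into another (symbol ↘);
* ``fusion_mixing``    — fuse and scramble into a single mixed unit (symbol ⊗),
  treated downstream as irreversible;
* ``fission``          — split one chromosome into declared products;
* ``dispersal``        — dissolve a chromosome, scattering its genes genome-wide.

Histories (a rooted species tree with per-branch event lists) can be replayed
to annotate every tree node with its state, censused for intact ALGs, and
reconstructed from leaf states alone by pair-character parsimony (Dollo for
mixed co-residency, Fitch for unmixed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import dendropy
import yaml

from . import parsimony
from .genomeio import read_species_tree
from .parsimony import node_name

#: the 24 root linkage-group labels used for bilaterian/deuterostome ancestors
ROOT_ALG_LABELS = (
    "A1", "A2", "B1", "B2", "B3", "C1", "C2", "D", "E", "F", "G", "H",
    "I", "J1", "J2", "K", "L", "M", "N", "O1", "O2", "P", "Q", "R",
)

FUSION_SYMBOL = {"fusion_end_end": "●", "fusion_centric": "↘", "fusion_mixing": "⊗"}

__all__ = [
    "ROOT_ALG_LABELS",
    "Unit",
    "Chromosome",
    "AlgState",
    "EventRecord",
    "History",
    "root_state",
    "apply_event",
    "replay",
    "census_intact",
    "parsimony_reconstruct",
    "load_history",
    "fixture_path",
]


@dataclass(frozen=True)
class Unit:
    name: str
    labels: frozenset
    mixed: bool = False
    split: bool = False


#: (kind, display name, root labels involved) — the audit trail of a chromosome
Record = tuple[str, str, frozenset]


@dataclass(frozen=True)
class Chromosome:
    name: str
    units: tuple[Unit, ...]
    records: tuple[Record, ...] = ()

    @property
    def labels(self) -> frozenset:
        out: set = set()
        for u in self.units:
            out |= u.labels
        return frozenset(out)

    @property
    def intact(self) -> bool:
        return not self.records and len(self.units) == 1 and not self.units[0].split


@dataclass
class AlgState:
    chromosomes: dict[str, Chromosome] = field(default_factory=dict)
    dispersed: dict[str, tuple[frozenset, tuple[Record, ...]]] = field(default_factory=dict)

    def copy(self) -> "AlgState":
        return AlgState(dict(self.chromosomes), dict(self.dispersed))

    def __len__(self) -> int:
        return len(self.chromosomes)

    @property
    def resident_labels(self) -> frozenset:
        out: set = set()
        for chrom in self.chromosomes.values():
            out |= chrom.labels
        return frozenset(out)

    @property
    def dispersed_labels(self) -> frozenset:
        out: set = set()
        for labels, _ in self.dispersed.values():
            out |= labels
        return frozenset(out)

    def chromosome_of(self, label: str) -> list[str]:
        """Names of chromosomes carrying a root label (two after a split)."""
        return [name for name, c in self.chromosomes.items() if label in c.labels]

    def resolve(self, operand: str) -> str:
        """Resolve an operand (chromosome name or unit name) to a chromosome."""
        if operand in self.chromosomes:
            return operand
        hits = [name for name, c in self.chromosomes.items()
                if any(u.name == operand for u in c.units)]
        if len(hits) == 1:
            return hits[0]
        raise KeyError(f"operand {operand!r} not resolvable to a single chromosome "
                       f"(matches {hits!r})")


@dataclass(frozen=True)
class EventRecord:
    kind: str  # fusion_end_end | fusion_centric | fusion_mixing | fission | dispersal
    operands: tuple[str, ...] = ()
    products: tuple[str, ...] = ()  # fission only: declared split-part names
    branch: str = ""

    def __post_init__(self) -> None:
        if self.kind in FUSION_SYMBOL and len(self.operands) < 2:
            raise ValueError(f"{self.kind} needs >=2 operands")
        if self.kind == "fission" and len(self.products) < 2:
            raise ValueError("fission needs >=2 declared products")


@dataclass
class History:
    tree: dendropy.Tree
    root_labels: tuple[str, ...]
    stem_events: list[EventRecord]
    events: dict[str, list[EventRecord]]  # branch label -> events (edge above node)
    name: str = ""


def root_state(labels=ROOT_ALG_LABELS) -> AlgState:
    return AlgState({lab: Chromosome(lab, (Unit(lab, frozenset([lab])),)) for lab in labels})


def _wrap(name: str) -> str:
    return f"({name})" if any(sym in name for sym in "●↘⊗") else name


def apply_event(state: AlgState, e: EventRecord) -> AlgState:
    """Return the state after one rearrangement event (input untouched)."""
    state = state.copy()
    if e.kind in FUSION_SYMBOL:
        try:
            names = [state.resolve(op) for op in e.operands]
        except KeyError as exc:
            raise KeyError(f"event {e.kind}{e.operands}: {exc}") from exc
        chroms = [state.chromosomes.pop(n) for n in names]
        sym = FUSION_SYMBOL[e.kind]
        new_name = sym.join(_wrap(c.name) for c in chroms)
        all_labels = frozenset().union(*(c.labels for c in chroms))
        records = tuple(r for c in chroms for r in c.records)
        records += ((e.kind, new_name, all_labels),)
        if e.kind == "fusion_mixing":
            units: tuple[Unit, ...] = (Unit(new_name, all_labels, mixed=True),)
        else:
            units = tuple(u for c in chroms for u in c.units)
        state.chromosomes[new_name] = Chromosome(new_name, units, records)
    elif e.kind == "fission":
        src_name = state.resolve(e.operands[0])
        src = state.chromosomes.pop(src_name)
        mixed = any(u.mixed for u in src.units)
        for prod in e.products:
            unit = Unit(prod, src.labels, mixed=mixed, split=True)
            records = src.records + (("fission", f"split:{src.name}", src.labels),)
            state.chromosomes[prod] = Chromosome(prod, (unit,), records)
    elif e.kind == "dispersal":
        src_name = state.resolve(e.operands[0])
        src = state.chromosomes.pop(src_name)
        state.dispersed[src.name] = (src.labels, src.records)
    else:
        raise ValueError(f"unknown event kind {e.kind!r}")
    return state


def replay(history: History) -> dict[str, AlgState]:
    """Annotate every tree node with its ALG state.

    Events listed under a node label apply on the edge leading into that node;
    ``stem_events`` apply above the root.
    """
    state = root_state(history.root_labels)
    for e in history.stem_events:
        state = _apply_checked(state, e, "stem")
    states: dict[str, AlgState] = {}
    root = history.tree.seed_node
    stack = [(root, state)]
    while stack:
        node, parent_state = stack.pop()
        name = node_name(node)
        st = parent_state
        for e in history.events.get(name, []):
            st = _apply_checked(st, e, name)
        states[name] = st
        for child in node.child_nodes():
            stack.append((child, st))
    return states


def _apply_checked(state: AlgState, e: EventRecord, branch: str) -> AlgState:
    try:
        return apply_event(state, e)
    except KeyError as exc:
        raise KeyError(f"branch {branch!r}: inapplicable event {e.kind}{e.operands}: {exc}") from exc


def census_intact(leaf_states: dict[str, AlgState],
                  root_labels=ROOT_ALG_LABELS) -> tuple[int, int]:
    """(intact, changed): an ALG is intact iff it sits alone on an unfused,
    unsplit, undispersed chromosome in *every* leaf."""
    intact = 0
    for lab in root_labels:
        ok = True
        for st in leaf_states.values():
            if lab in st.dispersed_labels:
                ok = False
                break
            homes = st.chromosome_of(lab)
            if len(homes) != 1 or not st.chromosomes[homes[0]].intact:
                ok = False
                break
        intact += ok
    return intact, len(root_labels) - intact


# ---------------------------------------------------------------------------
# parsimony reconstruction from leaf states


@dataclass
class ReconResult:
    states: dict[str, AlgState]
    mixed_pairs: dict[tuple[str, str], dict[str, int]]    # pair -> node presence
    unmixed_pairs: dict[tuple[str, str], dict[str, int]]
    conflicts: list[str]


def _pair_characters(state: AlgState, labels) -> tuple[set, set]:
    mixed, unmixed = set(), set()
    for chrom in state.chromosomes.values():
        for u in chrom.units:
            for x, y in combinations(sorted(u.labels & set(labels)), 2):
                if u.mixed:
                    mixed.add((x, y))
        for x, y in combinations(sorted(chrom.labels & set(labels)), 2):
            if (x, y) not in mixed:
                unmixed.add((x, y))
    return mixed, unmixed


def parsimony_reconstruct(leaf_states: dict[str, AlgState], tree: dendropy.Tree,
                          outgroup: str, root_labels=ROOT_ALG_LABELS) -> ReconResult:
    """Reconstruct ancestral co-residency from leaf states.

    Each unordered ALG pair yields a binary character: mixed co-residency is
    reconstructed under Dollo (fusion-with-mixing is irreversible — single
    gain, losses only by subsequent dispersal), unmixed co-residency under
    Fitch.  Internal states are assembled from the reconstructed pair
    relations (connected components = chromosomes); non-transitive
    co-residency is reported as a conflict, never silently repaired.
    """
    labels = tuple(root_labels)
    leaf_chars = {leaf: _pair_characters(st, labels) for leaf, st in leaf_states.items()}
    all_mixed = sorted(set().union(*(m for m, _ in leaf_chars.values())) if leaf_chars else set())
    all_unmixed = sorted(set().union(*(u for _, u in leaf_chars.values())) if leaf_chars else set())
    og_state = leaf_states.get(outgroup)

    mixed_rec: dict[tuple[str, str], dict[str, int]] = {}
    for pair in all_mixed:
        lv = {leaf: int(pair in chars[0]) for leaf, chars in leaf_chars.items()}
        mixed_rec[pair] = parsimony.dollo_binary(tree, lv)
    unmixed_rec: dict[tuple[str, str], dict[str, int]] = {}
    for pair in all_unmixed:
        lv = {leaf: int(pair in chars[1]) for leaf, chars in leaf_chars.items()}
        root_pref = 0
        if og_state is not None:
            root_pref = lv.get(outgroup, 0)
        unmixed_rec[pair] = parsimony.fitch_binary(tree, lv, root_pref=root_pref)

    states: dict[str, AlgState] = {}
    conflicts: list[str] = []
    for node in tree.preorder_node_iter():
        name = node_name(node)
        present = {p for p, rec in mixed_rec.items() if rec.get(name)}
        present |= {p for p, rec in unmixed_rec.items() if rec.get(name)}
        # connected components over co-residency edges
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(labels)
        g.add_edges_from(present)
        st = AlgState()
        for comp in nx.connected_components(g):
            comp = sorted(comp)
            missing = [(x, y) for x, y in combinations(comp, 2) if (x, y) not in present]
            if missing:
                conflicts.append(f"{name}: non-transitive co-residency in {comp}: missing {missing}")
            mixedness = any((x, y) in mixed_rec and mixed_rec[(x, y)].get(name)
                            for x, y in combinations(comp, 2))
            cname = "+".join(comp)
            st.chromosomes[cname] = Chromosome(
                cname, (Unit(cname, frozenset(comp), mixed=mixedness),))
        states[name] = st
    return ReconResult(states, mixed_rec, unmixed_rec, conflicts)


# ---------------------------------------------------------------------------
# history fixtures


def fixture_path(name: str) -> Path:
    return Path(__file__).parent / "fixtures" / f"{name}.yaml"


def _parse_event(d: dict, branch: str) -> EventRecord:
    return EventRecord(
        kind=d["kind"],
        operands=tuple(str(x) for x in d.get("operands", ())),
        products=tuple(str(x) for x in d.get("products", ())),
        branch=branch,
    )


def load_history(source: str | Path) -> History:
    """Load a history fixture (YAML: root_labels, newick tree, branch events).

    ``source`` is a path, or the name of a packaged fixture
    (``deuterostome``, ``sea_urchin``, ``spiralian``).
    """
    path = Path(source)
    if not path.exists():
        path = fixture_path(str(source))
    data = yaml.safe_load(path.read_text())
    tree = read_species_tree(data["tree"])
    events = {
        branch: [_parse_event(e, branch) for e in evs]
        for branch, evs in (data.get("events") or {}).items()
    }
    stem = [_parse_event(e, "stem") for e in data.get("stem_events", [])]
    return History(tree, tuple(data["root_labels"]), stem, events, data.get("name", path.stem))
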