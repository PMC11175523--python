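import numpy as np
import pytest

from algtracer import algebra
from algtracer.algebra import (EventRecord, apply_event, census_intact,
                               load_history, parsimony_reconstruct, replay,
                               root_state, ROOT_ALG_LABELS, _pair_characters)
from algtracer.genomeio import read_species_tree


def test_fusion_mixing_reduces_count_by_one():
    state = root_state()
    assert len(state) == 24
    fused = apply_event(state, EventRecord("fusion_mixing", ("B2", "C2")))
    assert len(fused) == 23
    assert fused.chromosomes["B2⊗C2"].units[0].mixed
    # input state untouched
    assert len(state) == 24


def test_empty_event_list_is_identity():
    state = root_state()
    for _ in []:
        state = apply_event(state, _)
    assert len(state) == 24 and set(state.chromosomes) == set(ROOT_ALG_LABELS)


def test_hemichordate_branch_arithmetic():
    """Fission of the fused B2/C2 group then the R/B1 fusion keeps 23."""
    st = apply_event(root_state(), EventRecord("fusion_mixing", ("B2", "C2")))
    st = apply_event(st, EventRecord("fission", ("B2⊗C2",),
                                     ("B2⊗C2-a", "B2⊗C2-b")))
    st = apply_event(st, EventRecord("fusion_mixing", ("R", "B1")))
    assert len(st) == 23
    assert len(st.chromosome_of("B2")) == 2


def test_missing_operand_errors_with_name():
    with pytest.raises(KeyError, match="ZZ"):
        apply_event(root_state(), EventRecord("fusion_mixing", ("B2", "ZZ")))


@pytest.mark.parametrize("fixture,expected", [
    ("deuterostome", {"Deuterostomia": 24, "Ambulacraria": 23, "Hemichordata": 23,
                      "PFL": 23, "SCA": 23, "Echinodermata": 23, "SPU": 21,
                      "POC": 22, "Chordata": 23, "BFL": 19, "VRT": 18}),
    ("sea_urchin", {"SeaUrchin": 21, "SPU": 21, "Lytechinus": 20,
                    "LVA": 19, "LPI": 19}),
    ("spiralian", {"Spiralia": 20, "Bivalvia": 20, "Annelida": 19,
                   "RPH": 19, "SCO": 19, "PYE": 19, "PEC": 14, "SBE": 11}),
])
def test_replay_reproduces_recorded_karyotypes(fixture, expected):
    states = replay(load_history(fixture))
    assert {node: len(st) for node, st in states.items()} == expected


def test_census_on_deuterostome_leaves():
    states = replay(load_history("deuterostome"))
    leaves = {l: states[l] for l in ("BFL", "PFL", "SCA", "SPU", "POC")}
    assert census_intact(leaves) == (9, 15)


def test_census_degenerate_cases():
    assert census_intact({"X": root_state()}) == (24, 0)
    st = root_state()
    labels = list(ROOT_ALG_LABELS)
    for a, b in zip(labels[::2], labels[1::2]):
        st = apply_event(st, EventRecord("fusion_end_end", (a, b)))
    assert census_intact({"X": st}) == (0, 24)


def test_single_leaf_no_events_replay():
    hist = algebra.History(read_species_tree("(X);"), ROOT_ALG_LABELS, [], {})
    states = replay(hist)
    assert len(states["X"]) == 24


def test_chromosome_count_formula_on_random_sequences():
    """count = 24 - sum(k-1 over fusions) + sum(|products|-1 over fissions)
    - #dispersals, and root labels are conserved."""
    rng = np.random.default_rng(5)
    for _ in range(30):
        state = root_state()
        expected = 24
        for _ in range(int(rng.integers(1, 10))):
            kinds = ["fusion_mixing", "fusion_end_end", "fusion_centric",
                     "fission", "dispersal"]
            kind = kinds[int(rng.integers(len(kinds)))]
            names = sorted(state.chromosomes)
            if kind.startswith("fusion"):
                k = int(rng.integers(2, 4))
                if len(names) < k:
                    continue
                ops = [names[i] for i in rng.choice(len(names), size=k, replace=False)]
                state = apply_event(state, EventRecord(kind, tuple(ops)))
                expected -= k - 1
            elif kind == "fission":
                src = names[int(rng.integers(len(names)))]
                state = apply_event(state, EventRecord(
                    "fission", (src,), (f"{src}-a", f"{src}-b")))
                expected += 1
            else:
                if len(names) < 2:
                    continue
                src = names[int(rng.integers(len(names)))]
                state = apply_event(state, EventRecord("dispersal", (src,)))
                expected -= 1
        assert len(state) == expected
        assert state.resident_labels | state.dispersed_labels == set(ROOT_ALG_LABELS)


# ---------------------------------------------------------------------------
# parsimony reconstruction


def _b2c2_scenario():
    tree = read_species_tree("(((PFL,(SPU,POC)Ech)Amb,BFL)Deut);")
    b2c2 = EventRecord("fusion_mixing", ("B2", "C2"))
    leaf_states = {}
    st = apply_event(root_state(), b2c2)
    leaf_states["POC"] = st
    leaf_states["SPU"] = apply_event(st, EventRecord("fusion_mixing", ("E", "B2⊗C2")))
    leaf_states["PFL"] = apply_event(st, EventRecord(
        "fission", ("B2⊗C2",), ("B2⊗C2-a", "B2⊗C2-b")))
    leaf_states["BFL"] = root_state()
    return leaf_states, tree


def test_reconstruct_places_fusion_on_ambulacrarian_stem():
    """B2/C2 are fused-with-mixing in the ambulacrarian ancestor but separate
    in the deuterostome ancestor (outgroup keeps them apart)."""
    leaf_states, tree = _b2c2_scenario()
    recon = parsimony_reconstruct(leaf_states, tree, outgroup="BFL")
    assert recon.mixed_pairs[("B2", "C2")]["Amb"] == 1
    assert recon.mixed_pairs[("B2", "C2")]["Deut"] == 0
    amb = recon.states["Amb"]
    assert any(u.mixed and u.labels == frozenset({"B2", "C2"})
               for c in amb.chromosomes.values() for u in c.units)


def test_reconstruct_identity_when_all_leaves_match_outgroup():
    tree = read_species_tree("(((A,B)n1,C)n2,OG)root;")
    leaf_states = {l: root_state() for l in ("A", "B", "C", "OG")}
    recon = parsimony_reconstruct(leaf_states, tree, outgroup="OG")
    for node, st in recon.states.items():
        assert len(st) == 24
    assert not recon.conflicts


def test_dollo_single_gain_per_mixing_character():
    leaf_states, tree = _b2c2_scenario()
    recon = parsimony_reconstruct(leaf_states, tree, outgroup="BFL")
    for pair, rec in recon.mixed_pairs.items():
        gains = 0
        for node in tree.preorder_node_iter():
            from algtracer.parsimony import node_name

            parent = node.parent_node
            pv = rec.get(node_name(parent), 0) if parent else 0
            gains += int(rec.get(node_name(node), 0) and not pv)
        assert gains == 1


def _random_history(seed):
    rng = np.random.default_rng(seed)
    newick = "(((A,B)n1,(C,D)n2)n3,((E,F)n4,G)n5,OG)root;"
    tree = read_species_tree(newick)
    branches = ["n1", "n2", "n3", "n4", "n5", "A", "B", "C", "D", "E", "F", "G"]
    below = {"n1": ["A", "B"], "n2": ["C", "D"], "n3": ["n1", "n2", "A", "B", "C", "D"],
             "n4": ["E", "F"], "n5": ["n4", "E", "F", "G"]}
    labels = list(ROOT_ALG_LABELS)
    rng.shuffle(labels)
    events: dict[str, list[EventRecord]] = {}
    kinds = ["fusion_mixing", "fusion_mixing", "fusion_end_end"]
    fusion_sites = []
    for i, kind in enumerate(kinds):
        br = branches[int(rng.integers(len(branches)))]
        a, b = labels[2 * i], labels[2 * i + 1]
        events.setdefault(br, []).append(EventRecord(kind, (a, b)))
        fusion_sites.append((br, kind, a, b))
    # fission of one mixed fusion product, on a descendant branch (or the same)
    br, kind, a, b = fusion_sites[0]
    sym = "⊗" if kind == "fusion_mixing" else "●"
    fuse_name = f"{a}{sym}{b}"
    candidates = [x for x in below.get(br, [br]) + [br]]
    fbr = candidates[int(rng.integers(len(candidates)))]
    if fbr == br:
        events[br].append(EventRecord("fission", (fuse_name,),
                                      (f"{fuse_name}-a", f"{fuse_name}-b")))
    else:
        events.setdefault(fbr, []).append(EventRecord(
            "fission", (fuse_name,), (f"{fuse_name}-a", f"{fuse_name}-b")))
    dbr = branches[int(rng.integers(len(branches)))]
    events.setdefault(dbr, []).append(EventRecord("dispersal", (labels[6],)))
    return algebra.History(tree, ROOT_ALG_LABELS, [], events), newick


def test_ancestral_coresidency_recovered_on_random_histories():
    """Eight-leaf histories (3 fusions, 1 fission, 1 dispersal): ancestral
    co-residency is recovered exactly in >=90% of 50 seeds."""
    ok = 0
    for seed in range(50):
        hist, newick = _random_history(seed)
        states = replay(hist)
        leaves = {l: states[l] for l in ("A", "B", "C", "D", "E", "F", "G", "OG")}
        recon = parsimony_reconstruct(leaves, hist.tree, outgroup="OG")
        good = True
        for node in ("n1", "n2", "n3", "n4", "n5", "root"):
            t_mixed, t_unmixed = _pair_characters(states[node], ROOT_ALG_LABELS)
            r_mixed, r_unmixed = _pair_characters(recon.states[node], ROOT_ALG_LABELS)
            good &= (t_mixed == r_mixed) and (t_unmixed == r_unmixed)
        ok += good
    assert ok >= 45


def test_nontransitive_coresidency_is_reported():
    tree = read_species_tree("((A,B)n1,OG)root;")
    st_a = apply_event(root_state(), EventRecord("fusion_end_end", ("B2", "C2")))
    st_b = apply_event(root_state(), EventRecord("fusion_end_end", ("C2", "Q")))
    recon = parsimony_reconstruct(
        {"A": st_a, "B": st_b, "OG": root_state()}, tree, outgroup="OG")
    # Fitch may union the two leaf-specific pairs at n1 only if parsimony
    # favors it; with a clean outgroup it does not, so no conflicts here —
    # force one by giving both pairs to a single leaf without the third
    st_c = apply_event(st_a, EventRecord("fusion_end_end", ("B2●C2", "Q")))
    chars_mixed, chars_unmixed = _pair_characters(st_c, ROOT_ALG_LABELS)
    assert ("B2", "C2") in chars_unmixed and ("C2", "Q") in chars_unmixed
    assert ("B2", "Q") in chars_unmixed  # same chromosome => transitive here
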