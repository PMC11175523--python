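import numpy as np
import pandas as pd
import pytest
from scipy.special import logsumexp

from algtracer import pipeline
from algtracer.genomeio import read_species_tree
from algtracer.syntenychar import (McmcConfig, binarize, binary_distance,
                                   check_monophyly, cluster, dendrogram_clades,
                                   encode_categories, sample_trees,
                                   splits_contain)

DEUTEROSTOMES = {"BFL", "PFL", "SCA", "SPU", "POC"}


def test_category_counts_match_recorded_range(ten_species_table):
    """Across the ten species the per-linkage-group category count runs from
    2 (F, G, N, I) to 8 (B2)."""
    counts = ten_species_table.category_counts()
    assert counts["B2"] == 8
    for balg in ("F", "G", "N", "I"):
        assert counts[balg] == 2
    assert min(counts.values()) == 2 and max(counts.values()) == 8
    assert max(counts, key=counts.get) == "B2"


def test_category_example_for_balg_k(ten_species_table):
    """BALG K: intact, O2(x)K, and the nested J1(x)(O2(x)K) — three
    categories, with the doubly fused species a member of both fusions."""
    assert set(ten_species_table.categories("K")) == \
        {"intact:K", "O2⊗K", "J1⊗(O2⊗K)"}
    memb = ten_species_table.memberships["K"]
    assert "O2⊗K" in memb["SBE"] and "J1⊗(O2⊗K)" in memb["SBE"]
    assert memb["BFL"] == frozenset({"intact:K"})


def test_encode_is_invariant_to_species_order():
    states = pipeline.ten_species_states()
    t1 = encode_categories(states)
    t2 = encode_categories(dict(reversed(list(states.items()))))
    assert t1.memberships == t2.memberships


def test_all_intact_gives_one_category_per_balg():
    from algtracer.algebra import root_state

    table = encode_categories({"X": root_state(), "Y": root_state()})
    assert all(n == 1 for n in table.category_counts().values())


def test_binarize_nested_membership_and_dedup(ten_species_table):
    m_dedup = binarize(ten_species_table, deduplicate=True)
    m_full = binarize(ten_species_table, deduplicate=False)
    assert m_full.shape[1] > m_dedup.shape[1]
    # each fused-category column appears exactly once after de-duplication
    fused_cols = [c for c in m_dedup.columns if "C2⊗(L⊗J2)" in c]
    assert len({c.split("|")[1] for c in fused_cols}) == len(fused_cols)
    # PEC carries both the early L(x)J2 fusion and the later C2 fusion
    lj2 = next(c for c in m_dedup.columns if c.endswith("|L⊗J2"))
    c2lj2 = next(c for c in m_dedup.columns if c.endswith("|C2⊗(L⊗J2)"))
    assert m_dedup.loc["PEC", lj2] == 1 and m_dedup.loc["PEC", c2lj2] == 1
    assert not m_dedup.columns.duplicated().any()


@pytest.mark.parametrize("rows,expected", [
    (([1, 1, 0, 0], [1, 1, 0, 0]), 0.0),
    (([1, 1, 0, 0], [0, 0, 1, 1]), 1.0),
    (([1, 1, 0], [0, 1, 1]), 2 / 3),
])
def test_binary_distance_hand_enumeration(rows, expected):
    m = pd.DataFrame(list(rows), index=["x", "y"])
    assert binary_distance(m).loc["x", "y"] == pytest.approx(expected)


def test_binary_distance_properties(ten_species_matrix):
    d = binary_distance(ten_species_matrix)
    assert np.allclose(d.values, d.values.T)
    assert np.allclose(np.diag(d.values), 0)
    assert np.nanmax(d.values) <= 1.0


def test_clustering_joins_closest_pair_first():
    d = pd.DataFrame([[0, 0.1, 0.9], [0.1, 0, 0.8], [0.9, 0.8, 0]],
                     index=list("ABC"), columns=list("ABC"))
    clades = dendrogram_clades(cluster(d), list("ABC"))
    assert clades[0] == frozenset("AB")


def test_clustering_groups_deuterostomes(ten_species_matrix):
    d = binary_distance(ten_species_matrix)
    clades = dendrogram_clades(cluster(d), list(d.index))
    assert frozenset(DEUTEROSTOMES) in set(clades)


def test_clustering_invariant_to_label_permutation(ten_species_matrix):
    d = binary_distance(ten_species_matrix)
    perm = list(d.index)[::-1]
    d2 = d.loc[perm, perm]
    c1 = set(dendrogram_clades(cluster(d), list(d.index)))
    c2 = set(dendrogram_clades(cluster(d2), perm))
    assert c1 == c2


# ---------------------------------------------------------------------------
# Mk2 MCMC


def _mk2_p(t, same):
    return 0.5 * (1 + np.exp(-2 * t)) if same else 0.5 * (1 - np.exp(-2 * t))


def _marginal_loglik_4taxa(cols, split, rng, n_mc=60_000, rate=10.0):
    """Independent oracle: prior Monte-Carlo estimate of the Mk2 marginal
    likelihood of a 4-taxon topology (pair ``split`` joined)."""
    names = ["A", "B", "C", "D"]
    left = sorted(split)
    right = sorted(set(names) - set(split))
    bl = {n: rng.exponential(1 / rate, size=n_mc) for n in names + ["e"]}
    total = np.zeros(n_mc)
    for col in cols:
        s = dict(zip(names, col))
        like = np.zeros(n_mc)
        for x in (0, 1):
            fx = (_mk2_p(bl[left[0]], x == s[left[0]]) *
                  _mk2_p(bl[left[1]], x == s[left[1]]))
            for y in (0, 1):
                gy = (_mk2_p(bl[right[0]], y == s[right[0]]) *
                      _mk2_p(bl[right[1]], y == s[right[1]]))
                like += 0.5 * fx * _mk2_p(bl["e"], x == y) * gy
        total += np.log(like)
    return logsumexp(total) - np.log(n_mc)


def test_sampler_recovers_perfect_split_and_matches_exact_odds():
    """Eight identical AB|CD columns: the sampler's posterior for AB|CD
    agrees with exact per-topology marginal likelihoods and exceeds 0.95."""
    cols = [(1, 1, 0, 0)] * 8
    m = pd.DataFrame(np.array(cols).T, index=["A", "B", "C", "D"])
    res = sample_trees(m, McmcConfig(n_samples=4000, seed=1, thin=4))
    rng = np.random.default_rng(9)
    logml = {s: _marginal_loglik_4taxa(cols, s, rng)
             for s in (("A", "B"), ("A", "C"), ("A", "D"))}
    z = logsumexp(list(logml.values()))
    exact = {s: np.exp(v - z) for s, v in logml.items()}
    freq_ab = res.split_freqs.get(frozenset({"C", "D"}), 0.0)
    assert freq_ab >= 0.95
    assert freq_ab == pytest.approx(exact[("A", "B")], abs=0.05)
    assert splits_contain(res, {"A", "B"})


def test_sampler_flat_posterior_without_signal():
    m = pd.DataFrame(np.ones((4, 6), dtype=int), index=list("ABCD"))
    res = sample_trees(m, McmcConfig(n_samples=3000, seed=2, thin=3))
    assert all(f <= 0.6 for f in res.split_freqs.values())


def test_sampler_rejects_non_binary_cells():
    m = pd.DataFrame([[0, 2], [1, 0], [0, 1], [1, 1]], index=list("ABCD"))
    with pytest.raises(ValueError):
        sample_trees(m, McmcConfig(n_samples=10))


def test_sampler_seed_reproducible(ten_species_matrix):
    cfg = McmcConfig(n_samples=200, seed=5, thin=1)
    r1 = sample_trees(ten_species_matrix, cfg)
    r2 = sample_trees(ten_species_matrix, cfg)
    assert r1.split_freqs == r2.split_freqs


def test_sampler_recovers_deuterostome_clade(ten_species_mcmc):
    assert splits_contain(ten_species_mcmc, DEUTEROSTOMES)


@pytest.mark.parametrize("taxa,expected", [
    ({"A", "B"}, True),
    ({"A", "C"}, False),
])
def test_check_monophyly(taxa, expected):
    tree = read_species_tree("((A,B),(C,D));")
    assert check_monophyly(tree, taxa) is expected
    with pytest.raises(KeyError):
        check_monophyly(tree, {"A", "Z"})
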