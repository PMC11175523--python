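import itertools
import math

import numpy as np
import pytest
from scipy.stats import fisher_exact as scipy_fisher

from algtracer.chromassign import (ContingencyTable,
                                   assign_all, build_contingency,
                                   fisher_exact, risk_difference)
from algtracer.genomeio import Gene, GeneMap, OrthologPairSet
from algtracer.simgenome import SimConfig, simulate


def enumeration_fisher(tab):
    """Oracle: full enumeration of all tables with the observed margins."""
    a, b, c, d = tab.a, tab.b, tab.c, tab.d
    n, row1, col1 = a + b + c + d, a + b, a + c
    denom = math.comb(n, row1)

    def point(x):
        if x < 0 or x > col1 or row1 - x > n - col1:
            return 0.0
        return math.comb(col1, x) * math.comb(n - col1, row1 - x) / denom

    p_obs = point(a)
    return sum(p for x in range(0, min(row1, col1) + 1)
               if (p := point(x)) <= p_obs * (1 + 1e-12))


def test_fisher_small_table_enumeration_values():
    """(3,0,0,3) has p = 2/20 = 0.1; the balanced table is p = 1."""
    assert fisher_exact(ContingencyTable(3, 0, 0, 3)) == pytest.approx(0.1)
    assert fisher_exact(ContingencyTable(1, 1, 1, 1)) == pytest.approx(1.0)


def test_fisher_matches_enumeration_for_all_small_tables():
    """Exact equality with the enumeration oracle (and scipy's independent
    implementation) for every table with total <= 30."""
    count = 0
    for total in range(1, 31):
        for a, b, c in itertools.product(range(total + 1), repeat=3):
            d = total - a - b - c
            if d < 0:
                continue
            tab = ContingencyTable(a, b, c, d)
            p = fisher_exact(tab)
            assert p == pytest.approx(enumeration_fisher(tab), abs=1e-12)
            count += 1
    assert count > 1000
    # spot-check the independent library route on a sample
    rng = np.random.default_rng(0)
    for _ in range(50):
        a, b, c, d = rng.integers(0, 40, size=4)
        if a + b + c + d == 0:
            continue
        tab = ContingencyTable(int(a), int(b), int(c), int(d))
        assert fisher_exact(tab) == pytest.approx(
            scipy_fisher([[a, b], [c, d]]).pvalue, rel=1e-9)


def test_fisher_rejects_all_zero_table():
    with pytest.raises(ValueError):
        fisher_exact(ContingencyTable(0, 0, 0, 0))


def test_risk_difference_values():
    """Printed worked example: (202, 99, 45, 8528) -> 0.66585."""
    assert risk_difference(ContingencyTable(202, 99, 45, 8528)) == \
        pytest.approx(0.66585, abs=1e-5)
    assert risk_difference(ContingencyTable(7, 0, 0, 7)) == 1.0
    assert risk_difference(ContingencyTable(0, 7, 7, 0)) == -1.0
    assert risk_difference(ContingencyTable(5, 0, 0, 0)) is None


def test_rd_sign_matches_proportion_order():
    rng = np.random.default_rng(1)
    for _ in range(100):
        a, b, c, d = (int(x) for x in rng.integers(0, 50, size=4))
        tab = ContingencyTable(a, b, c, d)
        rd = risk_difference(tab)
        if rd is None:
            continue
        assert -1 <= rd <= 1
        assert (rd > 0) == (a / (a + b) > c / (c + d))


def test_homologous_pair_is_strong_tier():
    """The PFL1-SPU15-like table at m=483 comparisons is a strong call."""
    tab = ContingencyTable(202, 99, 45, 8528)
    p_adj = min(1.0, fisher_exact(tab) * 483)
    assert p_adj < 1e-10 and risk_difference(tab) > 0


def _toy_instance():
    ga = [Gene(f"a{i}", f"c{i % 2 + 1}", (i // 2) * 10, (i // 2) * 10 + 5) for i in range(20)]
    gb = [Gene(f"b{i}", f"d{i % 2 + 1}", (i // 2) * 10, (i // 2) * 10 + 5) for i in range(20)]
    return GeneMap("A", ga), GeneMap("B", gb)


def test_build_contingency_counts_partition():
    ma, mb = _toy_instance()
    # even ids sit on c1/d1, odd ids on c2/d2
    plist = [("a0", "b0"), ("a2", "b2"), ("a4", "b4"), ("a6", "b6")]  # c1 -> d1
    plist += [("a8", "b1")]                                           # c1 -> d2
    plist += [("a1", "b8"), ("a3", "b10")]                            # c2 -> d1
    plist += [("a5", "b3"), ("a7", "b5"), ("a9", "b7")]               # c2 -> d2
    pairs = OrthologPairSet("A", "B", plist)
    tab = build_contingency(pairs, ma, mb, "c1", "d1")
    assert (tab.a, tab.b, tab.c, tab.d) == (4, 1, 2, 3)
    # the a-cells over all chromosome pairs partition the pair set
    total = sum(build_contingency(pairs, ma, mb, ca, cb).a
                for ca in ("c1", "c2") for cb in ("d1", "d2"))
    assert total == len(pairs)
    with pytest.raises(KeyError):
        build_contingency(pairs, ma, mb, "nope", "d1")


def _identity_sim(seed, n_chrom=5, genes=100, noise=0.0):
    cfg = SimConfig(seed=seed, n_alg=n_chrom, genes_per_alg=genes,
                    tree="(X,OG)R;", events={}, noise_frac=noise, loss_frac=0.0)
    sim = simulate(cfg)
    return sim.maps["X"], sim.maps["OG"], sim.pairs_between("X", "OG")


def test_identity_genomes_give_perfect_strong_matching():
    mx, mog, pairs = _identity_sim(0)
    results = assign_all(pairs, mx, mog)
    strong = [(r.chrom_a, r.chrom_b) for r in results if r.tier == "strong"]
    assert strong == [(c, c) for c in mx.chromosomes]


def test_shuffled_orthology_yields_no_strong_tier():
    """Monte-Carlo null: permuted partners over 5x5 chromosomes produce zero
    strong-tier calls in at least 99% of replicates."""
    mx, mog, pairs = _identity_sim(1, n_chrom=5, genes=200, noise=0.0)
    rng = np.random.default_rng(2024)
    clean = 0
    n_rep = 200
    for _ in range(n_rep):
        bs = [b for _, b in pairs.pairs]
        perm = rng.permutation(len(bs))
        shuffled = OrthologPairSet("X", "OG",
                                   [(a, bs[j]) for (a, _), j in zip(pairs.pairs, perm)])
        results = assign_all(shuffled, mx, mog)
        if not any(r.tier == "strong" for r in results):
            clean += 1
    assert clean >= 0.99 * n_rep


def test_power_full_recall_under_noise():
    """>=50 orthologs per chromosome with 10% noise: every true chromosome
    pair is recovered at strong tier in all 50 replicates."""
    for seed in range(50):
        mx, mog, pairs = _identity_sim(seed, n_chrom=5, genes=60, noise=0.10)
        results = assign_all(pairs, mx, mog)
        strong = {(r.chrom_a, r.chrom_b) for r in results if r.tier == "strong"}
        assert {(c, c) for c in mog.chromosomes} <= strong


def test_assign_all_invariant_to_relabeling():
    mx, mog, pairs = _identity_sim(3, n_chrom=3, genes=60)
    res1 = {(r.chrom_a, r.chrom_b): r.p_adj for r in assign_all(pairs, mx, mog)}
    relabel = {c: f"z{i}" for i, c in enumerate(mx.chromosomes)}
    genes2 = [Gene(g.gene_id, relabel[g.chrom], g.start, g.end, g.strand)
              for g in mx.genes]
    mx2 = GeneMap("A2", genes2)
    res2 = {(r.chrom_a, r.chrom_b): r.p_adj for r in assign_all(pairs, mx2, mog)}
    for (ca, cb), p in res1.items():
        assert res2[(relabel[ca], cb)] == pytest.approx(p)
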