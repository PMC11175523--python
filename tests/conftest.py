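import pytest

from algtracer import pipeline, syntenychar
from algtracer.simgenome import SimConfig, SimEvent, simulate

#: six-leaf test history: four fusions (two mixed, one centric, one end-end),
#: one fission of the mixed group, one dispersal; OG stays event-free
RECOVERY_TREE = "(((L1,L2)N1,(L3,L4)N2)N3,L5,OG)R;"
RECOVERY_EVENTS = {
    "N3": [SimEvent("fusion_mixing", ("c01", "c02"), "N3")],
    "N1": [SimEvent("fission", ("c01⊗c02",), "N1")],
    "L3": [SimEvent("fusion_centric", ("c03", "c04"), "L3")],
    "L4": [SimEvent("fusion_mixing", ("c05", "c06"), "L4")],
    "L5": [SimEvent("fusion_end_end", ("c07", "c08"), "L5"),
           SimEvent("dispersal", ("c09",), "L5")],
}


def recovery_config(seed: int) -> SimConfig:
    return SimConfig(seed=seed, n_alg=12, tree=RECOVERY_TREE, events=RECOVERY_EVENTS)


@pytest.fixture(scope="session")
def recovery_runs():
    """Recovered vs true event sets for 50 simulated six-leaf histories."""
    runs = []
    for seed in range(50):
        sim = simulate(recovery_config(seed))
        recovered, _ = pipeline.recover_from_simulation(sim, "OG", RECOVERY_TREE)
        runs.append((recovered, pipeline.truth_event_set(sim)))
    return runs


@pytest.fixture(scope="session")
def ten_species_table():
    return syntenychar.encode_categories(pipeline.ten_species_states())


@pytest.fixture(scope="session")
def ten_species_matrix(ten_species_table):
    return syntenychar.binarize(ten_species_table)


@pytest.fixture(scope="session")
def ten_species_mcmc(ten_species_matrix):
    cfg = syntenychar.McmcConfig(n_samples=3000, burnin_frac=0.25, seed=7, thin=5)
    return syntenychar.sample_trees(ten_species_matrix, cfg)
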