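import logging

import pytest
from hypothesis import HealthCheck, settings

import clonedyn as cd

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")

logging.getLogger("clonedyn").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def p04_scenario():
    return cd.build_scenario("p04_like")


@pytest.fixture(scope="session")
def p04_calls(p04_scenario):
    return cd.simulate_all_biopsies(p04_scenario, seed=1)


@pytest.fixture(scope="session")
def p04_matrix(p04_scenario, p04_calls):
    return cd.ccf_matrix(
        p04_calls,
        {s.sample_id: s.purity for s in p04_scenario.samples},
        {s.sample_id: s.cn_profile for s in p04_scenario.samples},
    )


@pytest.fixture(scope="session")
def p04_results(p04_matrix):
    return cd.ClonalStructureModel(p04_matrix).fit()


@pytest.fixture(scope="session")
def p04_noiseless_clusters(p04_scenario):
    """Clusters built directly from the scenario's true clone CCFs."""
    clusters = []
    for clone in p04_scenario.clones:
        cl = cd.CCFCluster(
            cluster_id=clone.clone_id,
            centers=dict(clone.per_sample_ccf),
            members=[("1", i, "A", "T") for i in range(clone.n_private_mutations)],
        )
        cl.n_private_mutations = clone.n_private_mutations
        cd.classify_cluster(cl)
        clusters.append(cl)
    return clusters
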