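import numpy as np
import pandas as pd
import pytest

from fosnet import StudyConfig, generate_anatomical_connectome, generate_study


@pytest.fixture(scope="session")
def default_config() -> StudyConfig:
    return StudyConfig.default(seed=7)


@pytest.fixture(scope="session")
def study(default_config):
    """One full default study (10 CTR + 11 VPA, 36 regions)."""
    counts, truth = generate_study(default_config)
    return counts, truth


@pytest.fixture(scope="session")
def counts(study) -> pd.DataFrame:
    return study[0]


@pytest.fixture(scope="session")
def adjacency(default_config) -> pd.DataFrame:
    return generate_anatomical_connectome(
        default_config.regions, edge_density=0.3, seed=11
    )


@pytest.fixture
def tiny_counts() -> pd.DataFrame:
    """Hand-written two-subject, two-region bilateral count table."""
    rows = []
    for subj, grp, lit in [("s1", "CTR", "L1"), ("s2", "VPA", "L2")]:
        for region, (cl, cr) in {"A": (50, 30), "B": (10, 20)}.items():
            rows.append(dict(subject_id=subj, group=grp, litter_id=lit,
                             region=region, hemisphere="left", slide_index=0,
                             count=cl, area_mm2=0.5))
            rows.append(dict(subject_id=subj, group=grp, litter_id=lit,
                             region=region, hemisphere="right", slide_index=0,
                             count=cr, area_mm2=0.5))
    return pd.DataFrame(rows)


def random_graph(n_nodes: int, p: float, seed: int):
    import networkx as nx

    rng = np.random.default_rng(seed)
    g = nx.Graph()
    g.add_nodes_from(range(n_nodes))
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p:
                g.add_edge(i, j)
    return g
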