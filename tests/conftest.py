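import networkx as nx
import pytest

from comorbinet import ComorbidityNetwork, PlantedPair, StratumSpec, SyntheticConfig


def make_network(edges, stratum="test", alpha=0.05):
    """Build a ComorbidityNetwork from (code_a, code_b, mi) triples."""
    G = nx.Graph()
    for a, b, mi in edges:
        G.add_edge(a, b, mi=float(mi), weight=float(mi), p_value=1e-4, q_value=1e-3, k=1, n_a=1, n_b=1)
    return ComorbidityNetwork(graph=G, stratum=stratum, alpha=alpha)


@pytest.fixture
def single_stratum():
    return StratumSpec(label="man-low-0-20", age_lo=0, age_hi=20, sex="man", ses="low")


@pytest.fixture
def base_config(single_stratum):
    """Two-code universe, one stratum, independent 10% prevalences."""
    return SyntheticConfig(
        code_universe=["A00", "B00"],
        strata=[single_stratum],
        n_per_stratum=1000,
        prevalence={single_stratum.label: 0.1},
        seed=11,
    )


def planted_config(stratum, rho=4.0, n=2000, n_codes=30, prevalence=0.1, seed=0):
    codes = [f"A{i:02d}" for i in range(n_codes)]
    return SyntheticConfig(
        code_universe=codes,
        strata=[stratum],
        n_per_stratum=n,
        prevalence={stratum.label: prevalence},
        planted_pairs=[PlantedPair("A00", "A01", stratum.label, rho)],
        seed=seed,
    )
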