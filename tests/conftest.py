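import pytest

from mircoord.clustering import detect_clusters
from mircoord.modules import MCODEParams, predict_modules, undirected_projection
from mircoord.simulate import build_scenario, default_config


@pytest.fixture(scope="session")
def planted():
    """Default planted scenario with clusters called and modules detected."""
    scenario = build_scenario(default_config(seed=3))
    genes = [g.with_family(scenario.families[g.id]) for g in scenario.genes]
    clusters = detect_clusters(genes)
    modules = predict_modules(
        undirected_projection(scenario.network), MCODEParams()
    )
    return scenario, genes, clusters, modules
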