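"""Shared corpora and graphs; session-scoped since generation is the slow part."""

import pytest

from rxnnet import synthetic as syn
from rxnnet.etl import run_etl
from rxnnet.graphs import build_bipartite, project_molecule_graph


@pytest.fixture(scope="session")
def clean_config():
    return syn.GeneratorConfig(n_reactions=300, seed=42)


@pytest.fixture(scope="session")
def clean_lines(clean_config):
    return syn.generate_dataset(clean_config)


@pytest.fixture(scope="session")
def clean_etl(clean_lines):
    return run_etl(clean_lines)


@pytest.fixture(scope="session")
def clean_net(clean_etl):
    return build_bipartite(clean_etl.accepted)


@pytest.fixture(scope="session")
def pa_config():
    # the preferential-attachment study condition: strong reuse, offset 1
    return syn.GeneratorConfig(n_reactions=20_000, seed=7, reuse_prob=0.9, attach_strength=1.0)


@pytest.fixture(scope="session")
def pa_etl(pa_config):
    return run_etl(syn.generate_dataset(pa_config))


@pytest.fixture(scope="session")
def pa_net(pa_etl):
    return build_bipartite(pa_etl.accepted)


@pytest.fixture(scope="session")
def pa_molgraph(pa_net):
    return project_molecule_graph(pa_net)


@pytest.fixture(scope="session")
def skeleton_5k():
    """~5000-node molecule graph from the growth skeleton (no SMILES)."""
    trace = syn.simulate_growth(syn.GeneratorConfig(n_reactions=4200, seed=13))
    return syn.skeleton_molecule_graph(trace)


@pytest.fixture(scope="session")
def skeleton_2k():
    trace = syn.simulate_growth(syn.GeneratorConfig(n_reactions=1700, seed=17))
    return syn.skeleton_molecule_graph(trace)


@pytest.fixture(scope="session")
def trend_bundle():
    """Designed corpus with hub < core < periphery < island weight gradient."""
    from rxnnet import topology
    from rxnnet.components import decompose
    from rxnnet.descriptors import descriptor_table

    lines = syn.generate_trend_dataset(seed=0)
    result = run_etl(lines)
    net = build_bipartite(result.accepted)
    molgraph = project_molecule_graph(net)
    labels = decompose(net)
    hubs = topology.find_hubs_total(molgraph)
    table = descriptor_table(result.molecules)
    return {
        "lines": lines,
        "etl": result,
        "net": net,
        "molgraph": molgraph,
        "labels": labels,
        "hubs": hubs,
        "table": table,
    }
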