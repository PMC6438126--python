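import numpy as np
import pytest

from ribonet import (
    Category,
    SiteDefinition,
    bridge_report,
    centrality_table,
    component_stats,
    default_bridges,
    default_sites,
    extract_hubs,
    hub_pathways,
    site_report,
)
from ribonet.analysis import hub_pymol_selection, resolve_selector
from ribonet.centrality import CentralityTable
from ribonet.structure_io import ComponentAnnotation, ComponentEntry, ResidueClass

from conftest import path_lengths, toy_network


def scored_table(scores, classes=None, categories=None) -> CentralityTable:
    """A centrality table with prescribed betweenness scores."""
    import pandas as pd

    n = len(scores)
    classes = classes or [ResidueClass.AMINO_ACID.value] * n
    categories = categories or [""] * n
    frame = pd.DataFrame(
        {
            "chain": ["A"] * n,
            "resnum": np.arange(1, n + 1),
            "icode": [""] * n,
            "resname": ["ALA"] * n,
            "class": classes,
            "component": categories,
            "degree": np.ones(n, dtype=int),
            "closeness": np.ones(n),
            "betweenness": np.asarray(scores, dtype=float),
            "betweenness_quantile_rank": np.zeros(n),
        }
    )
    return CentralityTable(frame=frame, n_nodes=n, connected=True, tie_tol=1e-9)


def test_component_stats_two_groups():
    """Known scores {1,3} and {2,2}: equal means, sds sqrt(1) and 0."""
    import pandas as pd

    table = scored_table([0, 0, 0, 0])
    table.frame["degree"] = [1, 3, 2, 2]
    table.frame["closeness"] = [1.0, 3.0, 2.0, 2.0]
    table.frame["component"] = [
        Category.R_PROTEIN.value, Category.R_PROTEIN.value,
        Category.RRNA_16S.value, Category.RRNA_16S.value,
    ]
    stats = component_stats(table)
    aa = stats.set_index("group").loc["amino_acid"]
    rr = stats.set_index("group").loc["rRNA"]
    assert aa["degree_mean"] == pytest.approx(2.0)
    assert rr["degree_mean"] == pytest.approx(2.0)
    assert aa["degree_sd"] == pytest.approx(1.0)
    assert rr["degree_sd"] == pytest.approx(0.0)


def test_component_stats_weighted_mean_identity(two_domain21):
    """Group means recombine exactly to the grand mean (groups partition)."""
    structure, truth, network = two_domain21
    ann = ComponentAnnotation(entries={
        "A": ComponentEntry(Category.R_PROTEIN, "S12"),
        "B": ComponentEntry(Category.RRNA_16S, "16S"),
    })
    from ribonet import build_network

    net = build_network(structure, annotation=ann)
    table = centrality_table(net)
    stats = component_stats(table, ann)
    grand = table.degree.mean()
    weighted = (stats["degree_mean"] * stats["n_residues"]).sum() / stats["n_residues"].sum()
    assert weighted == pytest.approx(grand, rel=1e-12)
    assert stats["n_residues"].sum() == net.n_nodes


def test_component_stats_empty_group_warns():
    """An annotated category with no resolved nodes is omitted with a warning."""
    table = scored_table([1.0, 2.0], categories=[Category.TRNA.value] * 2)
    ann = ComponentAnnotation(entries={
        "A": ComponentEntry(Category.TRNA, "P-tRNA"),
        "Z": ComponentEntry(Category.MRNA, "mRNA"),  # no nodes on chain Z
    })
    with pytest.warns(UserWarning, match="'mRNA' has no members"):
        stats = component_stats(table, ann)
    assert list(stats["group"]) == ["tRNA"]


def test_extract_hubs_linear_interpolation():
    """Scores 1..100 at q=0.95: threshold 95.05, members 96..100."""
    table = scored_table(np.arange(1, 101))
    hubs = extract_hubs(table, 0.95)
    assert hubs.threshold == pytest.approx(95.05)
    assert list(table.frame["resnum"].iloc[hubs.members]) == [96, 97, 98, 99, 100]
    assert hubs.size == 5


def test_extract_hubs_degenerate_distribution():
    table = scored_table(np.full(10, 0.25))
    with pytest.warns(UserWarning, match="degenerate"):
        hubs = extract_hubs(table, 0.95)
    assert hubs.size == 10  # everyone ties at the threshold


def test_extract_hubs_member_count_near_quantile():
    rng = np.random.default_rng(0)
    scores = rng.exponential(size=400)
    table = scored_table(scores)
    hubs = extract_hubs(table, 0.95)
    assert hubs.size == pytest.approx(0.05 * 400, abs=1)
    assert np.all(table.betweenness[hubs.members] >= hubs.threshold)


def test_extract_hubs_composition():
    classes = [ResidueClass.NUCLEOTIDE.value] * 90 + [ResidueClass.AMINO_ACID.value] * 10
    scores = np.concatenate([np.linspace(1, 2, 90), np.full(10, 0.1)])
    table = scored_table(scores, classes=classes)
    hubs = extract_hubs(table, 0.9)
    assert hubs.composition["nucleotide"] == pytest.approx(1.0)
    assert hubs.composition["amino_acid"] == 0.0


def test_hub_pathways_on_path_graph():
    """P10 with hubs {3,4,5} and {8} (1-based 4,5,6 and 9): two components."""
    net = toy_network(path_lengths(10))
    table = centrality_table(net)
    hubs = extract_hubs(table, 0.9)
    hubs.members = np.array([3, 4, 5, 8])
    comps = hub_pathways(net, hubs)
    sets = sorted([sorted(c.nodes.tolist()) for c in comps], key=len, reverse=True)
    assert sets == [[3, 4, 5], [8]]
    # partition property
    union = sorted(int(i) for c in comps for i in c.nodes)
    assert union == [3, 4, 5, 8]


def test_hub_pathways_nonadjacent_singletons():
    net = toy_network(path_lengths(6))
    table = centrality_table(net)
    hubs = extract_hubs(table, 0.9)
    hubs.members = np.array([0, 5])
    comps = hub_pathways(net, hubs)
    assert [c.size for c in comps] == [1, 1]
    hubs.members = np.array([], dtype=int)
    assert hub_pathways(net, hubs) == []


def test_two_domain_bridge_site_and_pathway(two_domain21):
    structure, truth, network = two_domain21
    table = centrality_table(network)
    hubs = extract_hubs(table, 0.9)
    bridge_node = network.nodes[truth.bridge_index]
    assert truth.bridge_index in hubs.members

    site = SiteDefinition(
        name="bridge",
        members=(f"{bridge_node.chain_id}:{bridge_node.seq_number}",),
    )
    rep = site_report(table, [site], network, hubs=hubs)
    assert len(rep) == 1
    assert bool(rep.iloc[0]["is_hub"])
    assert rep.iloc[0]["resolved"]

    comps = hub_pathways(network, hubs)
    spanning = [c for c in comps if {"A", "B"} <= set(c.chains)]
    assert spanning, "a hub pathway should cross the two domains via the bridge"


def test_articulation_point_property(two_domain21):
    """Removing the bridge disconnects the graph; its betweenness was max."""
    from scipy.sparse.csgraph import connected_components

    structure, truth, network = two_domain21
    cb = centrality_table(network).betweenness
    assert int(np.argmax(cb)) == truth.bridge_index
    keep = np.array([i for i in range(network.n_nodes) if i != truth.bridge_index])
    sub = network.adjacency[keep][:, keep]
    n_comp, _ = connected_components(sub, directed=False)
    assert n_comp == 2


def test_site_report_missing_selector_and_empty(two_domain21):
    _, _, network = two_domain21
    table = centrality_table(network)
    site = SiteDefinition(name="ghost", members=("Z:999",))
    rep = site_report(table, [site], network)
    assert len(rep) == 1 and not rep.iloc[0]["resolved"]
    assert site_report(table, [], network).empty


def test_selector_resolution_via_molecule_name(two_domain21):
    structure, truth, network = two_domain21
    ann = ComponentAnnotation(entries={
        "A": ComponentEntry(Category.R_PROTEIN, "S12"),
        "B": ComponentEntry(Category.RRNA_16S, "16S"),
    })
    direct = resolve_selector("B:1", network, ann)
    by_name = resolve_selector("16S:1", network, ann)
    assert direct == by_name and len(direct) == 1
    assert resolve_selector("23S:1", network, ann) == []


def test_bridge_report_flags(two_domain21):
    structure, truth, network = two_domain21
    table = centrality_table(network)
    hubs = extract_hubs(table, 0.9)
    bridge_node = network.nodes[truth.bridge_index]
    sat = network.nodes[int(truth.domain_a[-1])]
    bridges = [
        SiteDefinition("real", (f"{bridge_node.chain_id}:{bridge_node.seq_number}",)),
        SiteDefinition("cold", (f"{sat.chain_id}:{sat.seq_number}",)),
        SiteDefinition("ghost", ("Q:42",)),
    ]
    rep = bridge_report(network, hubs, bridges, complex_id="fixture")
    rep = rep.set_index("bridge")
    assert bool(rep.loc["real", "any_hub"])
    assert rep.loc["ghost", "n_resolved"] == 0
    assert rep.loc["ghost", "missing_selectors"] == "Q:42"
    # clique-interior residue is no hub: row retained with zero flags
    assert rep.loc["cold", "n_resolved"] == 1
    assert not bool(rep.loc["cold", "any_hub"])
    assert rep.loc["cold", "n_hub_members"] == 0


def test_default_definitions_load():
    sites = default_sites()
    names = {s.name for s in sites}
    assert names == {"DC", "PTC"}
    dc = next(s for s in sites if s.name == "DC")
    assert set(dc.members) == {"16S:530", "16S:1492", "16S:1493"}
    bridges = default_bridges()
    assert {b.name for b in bridges} == {
        "B1b", "B2a/d", "B2b", "B2c", "B3", "B5", "B7a", "B7b", "B8"
    }
    b3 = next(b for b in bridges if b.name == "B3")
    assert "16S:1483" in b3.members and "23S:1947" in b3.members


def test_pymol_selection_string(two_domain21):
    _, truth, network = two_domain21
    table = centrality_table(network)
    hubs = extract_hubs(table, 0.9)
    sel = hub_pymol_selection(network, hubs)
    assert sel.startswith("select hubs,")
    bridge_node = network.nodes[truth.bridge_index]
    assert f"chain {bridge_node.chain_id}" in sel
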