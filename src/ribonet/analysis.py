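"""Reporting layers over the centrality tables.

Covers grouped component statistics (amino acid / rRNA / tRNA / mRNA /
factor), per-site centrality reports for named functional sites such as
the decoding center (DC) and peptidyl transferase center (PTC),
top-quantile hub extraction, hub-pathway detection (connected runs of hub
residues in the contact topology) and intersubunit-bridge hub tables.

Site and bridge definitions are plain config: a selector is
``"<chain-or-molecule>:<resnum>[<icode>]"``, where the prefix is matched
first against chain IDs and then against annotation molecule names
(e.g. ``16S:530`` finds residue 530 on whichever chain is annotated as
the 16S rRNA).  Packaged defaults for the Thermus thermophilus 70S
(author numbering) live in ``ribonet/data/``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from .centrality import CentralityTable
from .network import ResidueNetwork
from .structure_io import Category, ComponentAnnotation, ResidueClass

__all__ = [
    "SiteDefinition",
    "HubSet",
    "PathwayComponent",
    "load_site_definitions",
    "default_sites",
    "default_bridges",
    "component_stats",
    "site_report",
    "extract_hubs",
    "hub_pathways",
    "bridge_report",
    "hub_pymol_selection",
]

#: Table-1 style grouping of annotation categories
_GROUP_OF = {
    Category.R_PROTEIN: "amino_acid",
    Category.RRNA_16S: "rRNA",
    Category.RRNA_23S: "rRNA",
    Category.RRNA_5S: "rRNA",
    Category.TRNA: "tRNA",
    Category.MRNA: "mRNA",
    Category.FACTOR: "factor",
}

_SELECTOR_RE = re.compile(r"^(?P<mol>[^:]+):(?P<num>-?\d+)(?P<icode>[A-Za-z]?)$")


@dataclass(frozen=True)
class SiteDefinition:
    """A named functional site: a set of residue selectors."""

    name: str
    members: tuple[str, ...]

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"site {self.name!r} has no members")


@dataclass
class HubSet:
    """Nodes in the top betweenness quantile."""

    quantile: float
    threshold: float
    members: np.ndarray  # node indices, sorted
    composition: dict[str, float] = field(default_factory=dict)

    def __contains__(self, idx: int) -> bool:
        return bool(np.isin(idx, self.members))

    @property
    def size(self) -> int:
        return int(self.members.size)


@dataclass
class PathwayComponent:
    """A connected set of hub residues in the full contact topology."""

    nodes: np.ndarray
    chains: tuple[str, ...]
    components: tuple[str, ...]
    sites_touched: tuple[str, ...] = ()

    @property
    def size(self) -> int:
        return int(self.nodes.size)


# ---------------------------------------------------------------------------
# selectors & config


def _parse_selector(sel: str) -> tuple[str, int, str]:
    m = _SELECTOR_RE.match(sel.strip())
    if not m:
        raise ValueError(f"bad residue selector {sel!r}; expected 'chain:resnum'")
    return m.group("mol"), int(m.group("num")), m.group("icode")


def resolve_selector(
    sel: str,
    network: ResidueNetwork,
    annotation: ComponentAnnotation | None = None,
) -> list[int]:
    """Node indices matching a selector; empty when unresolvable."""
    mol, num, icode = _parse_selector(sel)
    chains = {mol}
    if annotation is not None:
        chains.update(annotation.chains_of_molecule(mol))
    hits = [
        i
        for i, nd in enumerate(network.nodes)
        if nd.chain_id in chains and nd.seq_number == num and nd.insertion_code == icode
    ]
    return hits


def load_site_definitions(path: str | Path) -> list[SiteDefinition]:
    """Load site/bridge definitions from YAML (``sites:`` list of
    ``{name, members}``)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    block = raw.get("sites", raw) if isinstance(raw, dict) else raw
    out = []
    for item in block:
        out.append(SiteDefinition(name=str(item["name"]), members=tuple(item["members"])))
    return out


def _packaged(name: str) -> list[SiteDefinition]:
    ref = resources.files("ribonet").joinpath("data", name)
    with resources.as_file(ref) as p:
        return load_site_definitions(p)


def default_sites() -> list[SiteDefinition]:
    """Packaged DC / PTC definitions (T. thermophilus author numbering)."""
    return _packaged("sites.yaml")


def default_bridges() -> list[SiteDefinition]:
    """Packaged intersubunit-bridge definitions (B1b … B8)."""
    return _packaged("bridges.yaml")


# ---------------------------------------------------------------------------
# component statistics


def component_stats(
    table: CentralityTable,
    annotation: ComponentAnnotation | None = None,
    per_chain: bool = False,
) -> pd.DataFrame:
    """Mean ± sd of degree and closeness per structural component group.

    Groups partition the annotated nodes: r-proteins as one amino-acid
    class, all rRNA chains as one, tRNA as one, mRNA and factors separate.
    Categories with no members are omitted (with a warning).
    """
    frame = table.frame
    cats = frame["component"].to_numpy()
    groups = np.array(
        [_GROUP_OF.get(Category(c)) if c else None for c in cats], dtype=object
    )
    key = frame["chain"] if per_chain else pd.Series(groups, index=frame.index, name="group")
    rows = []
    order = ["amino_acid", "rRNA", "tRNA", "mRNA", "factor"]
    # a group is "expected" when the annotation (or the table itself) names it
    if annotation is not None:
        expected = {_GROUP_OF[e.category] for e in annotation.entries.values()}
    else:
        expected = set(groups[groups != None])  # noqa: E711
    if per_chain:
        order = list(dict.fromkeys(frame["chain"]))
        expected = set(order)
    for g in order:
        mask = (key == g).to_numpy()
        if not mask.any():
            if g in expected:
                warnings.warn(f"component group {g!r} has no members; omitted")
            continue
        sub = frame.loc[mask]
        rows.append(
            {
                "group": g,
                "n_residues": int(mask.sum()),
                "degree_mean": float(sub["degree"].mean()),
                "degree_sd": float(sub["degree"].std(ddof=0)),
                "closeness_mean": float(sub["closeness"].mean()),
                "closeness_sd": float(sub["closeness"].std(ddof=0)),
                "betweenness_mean": float(sub["betweenness"].mean()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# hubs


def extract_hubs(table: CentralityTable, quantile: float = 0.95) -> HubSet:
    """Nodes whose betweenness reaches the given quantile of the score
    distribution (linear-interpolation quantile; membership uses >=)."""
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must be in (0, 1)")
    cb = table.betweenness
    threshold = float(np.quantile(cb, quantile))
    members = np.flatnonzero(cb >= threshold)
    if np.ptp(cb) == 0:
        warnings.warn("degenerate betweenness distribution: all scores equal")
    classes = table.frame["class"].to_numpy()[members]
    n = max(members.size, 1)
    composition = {
        "nucleotide": float(np.sum(classes == ResidueClass.NUCLEOTIDE.value) / n),
        "amino_acid": float(np.sum(classes == ResidueClass.AMINO_ACID.value) / n),
    }
    return HubSet(
        quantile=quantile, threshold=threshold, members=np.sort(members),
        composition=composition,
    )


def hub_pathways(
    network: ResidueNetwork,
    hubs: HubSet,
    sites: list[SiteDefinition] | None = None,
    annotation: ComponentAnnotation | None = None,
) -> list[PathwayComponent]:
    """Connected components of the hub-induced subgraph, largest first.

    Adjacency is the full network's edge set restricted to hub nodes:
    hub residues sitting next to each other in the contact topology form
    candidate communication pathways.
    """
    members = hubs.members
    if members.size == 0:
        return []
    sub = network.adjacency[members][:, members]
    n_comp, labels = connected_components(sub, directed=False)
    site_nodes: dict[str, set[int]] = {}
    if sites:
        for site in sites:
            nodes: set[int] = set()
            for sel in site.members:
                nodes.update(resolve_selector(sel, network, annotation))
            site_nodes[site.name] = nodes
    comps: list[PathwayComponent] = []
    for c in range(n_comp):
        nodes = members[labels == c]
        chains = tuple(dict.fromkeys(network.nodes[i].chain_id for i in nodes))
        categories = tuple(
            dict.fromkeys(
                network.nodes[i].category.value
                for i in nodes
                if network.nodes[i].category is not None
            )
        )
        touched = tuple(
            name for name, sn in site_nodes.items() if sn.intersection(nodes.tolist())
        )
        comps.append(
            PathwayComponent(
                nodes=np.sort(nodes), chains=chains, components=categories,
                sites_touched=touched,
            )
        )
    comps.sort(key=lambda p: (-p.size, p.nodes[0] if p.size else 0))
    return comps


# ---------------------------------------------------------------------------
# site & bridge reports


def site_report(
    table: CentralityTable,
    sites: list[SiteDefinition],
    network: ResidueNetwork,
    hubs: HubSet | None = None,
    annotation: ComponentAnnotation | None = None,
) -> pd.DataFrame:
    """Per-residue centralities for named sites, with hub membership flags.

    Unresolvable selectors are reported as rows with ``resolved=False``.
    """
    rows = []
    hub_members = set(hubs.members.tolist()) if hubs is not None else set()
    for site in sites:
        for sel in site.members:
            hits = resolve_selector(sel, network, annotation)
            if not hits:
                rows.append(
                    {"site": site.name, "selector": sel, "resolved": False,
                     "residue": "", "degree": np.nan, "closeness": np.nan,
                     "betweenness": np.nan, "is_hub": False}
                )
                continue
            for idx in hits:
                rec = table.frame.iloc[idx]
                rows.append(
                    {
                        "site": site.name,
                        "selector": sel,
                        "resolved": True,
                        "residue": network.nodes[idx].label,
                        "degree": int(rec["degree"]),
                        "closeness": float(rec["closeness"]),
                        "betweenness": float(rec["betweenness"]),
                        "is_hub": idx in hub_members,
                    }
                )
    columns = ["site", "selector", "resolved", "residue", "degree",
               "closeness", "betweenness", "is_hub"]
    return pd.DataFrame(rows, columns=columns)


def bridge_report(
    network: ResidueNetwork,
    hubs: HubSet,
    bridges: list[SiteDefinition],
    table: CentralityTable | None = None,
    annotation: ComponentAnnotation | None = None,
    complex_id: str = "",
) -> pd.DataFrame:
    """Which bridge residues are betweenness hubs, one row per bridge.

    A bridge with no hub members keeps its row with zero flags, so state
    comparisons across complexes stay aligned.
    """
    rows = []
    hub_members = set(hubs.members.tolist())
    for bridge in bridges:
        resolved, missing, hub_labels = [], [], []
        for sel in bridge.members:
            hits = resolve_selector(sel, network, annotation)
            if not hits:
                missing.append(sel)
                continue
            resolved.extend(hits)
            for idx in hits:
                if idx in hub_members:
                    hub_labels.append(network.nodes[idx].label)
        rows.append(
            {
                "bridge": bridge.name,
                "complex": complex_id,
                "n_members": len(bridge.members),
                "n_resolved": len(resolved),
                "n_hub_members": len(hub_labels),
                "hub_members": ";".join(hub_labels),
                "missing_selectors": ";".join(missing),
                "any_hub": bool(hub_labels),
            }
        )
    return pd.DataFrame(rows)


def hub_pymol_selection(network: ResidueNetwork, hubs: HubSet, name: str = "hubs") -> str:
    """PyMOL selection string for the hub set."""
    parts = []
    by_chain: dict[str, list[str]] = {}
    for idx in hubs.members:
        nd = network.nodes[idx]
        by_chain.setdefault(nd.chain_id, []).append(f"{nd.seq_number}{nd.insertion_code}")
    for chain, nums in by_chain.items():
        parts.append(f"(chain {chain} and resi {'+'.join(nums)})")
    body = " or ".join(parts) if parts else "none"
    return f"select {name}, {body}"
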