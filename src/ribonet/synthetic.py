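"""Desk-scale structure fixtures with analytically known contact topology.

Each generator returns a :class:`~ribonet.structure_io.Structure` built from
pseudo-atoms together with its declared ground truth (edge list, expected
hub, ...), and self-verifies by brute force that the intended adjacency is
realised at the target cutoff before handing the fixture over.  Geometry
margins: intended contacts are placed at 0.8×cutoff and intended
non-contacts at ≥1.3×cutoff, so the topology is robust to floating-point
noise.  Amino-acid fixtures use CA pseudo-atoms, nucleotide fixtures P plus
filler atoms, so representative-atom selection is exercised for both
residue classes.  None of this is physically realistic conformation — only
the contact graph is meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import sparse

from .network import count_contacts_bruteforce
from .structure_io import AtomRecord, Residue, ResidueClass, Structure

__all__ = [
    "FixtureSpec",
    "GeneratorError",
    "make_polymer",
    "make_star",
    "make_two_domain",
    "make_random_geometric",
    "write_ground_truth_tsv",
]

CONTACT_MARGIN = 0.8   # intended contacts at this fraction of the cutoff
SEPARATION_MARGIN = 1.3  # intended non-contacts at least this multiple


class GeneratorError(RuntimeError):
    """Raised when a fixture's geometry cannot realise its declared topology."""


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters shared by the fixture generators."""

    n_residues: int = 10
    atoms_per_residue: int = 3
    cutoff_target: float = 4.5
    seed: int = 0
    chain_labels: tuple[str, ...] = ("A", "B")
    polymer_type: str = "protein"  # or "rna"

    def __post_init__(self):
        if self.cutoff_target <= 0:
            raise GeneratorError("cutoff_target must be positive")
        if self.atoms_per_residue < 1:
            raise GeneratorError("atoms_per_residue must be >= 1")
        if self.polymer_type not in ("protein", "rna"):
            raise GeneratorError("polymer_type must be 'protein' or 'rna'")


def _make_residue(
    spec: FixtureSpec, chain: str, number: int, center: np.ndarray,
    extra_atoms: list[np.ndarray] | None = None,
    offset_scale: float = 0.5,
) -> Residue:
    """A pseudo-residue: representative atom at ``center`` plus filler atoms
    ``offset_scale`` Å away, so residues are genuine atom clusters rather
    than points."""
    if spec.polymer_type == "protein":
        res_name, rep_name, rep_el = "ALA", "CA", "C"
        filler = [("CB", "C"), ("CG", "C"), ("CD", "C"), ("CE", "C")]
        res_class = ResidueClass.AMINO_ACID
    else:
        res_name, rep_name, rep_el = "A", "P", "P"
        filler = [("O5'", "O"), ("C5'", "C"), ("C4'", "C"), ("C3'", "C")]
        res_class = ResidueClass.NUCLEOTIDE
    atoms = [AtomRecord(name=rep_name, element=rep_el, coord=center)]
    s = offset_scale
    offsets = [
        np.array([0.0, 0.0, s]), np.array([0.0, 0.0, -s]),
        np.array([0.0, s, 0.0]), np.array([0.0, -s, 0.0]),
    ]
    for k in range(spec.atoms_per_residue - 1):
        name, el = filler[k % len(filler)]
        if k >= len(filler):
            name = f"{name}{k}"
        atoms.append(AtomRecord(name=name, element=el, coord=center + offsets[k % 4]))
    for idx, coord in enumerate(extra_atoms or []):
        atoms.append(AtomRecord(name=f"CX{idx + 1}", element="C", coord=coord))
    return Residue(
        chain_id=chain, seq_number=number, insertion_code="", res_name=res_name,
        res_class=res_class, atoms=atoms, rep_coord=center,
    )


def _edge_set(structure: Structure, cutoff: float) -> set[tuple[int, int]]:
    mat = count_contacts_bruteforce(structure, cutoff)
    coo = sparse.triu(mat, k=1).tocoo()
    return {(int(i), int(j)) for i, j in zip(coo.row, coo.col)}


def _verify(structure: Structure, cutoff: float, expected: set[tuple[int, int]],
            dont_care: set[tuple[int, int]] | None = None) -> None:
    got = _edge_set(structure, cutoff)
    dont_care = dont_care or set()
    unexpected = got - expected - dont_care
    missing = expected - got
    if unexpected or missing:
        raise GeneratorError(
            f"fixture self-check failed: unexpected={sorted(unexpected)[:5]} "
            f"missing={sorted(missing)[:5]}"
        )


# ---------------------------------------------------------------------------


def make_polymer(spec: FixtureSpec) -> tuple[Structure, list[tuple[int, int]]]:
    """Linear polymer whose only contacts are sequential: a path graph P_n.

    Residue centers sit 0.8×cutoff apart along x, so |i−j| = 1 pairs touch
    while |i−j| ≥ 2 pairs are ≥ 1.6×cutoff away.
    """
    if spec.n_residues < 2:
        raise GeneratorError("polymer needs n_residues >= 2")
    spacing = CONTACT_MARGIN * spec.cutoff_target
    if 2 * spacing < SEPARATION_MARGIN * spec.cutoff_target:
        raise GeneratorError("spacing infeasible for the separation margin")
    chain = spec.chain_labels[0]
    residues = [
        _make_residue(spec, chain, i + 1, np.array([i * spacing, 0.0, 0.0]))
        for i in range(spec.n_residues)
    ]
    structure = Structure(residues=residues, source_ids=["polymer"],
                          chain_map={chain: chain})
    structure.validate()
    edges = [(i, i + 1) for i in range(spec.n_residues - 1)]
    _verify(structure, spec.cutoff_target, set(edges))
    return structure, edges


def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def make_star(spec: FixtureSpec) -> tuple[Structure, list[tuple[int, int]]]:
    """Hub residue contacting n−1 satellites that touch nothing else: K_{1,n−1}.

    The hub carries one arm pseudo-atom per satellite so hub–satellite
    contacts sit at 0.8×cutoff while satellites stay mutually separated for
    any satellite count; the radius grows until all margins verify.
    """
    if spec.n_residues < 3:
        raise GeneratorError("star needs n_residues >= 3 (hub + 2 satellites)")
    n_sat = spec.n_residues - 1
    dirs = _fibonacci_sphere(n_sat)
    reach = CONTACT_MARGIN * spec.cutoff_target
    min_sep = SEPARATION_MARGIN * spec.cutoff_target
    chords = np.linalg.norm(dirs[:, None, :] - dirs[None, :, :], axis=-1)
    min_chord = chords[np.triu_indices(n_sat, k=1)].min() if n_sat > 1 else 2.0
    radius = max(min_sep / min_chord, reach + 1.0) + 1.0  # +1 Å filler slack
    chain = spec.chain_labels[0]
    arm_tips = [d * (radius - reach) for d in dirs]
    hub = _make_residue(spec, chain, 1, np.zeros(3), extra_atoms=arm_tips)
    residues = [hub] + [
        _make_residue(spec, chain, i + 2, dirs[i] * radius) for i in range(n_sat)
    ]
    structure = Structure(residues=residues, source_ids=["star"],
                          chain_map={chain: chain})
    structure.validate()
    edges = [(0, i + 1) for i in range(n_sat)]
    _verify(structure, spec.cutoff_target, set(edges))
    return structure, edges


@dataclass
class TwoDomainTruth:
    """Declared ground truth of the bridged two-domain fixture."""

    bridge_index: int
    domain_a: np.ndarray
    domain_b: np.ndarray
    anchor_a: int
    anchor_b: int
    inter_domain_edges: list[tuple[int, int]] = field(default_factory=list)


def _domain_grid(m: int, spacing: float) -> np.ndarray:
    """m points on a compact cubic grid, ordered by distance to the grid
    origin corner so index 0 is the anchor closest to the bridge."""
    side = int(np.ceil(m ** (1.0 / 3.0)))
    pts = np.array(
        [[x, y, z] for x in range(side) for y in range(side) for z in range(side)],
        dtype=float,
    )
    order = np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0], np.linalg.norm(pts, axis=1)))
    return pts[order[:m]] * spacing


def _clique_cluster(m: int, anchor: np.ndarray, direction: np.ndarray,
                    reach: float) -> np.ndarray:
    """m residue centers forming a contact clique: the anchor plus m−1
    points in a tight ball one ``reach`` behind it along ``direction``.

    All mutual center distances stay ≤ reach (every pair in contact) while
    the non-anchor points sit far enough from the opposite side of the
    anchor that only the anchor can reach anything in front of it.
    """
    pts = [anchor]
    if m > 1:
        ball_center = anchor + direction * (0.75 * reach)
        # deterministic lattice inside a 0.45 Å ball
        lattice = []
        for x in (-0.3, 0.0, 0.3):
            for y in (-0.3, 0.0, 0.3):
                for z in (-0.3, 0.0, 0.3):
                    lattice.append(np.array([x, y, z]))
        lattice.sort(key=lambda p: (np.linalg.norm(p), p[0], p[1], p[2]))
        if m - 1 > len(lattice):
            raise GeneratorError(f"clique cluster supports at most {len(lattice) + 1} residues")
        for k in range(m - 1):
            pts.append(ball_center + lattice[k])
    return np.array(pts)


def make_two_domain(spec: FixtureSpec) -> tuple[Structure, TwoDomainTruth]:
    """Two contact cliques joined only through one bridging residue.

    Each domain is an anchor residue plus a tight cluster behind it, so all
    domain-internal pairs are in direct contact (a clique) and every
    inter-domain shortest path runs anchor → bridge → anchor.  The bridge is
    then the unique articulation point between the domains and the strict
    global betweenness maximum.  Chain A (protein) holds domain A plus the
    bridge; chain B (RNA pseudo-nucleotides) holds domain B, so component
    annotation is exercised too.
    """
    if spec.n_residues < 7:
        raise GeneratorError("two_domain needs n_residues >= 7")
    m = (spec.n_residues - 1) // 2
    m_b = spec.n_residues - 1 - m
    reach = CONTACT_MARGIN * spec.cutoff_target
    ex = np.array([1.0, 0.0, 0.0])
    pos_a = _clique_cluster(m, -reach * ex, -ex, reach)
    pos_b = _clique_cluster(m_b, reach * ex, ex, reach)

    chain_a, chain_b = spec.chain_labels[0], spec.chain_labels[1]
    spec_rna = FixtureSpec(
        n_residues=spec.n_residues, atoms_per_residue=spec.atoms_per_residue,
        cutoff_target=spec.cutoff_target, seed=spec.seed,
        chain_labels=spec.chain_labels, polymer_type="rna",
    )
    residues = [
        _make_residue(spec, chain_a, i + 1, pos_a[i], offset_scale=0.15)
        for i in range(m)
    ]
    bridge_index = m
    residues.append(
        _make_residue(spec, chain_a, m + 1, np.zeros(3), offset_scale=0.15)
    )
    residues += [
        _make_residue(spec_rna, chain_b, i + 1, pos_b[i], offset_scale=0.15)
        for i in range(m_b)
    ]
    structure = Structure(
        residues=residues, source_ids=["two_domain"],
        chain_map={chain_a: chain_a, chain_b: chain_b},
    )
    structure.validate()

    domain_a = np.arange(m)
    domain_b = np.arange(m + 1, spec.n_residues)
    expected = {(int(i), int(j)) for i in domain_a for j in domain_a if i < j}
    expected |= {(int(i), int(j)) for i in domain_b for j in domain_b if i < j}
    expected |= {(0, bridge_index), (bridge_index, int(domain_b[0]))}
    _verify(structure, spec.cutoff_target, expected)

    truth = TwoDomainTruth(
        bridge_index=bridge_index, domain_a=domain_a, domain_b=domain_b,
        anchor_a=0, anchor_b=int(domain_b[0]),
        inter_domain_edges=[(0, bridge_index), (bridge_index, int(domain_b[0]))],
    )
    return structure, truth


def make_random_geometric(spec: FixtureSpec, target_mean_degree: float = 8.5,
                          ) -> tuple[Structure, dict]:
    """Residues at uniform-random positions in a box sized for a target mean
    degree; deterministic given the seed.  Used for oracle-equivalence tests.

    The declared ground truth records the target and a generous relative
    tolerance (finite-size and box-edge effects make the realised mean
    fluctuate).
    """
    if spec.n_residues < 2:
        raise GeneratorError("random_geometric needs n_residues >= 2")
    rng = np.random.default_rng(spec.seed)
    c = spec.cutoff_target
    n = spec.n_residues

    # P(two residues in an L-cube are in contact) estimated once by a
    # fixed-seed sample, so the box size L solving (n−1)·P(L) = target is a
    # deterministic function of the target alone.  The estimate uses the
    # actual atom clusters: a pair is in contact when any combination of the
    # residues' (deterministic) atom offsets comes within the cutoff.
    offset_scale = 0.15
    base = [np.zeros(3)] + [
        np.array(o) * offset_scale
        for o in ([0, 0, 1], [0, 0, -1], [0, 1, 0], [0, -1, 0])
    ][: spec.atoms_per_residue - 1]
    deltas = np.unique(
        np.array([oa - ob for oa in base for ob in base]).round(6), axis=0
    )
    cal = np.random.default_rng(20180814)
    gaps = cal.uniform(size=(200_000, 3)) - cal.uniform(size=(200_000, 3))

    def mean_deg(L: float) -> float:
        shifted = gaps[:, None, :] * L + deltas[None, :, :]
        within = np.any(np.einsum("ikj,ikj->ik", shifted, shifted) <= c * c, axis=1)
        return (n - 1) * within.mean()

    from scipy.optimize import brentq

    L = brentq(lambda x: mean_deg(x) - target_mean_degree, c * 1.01, c * 100, xtol=1e-6)
    centers = rng.uniform(0.0, L, size=(n, 3))
    chain = spec.chain_labels[0]
    kind = spec.polymer_type
    residues = []
    for i in range(n):
        # tight clusters: fillers 0.15 Å off-center so the realised mean
        # degree stays close to the point-residue calibration
        residues.append(_make_residue(spec, chain, i + 1, centers[i], offset_scale=0.15))
    structure = Structure(residues=residues, source_ids=["rgg"],
                          chain_map={chain: chain})
    structure.validate()
    truth = {
        "target_mean_degree": target_mean_degree,
        "rel_tolerance": 0.2,
        "box_size": L,
        "kind": kind,
    }
    return structure, truth


def write_ground_truth_tsv(edges: list[tuple[int, int]], structure: Structure,
                           path: str | Path) -> None:
    """Declared edge list as TSV beside a fixture's PDB file."""
    with open(path, "w") as fh:
        fh.write("node_i\tnode_j\n")
        for i, j in edges:
            fh.write(f"{structure.residues[i].label}\t{structure.residues[j].label}\n")
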