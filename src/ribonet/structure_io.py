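"""Reading, merging and annotating macromolecular structures.

Structures are reduced to the information the residue network needs: for
every polymer residue, its heavy atoms and a representative coordinate
(the Cα for amino acids, the phosphorus for nucleotides).  Waters, ions
and non-polymer ligands are dropped; modified polymer residues (e.g.
methylated nucleotides deposited as HETATM) are kept.  Parsing is done
with gemmi, which handles both PDB and mmCIF.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import yaml

__all__ = [
    "AtomRecord",
    "ResidueClass",
    "Residue",
    "Structure",
    "Category",
    "ComponentEntry",
    "ComponentAnnotation",
    "StructureError",
    "AnnotationError",
    "parse_structure",
    "merge_structures",
    "load_annotation",
    "write_pdb",
]


class StructureError(ValueError):
    """Raised for unparseable or empty structure input."""


class AnnotationError(ValueError):
    """Raised when a chain annotation cannot be applied in strict mode."""


class ResidueClass(Enum):
    AMINO_ACID = "amino_acid"
    NUCLEOTIDE = "nucleotide"
    OTHER = "other"


class Category(Enum):
    """Structural component a chain belongs to."""

    R_PROTEIN = "r_protein"
    RRNA_16S = "rrna_16s"
    RRNA_23S = "rrna_23s"
    RRNA_5S = "rrna_5s"
    TRNA = "trna"
    MRNA = "mrna"
    FACTOR = "factor"

    @property
    def is_rrna(self) -> bool:
        return self in (Category.RRNA_16S, Category.RRNA_23S, Category.RRNA_5S)


@dataclass(frozen=True)
class AtomRecord:
    name: str
    element: str
    coord: np.ndarray  # (3,) Å
    occupancy: float = 1.0
    altloc: str = ""
    is_hetero: bool = False

    def __post_init__(self):
        coord = np.asarray(self.coord, dtype=float)
        if coord.shape != (3,) or not np.all(np.isfinite(coord)):
            raise ValueError(f"atom {self.name!r}: coord must be 3 finite components")
        object.__setattr__(self, "coord", coord)
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name!r}: occupancy {self.occupancy} not in [0, 1]")


@dataclass
class Residue:
    """One network node: a polymer residue with its heavy atoms.

    ``rep_coord`` is the node position — the Cα for amino acids and the P
    for nucleotides.  When the representative atom is absent from the model
    (common for 5'-terminal nucleotides, which have no phosphate) the
    centroid of the residue's atoms is used and ``rep_fallback`` is set.
    """

    chain_id: str
    seq_number: int
    insertion_code: str
    res_name: str
    res_class: ResidueClass
    atoms: list[AtomRecord]
    rep_coord: np.ndarray
    rep_fallback: bool = False

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_number, self.insertion_code)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def label(self) -> str:
        icode = self.insertion_code.strip()
        return f"{self.chain_id}:{self.res_name}{self.seq_number}{icode}"


@dataclass
class Structure:
    residues: list[Residue]
    source_ids: list[str] = field(default_factory=list)
    chain_map: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.residues:
            seen.setdefault(r.chain_id, None)
        return list(seen)

    def validate(self) -> None:
        keys = [r.key for r in self.residues]
        if len(set(keys)) != len(keys):
            raise StructureError("duplicate residue identity keys in structure")
        for r in self.residues:
            if not r.atoms:
                raise StructureError(f"residue {r.label} has no atoms")


@dataclass(frozen=True)
class ComponentEntry:
    category: Category
    molecule_name: str


@dataclass
class ComponentAnnotation:
    """Chain → structural-component mapping used for grouped statistics."""

    entries: dict[str, ComponentEntry] = field(default_factory=dict)
    excluded: set[str] = field(default_factory=set)

    def category_of(self, chain_id: str) -> Category | None:
        entry = self.entries.get(chain_id)
        return entry.category if entry is not None else None

    def molecule_of(self, chain_id: str) -> str | None:
        entry = self.entries.get(chain_id)
        return entry.molecule_name if entry is not None else None

    def chains_of_molecule(self, molecule_name: str) -> list[str]:
        """Chains whose molecule name matches (case-insensitive)."""
        want = molecule_name.strip().lower()
        return [c for c, e in self.entries.items() if e.molecule_name.strip().lower() == want]


# ---------------------------------------------------------------------------
# parsing


def _select_altlocs(gres: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one atom per atom name: highest occupancy, ties by altloc letter."""
    by_name: dict[str, gemmi.Atom] = {}
    for atom in gres:
        if atom.is_hydrogen():
            continue
        prev = by_name.get(atom.name)
        if prev is None:
            by_name[atom.name] = atom
        elif atom.occ > prev.occ or (atom.occ == prev.occ and atom.altloc < prev.altloc):
            by_name[atom.name] = atom
    return list(by_name.values())


def _classify(res_name: str, atom_names: Mapping[str, str]) -> ResidueClass:
    """Residue class from chemical identity, falling back to atom content.

    ``atom_names`` maps atom name → element symbol.
    """
    info = gemmi.find_tabulated_residue(res_name)
    if info is not None:
        if info.is_amino_acid():
            return ResidueClass.AMINO_ACID
        if info.is_nucleic_acid():
            return ResidueClass.NUCLEOTIDE
    if atom_names.get("P") == "P":
        return ResidueClass.NUCLEOTIDE
    if atom_names.get("CA") == "C":
        return ResidueClass.AMINO_ACID
    return ResidueClass.OTHER


_REP_ATOM = {ResidueClass.AMINO_ACID: "CA", ResidueClass.NUCLEOTIDE: "P"}


def _convert_residue(
    chain_id: str, gres: gemmi.Residue, on_missing_rep: str
) -> Residue | None:
    atoms_g = _select_altlocs(gres)
    if not atoms_g:
        return None
    atom_el = {a.name: a.element.name for a in atoms_g}
    res_class = _classify(gres.name, atom_el)
    if res_class is ResidueClass.OTHER:
        return None

    atoms = [
        AtomRecord(
            name=a.name,
            element=a.element.name,
            coord=np.array([a.pos.x, a.pos.y, a.pos.z]),
            occupancy=min(max(a.occ, 0.0), 1.0),
            altloc=a.altloc if a.altloc not in ("\x00",) else "",
            is_hetero=gres.het_flag == "H",
        )
        for a in atoms_g
    ]
    rep_name = _REP_ATOM[res_class]
    rep = next((a for a in atoms if a.name == rep_name), None)
    fallback = rep is None
    if fallback:
        if on_missing_rep == "drop":
            return None
        rep_coord = np.mean([a.coord for a in atoms], axis=0)
    else:
        rep_coord = rep.coord
    return Residue(
        chain_id=chain_id,
        seq_number=gres.seqid.num,
        insertion_code=(gres.seqid.icode or " ").strip() or "",
        res_name=gres.name,
        res_class=res_class,
        atoms=atoms,
        rep_coord=rep_coord,
        rep_fallback=fallback,
    )


def parse_structure(
    path: str | Path,
    format: str = "auto",
    on_missing_rep: str = "centroid",
) -> Structure:
    """Parse a PDB or mmCIF file into a residue-level :class:`Structure`.

    Only model 1 is read.  Polymer residues are kept (waters, ions and
    non-polymer ligands are dropped); residue numbering is taken verbatim
    from the file.  ``on_missing_rep`` controls residues lacking their
    representative atom: ``"centroid"`` keeps them at their atom centroid,
    ``"drop"`` removes them.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"input file not found: {path}")
    if on_missing_rep not in ("centroid", "drop"):
        raise ValueError(f"unknown on_missing_rep: {on_missing_rep!r}")
    fmt = {
        "auto": gemmi.CoorFormat.Detect,
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
    }.get(format)
    if fmt is None:
        raise ValueError(f"unknown format: {format!r}")
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise StructureError(f"{path}: no models")
    model = st[0]

    residues: list[Residue] = []
    for chain in model:
        for gres in chain:
            if gres.is_water():
                continue
            etype = gres.entity_type
            if etype in (gemmi.EntityType.NonPolymer, gemmi.EntityType.Water,
                         gemmi.EntityType.Branched):
                continue
            converted = _convert_residue(chain.name, gres, on_missing_rep)
            if converted is not None:
                residues.append(converted)
    if not residues:
        raise StructureError(f"{path}: no polymer residues after selection")
    source = st.name.strip() or path.stem
    struct = Structure(
        residues=residues,
        source_ids=[source],
        chain_map={c: c for c in {r.chain_id for r in residues}},
    )
    struct.validate()
    return struct


# ---------------------------------------------------------------------------
# merging


def _fresh_chain_ids() -> Iterable[str]:
    alphabet = string.ascii_uppercase + string.ascii_lowercase + string.digits
    yield from alphabet
    for a in alphabet:
        for b in alphabet:
            yield a + b


def merge_structures(parts: Sequence[Structure]) -> Structure:
    """Combine deposited entries into one complex.

    Chain-ID collisions between parts are resolved by remapping the later
    part's chain to a fresh ID; the mapping is recorded in ``chain_map``
    under ``"<source>:<original>"`` keys.
    """
    if not parts:
        raise ValueError("merge_structures needs at least one part")
    used: set[str] = set()
    fresh = (c for c in _fresh_chain_ids())
    residues: list[Residue] = []
    chain_map: dict[str, str] = {}
    source_ids: list[str] = []
    for part in parts:
        source = part.source_ids[0] if part.source_ids else "part"
        source_ids.extend(part.source_ids)
        remap: dict[str, str] = {}
        for cid in part.chain_ids:
            if cid in used:
                new = next(c for c in fresh if c not in used and c not in part.chain_ids)
                remap[cid] = new
            else:
                remap[cid] = cid
            used.add(remap[cid])
            chain_map[f"{source.lower()}:{cid}"] = remap[cid]
            # plain key points at the first part that used this chain ID
            chain_map.setdefault(cid, remap[cid])
        for r in part.residues:
            if remap[r.chain_id] == r.chain_id:
                residues.append(r)
            else:
                residues.append(
                    Residue(
                        chain_id=remap[r.chain_id],
                        seq_number=r.seq_number,
                        insertion_code=r.insertion_code,
                        res_name=r.res_name,
                        res_class=r.res_class,
                        atoms=r.atoms,
                        rep_coord=r.rep_coord,
                        rep_fallback=r.rep_fallback,
                    )
                )
    merged = Structure(residues=residues, source_ids=source_ids, chain_map=chain_map)
    merged.validate()
    return merged


# ---------------------------------------------------------------------------
# annotation


def load_annotation(
    path: str | Path, structure: Structure, strict: bool = False
) -> ComponentAnnotation:
    """Load a chain → component YAML mapping and check it against a structure.

    The config maps chain IDs either to ``{category, molecule}`` or to the
    string ``"exclude"``.  Keys of the form ``"<source>:<chain>"`` (e.g.
    ``"2j01:A"``) are translated through the structure's ``chain_map``, so a
    config can address chains of a merged complex by their original entry
    even after collision remapping.  Structure chains missing from the config
    raise in strict mode; otherwise they are warned about and excluded.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise AnnotationError(f"{path}: expected a mapping of chain IDs")
    chains_block = raw.get("chains", raw)

    def _resolve_chain_key(cid: str) -> str:
        if ":" in cid:
            src, _, orig = cid.partition(":")
            mapped = structure.chain_map.get(f"{src.lower()}:{orig}")
            if mapped is not None:
                return mapped
        return cid

    ann = ComponentAnnotation()
    for cid, value in chains_block.items():
        cid = _resolve_chain_key(str(cid))
        if isinstance(value, str) and value.strip().lower() in ("exclude", "excluded"):
            ann.excluded.add(cid)
            continue
        if not isinstance(value, dict) or "category" not in value:
            raise AnnotationError(f"{path}: chain {cid}: need 'category' or 'exclude'")
        cat_name = str(value["category"]).strip().upper()
        try:
            category = Category[cat_name]
        except KeyError as exc:
            valid = ", ".join(c.name for c in Category)
            raise AnnotationError(
                f"{path}: chain {cid}: unknown category {cat_name!r} (valid: {valid})"
            ) from exc
        ann.entries[cid] = ComponentEntry(
            category=category, molecule_name=str(value.get("molecule", cid))
        )

    structure_chains = set(structure.chain_ids)
    for cid in ann.entries.keys() | ann.excluded:
        if cid not in structure_chains:
            warnings.warn(f"annotation names chain {cid!r} absent from the structure")
    unassigned = structure_chains - ann.entries.keys() - ann.excluded
    if unassigned:
        if strict:
            raise AnnotationError(
                "unannotated chains in strict mode: " + ", ".join(sorted(unassigned))
            )
        warnings.warn(
            "unannotated chains excluded from component grouping: "
            + ", ".join(sorted(unassigned))
        )
        ann.excluded.update(unassigned)
    return ann


# ---------------------------------------------------------------------------
# writing


def write_pdb(
    structure: Structure,
    path: str | Path,
    bfactors: Mapping[tuple[str, int, str], float] | None = None,
) -> None:
    """Write a Structure to PDB, optionally placing per-residue scores in the
    B-factor column (clipped to the PDB field range [0, 999.99])."""
    st = gemmi.Structure()
    st.name = "+".join(structure.source_ids) or "ribonet"
    model = gemmi.Model(1)
    chains: dict[str, gemmi.Chain] = {}
    for res in structure.residues:
        chain = chains.get(res.chain_id)
        if chain is None:
            chain = gemmi.Chain(res.chain_id)
            chains[res.chain_id] = chain
        gres = gemmi.Residue()
        gres.name = res.res_name
        gres.seqid = gemmi.SeqId(res.seq_number, res.insertion_code or " ")
        gres.het_flag = "H" if res.atoms and res.atoms[0].is_hetero else "A"
        b = 0.0
        if bfactors is not None:
            b = float(np.clip(bfactors.get(res.key, 0.0), 0.0, 999.99))
        for arec in res.atoms:
            atom = gemmi.Atom()
            atom.name = arec.name
            atom.element = gemmi.Element(arec.element)
            atom.pos = gemmi.Position(*arec.coord)
            atom.occ = arec.occupancy
            atom.b_iso = b
            gres.add_atom(atom)
        chain.add_residue(gres)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))
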