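"""Hierarchical atomic-structure model with PDB/mmCIF input and output.

The in-memory model is a plain chains -> residues -> atoms hierarchy carrying
the crystal metadata (cell, space-group operators) needed for symmetry
expansion, plus per-atom slots for the van der Waals radius and partial charge
used by the surface-area and electrostatics machinery.  Parsing and writing of
the standard formats is delegated to gemmi; everything downstream operates on
this model only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .errors import (
    ConfigurationError,
    EmptyStructureError,
    FormatCapacityError,
    InputError,
    MetadataError,
    ParseError,
)

# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Atom:
    """One atom: standard atom name, element symbol, Cartesian position in A."""

    name: str
    element: str
    pos: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    altloc: str = ""
    vdw_radius: float | None = None
    charge: float = 0.0

    def __post_init__(self):
        self.pos = np.asarray(self.pos, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.pos)):
            raise InputError(f"atom {self.name}: non-finite position")
        if not 0.0 <= self.occupancy <= 1.0:
            raise InputError(f"atom {self.name}: occupancy {self.occupancy} outside [0,1]")
        if self.vdw_radius is not None and self.vdw_radius <= 0:
            raise InputError(f"atom {self.name}: vdW radius must be positive")

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.pos.copy(), self.occupancy,
                    self.b_factor, self.altloc, self.vdw_radius, self.charge)


@dataclass
class Residue:
    chain_id: str
    seq_number: int
    insertion_code: str
    name: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def id(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_number, self.insertion_code)

    @property
    def label(self) -> str:
        return f"{self.name}{self.seq_number}{self.insertion_code}/{self.chain_id}"

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def copy(self) -> "Residue":
        return Residue(self.chain_id, self.seq_number, self.insertion_code,
                       self.name, [a.copy() for a in self.atoms])


WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)
    entity_kind: str = "polymer"  # polymer | non-polymer | water

    def __iter__(self):
        return iter(self.residues)

    def atoms(self) -> list[Atom]:
        return [a for r in self.residues for a in r.atoms]

    def residue(self, seq_number: int, insertion_code: str = "") -> Residue | None:
        for r in self.residues:
            if r.seq_number == seq_number and r.insertion_code == insertion_code:
                return r
        return None

    def copy(self, new_id: str | None = None) -> "Chain":
        c = Chain(new_id if new_id is not None else self.id,
                  [r.copy() for r in self.residues], self.entity_kind)
        for r in c.residues:
            r.chain_id = c.id
        return c


# built-in fallback operator tables; files are authoritative when they carry
# explicit operators (REMARK 290 / _space_group_symop)
BUILTIN_OPERATORS = {
    "P 1": ["x,y,z"],
    "P 3": ["x,y,z", "-y,x-y,z", "-x+y,-x,z"],
}


@dataclass
class CrystalInfo:
    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float
    space_group_symbol: str = "P 1"
    symmetry_operators: list[str] = field(default_factory=lambda: ["x,y,z"])

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise MetadataError("all cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise MetadataError("cell angles must be in (0, 180) degrees")
        if not self.symmetry_operators:
            self.symmetry_operators = ["x,y,z"]


@dataclass
class Structure:
    chains: list[Chain] = field(default_factory=list)
    crystal_info: CrystalInfo | None = None
    source_id: str = ""
    model_number: int = 1

    def __post_init__(self):
        ids = [c.id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise InputError(f"duplicate chain ids: {ids}")

    def __getitem__(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise KeyError(chain_id)

    def __contains__(self, chain_id: str) -> bool:
        return any(c.id == chain_id for c in self.chains)

    def atoms(self) -> list[Atom]:
        return [a for c in self.chains for a in c.atoms()]

    def residues(self) -> list[Residue]:
        return [r for c in self.chains for r in c.residues]

    def polymer_chains(self) -> list[Chain]:
        return [c for c in self.chains if c.entity_kind == "polymer"]

    def select(self, chain_ids) -> "Structure":
        """Sub-structure containing the named chains (shared crystal metadata)."""
        return Structure([self[cid].copy() for cid in chain_ids],
                         self.crystal_info, self.source_id, self.model_number)

    def copy(self) -> "Structure":
        return Structure([c.copy() for c in self.chains], self.crystal_info,
                         self.source_id, self.model_number)

    def add_chain(self, chain: Chain):
        if chain.id in self:
            raise InputError(f"chain id {chain.id!r} already present")
        self.chains.append(chain)


# ---------------------------------------------------------------------------
# coordinate-array helpers used throughout the toolkit
# ---------------------------------------------------------------------------


def iter_atoms(obj):
    """Yield atoms from a Structure, Chain, Residue, list of any of those, or list of Atoms."""
    if isinstance(obj, Atom):
        yield obj
    elif isinstance(obj, Residue):
        yield from obj.atoms
    elif isinstance(obj, Chain):
        yield from obj.atoms()
    elif isinstance(obj, Structure):
        yield from obj.atoms()
    else:
        for item in obj:
            yield from iter_atoms(item)


def coords_of(obj) -> np.ndarray:
    atoms = list(iter_atoms(obj))
    if not atoms:
        return np.zeros((0, 3))
    return np.array([a.pos for a in atoms])


def set_coords(obj, coords: np.ndarray):
    for a, xyz in zip(iter_atoms(obj), np.asarray(coords, dtype=float), strict=True):
        a.pos = np.array(xyz, dtype=float)


def heavy_atoms(obj) -> list[Atom]:
    return [a for a in iter_atoms(obj) if not a.is_hydrogen]


def atom_residues(obj):
    """Yield (residue, atom) pairs."""
    if isinstance(obj, Residue):
        for a in obj.atoms:
            yield obj, a
    elif isinstance(obj, Chain):
        for r in obj.residues:
            for a in r.atoms:
                yield r, a
    elif isinstance(obj, Structure):
        for c in obj.chains:
            yield from atom_residues(c)
    else:
        for item in obj:
            yield from atom_residues(item)


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
    "MSE": "M",  # selenomethionine maps to M
}


def extract_sequence(chain: Chain) -> str:
    """One-letter sequence of a polymer chain; nonstandard residues become 'X'."""
    if chain.entity_kind != "polymer":
        raise InputError(f"chain {chain.id!r} is {chain.entity_kind}, not polymer")
    return "".join(THREE_TO_ONE.get(r.name, "X") for r in chain.residues)


# ---------------------------------------------------------------------------
# van der Waals radii
# ---------------------------------------------------------------------------

# Bondi (1964) element-wise van der Waals radii in Angstrom, the standard set
# for accessible-surface computations; Se from Bondi's extended table.
VDW_RADII_SETS = {
    "bondi": {
        "H": 1.20, "D": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
        "P": 1.80, "S": 1.80, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
        "ZN": 1.39, "MG": 1.73, "NA": 2.27, "K": 2.75, "CA": 2.31, "FE": 1.63,
    },
}

DEFAULT_RADII_SET = "bondi"
DEFAULT_FALLBACK_RADIUS = 1.80


def load_radii_config(path) -> dict:
    """Plain key=value config: element symbols to radii, plus 'fallback'."""
    table = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ParseError(f"{path}:{lineno}: expected KEY=VALUE, got {line!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        try:
            table[key.upper()] = float(value)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {value!r} is not a number") from exc
    return table


def assign_radii(structure: Structure, radii_set_name: str = DEFAULT_RADII_SET,
                 fallback: float = DEFAULT_FALLBACK_RADIUS,
                 overrides: dict | None = None) -> Structure:
    """Assign a vdW radius to every atom, in place; returns the structure.

    Unknown elements receive ``fallback`` with a warning rather than failing,
    so that a stray ligand atom cannot abort a surface computation.
    """
    try:
        table = dict(VDW_RADII_SETS[radii_set_name])
    except KeyError:
        raise ConfigurationError(
            f"unknown radii set {radii_set_name!r}; available: {sorted(VDW_RADII_SETS)}")
    if overrides:
        table.update({k.upper(): float(v) for k, v in overrides.items()})
    fallback = float(table.pop("FALLBACK", fallback))
    unknown = set()
    for atom in structure.atoms():
        r = table.get(atom.element.upper())
        if r is None:
            unknown.add(atom.element)
            r = fallback
        atom.vdw_radius = r
    if unknown:
        warnings.warn(
            f"elements {sorted(unknown)} not in radii set {radii_set_name!r}; "
            f"using fallback {fallback} A", stacklevel=2)
    return structure


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------


def _resolve_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep the highest-occupancy conformer per atom name; ties break on altloc order."""
    by_name: dict[str, gemmi.Atom] = {}
    for atom in residue:
        prev = by_name.get(atom.name)
        if prev is None:
            by_name[atom.name] = atom
        elif (atom.occ, -ord(atom.altloc or "z")) > (prev.occ, -ord(prev.altloc or "z")):
            by_name[atom.name] = atom
    # preserve file order of first appearance
    seen, out = set(), []
    for atom in residue:
        if atom.name not in seen:
            seen.add(atom.name)
            out.append(by_name[atom.name])
    return out


def _chain_kind(residues: list[Residue]) -> str:
    names = {r.name for r in residues}
    if names <= WATER_NAMES:
        return "water"
    n_aa = sum(1 for r in residues
               if r.name in THREE_TO_ONE or _is_tabulated_aa(r.name))
    return "polymer" if n_aa >= max(1, len(residues) // 2) else "non-polymer"


def _is_tabulated_aa(name: str) -> bool:
    info = gemmi.find_tabulated_residue(name)
    return bool(info and info.is_amino_acid())


def _operators_from_file(path: Path, fmt: str) -> list[str] | None:
    """Explicit operators stored in the file itself, if any."""
    try:
        if fmt == "cif":
            doc = gemmi.cif.read(str(path))
            block = doc.sole_block()
            for tag in ("_space_group_symop.operation_xyz",
                        "_symmetry_equiv.pos_as_xyz",
                        "_symmetry_equiv_pos_as_xyz"):
                values = block.find_values(tag)
                if values and len(values) > 0:
                    return [gemmi.cif.as_string(v).lower() for v in values]
        else:
            ops = _parse_remark_290(Path(path).read_text(errors="replace"))
            if ops:
                return ops
    except Exception:
        return None
    return None


def _parse_remark_290(text: str) -> list[str]:
    rows: dict[int, list[list[float]]] = {}
    for line in text.splitlines():
        if not line.startswith("REMARK 290   SMTRY"):
            continue
        try:
            axis = int(line[18])
            fields = line[19:].split()
            op_num = int(fields[0])
            values = [float(x) for x in fields[1:5]]
        except (ValueError, IndexError):
            continue
        rows.setdefault(op_num, [[0.0] * 4] * 3)
        mat = rows[op_num]
        mat[axis - 1] = values
        rows[op_num] = mat
    triplets = []
    for op_num in sorted(rows):
        mat = rows[op_num]
        op = gemmi.Op()
        op.rot = [[int(round(v * gemmi.Op.DEN)) for v in row[:3]] for row in mat]
        op.tran = [int(round(row[3] * gemmi.Op.DEN)) for row in mat]
        triplets.append(op.triplet())
    return triplets


def _operators_for(symbol: str) -> list[str]:
    sg = gemmi.find_spacegroup_by_name(symbol) if symbol else None
    if sg is not None:
        return [op.triplet() for op in sg.operations()]
    if symbol in BUILTIN_OPERATORS:
        return list(BUILTIN_OPERATORS[symbol])
    warnings.warn(f"unknown space group {symbol!r}; assuming P 1", stacklevel=3)
    return ["x,y,z"]


def _detect_format(path: Path, format_hint: str | None) -> str:
    if format_hint:
        hint = format_hint.lower()
        if hint in ("pdb", "cif", "mmcif"):
            return "cif" if hint in ("cif", "mmcif") else "pdb"
        raise InputError(f"unknown format hint {format_hint!r}")
    suffix = path.suffix.lower()
    if suffix in (".cif", ".mmcif"):
        return "cif"
    if suffix in (".pdb", ".ent"):
        return "pdb"
    # content sniff: mmCIF files start with data_
    try:
        head = path.read_text(errors="replace")[:2048]
    except OSError as exc:
        raise ParseError(f"cannot read {path}: {exc}") from exc
    return "cif" if head.lstrip().startswith("data_") else "pdb"


def read_structure(path, format_hint: str | None = None,
                   model_index: int = 0) -> Structure:
    """Read a PDB or mmCIF file into the hierarchical model.

    Altlocs are resolved to the highest-occupancy conformer; for multi-model
    (NMR) files one model is selected (the first by default).  Waters and
    non-polymer entities are kept but flagged through ``Chain.entity_kind``.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"file not found: {path}")
    fmt = _detect_format(path, format_hint)
    try:
        if fmt == "cif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    if not 0 <= model_index < len(st):
        raise InputError(f"model index {model_index} out of range (file has {len(st)} models)")
    model = st[model_index]

    chains: list[Chain] = []
    for gchain in model:
        residues: list[Residue] = []
        for gres in gchain:
            atoms = []
            for gatom in _resolve_altlocs(gres):
                atoms.append(Atom(
                    name=gatom.name,
                    element=gatom.element.name.upper(),
                    pos=np.array([gatom.pos.x, gatom.pos.y, gatom.pos.z]),
                    occupancy=min(max(gatom.occ, 0.0), 1.0),
                    b_factor=gatom.b_iso,
                    altloc=gatom.altloc or "",
                ))
            if atoms:
                residues.append(Residue(gchain.name, gres.seqid.num,
                                        (gres.seqid.icode or "").strip(), gres.name, atoms))
        if residues:
            chains.append(Chain(gchain.name, residues, _chain_kind(residues)))
    if not chains:
        raise EmptyStructureError(f"{path}: zero atoms")

    crystal = None
    cell = st.cell
    # gemmi uses a 1x1x1 placeholder cell when CRYST1/_cell is absent
    if cell.a > 1.0 and cell.volume > 1.0:
        symbol = st.spacegroup_hm or "P 1"
        ops = _operators_from_file(path, fmt) or _operators_for(symbol)
        crystal = CrystalInfo(cell.a, cell.b, cell.c, cell.alpha, cell.beta,
                              cell.gamma, symbol, ops)
    return Structure(chains, crystal, source_id=path.stem,
                     model_number=model_index + 1)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

_PDB_CHAIN_IDS = ("ABCDEFGHIJKLMNOPQRSTUVWXYZ"
                  "abcdefghijklmnopqrstuvwxyz"
                  "0123456789")


def _chain_rename_map(chains: list[Chain]) -> dict[str, str]:
    """Map chain ids onto single characters for PDB export (identity when possible)."""
    taken = {c.id for c in chains if len(c.id) == 1}
    mapping = {}
    pool = iter(cid for cid in _PDB_CHAIN_IDS if cid not in taken)
    for chain in chains:
        if len(chain.id) == 1:
            mapping[chain.id] = chain.id
        else:
            try:
                mapping[chain.id] = next(pool)
            except StopIteration:
                raise FormatCapacityError(
                    f"{len(chains)} chains exceed the 62 single-character PDB chain ids")
    return mapping


def _to_gemmi(structure: Structure, rename: dict[str, str] | None = None) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structure.source_id or "thdtools"
    model = gemmi.Model(structure.model_number)
    for chain in structure.chains:
        gchain = gemmi.Chain(rename.get(chain.id, chain.id) if rename else chain.id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.seq_number, res.insertion_code or " ")
            gres.het_flag = "A" if chain.entity_kind == "polymer" else "H"
            for atom in res.atoms:
                gatom = gemmi.Atom()
                gatom.name = atom.name
                gatom.element = gemmi.Element(atom.element.capitalize())
                gatom.pos = gemmi.Position(*atom.pos)
                gatom.occ = atom.occupancy
                gatom.b_iso = atom.b_factor
                gatom.altloc = atom.altloc or "\0"
                gres.add_atom(gatom)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    st.add_model(model)
    ci = structure.crystal_info
    if ci is not None:
        st.cell = gemmi.UnitCell(ci.a, ci.b, ci.c, ci.alpha, ci.beta, ci.gamma)
        st.spacegroup_hm = ci.space_group_symbol
    return st


def write_structure(structure: Structure, path, format: str | None = None) -> dict[str, str]:
    """Write PDB or mmCIF; returns the chain-renaming map used (identity if none).

    PDB chain ids are single characters; multi-character ids (symmetry mates
    like ``A_s1``) are mapped deterministically and the map is stored next to
    the file as ``<path>.chainmap.tsv``.
    """
    if not structure.chains or not structure.atoms():
        raise EmptyStructureError("refusing to write an empty structure")
    path = Path(path)
    requested = (format or path.suffix.lstrip(".")).lower()
    fmt = "cif" if requested in ("cif", "mmcif") else "pdb"
    rename = {c.id: c.id for c in structure.chains}
    if fmt == "pdb" and any(len(c.id) > 1 for c in structure.chains):
        rename = _chain_rename_map(structure.chains)
        map_path = path.with_suffix(path.suffix + ".chainmap.tsv")
        map_path.write_text("original\tpdb\n" +
                            "".join(f"{k}\t{v}\n" for k, v in rename.items()))
    st = _to_gemmi(structure, rename)
    st.setup_entities()
    if fmt == "pdb":
        st.write_pdb(str(path))
    else:
        st.make_mmcif_document().write_file(str(path))
    return rename
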