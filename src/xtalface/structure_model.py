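"""Parsed crystallographic entries, domain annotations and architectures.

This module turns structure files (mmCIF or legacy PDB) and tab-separated
annotation tables into a validated in-memory model:

* :class:`CrystalEntry` — one deposited crystal: unit cell, space-group
  operators, polymer chains, ligands and biological-assembly definitions;
* :class:`DomainInstance` — a family-assigned residue interval set on a
  chain, with the residue -> profile-HMM match-position map that gives a
  sequence-independent coordinate system for comparing homologs;
* :class:`ChainArchitecture` — the ordered list of families along a chain,
  rendered ``(Pkinase)_(SH2)``.

Parsing is delegated to :mod:`gemmi`; this module owns the validation rules
(single conformer per residue, hydrogens dropped, referential integrity of
annotation rows) and the altloc/occupancy policy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd

WATER_COMPONENTS = {"HOH", "WAT", "DOD"}

#: Columns of the domain-annotation TSV, in order.
ANNOTATION_COLUMNS = [
    "entry_id", "asym_id", "pfam_acc", "pfam_id", "clan", "intervals",
    "hmm_length", "hmm_map", "uniprot", "species",
]

#: Columns of the assembly-annotation TSV.  ``members`` is a
#: semicolon-separated list of ``asym:op_index:i,j,k`` triples.
ASSEMBLY_COLUMNS = ["entry_id", "assembly_id", "provenance", "members"]


class FormatError(ValueError):
    """The structure file could not be parsed."""


class NonCrystallographicError(ValueError):
    """The entry lacks a usable cell or space group for lattice work."""


class AnnotationError(ValueError):
    """An annotation table row failed validation."""


# ---------------------------------------------------------------------------
# core records


@dataclass
class Atom:
    name: str
    element: str
    pos: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        if not np.all(np.isfinite(self.pos)):
            raise ValueError("atom position must be finite")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must lie in [0, 1]")


@dataclass
class Residue:
    chain_ref: str
    seq_pos: int
    name: str
    atoms: list[Atom]
    is_polymer: bool = True
    auth_seq: int | None = None

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def cbeta(self) -> np.ndarray | None:
        """C-beta position; glycine (or a missing CB) falls back to CA."""
        a = self.atom("CB") or self.atom("CA")
        return None if a is None else a.pos


@dataclass
class PolymerChain:
    asym_id: str
    auth_id: str
    entity_id: str
    sequence: str
    polymer_type: str  # polypeptide | DNA | RNA | hybrid
    residues: list[Residue]
    uniprot: str | None = None
    species: str | None = None

    _TYPES = {"polypeptide", "DNA", "RNA", "hybrid"}

    def __post_init__(self) -> None:
        if self.polymer_type not in self._TYPES:
            raise ValueError(f"bad polymer_type {self.polymer_type!r}")

    @property
    def length(self) -> int:
        """Full polymer length including unmodeled residues."""
        return len(self.sequence)

    @property
    def is_nucleic(self) -> bool:
        return self.polymer_type in ("DNA", "RNA", "hybrid")

    def heavy_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """All heavy-atom coordinates and their residue indices."""
        coords, ridx = [], []
        for i, res in enumerate(self.residues):
            for a in res.atoms:
                coords.append(a.pos)
                ridx.append(i)
        if not coords:
            return np.empty((0, 3)), np.empty(0, dtype=int)
        return np.asarray(coords), np.asarray(ridx, dtype=int)

    def cbeta_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """One C-beta (or CA surrogate) per residue that has one."""
        coords, ridx = [], []
        for i, res in enumerate(self.residues):
            cb = res.cbeta
            if cb is not None:
                coords.append(cb)
                ridx.append(i)
        if not coords:
            return np.empty((0, 3)), np.empty(0, dtype=int)
        return np.asarray(coords), np.asarray(ridx, dtype=int)

    def ca_map(self) -> dict[int, np.ndarray]:
        out = {}
        for res in self.residues:
            a = res.atom("CA")
            if a is not None:
                out[res.seq_pos] = a.pos
        return out


@dataclass
class LigandInstance:
    comp_id: str
    atoms: list[Atom]
    is_water: bool
    ligand_id: str = ""
    chain_ref: str = ""

    def __post_init__(self) -> None:
        if self.is_water != (self.comp_id in WATER_COMPONENTS):
            raise ValueError("is_water inconsistent with comp_id")

    def coords(self) -> np.ndarray:
        return (np.asarray([a.pos for a in self.atoms])
                if self.atoms else np.empty((0, 3)))


@dataclass
class UnitCell:
    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell edges must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0 < ang < 180:
                raise ValueError("cell angles must lie in (0, 180)")

    def as_gemmi(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(self.a, self.b, self.c,
                              self.alpha, self.beta, self.gamma)

    def orth_matrix(self) -> np.ndarray:
        """Fractional -> orthogonal matrix (a along x)."""
        return np.asarray(self.as_gemmi().orth.mat.tolist())

    def frac_matrix(self) -> np.ndarray:
        return np.asarray(self.as_gemmi().frac.mat.tolist())

    def params(self) -> tuple[float, ...]:
        return (self.a, self.b, self.c, self.alpha, self.beta, self.gamma)


@dataclass
class SymOp:
    """One space-group operator: fractional rotation matrix + translation."""
    rot: np.ndarray
    tran: np.ndarray

    def __post_init__(self) -> None:
        self.rot = np.asarray(self.rot, dtype=float)
        self.tran = np.asarray(self.tran, dtype=float)

    @property
    def is_identity(self) -> bool:
        return (np.allclose(self.rot, np.eye(3))
                and np.allclose(self.tran, 0.0))


@dataclass
class AssemblyDef:
    assembly_id: str
    provenance: str  # author | pisa
    members: list[tuple[str, int, tuple[int, int, int]]]
    """Each member is (chain asym_id, sym-op index, cell translation)."""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("assembly must have at least one member")
        if self.provenance not in ("author", "pisa"):
            raise ValueError(f"bad provenance {self.provenance!r}")


@dataclass
class CrystalEntry:
    entry_id: str
    cell: UnitCell | None
    space_group: str | None
    sym_ops: list[SymOp]
    chains: list[PolymerChain]
    ligands: list[LigandInstance]
    assemblies: list[AssemblyDef] = field(default_factory=list)
    resolution: float | None = None

    def __post_init__(self) -> None:
        if self.sym_ops and not any(op.is_identity for op in self.sym_ops):
            raise ValueError("sym_ops must include the identity")
        known = {c.asym_id for c in self.chains}
        for asm in self.assemblies:
            for asym, op_idx, _ in asm.members:
                if asym not in known:
                    raise ValueError(
                        f"assembly {asm.assembly_id} references unknown "
                        f"chain {asym}")
                if not 0 <= op_idx < max(len(self.sym_ops), 1):
                    raise ValueError(
                        f"assembly {asm.assembly_id} references sym-op "
                        f"{op_idx} outside the entry's operator list")

    @property
    def is_crystallographic(self) -> bool:
        return (self.cell is not None and self.space_group is not None
                and bool(self.sym_ops))

    def require_crystallographic(self) -> None:
        if not self.is_crystallographic:
            raise NonCrystallographicError(
                f"entry {self.entry_id} has no cell/space group; lattice "
                "workflows are unavailable (assembly and ligand workflows "
                "still apply)")

    def chain(self, asym_id: str) -> PolymerChain:
        for c in self.chains:
            if c.asym_id == asym_id:
                return c
        raise KeyError(f"no chain {asym_id} in entry {self.entry_id}")

    @property
    def protein_chains(self) -> list[PolymerChain]:
        return [c for c in self.chains if c.polymer_type == "polypeptide"]

    @property
    def nucleic_chains(self) -> list[PolymerChain]:
        return [c for c in self.chains if c.is_nucleic]


@dataclass
class DomainInstance:
    domain_id: str
    pfam_acc: str
    pfam_id: str
    clan: str | None
    chain_ref: str
    intervals: list[tuple[int, int]]
    hmm_map: dict[int, int]
    hmm_length: int

    def __post_init__(self) -> None:
        self.intervals = sorted((int(s), int(e)) for s, e in self.intervals)
        for (s, e) in self.intervals:
            if s > e or s < 1:
                raise AnnotationError(
                    f"{self.domain_id}: bad interval {s}-{e}")
        for (_, e1), (s2, _) in zip(self.intervals, self.intervals[1:]):
            if s2 <= e1:
                raise AnnotationError(
                    f"{self.domain_id}: overlapping intervals")
        for pos, hmm in self.hmm_map.items():
            if not self.contains(pos):
                raise AnnotationError(
                    f"{self.domain_id}: hmm_map key {pos} outside intervals")
            if not 1 <= hmm <= self.hmm_length:
                raise AnnotationError(
                    f"{self.domain_id}: hmm position {hmm} outside "
                    f"[1, {self.hmm_length}]")

    def contains(self, seq_pos: int) -> bool:
        return any(s <= seq_pos <= e for s, e in self.intervals)

    @property
    def start(self) -> int:
        return self.intervals[0][0]

    @property
    def n_residues(self) -> int:
        return sum(e - s + 1 for s, e in self.intervals)

    @property
    def coverage(self) -> float:
        return len(self.hmm_map) / self.hmm_length

    def seq_positions(self) -> set[int]:
        return {p for s, e in self.intervals for p in range(s, e + 1)}


@dataclass(frozen=True)
class ChainArchitecture:
    families: tuple[str, ...]

    @property
    def arch_string(self) -> str:
        return "_".join(f"({f})" for f in self.families)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.arch_string


# ---------------------------------------------------------------------------
# structure-file reading


_POLY_TYPE = {
    gemmi.PolymerType.PeptideL: "polypeptide",
    gemmi.PolymerType.PeptideD: "polypeptide",
    gemmi.PolymerType.Dna: "DNA",
    gemmi.PolymerType.Rna: "RNA",
    gemmi.PolymerType.DnaRnaHybrid: "hybrid",
}


def _choose_altloc(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Single-conformer policy: per atom name keep the altloc with the
    highest occupancy, ties broken by the alphabetically first code."""
    best: dict[str, gemmi.Atom] = {}
    for atom in residue:
        if atom.is_hydrogen():
            continue
        prev = best.get(atom.name)
        if prev is None:
            best[atom.name] = atom
        else:
            key = (-atom.occ, atom.altloc or "~")
            prev_key = (-prev.occ, prev.altloc or "~")
            if key < prev_key:
                best[atom.name] = atom
    return [best[k] for k in best]


def _convert_atoms(residue: gemmi.Residue) -> list[Atom]:
    out = []
    for atom in _choose_altloc(residue):
        out.append(Atom(
            name=atom.name,
            element=atom.element.name,
            pos=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
            occupancy=min(max(atom.occ, 0.0), 1.0),
            altloc=atom.altloc or "",
        ))
    return out


def read_entry(path: str | Path, dialect: str | None = None) -> CrystalEntry:
    """Read an mmCIF or legacy-PDB structure file into a :class:`CrystalEntry`.

    The format is detected from the file content/extension unless ``dialect``
    (``"mmcif"`` or ``"pdb"``) forces it.  Hydrogens are dropped and one
    conformer per residue is kept.  Symmetry operators are resolved from the
    Hermann-Mauguin space-group symbol via the standard tables.

    An entry without a cell or space group is still returned (usable for
    assembly and ligand analyses); lattice operations on it raise
    :class:`NonCrystallographicError`.
    """
    path = Path(path)
    try:
        if dialect == "mmcif":
            st = gemmi.read_structure(str(path),
                                      format=gemmi.CoorFormat.Mmcif)
        elif dialect == "pdb":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
        else:
            st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()

    cell = None
    if st.cell and st.cell.a > 1.0 and st.cell.b > 1.0 and st.cell.c > 1.0:
        cell = UnitCell(st.cell.a, st.cell.b, st.cell.c,
                        st.cell.alpha, st.cell.beta, st.cell.gamma)
    sg_symbol = (st.spacegroup_hm or "").strip() or None
    sym_ops: list[SymOp] = []
    if sg_symbol is not None:
        sg = gemmi.find_spacegroup_by_name(sg_symbol)
        if sg is None:
            raise FormatError(f"unknown space group {sg_symbol!r} in {path}")
        den = float(gemmi.Op.DEN)
        for op in sg.operations():
            sym_ops.append(SymOp(np.asarray(op.rot, float) / den,
                                 np.asarray(op.tran, float) / den))

    ent_by_subchain: dict[str, gemmi.Entity] = {}
    for ent in st.entities:
        for sub in ent.subchains:
            ent_by_subchain[sub] = ent

    model = st[0]
    chains: list[PolymerChain] = []
    ligands: list[LigandInstance] = []
    for chain in model:
        poly_res: list[Residue] = []
        poly_ent: gemmi.Entity | None = None
        for res in chain:
            comp = res.name.strip()
            if res.is_water() or comp in WATER_COMPONENTS:
                ligands.append(LigandInstance(
                    comp_id=comp, atoms=_convert_atoms(res), is_water=True,
                    ligand_id=f"{comp}_{chain.name}_{res.seqid.num}",
                    chain_ref=chain.name))
                continue
            ent = ent_by_subchain.get(res.subchain)
            is_poly = (ent is not None
                       and ent.entity_type == gemmi.EntityType.Polymer)
            if is_poly:
                poly_ent = ent
                seq_pos = res.label_seq if res.label_seq else res.seqid.num
                poly_res.append(Residue(
                    chain_ref=chain.name, seq_pos=int(seq_pos), name=comp,
                    atoms=_convert_atoms(res), auth_seq=res.seqid.num))
            else:
                ligands.append(LigandInstance(
                    comp_id=comp, atoms=_convert_atoms(res), is_water=False,
                    ligand_id=f"{comp}_{chain.name}_{res.seqid.num}",
                    chain_ref=chain.name))
        if poly_res:
            ptype = "polypeptide"
            seq = ""
            entity_id = ""
            if poly_ent is not None:
                ptype = _POLY_TYPE.get(poly_ent.polymer_type, "polypeptide")
                entity_id = poly_ent.name
                if poly_ent.full_sequence:
                    seq = gemmi.one_letter_code(
                        [gemmi.Entity.first_mon(m)
                         for m in poly_ent.full_sequence]).upper()
            if not seq:
                seq = gemmi.one_letter_code(
                    [r.name for r in poly_res]).upper()
            chains.append(PolymerChain(
                asym_id=chain.name, auth_id=chain.name, entity_id=entity_id,
                sequence=seq, polymer_type=ptype, residues=poly_res))

    entry = CrystalEntry(
        entry_id=st.name or path.stem,
        cell=cell, space_group=sg_symbol, sym_ops=sym_ops,
        chains=chains, ligands=ligands,
        resolution=st.resolution if st.resolution > 0 else None)
    entry.assemblies = _convert_assemblies(st, entry)
    return entry


def _convert_assemblies(st: gemmi.Structure,
                        entry: CrystalEntry) -> list[AssemblyDef]:
    """Map deposited assembly transforms onto the entry's operator list."""
    out: list[AssemblyDef] = []
    known = {c.asym_id for c in entry.chains}
    for asm in st.assemblies:
        members: list[tuple[str, int, tuple[int, int, int]]] = []
        ok = True
        for gen in asm.generators:
            names = list(gen.chains) or [s for s in gen.subchains]
            for oper in (gen.operators or [None]):
                matched = _match_operator(oper, entry)
                if matched is None:
                    ok = False
                    break
                for name in names:
                    if name in known:
                        members.append((name, matched[0], matched[1]))
            if not ok:
                break
        if ok and members:
            prov = "pisa" if "software" in (asm.name or "").lower() else \
                ("pisa" if asm.software_determined and not
                 asm.author_determined else "author")
            out.append(AssemblyDef(assembly_id=asm.name or str(len(out) + 1),
                                   provenance=prov, members=members))
    return out


def _match_operator(oper, entry: CrystalEntry):
    """Resolve an assembly transform to (sym-op index, cell shift)."""
    if oper is None:
        return _identity_index(entry), (0, 0, 0)
    t = oper.transform
    rot = np.asarray(t.mat.tolist())
    tran = np.asarray(t.vec.tolist())
    if np.allclose(rot, np.eye(3)) and np.allclose(tran, 0.0, atol=1e-6):
        return _identity_index(entry), (0, 0, 0)
    if entry.cell is None or not entry.sym_ops:
        return None
    orth = entry.cell.orth_matrix()
    frac = entry.cell.frac_matrix()
    for idx, op in enumerate(entry.sym_ops):
        r_orth = orth @ op.rot @ frac
        if not np.allclose(r_orth, rot, atol=1e-4):
            continue
        shift_frac = frac @ tran - op.tran
        shift = np.round(shift_frac)
        if np.allclose(shift_frac, shift, atol=1e-4):
            return idx, tuple(int(x) for x in shift)
    return None


def _identity_index(entry: CrystalEntry) -> int:
    for i, op in enumerate(entry.sym_ops):
        if op.is_identity:
            return i
    return 0


# ---------------------------------------------------------------------------
# structure-file writing (fixtures, round-trips, per-interface exports)

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

_NUC_THREE = {"DNA": {"A": "DA", "C": "DC", "G": "DG", "T": "DT"},
              "RNA": {"A": "A", "C": "C", "G": "G", "U": "U"}}


def three_letter(one: str, polymer_type: str = "polypeptide") -> str:
    if polymer_type == "polypeptide":
        return _ONE_TO_THREE.get(one.upper(), "UNK")
    return _NUC_THREE.get(polymer_type, {}).get(one.upper(), "DN")


def write_entry(entry: CrystalEntry, path: str | Path) -> None:
    """Write an entry as mmCIF (round-trippable through :func:`read_entry`)."""
    st = gemmi.Structure()
    st.name = entry.entry_id
    if entry.cell is not None:
        st.cell = entry.cell.as_gemmi()
    if entry.space_group is not None:
        st.spacegroup_hm = entry.space_group
    model = gemmi.Model("1")
    ptype_back = {
        "polypeptide": gemmi.PolymerType.PeptideL,
        "DNA": gemmi.PolymerType.Dna,
        "RNA": gemmi.PolymerType.Rna,
        "hybrid": gemmi.PolymerType.DnaRnaHybrid,
    }
    for ci, ch in enumerate(entry.chains):
        g_chain = gemmi.Chain(ch.asym_id)
        sub = f"{ch.asym_id}p"
        for res in ch.residues:
            g_res = gemmi.Residue()
            g_res.name = res.name
            g_res.seqid = gemmi.SeqId(res.auth_seq or res.seq_pos, " ")
            g_res.label_seq = res.seq_pos
            g_res.subchain = sub
            g_res.entity_type = gemmi.EntityType.Polymer
            for a in res.atoms:
                g_atom = gemmi.Atom()
                g_atom.name = a.name
                g_atom.element = gemmi.Element(a.element)
                g_atom.pos = gemmi.Position(*a.pos)
                g_atom.occ = a.occupancy
                g_res.add_atom(g_atom)
            g_chain.add_residue(g_res)
        model.add_chain(g_chain)
        ent = gemmi.Entity(str(ci + 1))
        ent.entity_type = gemmi.EntityType.Polymer
        ent.polymer_type = ptype_back[ch.polymer_type]
        ent.subchains = [sub]
        ent.full_sequence = [three_letter(s, ch.polymer_type)
                             for s in ch.sequence]
        st.entities.append(ent)
    lig_by_chain: dict[str, list[LigandInstance]] = {}
    for lig in entry.ligands:
        lig_by_chain.setdefault(lig.chain_ref or "X", []).append(lig)
    for lname, ligs in lig_by_chain.items():
        g_chain = gemmi.Chain(lname)
        for li, lig in enumerate(ligs):
            g_res = gemmi.Residue()
            g_res.name = lig.comp_id
            g_res.seqid = gemmi.SeqId(900 + li, " ")
            g_res.subchain = f"{lname}lig{li}"
            g_res.entity_type = (gemmi.EntityType.Water if lig.is_water
                                 else gemmi.EntityType.NonPolymer)
            for a in lig.atoms:
                g_atom = gemmi.Atom()
                g_atom.name = a.name
                g_atom.element = gemmi.Element(a.element)
                g_atom.pos = gemmi.Position(*a.pos)
                g_atom.occ = a.occupancy
                g_res.add_atom(g_atom)
            g_chain.add_residue(g_res)
        model.add_chain(g_chain)
    st.add_model(model)
    st.setup_entities()
    # setup_entities may rebuild entity records; re-impose polymer metadata
    for ent in st.entities:
        for ch, ptype in [(c.asym_id, c.polymer_type) for c in entry.chains]:
            if f"{ch}p" in ent.subchains:
                ent.polymer_type = ptype_back[ptype]
                ent.full_sequence = [
                    three_letter(s, ptype)
                    for s in entry.chain(ch).sequence]
    doc = st.make_mmcif_document()
    doc.write_file(str(path))


# ---------------------------------------------------------------------------
# annotation tables


def _parse_intervals(text: str) -> list[tuple[int, int]]:
    out = []
    for part in str(text).split(";"):
        part = part.strip()
        if not part:
            continue
        s, _, e = part.partition("-")
        out.append((int(s), int(e)))
    if not out:
        raise AnnotationError(f"empty interval spec {text!r}")
    return out


def _parse_hmm_map(text: str) -> dict[int, int]:
    out: dict[int, int] = {}
    for part in str(text).split(","):
        part = part.strip()
        if not part:
            continue
        k, _, v = part.partition(":")
        out[int(k)] = int(v)
    return out


def format_hmm_map(hmm_map: Mapping[int, int]) -> str:
    return ",".join(f"{k}:{v}" for k, v in sorted(hmm_map.items()))


def format_intervals(intervals: Iterable[tuple[int, int]]) -> str:
    return ";".join(f"{s}-{e}" for s, e in intervals)


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise AnnotationError(
            f"annotation table {path} missing columns {sorted(missing)}")
    return df


def ingest_annotations(entry: CrystalEntry,
                       table: pd.DataFrame | str | Path,
                       ) -> list[DomainInstance]:
    """Validate and attach domain annotations to an entry.

    ``table`` is either a path to the tab-separated annotation file or an
    already-loaded DataFrame with the same columns.  Rows for other entries
    are ignored; rows referencing chains absent from this entry, with
    intervals outside the chain, or with out-of-range HMM positions raise
    :class:`AnnotationError` naming the offending row.
    """
    if not isinstance(table, pd.DataFrame):
        table = read_annotation_table(table)
    domains: list[DomainInstance] = []
    chain_ids = {c.asym_id: c for c in entry.chains}
    for idx, row in table.iterrows():
        if row["entry_id"] != entry.entry_id:
            continue
        asym = row["asym_id"]
        if asym not in chain_ids:
            raise AnnotationError(
                f"row {idx}: chain {asym!r} not present in entry "
                f"{entry.entry_id}")
        chain = chain_ids[asym]
        intervals = _parse_intervals(row["intervals"])
        if max(e for _, e in intervals) > chain.length:
            raise AnnotationError(
                f"row {idx}: interval end beyond chain {asym} length "
                f"{chain.length}")
        dom = DomainInstance(
            domain_id=f"{entry.entry_id}_{asym}_{row['pfam_id']}_"
                      f"{intervals[0][0]}",
            pfam_acc=row["pfam_acc"], pfam_id=row["pfam_id"],
            clan=row["clan"] or None, chain_ref=asym,
            intervals=intervals,
            hmm_map=_parse_hmm_map(row["hmm_map"]),
            hmm_length=int(row["hmm_length"]))
        if row.get("uniprot"):
            chain.uniprot = row["uniprot"] or chain.uniprot
        if row.get("species"):
            chain.species = row["species"] or chain.species
        domains.append(dom)
    return domains


def read_assembly_table(entry: CrystalEntry,
                        path: str | Path) -> list[AssemblyDef]:
    """Read assembly compositions (author/PISA) from a TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(ASSEMBLY_COLUMNS) - set(df.columns)
    if missing:
        raise AnnotationError(
            f"assembly table {path} missing columns {sorted(missing)}")
    out = []
    for idx, row in df.iterrows():
        if row["entry_id"] != entry.entry_id:
            continue
        members = []
        for part in row["members"].split(";"):
            part = part.strip()
            if not part:
                continue
            asym, op_idx, shift = part.split(":")
            members.append((asym, int(op_idx),
                            tuple(int(x) for x in shift.split(","))))
        if not members:
            raise AnnotationError(f"row {idx}: assembly with no members")
        out.append(AssemblyDef(assembly_id=row["assembly_id"],
                               provenance=row["provenance"],
                               members=members))
    entry.assemblies.extend(out)
    return out


# ---------------------------------------------------------------------------
# architectures


def derive_architectures(entry: CrystalEntry,
                         domains: Sequence[DomainInstance],
                         ) -> dict[str, ChainArchitecture]:
    """Per-chain family architecture, ordered by first interval start.

    Chains without any domain get the empty architecture.  The rendering is
    canonical: it depends only on the (chain, start-sorted) domain list,
    not on the order of the input.
    """
    by_chain: dict[str, list[DomainInstance]] = {}
    for dom in domains:
        by_chain.setdefault(dom.chain_ref, []).append(dom)
    out: dict[str, ChainArchitecture] = {}
    for chain in entry.chains:
        doms = sorted(by_chain.get(chain.asym_id, []),
                      key=lambda d: (d.start, d.pfam_id))
        out[chain.asym_id] = ChainArchitecture(
            tuple(d.pfam_id for d in doms))
    return out


def entry_arch_key(architectures: Mapping[str, ChainArchitecture],
                   ) -> tuple[str, ...]:
    """Entry-level architecture signature: sorted distinct non-empty
    chain-architecture strings."""
    return tuple(sorted({a.arch_string for a in architectures.values()
                         if a.families}))


def entry_stoichiometry(architectures: Mapping[str, ChainArchitecture],
                        ) -> tuple[tuple[str, int], ...]:
    """Multiset of chain architectures in the asymmetric unit."""
    counts: dict[str, int] = {}
    for arch in architectures.values():
        counts[arch.arch_string] = counts.get(arch.arch_string, 0) + 1
    return tuple(sorted(counts.items()))
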