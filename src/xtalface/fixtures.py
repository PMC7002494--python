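"""Synthetic crystals with known ground truth.

Every pipeline stage is testable without downloading structures: this
module builds ideal-geometry helical folds (NeRF construction from ideal
bond lengths/angles and alpha-helical dihedrals, C-beta at the ideal
tetrahedral position), packs two copies into a designed dimer, and writes
crystals around it:

* a single entry in P1 (or across a two-fold screw axis in P21) whose
  lattice contains the designed interface plus controlled packing
  contacts;
* a benchmark series of homologous crystal forms (mutated sequences,
  identical fold) that share the designed dimer but differ in packing, so
  only the designed interface recurs across forms — the signal the
  cross-crystal clustering is built to find;
* peptide-bound and ligand-bound variants with designed binding modes and
  contact sites.

The synthetic "HMM" of the fold is its own residue index (identity map,
coverage 1), which isolates the clustering logic from annotation noise.
Identical spec + seed give bit-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .config import PipelineConfig
from .structure_model import (ANNOTATION_COLUMNS, ASSEMBLY_COLUMNS,
                              AssemblyDef, Atom, CrystalEntry, PolymerChain,
                              LigandInstance, Residue, SymOp, UnitCell,
                              format_hmm_map, format_intervals,
                              three_letter, write_entry)

#: glycine-free alphabet so every residue carries a real C-beta
AA_ALPHABET = "ADEFHIKLMNPQRSTVWY"


@dataclass
class FixtureSpec:
    """Parameters of one synthetic crystal series."""
    seed: int = 0
    n_res: int = 32
    n_homolog_forms: int = 3
    mutation_rate: float = 0.1
    dimer_sep: float = 8.8
    cell_padding: float = 40.0
    packing_gap: float | None = 3.5
    space_group: str = "P 1"
    include_dimer: bool = True
    asu_rotation_deg: float = 0.0
    pfam_acc: str = "PF99901"
    pfam_id: str = "ToyFold"
    entry_prefix: str = "XF"


# ---------------------------------------------------------------------------
# ideal-geometry fold construction


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle: float, torsion: float) -> np.ndarray:
    """NeRF: position the atom bonded to c at the given internal coords."""
    ang = np.radians(angle)
    tor = np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-bond * np.cos(ang),
                  bond * np.sin(ang) * np.cos(tor),
                  bond * np.sin(ang) * np.sin(tor)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def _helix_backbone(n_res: int, phi: float = -57.0, psi: float = -47.0,
                    ) -> dict[str, np.ndarray]:
    """Ideal backbone (N, CA, C, O, CB) of an alpha helix, axis on +z."""
    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([1.458, 0.0, 0.0])]
    dummy = np.array([0.0, -1.0, 0.0])
    C = [_place(dummy, N[0], CA[0], 1.525, 111.2, 60.0)]
    for _ in range(1, n_res):
        N.append(_place(N[-1], CA[-1], C[-1], 1.329, 116.2, psi))
        CA.append(_place(CA[-1], C[-1], N[-1], 1.458, 121.7, 180.0))
        C.append(_place(C[-1], N[-1], CA[-1], 1.525, 111.2, phi))
    O = [_place(N[i], CA[i], C[i], 1.231, 120.5, psi + 180.0)
         for i in range(n_res)]
    CB = []
    for i in range(n_res):
        b = CA[i] - N[i]
        c = C[i] - CA[i]
        a = np.cross(b, c)
        CB.append(-0.58273431 * a + 0.56802827 * b
                  - 0.54067466 * c + CA[i])
    coords = {k: np.asarray(v) for k, v in
              (("N", N), ("CA", CA), ("C", C), ("O", O), ("CB", CB))}
    # canonical frame: helix axis on +z (first->last CA direction), centred
    ca = coords["CA"]
    centred = ca - ca.mean(axis=0)
    _, _, vt = np.linalg.svd(centred)
    axis = vt[0]
    if axis @ (ca[-1] - ca[0]) < 0:
        axis = -axis
    rot, _ = Rotation.align_vectors([[0.0, 0.0, 1.0]], [axis])
    centre = ca.mean(axis=0)
    return {k: rot.apply(v - centre) for k, v in coords.items()}


def random_sequence(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AA_ALPHABET), size=n))


def mutate_sequence(seq: str, rate: float,
                    rng: np.random.Generator) -> str:
    out = []
    for ch in seq:
        if rng.random() < rate:
            out.append(rng.choice([a for a in AA_ALPHABET if a != ch]))
        else:
            out.append(ch)
    return "".join(out)


def generate_toy_fold(n_res: int, seed: int = 0,
                      sequence: str | None = None,
                      ) -> tuple[str, dict[str, np.ndarray]]:
    """Sequence and ideal-helix coordinates of one toy fold.

    Coordinates do not depend on the sequence, so mutated homologs share
    the fold bit-for-bit — contacts between homologs then differ only
    through the HMM-position bookkeeping, never through geometry.
    """
    if n_res < 8:
        raise ValueError("fold needs at least 8 residues")
    if sequence is None:
        sequence = random_sequence(n_res, np.random.default_rng(seed))
    if len(sequence) != n_res:
        raise ValueError("sequence length mismatch")
    return sequence, _helix_backbone(n_res)


def make_chain(asym_id: str, sequence: str,
               coords: dict[str, np.ndarray],
               transform: tuple[np.ndarray, np.ndarray] | None = None,
               polymer_type: str = "polypeptide") -> PolymerChain:
    """Assemble a PolymerChain from a fold's coordinate dict."""
    n = len(sequence)
    residues = []
    rot, tran = transform if transform else (np.eye(3), np.zeros(3))
    for i in range(n):
        atoms = []
        for name in ("N", "CA", "C", "O", "CB"):
            el = name[0]
            pos = coords[name][i] @ rot.T + tran
            atoms.append(Atom(name=name, element=el, pos=pos))
        residues.append(Residue(chain_ref=asym_id, seq_pos=i + 1,
                                name=three_letter(sequence[i]),
                                atoms=atoms, auth_seq=i + 1))
    return PolymerChain(asym_id=asym_id, auth_id=asym_id, entity_id="",
                        sequence=sequence, polymer_type=polymer_type,
                        residues=residues)


def _rot_z(deg: float) -> np.ndarray:
    return Rotation.from_euler("z", deg, degrees=True).as_matrix()


def _rot_x(deg: float) -> np.ndarray:
    return Rotation.from_euler("x", deg, degrees=True).as_matrix()


def _chain_coords(chain: PolymerChain) -> np.ndarray:
    return chain.heavy_coords()[0]


def designed_dimer(sequence: str, coords: dict[str, np.ndarray],
                   sep: float = 8.8) -> tuple[PolymerChain, PolymerChain]:
    """Antiparallel two-helix dimer: B is A flipped about x and shifted."""
    a = make_chain("A", sequence, coords)
    b = make_chain("B", sequence, coords,
                   transform=(_rot_x(180.0), np.array([sep, 0.0, 0.0])))
    return a, b


def brute_force_contacts(chain_a: PolymerChain, chain_b: PolymerChain,
                         config: PipelineConfig | None = None,
                         ) -> dict[str, object]:
    """All-pairs distance oracle for a chain pair (generator-side truth)."""
    config = config or PipelineConfig()
    pairs = {}
    for ra in chain_a.residues:
        pa = np.asarray([at.pos for at in ra.atoms])
        cba = ra.cbeta
        for rb in chain_b.residues:
            pb = np.asarray([at.pos for at in rb.atoms])
            d_atom = float(cdist(pa, pb).min())
            cbb = rb.cbeta
            d_cb = (float(np.linalg.norm(cba - cbb))
                    if cba is not None and cbb is not None else None)
            if d_atom <= config.atom_cutoff or \
                    (d_cb is not None and d_cb <= config.cbeta_cutoff):
                pairs[(ra.seq_pos, rb.seq_pos)] = (d_atom, d_cb)
    n_cb = sum(1 for _, cb in pairs.values()
               if cb is not None and cb <= config.cbeta_cutoff)
    n_at = sum(1 for d, _ in pairs.values() if d <= config.atom_cutoff)
    interacting = ((n_cb >= config.min_cbeta_pairs and n_at >= 1)
                   or n_at >= config.min_atom_contacts)
    return {"pairs": pairs, "n_cbeta12": n_cb, "n_atom5": n_at,
            "is_interacting": interacting}


# ---------------------------------------------------------------------------
# crystal assembly


def _p1_cell(chains: list[PolymerChain], padding: float,
             packing_gap: float | None) -> UnitCell:
    xyz = np.vstack([_chain_coords(c) for c in chains])
    extent = xyz.max(axis=0) - xyz.min(axis=0)
    gap_x = packing_gap if packing_gap is not None else padding
    return UnitCell(extent[0] + gap_x, extent[1] + padding,
                    extent[2] + padding, 90.0, 90.0, 90.0)


def _shift_to_origin(chains: list[PolymerChain]) -> None:
    xyz = np.vstack([_chain_coords(c) for c in chains])
    shift = -xyz.min(axis=0)
    for c in chains:
        for r in c.residues:
            for a in r.atoms:
                # quantized to mmCIF precision, so files round-trip exactly
                a.pos = np.round(a.pos + shift, 3)


def build_synthetic_crystal(spec: FixtureSpec,
                            entry_id: str | None = None,
                            sequence: str | None = None,
                            uniprot: str = "UP00001",
                            crowder_seq: str | None = None,
                            ) -> tuple[CrystalEntry, dict]:
    """One P1 (or P21) crystal around the designed dimer, plus its truth.

    In P1 the dimer sits in the asymmetric unit; with ``packing_gap`` set,
    the +a lattice neighbour makes one controlled packing contact, and
    with ``crowder_seq`` a third, unrelated chain C leans on the outer
    face of the dimer — a lattice contact whose partner differs between
    crystal forms.  In P21 a single chain is placed so that its screw
    image completes the dimer — the designed interface then exists only
    after lattice expansion, never inside the asymmetric unit.
    """
    seq, coords = generate_toy_fold(spec.n_res, spec.seed,
                                    sequence=sequence)
    entry_id = entry_id or f"{spec.entry_prefix}{spec.seed:04d}"
    config = PipelineConfig()

    if spec.space_group == "P 1 21 1":
        entry, truth = _build_p21_crystal(spec, entry_id, seq, coords,
                                          config)
    else:
        a, b = designed_dimer(seq, coords, spec.dimer_sep)
        chains = [a, b] if spec.include_dimer else [a]
        if crowder_seq is not None:
            _, ccoords = generate_toy_fold(len(crowder_seq),
                                           sequence=crowder_seq)
            outer_x = spec.dimer_sep if spec.include_dimer else 0.0
            crowd = make_chain("C", crowder_seq, ccoords,
                               transform=(np.eye(3),
                                          np.array([outer_x + 9.2,
                                                    0.0, 0.0])))
            chains.append(crowd)
        rot = _rot_z(spec.asu_rotation_deg)
        for c in chains:
            for r in c.residues:
                for at in r.atoms:
                    at.pos = rot @ at.pos
        _shift_to_origin(chains)
        cell = _p1_cell(chains, spec.cell_padding, spec.packing_gap)
        entry = CrystalEntry(
            entry_id=entry_id, cell=cell, space_group="P 1",
            sym_ops=[SymOp(np.eye(3), np.zeros(3))],
            chains=chains, ligands=[])
        truth = {"entry_id": entry_id, "space_group": "P 1",
                 "designed": None, "crowder_contact": None,
                 "has_packing": spec.packing_gap is not None}
        if spec.include_dimer:
            oracle = brute_force_contacts(a, b, config)
            if not oracle["is_interacting"]:
                raise ValueError(
                    "designed dimer fails the interaction rule; widen "
                    "dimer_sep tuning")
            truth["designed"] = {
                "pairs": sorted(map(list, oracle["pairs"])),
                "n_cbeta12": oracle["n_cbeta12"],
                "n_atom5": oracle["n_atom5"]}
        if crowder_seq is not None:
            partner = b if spec.include_dimer else a
            oracle = brute_force_contacts(partner, chains[-1], config)
            if not oracle["is_interacting"]:
                raise ValueError("crowder contact fails the rule")
            truth["crowder_contact"] = {
                "partner": partner.asym_id,
                "n_cbeta12": oracle["n_cbeta12"],
                "n_atom5": oracle["n_atom5"]}
    for c in entry.chains:
        c.uniprot = uniprot
        c.species = "synthetic"
    if crowder_seq is not None and entry.chains[-1].asym_id == "C":
        entry.chains[-1].uniprot = f"{uniprot}C"
    return entry, truth


def _build_p21_crystal(spec: FixtureSpec, entry_id: str, seq: str,
                       coords: dict, config: PipelineConfig):
    # helix axis along y, offset from the screw axis (x=0, z=0)
    rot = _rot_x(-90.0)
    half = spec.dimer_sep / 2.0
    a = make_chain("A", seq, coords,
                   transform=(rot, np.array([half, 0.0, 0.0])))
    for r in a.residues:
        for at in r.atoms:
            at.pos = np.round(at.pos, 3)
    span_y = float(np.ptp(_chain_coords(a)[:, 1]))
    cell = UnitCell(spec.cell_padding + 2 * half + 10.0,
                    2.0 * (span_y * 0.55),
                    spec.cell_padding + 10.0, 90.0, 90.0, 90.0)
    ops = [SymOp(np.eye(3), np.zeros(3)),
           SymOp(np.diag([-1.0, 1.0, -1.0]), np.array([0.0, 0.5, 0.0]))]
    entry = CrystalEntry(entry_id=entry_id, cell=cell,
                         space_group="P 1 21 1", sym_ops=ops,
                         chains=[a], ligands=[])
    # truth: the screw image of A completes the dimer
    orth = cell.orth_matrix()
    frac = cell.frac_matrix()
    rot2 = orth @ ops[1].rot @ frac
    tran2 = orth @ ops[1].tran
    img = _transformed_copy(a, "B", rot2, tran2)
    oracle = brute_force_contacts(a, img, config)
    if not oracle["is_interacting"]:
        raise ValueError("screw-axis dimer fails the interaction rule")
    truth = {"entry_id": entry_id, "space_group": "P 1 21 1",
             "designed": {"pairs": sorted(map(list, oracle["pairs"])),
                          "n_cbeta12": oracle["n_cbeta12"],
                          "n_atom5": oracle["n_atom5"]},
             "asu_only_designed": False,
             "has_packing": True}
    return entry, truth


def _transformed_copy(chain: PolymerChain, new_id: str,
                      rot: np.ndarray, tran: np.ndarray) -> PolymerChain:
    residues = []
    for r in chain.residues:
        atoms = [Atom(a.name, a.element, rot @ a.pos + tran,
                      a.occupancy, a.altloc) for a in r.atoms]
        residues.append(Residue(new_id, r.seq_pos, r.name, atoms,
                                auth_seq=r.auth_seq))
    return PolymerChain(asym_id=new_id, auth_id=new_id, entity_id="",
                        sequence=chain.sequence,
                        polymer_type=chain.polymer_type, residues=residues)


# ---------------------------------------------------------------------------
# annotations for fixtures


def identity_annotation_rows(entry: CrystalEntry, spec: FixtureSpec,
                             chains: list[str] | None = None) -> list[dict]:
    rows = []
    for c in entry.protein_chains:
        if chains is not None and c.asym_id not in chains:
            continue
        n = c.length
        rows.append({
            "entry_id": entry.entry_id, "asym_id": c.asym_id,
            "pfam_acc": spec.pfam_acc, "pfam_id": spec.pfam_id,
            "clan": "", "intervals": format_intervals([(1, n)]),
            "hmm_length": str(n),
            "hmm_map": format_hmm_map({i: i for i in range(1, n + 1)}),
            "uniprot": c.uniprot or "", "species": c.species or ""})
    return rows


def dimer_assembly_rows(entry: CrystalEntry,
                        chains: tuple[str, ...] = ("A", "B")) -> list[dict]:
    members = ";".join(f"{c.asym_id}:0:0,0,0"
                       for c in entry.protein_chains
                       if c.asym_id in chains)
    return [{"entry_id": entry.entry_id, "assembly_id": "1",
             "provenance": prov, "members": members}
            for prov in ("author", "pisa")]


# ---------------------------------------------------------------------------
# benchmark set


def generate_benchmark_set(spec: FixtureSpec, out_dir: str | Path,
                           add_dimerless_form: bool = False) -> dict:
    """k homologous crystal forms sharing the designed dimer.

    Each form mutates the parent sequence (same fold), rotates the
    asymmetric unit and varies the cell padding, and leans a
    form-specific unrelated crowder chain on the dimer's outer face, so
    the lattice contacts differ between forms while the designed
    interface recurs in all of them.  Optionally appends one form built
    without the dimer.  Writes mmCIF entries, the annotation and assembly
    tables and a truth record; returns the truth record.
    """
    if spec.n_homolog_forms < 2:
        raise ValueError("need at least two homolog forms")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    parent = random_sequence(spec.n_res, rng)
    ann_rows: list[dict] = []
    asm_rows: list[dict] = []
    truth: dict = {"forms": [], "expected_top_cluster":
                   {"n_crystal_forms": spec.n_homolog_forms,
                    "n_entries": spec.n_homolog_forms},
                   "dimerless_entry": None}
    n_total = spec.n_homolog_forms + (1 if add_dimerless_form else 0)
    for i in range(n_total):
        dimerless = add_dimerless_form and i == spec.n_homolog_forms
        seq = parent if i == 0 else mutate_sequence(
            parent, spec.mutation_rate, rng)
        form_spec = FixtureSpec(
            seed=spec.seed, n_res=spec.n_res,
            dimer_sep=spec.dimer_sep,
            cell_padding=spec.cell_padding + 2.5 * i,
            packing_gap=None,
            asu_rotation_deg=55.0 * i,
            include_dimer=not dimerless,
            pfam_acc=spec.pfam_acc, pfam_id=spec.pfam_id)
        entry_id = f"{spec.entry_prefix}{i + 1:03d}"
        crowder = random_sequence(spec.n_res + 3,
                                  np.random.default_rng(spec.seed
                                                        + 100 + i))
        entry, etruth = build_synthetic_crystal(
            form_spec, entry_id=entry_id, sequence=seq,
            uniprot=f"UP{i + 1:05d}", crowder_seq=crowder)
        write_entry(entry, out_dir / f"{entry_id}.cif")
        ann_rows.extend(identity_annotation_rows(
            entry, spec, chains=["A"] if dimerless else ["A", "B"]))
        if not dimerless:
            asm_rows.extend(dimer_assembly_rows(entry))
        etruth["sequence"] = seq
        truth["forms"].append(etruth)
        if dimerless:
            truth["dimerless_entry"] = entry_id
    pd.DataFrame(ann_rows, columns=ANNOTATION_COLUMNS).to_csv(
        out_dir / "annotations.tsv", sep="\t", index=False)
    pd.DataFrame(asm_rows, columns=ASSEMBLY_COLUMNS).to_csv(
        out_dir / "assemblies.tsv", sep="\t", index=False)
    (out_dir / "truth.json").write_text(json.dumps(truth, indent=1))
    return truth


# ---------------------------------------------------------------------------
# monomer-ASU vs dimer-ASU pair (crystal-form merging)


def build_merge_pair(seed: int = 0, spec: FixtureSpec | None = None,
                     ) -> tuple[list[CrystalEntry], list[dict]]:
    """The same lattice solved two ways: monomeric and dimeric ASU.

    Entry 1 is P1 with one chain and a tight a-edge, so the +a neighbour
    makes the only interface.  Entry 2 doubles the a-edge and deposits
    the chain plus its +a copy as a two-chain asymmetric unit.  The two
    lattices — hence their interface censuses — are identical, which is
    exactly the situation the two-thirds merging rule exists for.
    """
    spec = spec or FixtureSpec(seed=seed, packing_gap=3.2)
    seq, coords = generate_toy_fold(spec.n_res, spec.seed)
    a1 = make_chain("A", seq, coords)
    _shift_to_origin([a1])
    cell1 = _p1_cell([a1], spec.cell_padding, spec.packing_gap)
    e1 = CrystalEntry(entry_id="XM001", cell=cell1, space_group="P 1",
                      sym_ops=[SymOp(np.eye(3), np.zeros(3))],
                      chains=[a1], ligands=[])
    a2 = _transformed_copy(a1, "A", np.eye(3), np.zeros(3))
    b2 = _transformed_copy(a1, "B", np.eye(3),
                           np.array([cell1.a, 0.0, 0.0]))
    cell2 = UnitCell(2.0 * cell1.a, cell1.b, cell1.c, 90.0, 90.0, 90.0)
    e2 = CrystalEntry(entry_id="XM002", cell=cell2, space_group="P 1",
                      sym_ops=[SymOp(np.eye(3), np.zeros(3))],
                      chains=[a2, b2], ligands=[])
    rows = []
    for e in (e1, e2):
        for c in e.chains:
            c.uniprot = "UPM0001"
            c.species = "synthetic"
        rows.extend(identity_annotation_rows(e, spec))
    return [e1, e2], rows


# ---------------------------------------------------------------------------
# peptide fixtures


def build_peptide_complex(mode: str = "plus", pep_len: int = 8,
                          lead_extra: int = 0, domain_len: int = 34,
                          seed: int = 0, entry_id: str = "XP001",
                          spec: FixtureSpec | None = None,
                          z_offset: float = 0.0,
                          ) -> tuple[CrystalEntry, list[dict]]:
    """A domain with a peptide bound on one of two opposite faces.

    ``mode`` "plus" places the peptide groove-side at +x, "minus" at -x
    (the opposite face, ~17 A away, a distinct binding mode).
    ``lead_extra`` prepends residues to the peptide without moving the
    shared part, so two complexes differing only in ``lead_extra`` have
    peptide RMSD 0 at that alignment offset.
    """
    spec = spec or FixtureSpec(seed=seed)
    dom_seq, dom_coords = generate_toy_fold(domain_len, seed)
    dom = make_chain("A", dom_seq, dom_coords)
    total = pep_len + lead_extra
    # slice the peptide out of one master helix so the shared C-terminal
    # window keeps identical coordinates whatever lead_extra is
    master_len = 16
    if total > master_len:
        raise ValueError("peptide too long for the master helix")
    master_seq = random_sequence(master_len, np.random.default_rng(seed + 7))
    _, master = generate_toy_fold(master_len, sequence=master_seq)
    start = master_len - total
    pep_seq = master_seq[start:]
    sign = 1.0 if mode == "plus" else -1.0
    shift = np.array([sign * 8.0, 0.0, z_offset])
    pep_coords = {k: v[start:] + shift for k, v in master.items()}
    pep = make_chain("P", pep_seq, pep_coords)
    chains = [dom, pep]
    _shift_to_origin(chains)
    cell = _p1_cell(chains, 40.0, None)
    entry = CrystalEntry(entry_id=entry_id, cell=cell, space_group="P 1",
                         sym_ops=[SymOp(np.eye(3), np.zeros(3))],
                         chains=chains, ligands=[])
    dom.uniprot = f"UPD{seed:04d}"
    rows = identity_annotation_rows(entry, spec, chains=["A"])
    return entry, rows


# ---------------------------------------------------------------------------
# ligand / nucleic fixtures


def _site_ligand(chain: PolymerChain, residues: list[int], comp_id: str,
                 ligand_id: str, distance: float = 2.2) -> LigandInstance:
    """Pseudo-ligand: one atom beyond each named residue's C-beta."""
    atoms = []
    for i, seq_pos in enumerate(residues):
        res = chain.residues[seq_pos - 1]
        ca = res.atom("CA").pos
        cb = res.atom("CB").pos
        u = (cb - ca) / np.linalg.norm(cb - ca)
        atoms.append(Atom(name=f"C{i + 1}", element="C",
                          pos=cb + distance * u))
    return LigandInstance(comp_id=comp_id, atoms=atoms, is_water=False,
                          ligand_id=ligand_id, chain_ref="L")


def build_ligand_entry(seed: int = 0, entry_id: str = "XL001",
                       domain_len: int = 30,
                       spec: FixtureSpec | None = None,
                       with_water: bool = True,
                       ) -> tuple[CrystalEntry, list[dict]]:
    """A domain with two designed, disjoint ligand contact sites.

    Site 1 sits at the N-terminal end (residues 4-7), site 2 at the
    C-terminal end (residues 24-27, ~30 A away); each site carries one
    cofactor-like pseudo-ligand.  A water molecule placed inside site 1
    checks the water-exclusion rule.
    """
    spec = spec or FixtureSpec(seed=seed)
    seq, coords = generate_toy_fold(domain_len, seed)
    dom = make_chain("A", seq, coords)
    lig1 = _site_ligand(dom, [4, 5, 6, 7], "LG1", "LG1_L_901")
    lig2 = _site_ligand(dom, [24, 25, 26, 27], "LG2", "LG2_L_902")
    ligands = [lig1, lig2]
    if with_water:
        w_pos = lig1.atoms[0].pos + np.array([0.0, 1.0, 0.0])
        ligands.append(LigandInstance(
            comp_id="HOH", atoms=[Atom("O", "O", w_pos)], is_water=True,
            ligand_id="HOH_L_903", chain_ref="L"))
    cell = _p1_cell([dom], 40.0, None)
    entry = CrystalEntry(entry_id=entry_id, cell=cell, space_group="P 1",
                         sym_ops=[SymOp(np.eye(3), np.zeros(3))],
                         chains=[dom], ligands=ligands)
    dom.uniprot = f"UPL{seed:04d}"
    rows = identity_annotation_rows(entry, spec)
    return entry, rows


def _dna_chain(asym_id: str, n_res: int, origin: np.ndarray,
               seed: int = 0) -> PolymerChain:
    """Pseudo-DNA: P and C1' atoms on a straight 3.4 A-rise ladder."""
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=n_res))
    residues = []
    for i in range(n_res):
        base = origin + np.array([0.0, 0.0, 3.4 * i])
        atoms = [Atom("P", "P", base),
                 Atom("C1'", "C", base + np.array([1.2, 0.8, 0.0]))]
        residues.append(Residue(asym_id, i + 1,
                                three_letter(seq[i], "DNA"), atoms,
                                auth_seq=i + 1))
    return PolymerChain(asym_id=asym_id, auth_id=asym_id, entity_id="",
                        sequence=seq, polymer_type="DNA",
                        residues=residues)


def build_nucleic_entry(seed: int = 0, entry_id: str = "XN001",
                        domain_len: int = 30, tie: bool = False,
                        spec: FixtureSpec | None = None,
                        ) -> tuple[CrystalEntry, list[dict]]:
    """A domain flanked by two DNA duplex stand-ins in two assemblies.

    Chain D hugs the domain (many contacted model positions), chain E is
    farther out (few positions); assembly 1 holds A+D, assembly 2 A+E.
    With ``tie=True`` both DNA chains are placed symmetrically so the two
    assemblies contact the same number of positions.
    """
    spec = spec or FixtureSpec(seed=seed)
    seq, coords = generate_toy_fold(domain_len, seed)
    dom = make_chain("A", seq, coords)
    z0 = min(r.atom("CA").pos[2] for r in dom.residues)
    near = _dna_chain("D", 10, np.array([6.5, 0.0, z0]), seed)
    if tie:
        # co-located duplicate: both assemblies contact the same positions
        far = _dna_chain("E", 10, np.array([6.5, 0.0, z0]), seed + 1)
    else:
        far = _dna_chain("E", 10, np.array([-8.8, 0.0, z0 + 20.0]),
                         seed + 1)
    chains = [dom, near, far]
    _shift_to_origin(chains)
    cell = _p1_cell(chains, 40.0, None)
    entry = CrystalEntry(
        entry_id=entry_id, cell=cell, space_group="P 1",
        sym_ops=[SymOp(np.eye(3), np.zeros(3))],
        chains=chains, ligands=[],
        assemblies=[])
    entry.assemblies.extend([
        # assembly ids sort lexicographically: ties resolve to "1"
        AssemblyDef("1", "author",
                    [("A", 0, (0, 0, 0)), ("D", 0, (0, 0, 0))]),
        AssemblyDef("2", "author",
                    [("A", 0, (0, 0, 0)), ("E", 0, (0, 0, 0))]),
    ])
    dom.uniprot = f"UPN{seed:04d}"
    rows = identity_annotation_rows(entry, spec, chains=["A"])
    return entry, rows
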