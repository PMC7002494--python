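"""Residue contacts, interaction rules, unique-interface census and BSA.

Two chains (or domains) interact iff they have at least ten C-beta pairs
within 12 A and at least one atomic contact within 5 A, or at least five
atomic contacts within 5 A.  Interfaces are enumerated between the identity
asymmetric-unit copies and every placement of the 27-cell lattice block,
then symmetry-equivalent duplicates are collapsed: two interfaces of one
crystal are equivalent iff their residue-level contact sets map onto each
other under the identity sequence correspondence (Q = 1).

Buried surface area is half the solvent-accessible area lost on
complexation, computed with the package's deterministic Shrake-Rupley
sampler.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .config import PipelineConfig
from .geometry import shrake_rupley_sasa, vdw_radius
from .lattice import (SymmetryPlacement, candidate_pairs,
                      identity_placements)
from .structure_model import (AssemblyDef, CrystalEntry, DomainInstance,
                              PolymerChain)


# ---------------------------------------------------------------------------
# placed units


@dataclass
class PlacedUnit:
    """A chain (or a domain slice of a chain) under a symmetry placement."""
    chain: PolymerChain
    placement: SymmetryPlacement
    domain: DomainInstance | None = None

    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def label(self) -> str:
        base = self.placement.label()
        return f"{base}[{self.domain.domain_id}]" if self.domain else base

    @property
    def key(self):
        return (self.placement.key,
                self.domain.domain_id if self.domain else "")

    def _allowed(self, seq_pos: int) -> bool:
        return self.domain is None or self.domain.contains(seq_pos)

    def heavy(self) -> tuple[np.ndarray, np.ndarray]:
        """(coords, seq_pos array) of heavy atoms, placement applied."""
        if "heavy" not in self._cache:
            coords, ridx = self.chain.heavy_coords()
            seq = np.asarray([r.seq_pos for r in self.chain.residues])
            if len(coords):
                keep = np.asarray([self._allowed(seq[i]) for i in ridx])
                coords, ridx = coords[keep], ridx[keep]
            self._cache["heavy"] = (self.placement.apply(coords), seq[ridx])
        return self._cache["heavy"]

    def cbeta(self) -> tuple[np.ndarray, np.ndarray]:
        if "cbeta" not in self._cache:
            coords, ridx = self.chain.cbeta_coords()
            seq = np.asarray([r.seq_pos for r in self.chain.residues])
            if len(coords):
                keep = np.asarray([self._allowed(seq[i]) for i in ridx])
                coords, ridx = coords[keep], ridx[keep]
            self._cache["cbeta"] = (self.placement.apply(coords), seq[ridx])
        return self._cache["cbeta"]

    def residue_atoms(self, seq_pos: int) -> np.ndarray:
        coords, seq = self.heavy()
        return coords[seq == seq_pos]

    def sasa_inputs(self) -> tuple[np.ndarray, np.ndarray]:
        if "sasa_in" not in self._cache:
            coords, radii = [], []
            for res in self.chain.residues:
                if not self._allowed(res.seq_pos):
                    continue
                for a in res.atoms:
                    coords.append(a.pos)
                    radii.append(vdw_radius(a.element))
            coords = (self.placement.apply(np.asarray(coords))
                      if coords else np.empty((0, 3)))
            self._cache["sasa_in"] = (coords, np.asarray(radii))
        return self._cache["sasa_in"]


# ---------------------------------------------------------------------------
# contact sets


@dataclass
class ContactSet:
    """Residue-pair contacts between two placed units.

    ``pairs`` maps (seq_pos_a, seq_pos_b) to (min atomic distance,
    C-beta distance or None).  A pair is listed when its minimum heavy-atom
    distance is within ``atom_cutoff`` or its C-beta distance within
    ``cbeta_cutoff``.
    """
    pairs: dict[tuple[int, int], tuple[float, float | None]]
    atom_cutoff: float
    cbeta_cutoff: float

    @property
    def n_atom5(self) -> int:
        return sum(1 for d, _ in self.pairs.values()
                   if d <= self.atom_cutoff)

    @property
    def n_cbeta12(self) -> int:
        return sum(1 for _, cb in self.pairs.values()
                   if cb is not None and cb <= self.cbeta_cutoff)

    def transpose(self) -> "ContactSet":
        return ContactSet({(j, i): v for (i, j), v in self.pairs.items()},
                          self.atom_cutoff, self.cbeta_cutoff)

    def restrict(self, side_a: set[int], side_b: set[int]) -> "ContactSet":
        return ContactSet(
            {(i, j): v for (i, j), v in self.pairs.items()
             if i in side_a and j in side_b},
            self.atom_cutoff, self.cbeta_cutoff)

    def __len__(self) -> int:
        return len(self.pairs)


def _min_dist(pts_a: np.ndarray, pts_b: np.ndarray) -> float:
    d2 = ((pts_a[:, None, :] - pts_b[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.min()))


def contact_set(unit_a: PlacedUnit, unit_b: PlacedUnit,
                config: PipelineConfig | None = None) -> ContactSet:
    """All residue pairs within the atomic or C-beta cutoff.

    Neighbor search uses k-d trees on the heavy atoms and on the C-beta
    (CA-surrogate for glycine) arrays; each listed pair carries its exact
    minimum heavy-atom distance.
    """
    config = config or PipelineConfig()
    ca, seq_a = unit_a.heavy()
    cb, seq_b = unit_b.heavy()
    if len(ca) == 0 or len(cb) == 0:
        raise ValueError("contact_set requires heavy atoms on both units")

    pairs: dict[tuple[int, int], tuple[float, float | None]] = {}
    tree_a = cKDTree(ca)
    tree_b = cKDTree(cb)
    min_atom: dict[tuple[int, int], float] = {}
    dist_mat = tree_a.sparse_distance_matrix(tree_b, config.atom_cutoff,
                                             output_type="coo_matrix")
    for ai, bi, d in zip(dist_mat.row, dist_mat.col, dist_mat.data):
        key = (int(seq_a[ai]), int(seq_b[bi]))
        if d < min_atom.get(key, np.inf):
            min_atom[key] = float(d)

    cba, cbseq_a = unit_a.cbeta()
    cbb, cbseq_b = unit_b.cbeta()
    cb_dist: dict[tuple[int, int], float] = {}
    if len(cba) and len(cbb):
        ctree_a = cKDTree(cba)
        ctree_b = cKDTree(cbb)
        cmat = ctree_a.sparse_distance_matrix(ctree_b, config.cbeta_cutoff,
                                              output_type="coo_matrix")
        for ai, bi, d in zip(cmat.row, cmat.col, cmat.data):
            cb_dist[(int(cbseq_a[ai]), int(cbseq_b[bi]))] = float(d)
        cb_pos_a = {int(s): c for s, c in zip(cbseq_a, cba)}
        cb_pos_b = {int(s): c for s, c in zip(cbseq_b, cbb)}
    else:
        cb_pos_a, cb_pos_b = {}, {}

    for key in set(min_atom) | set(cb_dist):
        i, j = key
        if key in min_atom:
            d_atom = min_atom[key]
        else:
            d_atom = _min_dist(unit_a.residue_atoms(i),
                               unit_b.residue_atoms(j))
        if key in cb_dist:
            d_cb = cb_dist[key]
        elif i in cb_pos_a and j in cb_pos_b:
            d_cb = float(np.linalg.norm(cb_pos_a[i] - cb_pos_b[j]))
        else:
            d_cb = None
        pairs[key] = (d_atom, d_cb)
    return ContactSet(pairs, config.atom_cutoff, config.cbeta_cutoff)


def is_interacting(contacts: ContactSet, level: str = "chain",
                   config: PipelineConfig | None = None) -> bool:
    """The chain/domain interaction rule (identical at both levels):
    (>= 10 C-beta pairs <= 12 A AND >= 1 atomic contact <= 5 A)
    OR >= 5 atomic contacts <= 5 A."""
    config = config or PipelineConfig()
    return ((contacts.n_cbeta12 >= config.min_cbeta_pairs
             and contacts.n_atom5 >= 1)
            or contacts.n_atom5 >= config.min_atom_contacts)


# ---------------------------------------------------------------------------
# interfaces


@dataclass
class Interface:
    interface_id: str
    entry_id: str
    level: str  # chain | domain
    unit_a: PlacedUnit
    unit_b: PlacedUnit
    contacts: ContactSet
    intra_chain: bool = False
    bsa: float | None = None
    below_bsa: bool = False
    in_author_assembly: bool | None = None
    in_pisa_assembly: bool | None = None
    cluster_id: str | None = None

    def signature(self) -> frozenset:
        """Contact-set signature under the identity sequence correspondence.

        Residues are tagged by (entity sequence, seq_pos), so copies of the
        same molecule compare positionally regardless of chain naming; each
        contact is a canonically sorted tag pair.  Equal signatures define
        symmetry-equivalent (duplicate) interfaces within one crystal.
        """
        sa = self.unit_a.chain.sequence
        sb = self.unit_b.chain.sequence
        out = set()
        for (i, j) in self.contacts.pairs:
            t1, t2 = (sa, i), (sb, j)
            out.add((t1, t2) if t1 <= t2 else (t2, t1))
        return frozenset(out)

    @property
    def family_key(self) -> tuple[str, str]:
        """Canonical (sorted) family or architecture pair of the sides."""
        if self.level == "domain":
            ka = self.unit_a.domain.pfam_acc
            kb = self.unit_b.domain.pfam_acc
        else:
            ka = getattr(self.unit_a, "arch_string", "")
            kb = getattr(self.unit_b, "arch_string", "")
        return tuple(sorted((ka, kb)))  # type: ignore[return-value]


def identity_q(a: Interface, b: Interface) -> float:
    """Jaccard similarity of the identity-correspondence signatures."""
    sa, sb = a.signature(), b.signature()
    union = sa | sb
    if not union:
        raise ValueError("Q undefined for two empty contact sets")
    return len(sa & sb) / len(union)


def buried_surface_area(interface: Interface,
                        config: PipelineConfig | None = None) -> float:
    """(SASA_a + SASA_b - SASA_ab) / 2, clamped at zero."""
    config = config or PipelineConfig()
    ca, ra = interface.unit_a.sasa_inputs()
    cb, rb = interface.unit_b.sasa_inputs()
    if len(ca) == 0 or len(cb) == 0:
        raise ValueError("buried_surface_area requires heavy atoms")
    kw = dict(probe=config.sasa_probe, n_points=config.sasa_points)
    sa = shrake_rupley_sasa(ca, ra, **kw).sum()
    sb = shrake_rupley_sasa(cb, rb, **kw).sum()
    sab = shrake_rupley_sasa(np.vstack([ca, cb]),
                             np.concatenate([ra, rb]), **kw).sum()
    return max(0.0, (sa + sb - sab) / 2.0)


def _unit_sort_key(u: PlacedUnit):
    return u.key


def _make_interface(entry_id: str, level: str, ua: PlacedUnit,
                    ub: PlacedUnit, contacts: ContactSet,
                    intra: bool = False) -> Interface:
    if _unit_sort_key(ub) < _unit_sort_key(ua):
        ua, ub = ub, ua
        contacts = contacts.transpose()
    iid = f"{entry_id}:{level}:{ua.label}--{ub.label}"
    return Interface(interface_id=iid, entry_id=entry_id, level=level,
                     unit_a=ua, unit_b=ub, contacts=contacts,
                     intra_chain=intra)


def enumerate_unique_interfaces(
        entry: CrystalEntry,
        placements: list[SymmetryPlacement],
        level: str = "chain",
        config: PipelineConfig | None = None,
        domains: list[DomainInstance] | None = None,
        architectures: dict | None = None,
        compute_bsa: bool = True) -> list[Interface]:
    """Census of unique interacting interfaces touching the identity ASU.

    Pairs are generated between identity asymmetric-unit placements and all
    lattice placements (bounding-box pruned), the interaction rule applied,
    and symmetry-equivalent duplicates collapsed to the lexicographically
    smallest representative.  At domain level, interfaces are derived from
    the chain-level contact sets by the family-defined residue intervals,
    and intra-chain domain pairs are included with ``intra_chain=True``.

    Interfaces burying less than the level's minimum area keep a
    ``below_bsa`` flag (they stay in the census but are excluded from
    clustering).
    """
    config = config or PipelineConfig()
    if level not in ("chain", "domain"):
        raise ValueError(f"bad level {level!r}")
    if level == "domain" and domains is None:
        raise ValueError("domain-level enumeration needs annotations")
    chains = {c.asym_id: c for c in entry.chains
              if c.polymer_type == "polypeptide"
              and c.length >= config.peptide_max_len}
    doms_by_chain: dict[str, list[DomainInstance]] = {}
    for d in (domains or []):
        doms_by_chain.setdefault(d.chain_ref, []).append(d)
    for lst in doms_by_chain.values():
        lst.sort(key=lambda d: d.start)

    raw: list[Interface] = []
    pairs = candidate_pairs(entry, placements,
                            prune_radius=config.prune_radius)
    for ref, other in pairs:
        if ref.source_chain not in chains or \
           other.source_chain not in chains:
            continue
        ua = PlacedUnit(chains[ref.source_chain], ref)
        ub = PlacedUnit(chains[other.source_chain], other)
        cs = contact_set(ua, ub, config)
        if not cs.pairs:
            continue
        if level == "chain":
            if is_interacting(cs, level, config):
                raw.append(_make_interface(entry.entry_id, level, ua, ub, cs))
        else:
            for da in doms_by_chain.get(ref.source_chain, []):
                for db in doms_by_chain.get(other.source_chain, []):
                    sub = cs.restrict(da.seq_positions(), db.seq_positions())
                    if sub.pairs and is_interacting(sub, level, config):
                        raw.append(_make_interface(
                            entry.entry_id, level,
                            PlacedUnit(ua.chain, ua.placement, da),
                            PlacedUnit(ub.chain, ub.placement, db), sub))
    if level == "domain":
        # intra-chain domain pairs, identity copies only
        for p in identity_placements(placements):
            doms = doms_by_chain.get(p.source_chain, [])
            if p.source_chain not in chains:
                continue
            for i in range(len(doms)):
                for j in range(i + 1, len(doms)):
                    ua = PlacedUnit(chains[p.source_chain], p, doms[i])
                    ub = PlacedUnit(chains[p.source_chain], p, doms[j])
                    cs = contact_set(ua, ub, config)
                    if cs.pairs and is_interacting(cs, "domain", config):
                        raw.append(_make_interface(
                            entry.entry_id, "domain", ua, ub, cs,
                            intra=True))

    unique = _deduplicate(raw)
    if architectures:
        for iface in unique:
            iface.unit_a.arch_string = architectures.get(
                iface.unit_a.chain.asym_id).arch_string \
                if architectures.get(iface.unit_a.chain.asym_id) else ""
            iface.unit_b.arch_string = architectures.get(
                iface.unit_b.chain.asym_id).arch_string \
                if architectures.get(iface.unit_b.chain.asym_id) else ""
    if compute_bsa:
        min_bsa = (config.min_bsa_chain if level == "chain"
                   else config.min_bsa_domain)
        for iface in unique:
            iface.bsa = buried_surface_area(iface, config)
            iface.below_bsa = iface.bsa < min_bsa
    return unique


def _deduplicate(raw: list[Interface]) -> list[Interface]:
    by_sig: dict[frozenset, Interface] = {}
    for iface in raw:
        sig = iface.signature()
        prev = by_sig.get(sig)
        if prev is None or (
                (_unit_sort_key(iface.unit_a), _unit_sort_key(iface.unit_b))
                < (_unit_sort_key(prev.unit_a), _unit_sort_key(prev.unit_b))):
            by_sig[sig] = iface
    return sorted(by_sig.values(), key=lambda f: f.interface_id)


# ---------------------------------------------------------------------------
# assemblies


def instantiate_assembly(entry: CrystalEntry, assembly: AssemblyDef,
                         ) -> list[PlacedUnit]:
    """Placed chain copies of a biological-assembly definition."""
    entry.require_crystallographic() if any(
        op != 0 or shift != (0, 0, 0)
        for _, op, shift in assembly.members) else None
    units = []
    orth = entry.cell.orth_matrix() if entry.cell else np.eye(3)
    frac = entry.cell.frac_matrix() if entry.cell else np.eye(3)
    for asym, op_idx, shift in assembly.members:
        try:
            chain = entry.chain(asym)
        except KeyError as exc:
            raise ValueError(
                f"assembly {assembly.assembly_id}: {exc}") from exc
        if op_idx == 0 and shift == (0, 0, 0):
            rot, tran = np.eye(3), np.zeros(3)
        else:
            op = entry.sym_ops[op_idx]
            rot = orth @ op.rot @ frac
            tran = orth @ (op.tran + np.asarray(shift, float))
        units.append(PlacedUnit(chain, SymmetryPlacement(
            source_chain=asym, op_index=op_idx, shift=tuple(shift),
            rot=tuple(map(tuple, rot)), tran=tuple(tran))))
    return units


def assembly_interfaces(entry: CrystalEntry, assembly: AssemblyDef,
                        config: PipelineConfig | None = None,
                        ) -> list[Interface]:
    config = config or PipelineConfig()
    units = [u for u in instantiate_assembly(entry, assembly)
             if u.chain.polymer_type == "polypeptide"]
    out = []
    for i in range(len(units)):
        for j in range(i + 1, len(units)):
            cs = contact_set(units[i], units[j], config)
            if cs.pairs and is_interacting(cs, "chain", config):
                out.append(_make_interface(entry.entry_id, "chain",
                                           units[i], units[j], cs))
    return out


def assembly_contains_interface(interface: Interface,
                                assembly: AssemblyDef,
                                entry: CrystalEntry,
                                config: PipelineConfig | None = None,
                                ) -> bool:
    """True iff the instantiated assembly holds an interface with
    Q >= q_high against the query (identity correspondence)."""
    config = config or PipelineConfig()
    for aiface in assembly_interfaces(entry, assembly, config):
        if identity_q(interface, aiface) >= config.q_high:
            return True
    return False


def flag_assembly_presence(interfaces: list[Interface],
                           entry: CrystalEntry,
                           config: PipelineConfig | None = None) -> None:
    """Fill in_author_assembly / in_pisa_assembly for chain interfaces."""
    config = config or PipelineConfig()
    by_prov: dict[str, list[AssemblyDef]] = {"author": [], "pisa": []}
    for asm in entry.assemblies:
        by_prov[asm.provenance].append(asm)
    cache: dict[str, list[Interface]] = {}
    for prov, asms in by_prov.items():
        cache[prov] = []
        for asm in asms:
            cache[prov].extend(assembly_interfaces(entry, asm, config))
    for iface in interfaces:
        for prov, attr in (("author", "in_author_assembly"),
                           ("pisa", "in_pisa_assembly")):
            if not by_prov[prov]:
                setattr(iface, attr, None)
                continue
            hit = any(identity_q(iface, ai) >= config.q_high
                      for ai in cache[prov])
            setattr(iface, attr, hit)
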