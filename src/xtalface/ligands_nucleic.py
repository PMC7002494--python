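"""Domain-ligand and domain-nucleic-acid contact profiles.

Any non-polymer component except water is a ligand; a ligand interaction
is at least one atomic contact within 4.5 A between a domain and the
ligand, computed on the asymmetric unit.  Each interaction is profiled by
the family-model (HMM) positions it contacts, and ligands of one family
are clustered by the overlap of those position sets, which separates,
e.g., substrate sites from allosteric sites.

Nucleic-acid chains flow through the same contact machinery but are taken
from the biological assemblies, keeping for each domain the interface
contacting the largest number of model positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .config import PipelineConfig
from .geometry import apply_rigid
from .interfaces import PlacedUnit, instantiate_assembly
from .lattice import SymmetryPlacement
from .peptides import superpose_by_hmm
from .structure_model import (CrystalEntry, DomainInstance, LigandInstance,
                              PolymerChain)

logger = logging.getLogger(__name__)


def _identity_unit(chain: PolymerChain,
                   domain: DomainInstance | None = None) -> PlacedUnit:
    return PlacedUnit(chain, SymmetryPlacement(
        chain.asym_id, 0, (0, 0, 0),
        tuple(map(tuple, np.eye(3))), (0.0, 0.0, 0.0)), domain)


@dataclass
class LigandContactProfile:
    pfam: str
    ligand_key: str  # component code, or DNA | RNA
    entry_id: str
    domain: DomainInstance
    ligand_ref: str
    hmm_positions: frozenset[int]
    n_atomic_contacts: int
    assembly_id: str | None = None


def ligand_contact_profile(entry: CrystalEntry, domain: DomainInstance,
                           ligand: LigandInstance,
                           config: PipelineConfig | None = None,
                           ) -> LigandContactProfile | None:
    """Contacted model positions of one domain-ligand pair, or None.

    Water is never profiled; a profile exists only if some heavy-atom pair
    is within the 4.5 A ligand cutoff.
    """
    config = config or PipelineConfig()
    if ligand.is_water:
        return None
    lig_xyz = ligand.coords()
    if len(lig_xyz) == 0:
        return None
    unit = _identity_unit(entry.chain(domain.chain_ref), domain)
    dom_xyz, dom_seq = unit.heavy()
    if len(dom_xyz) == 0:
        return None
    pairs = cKDTree(dom_xyz).sparse_distance_matrix(
        cKDTree(lig_xyz), config.ligand_cutoff, output_type="coo_matrix")
    if pairs.nnz == 0:
        return None
    touched = {int(dom_seq[i]) for i in pairs.row}
    positions = frozenset(domain.hmm_map[p] for p in touched
                          if p in domain.hmm_map)
    return LigandContactProfile(
        pfam=domain.pfam_acc, ligand_key=ligand.comp_id,
        entry_id=entry.entry_id, domain=domain,
        ligand_ref=ligand.ligand_id or ligand.comp_id,
        hmm_positions=positions, n_atomic_contacts=int(pairs.nnz))


def profile_entry_ligands(entry: CrystalEntry,
                          domains: list[DomainInstance],
                          config: PipelineConfig | None = None,
                          ) -> list[LigandContactProfile]:
    out = []
    for dom in domains:
        for lig in entry.ligands:
            prof = ligand_contact_profile(entry, dom, lig, config)
            if prof is not None:
                out.append(prof)
    return out


@dataclass
class LigandSiteCluster:
    cluster_id: str
    pfam: str
    members: list[LigandContactProfile]
    consensus_positions: frozenset[int] = frozenset()
    ligand_groups: tuple[str, ...] = ()

    def finalize(self) -> None:
        sites = None
        for m in self.members:
            sites = (m.hmm_positions if sites is None
                     else sites & m.hmm_positions)
        self.consensus_positions = sites or frozenset()
        self.ligand_groups = tuple(sorted({m.ligand_key
                                           for m in self.members}))


def _jaccard(a: frozenset, b: frozenset) -> float:
    union = a | b
    return len(a & b) / len(union) if union else 0.0


def cluster_ligand_sites(profiles: list[LigandContactProfile],
                         config: PipelineConfig | None = None,
                         ) -> list[LigandSiteCluster]:
    """Average-linkage clustering of ligand instances of one family by
    Jaccard overlap of their contacted model positions."""
    config = config or PipelineConfig()
    if not profiles:
        return []
    fams = {p.pfam for p in profiles}
    if len(fams) != 1:
        raise ValueError("profiles must belong to a single family")
    fam = fams.pop()
    members = sorted(profiles,
                     key=lambda p: (p.entry_id, p.ligand_ref,
                                    p.domain.domain_id))
    n = len(members)
    sim = np.zeros((n, n))
    for i in range(n):
        sim[i, i] = 1.0
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = _jaccard(members[i].hmm_positions,
                                             members[j].hmm_positions)
    from .clustering import average_linkage_cluster
    idx_clusters = average_linkage_cluster(
        sim, threshold=config.ligand_site_jaccard,
        member_ids=[f"{m.entry_id}:{m.ligand_ref}:{m.domain.domain_id}"
                    for m in members])
    out = []
    for ci, idxs in enumerate(idx_clusters, start=1):
        cl = LigandSiteCluster(cluster_id=f"{fam}:lig:{ci}", pfam=fam,
                               members=[members[k] for k in idxs])
        cl.finalize()
        out.append(cl)
    return out


# ---------------------------------------------------------------------------
# nucleic acids


def _nucleic_profile(entry: CrystalEntry, dom_unit: PlacedUnit,
                     nuc_unit: PlacedUnit,
                     config: PipelineConfig) -> tuple[frozenset[int], int]:
    dom_xyz, dom_seq = dom_unit.heavy()
    nuc_xyz, _ = nuc_unit.heavy()
    if len(dom_xyz) == 0 or len(nuc_xyz) == 0:
        return frozenset(), 0
    pairs = cKDTree(dom_xyz).sparse_distance_matrix(
        cKDTree(nuc_xyz), config.ligand_cutoff, output_type="coo_matrix")
    if pairs.nnz == 0:
        return frozenset(), 0
    touched = {int(dom_seq[i]) for i in pairs.row}
    dom = dom_unit.domain
    return (frozenset(dom.hmm_map[p] for p in touched if p in dom.hmm_map),
            int(pairs.nnz))


def select_nucleic_interface(entry: CrystalEntry,
                             domains: list[DomainInstance],
                             config: PipelineConfig | None = None,
                             ) -> list[LigandContactProfile]:
    """Per domain instance, the nucleic-acid interface contacting the most
    model positions, taken from the biological assemblies.

    Without any assembly definition the asymmetric unit is used instead
    (with a warning).  Ties go to the smallest (assembly id, chain id).
    """
    config = config or PipelineConfig()
    nuc_chains = entry.nucleic_chains
    if not nuc_chains:
        return []
    assemblies = entry.assemblies
    if not assemblies:
        logger.warning(
            "entry %s has no assembly definitions; selecting "
            "domain-nucleic interfaces from the asymmetric unit",
            entry.entry_id)
    out = []
    for dom in domains:
        best = None
        if assemblies:
            for asm in sorted(assemblies, key=lambda a: a.assembly_id):
                units = instantiate_assembly(entry, asm)
                dom_units = [PlacedUnit(u.chain, u.placement, dom)
                             for u in units
                             if u.chain.asym_id == dom.chain_ref]
                nuc_units = [u for u in units if u.chain.is_nucleic]
                for du in dom_units:
                    for nu in sorted(nuc_units,
                                     key=lambda u: u.chain.asym_id):
                        pos, n = _nucleic_profile(entry, du, nu, config)
                        if n == 0:
                            continue
                        key = (-len(pos), asm.assembly_id,
                               nu.chain.asym_id)
                        if best is None or key < best[0]:
                            best = (key, pos, n, asm.assembly_id,
                                    nu.chain)
        else:
            du = _identity_unit(entry.chain(dom.chain_ref), dom)
            for nc in sorted(nuc_chains, key=lambda c: c.asym_id):
                pos, n = _nucleic_profile(entry, du, _identity_unit(nc),
                                          config)
                if n == 0:
                    continue
                key = (-len(pos), "", nc.asym_id)
                if best is None or key < best[0]:
                    best = (key, pos, n, None, nc)
        if best is not None:
            _, pos, n, asm_id, nuc_chain = best
            nuc_class = ("DNA" if nuc_chain.polymer_type == "DNA"
                         else "RNA" if nuc_chain.polymer_type == "RNA"
                         else "DNA")
            out.append(LigandContactProfile(
                pfam=dom.pfam_acc, ligand_key=nuc_class,
                entry_id=entry.entry_id, domain=dom,
                ligand_ref=nuc_chain.asym_id, hmm_positions=pos,
                n_atomic_contacts=n, assembly_id=asm_id))
    return out


# ---------------------------------------------------------------------------
# per-family superposition export


def superpose_family_domains(entries: dict[str, CrystalEntry],
                             profiles: list[LigandContactProfile],
                             ) -> dict[str, np.ndarray]:
    """Superpose all domain copies of one family onto the first, via
    common model positions; returns domain_id -> transformed CA array."""
    if not profiles:
        return {}
    units = []
    for p in profiles:
        entry = entries[p.entry_id]
        units.append((p.domain.domain_id,
                      _identity_unit(entry.chain(p.domain.chain_ref),
                                     p.domain)))
    ref = units[0][1]
    out = {}
    for did, unit in units:
        if did == units[0][0]:
            rot, tran = np.eye(3), np.zeros(3)
        else:
            rot, tran, _, _ = superpose_by_hmm(ref, unit)
        ca = np.array([unit.chain.ca_map()[pos]
                       for pos in sorted(unit.domain.hmm_map)
                       if pos in unit.chain.ca_map()])
        out[did] = apply_rigid(ca, rot, tran)
    return out
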