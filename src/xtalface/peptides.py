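"""Domain-peptide interfaces and binding-mode clustering.

A peptide is any polypeptide chain shorter than 30 residues (full polymer
length, counting unmodeled residues).  A domain-peptide interface needs
>= 10 C-beta pairs within 12 A **or** >= 5 atomic contacts within 5 A
(note the OR, unlike the chain/domain rule).  Binding modes are compared
by (i) N_hmm, the number of family-model positions both domains contact
with their peptides, and (ii) RMSD_pep, the minimum peptide C-alpha RMSD
over ungapped sequence alignments after superposing the two domains on
their common model positions.  Clusters grow greedily by largest shared
site count while N_hmm >= 3 and RMSD_pep <= 10 A (average linkage).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .config import PipelineConfig
from .geometry import apply_rigid, kabsch
from .interfaces import ContactSet, PlacedUnit, contact_set
from .lattice import SymmetryPlacement, identity_placements
from .structure_model import CrystalEntry, DomainInstance, PolymerChain


def is_peptide(chain: PolymerChain,
               config: PipelineConfig | None = None) -> bool:
    config = config or PipelineConfig()
    return (chain.polymer_type == "polypeptide"
            and chain.length < config.peptide_max_len)


def is_peptide_interacting(contacts: ContactSet,
                           config: PipelineConfig | None = None) -> bool:
    """Peptide rule: >= 10 C-beta pairs <= 12 A OR >= 5 atomic <= 5 A."""
    config = config or PipelineConfig()
    return (contacts.n_cbeta12 >= config.min_cbeta_pairs
            or contacts.n_atom5 >= config.min_atom_contacts)


@dataclass
class PeptideInterface:
    interface_id: str
    entry_id: str
    domain_unit: PlacedUnit
    peptide_unit: PlacedUnit
    contacts: ContactSet  # (domain seq_pos, peptide seq_pos)
    hmm_sites: frozenset[int]
    cluster_id: str | None = None

    @property
    def domain(self) -> DomainInstance:
        return self.domain_unit.domain

    @property
    def pfam(self) -> str:
        return self.domain.pfam_acc

    @property
    def peptide_sequence(self) -> str:
        return self.peptide_unit.chain.sequence

    def signature(self) -> frozenset:
        ds = self.domain_unit.chain.sequence
        ps = self.peptide_unit.chain.sequence
        return frozenset(((ds, i), (ps, j))
                         for (i, j) in self.contacts.pairs)


def _atom_pair_count(unit_a: PlacedUnit, unit_b: PlacedUnit,
                     cutoff: float) -> int:
    ca, _ = unit_a.heavy()
    cb, _ = unit_b.heavy()
    if len(ca) == 0 or len(cb) == 0:
        return 0
    return int(cKDTree(ca).count_neighbors(cKDTree(cb), cutoff))


def _contact_sites(domain: DomainInstance, contacts: ContactSet,
                   config: PipelineConfig) -> frozenset[int]:
    """Family-model positions of the domain residues touching the peptide.

    Positions come from residues with an atomic contact within the 5 A
    cutoff; interfaces qualifying through the C-beta clause alone fall
    back to the C-beta pair residues.
    """
    close = {i for (i, _), (d, _) in contacts.pairs.items()
             if d <= config.atom_cutoff}
    if not close:
        close = {i for (i, _), (_, cb) in contacts.pairs.items()
                 if cb is not None and cb <= config.cbeta_cutoff}
    return frozenset(domain.hmm_map[i] for i in close if i in domain.hmm_map)


def find_peptide_interfaces(entry: CrystalEntry,
                            domains: list[DomainInstance],
                            placements: list[SymmetryPlacement] | None = None,
                            config: PipelineConfig | None = None,
                            ) -> list[PeptideInterface]:
    """Peptide-domain interfaces of one entry.

    Anchored on the identity copy of each peptide chain against domain
    copies from the asymmetric unit and, when ``placements`` is given, the
    expanded lattice; duplicates are collapsed by contact-set signature.
    A peptide contacting several chains is assigned to the chain carrying
    >= 75% of its atomic contacts; when no chain dominates, all its
    interfaces are kept.
    """
    config = config or PipelineConfig()
    chains = {c.asym_id: c for c in entry.chains}
    peptides = [c for c in entry.chains if is_peptide(c, config)
                and c.residues]
    if not peptides:
        return []
    dom_chains = {d.chain_ref for d in domains
                  if not is_peptide(chains[d.chain_ref], config)}
    if placements is None:
        dom_placements = [SymmetryPlacement(c, 0, (0, 0, 0),
                                            tuple(map(tuple, np.eye(3))),
                                            (0.0, 0.0, 0.0))
                          for c in sorted(dom_chains)]
    else:
        dom_placements = [p for p in placements
                          if p.source_chain in dom_chains]

    raw: list[PeptideInterface] = []
    for pep in peptides:
        pep_unit = PlacedUnit(pep, SymmetryPlacement(
            pep.asym_id, 0, (0, 0, 0),
            tuple(map(tuple, np.eye(3))), (0.0, 0.0, 0.0)))
        candidates: list[tuple[PlacedUnit, PeptideInterface]] = []
        chain_atom_counts: dict[tuple, int] = {}
        for pl in dom_placements:
            chain_unit = PlacedUnit(chains[pl.source_chain], pl)
            n_at = _atom_pair_count(chain_unit, pep_unit,
                                    config.atom_cutoff)
            for dom in (d for d in domains if d.chain_ref == pl.source_chain):
                dom_unit = PlacedUnit(chains[pl.source_chain], pl, dom)
                cs = contact_set(dom_unit, pep_unit, config)
                if not cs.pairs or not is_peptide_interacting(cs, config):
                    continue
                pi = PeptideInterface(
                    interface_id=(f"{entry.entry_id}:pep:"
                                  f"{dom_unit.label}--{pep_unit.label}"),
                    entry_id=entry.entry_id,
                    domain_unit=dom_unit, peptide_unit=pep_unit,
                    contacts=cs,
                    hmm_sites=_contact_sites(dom, cs, config))
                candidates.append((chain_unit, pi))
                chain_atom_counts[chain_unit.key] = n_at
        total = sum(chain_atom_counts.values())
        if total > 0 and len(chain_atom_counts) > 1:
            best_key = max(chain_atom_counts,
                           key=lambda k: (chain_atom_counts[k], k))
            if chain_atom_counts[best_key] >= config.peptide_assign_frac \
                    * total:
                candidates = [(cu, pi) for cu, pi in candidates
                              if cu.key == best_key]
        raw.extend(pi for _, pi in candidates)

    by_sig: dict[frozenset, PeptideInterface] = {}
    for pi in raw:
        sig = pi.signature()
        prev = by_sig.get(sig)
        if prev is None or pi.interface_id < prev.interface_id:
            by_sig[sig] = pi
    return sorted(by_sig.values(), key=lambda p: p.interface_id)


# ---------------------------------------------------------------------------
# superposition and peptide RMSD


def _hmm_ca(unit: PlacedUnit) -> dict[int, np.ndarray]:
    """HMM position -> placed CA coordinate for a domain unit."""
    ca_map = unit.chain.ca_map()
    out = {}
    for pos, h in unit.domain.hmm_map.items():
        if pos in ca_map:
            out[h] = unit.placement.apply(ca_map[pos][None, :])[0]
    return out


def superpose_by_hmm(dom_a: PlacedUnit, dom_b: PlacedUnit,
                     ) -> tuple[np.ndarray, np.ndarray, float, list[int]]:
    """Rigid transform taking ``dom_b`` onto ``dom_a`` via common
    family-model positions (least-squares over C-alpha).

    Returns (rotation, translation, RMSD, common position list); requires
    at least three common positions with coordinates.
    """
    ca_a = _hmm_ca(dom_a)
    ca_b = _hmm_ca(dom_b)
    common = sorted(set(ca_a) & set(ca_b))
    if len(common) < 3:
        raise ValueError(
            f"only {len(common)} common model positions; need >= 3")
    target = np.array([ca_a[h] for h in common])
    mobile = np.array([ca_b[h] for h in common])
    rot, tran, r = kabsch(mobile, target)
    return rot, tran, r, common


def _peptide_ca(unit: PlacedUnit) -> np.ndarray:
    out = []
    for res in unit.chain.residues:
        a = res.atom("CA")
        if a is not None:
            out.append(unit.placement.apply(a.pos[None, :])[0])
    return np.asarray(out)


def peptide_rmsd(pi_a: PeptideInterface, pi_b: PeptideInterface,
                 config: PipelineConfig | None = None,
                 ) -> tuple[float, int]:
    """Minimum peptide C-alpha RMSD over ungapped alignments.

    The domains are first superposed on their common family-model
    positions; the second peptide is carried along by that transform, so
    the score measures binding-site location, not peptide conformation
    alone.  All ungapped residue alignments (offsets) with overlap >=
    ``min_pep_overlap`` are scanned; alignment offset k pairs residue i of
    the first peptide with residue i + k of the second.
    """
    config = config or PipelineConfig()
    rot, tran, _, _ = superpose_by_hmm(pi_a.domain_unit, pi_b.domain_unit)
    ca_a = _peptide_ca(pi_a.peptide_unit)
    ca_b = apply_rigid(_peptide_ca(pi_b.peptide_unit), rot, tran)
    la, lb = len(ca_a), len(ca_b)
    m = config.min_pep_overlap
    if la < m or lb < m:
        raise ValueError("peptide too short for the minimum overlap")
    best: tuple[float, int] | None = None
    for k in range(-(la - m), lb - m + 1):
        i0 = max(0, -k)
        i1 = min(la, lb - k)
        if i1 - i0 < m:
            continue
        d = ca_a[i0:i1] - ca_b[i0 + k:i1 + k]
        r = float(np.sqrt((d ** 2).sum(axis=1).mean()))
        if best is None or (r, k) < best:
            best = (r, k)
    if best is None:
        raise ValueError("no alignment with sufficient overlap")
    return best


# ---------------------------------------------------------------------------
# clustering


@dataclass
class PeptideCluster:
    cluster_id: str
    pfam: str
    members: list[PeptideInterface]
    shared_hmm_sites: frozenset[int] = frozenset()
    n_peptide_sequences: int = 0
    n_entries: int = 0
    n_crystal_forms: int = 0
    rmsd_mean: float | None = None
    rmsd_max: float | None = None

    def finalize(self, form_map: dict[str, str] | None = None) -> None:
        self.n_peptide_sequences = len({m.peptide_sequence
                                        for m in self.members})
        self.n_entries = len({m.entry_id for m in self.members})
        if form_map:
            self.n_crystal_forms = len({form_map.get(m.entry_id, m.entry_id)
                                        for m in self.members})
        else:
            self.n_crystal_forms = self.n_entries
        sites = None
        for m in self.members:
            sites = m.hmm_sites if sites is None else sites & m.hmm_sites
        self.shared_hmm_sites = sites or frozenset()


def cluster_peptide_interfaces(pis: list[PeptideInterface],
                               config: PipelineConfig | None = None,
                               form_map: dict[str, str] | None = None,
                               ) -> list[PeptideCluster]:
    """Greedy agglomeration of binding modes within each family.

    At each step the two clusters with the largest average shared-site
    count merge, provided the average N_hmm >= 3 and the average RMSD_pep
    <= 10 A across cross-cluster member pairs.  Pairs whose domains lack
    three common model positions block merging (RMSD undefined).
    """
    config = config or PipelineConfig()
    out: list[PeptideCluster] = []
    by_fam: dict[str, list[PeptideInterface]] = {}
    for pi in pis:
        by_fam.setdefault(pi.pfam, []).append(pi)
    for fam in sorted(by_fam):
        members = sorted(by_fam[fam], key=lambda p: p.interface_id)
        n = len(members)
        nhmm = np.zeros((n, n))
        rms = np.full((n, n), np.inf)
        for i in range(n):
            rms[i, i] = 0.0
            for j in range(i + 1, n):
                nhmm[i, j] = nhmm[j, i] = len(
                    members[i].hmm_sites & members[j].hmm_sites)
                try:
                    r, _ = peptide_rmsd(members[i], members[j], config)
                    rms[i, j] = rms[j, i] = r
                except ValueError:
                    pass
        clusters = [[i] for i in range(n)]
        while len(clusters) > 1:
            best = None
            for a in range(len(clusters)):
                for b in range(a + 1, len(clusters)):
                    pairs = [(i, j) for i in clusters[a]
                             for j in clusters[b]]
                    avg_n = float(np.mean([nhmm[i, j] for i, j in pairs]))
                    avg_r = float(np.mean([rms[i, j] for i, j in pairs]))
                    if avg_n < config.pep_min_nhmm or \
                            avg_r > config.pep_max_rmsd:
                        continue
                    tie = tuple(sorted(members[k].interface_id
                                       for k in clusters[a] + clusters[b]))
                    cand = (-avg_n, tie, a, b)
                    if best is None or cand < best:
                        best = cand
            if best is None:
                break
            _, _, a, b = best
            clusters[a] = sorted(clusters[a] + clusters[b])
            del clusters[b]
        clusters.sort(key=lambda c: (-len(c),
                                     members[c[0]].interface_id))
        for ci, idxs in enumerate(clusters, start=1):
            mem = [members[k] for k in idxs]
            pc = PeptideCluster(cluster_id=f"{fam}:pep:{ci}", pfam=fam,
                                members=mem)
            pairs = [(i, j) for ai, i in enumerate(idxs)
                     for j in idxs[ai + 1:]]
            if pairs:
                vals = [rms[i, j] for i, j in pairs
                        if np.isfinite(rms[i, j])]
                if vals:
                    pc.rmsd_mean = float(np.mean(vals))
                    pc.rmsd_max = float(np.max(vals))
            pc.finalize(form_map)
            for m in mem:
                m.cluster_id = pc.cluster_id
            out.append(pc)
    return out
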