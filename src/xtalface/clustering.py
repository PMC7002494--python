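"""Interface similarity (Q score) and average-linkage clustering.

Comparing interfaces from homologous (not identical) proteins needs a
common coordinate system.  Residues are mapped to profile-HMM match
positions of their family; two domains are comparable when the model
covers at least 80% of the shorter domain.  Identical sequences fall back
to plain sequence-position correspondence.  The Q score is then the
(weighted, default unit-weight) Jaccard index of the two mapped
contact-pair sets: 1 = identical interaction mode, 0 = no common contacts.

Clusters are built by hierarchical average linkage: repeatedly merge the
two clusters with the highest average pairwise Q while that average is at
least 0.30 (pairs with no valid correspondence contribute 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from Bio import Align

from .config import PipelineConfig
from .crystal_forms import CrystalForm, form_of_entry
from .interfaces import Interface, PlacedUnit
from .structure_model import DomainInstance

#: maps (entry_id, asym_id) -> start-sorted domain list
DomainIndex = dict[tuple[str, str], list[DomainInstance]]


@dataclass
class Pairing:
    """One side-assignment between two interfaces with its residue maps."""
    map_a1: dict[int, object]
    map_a2: dict[int, object]
    map_b1: dict[int, object]
    map_b2: dict[int, object]
    flipped: bool
    covered_fraction: float


@dataclass
class Correspondence:
    kind: str  # hmm | identity
    pairings: list[Pairing]

    @property
    def covered_fraction(self) -> float:
        return max(p.covered_fraction for p in self.pairings)


def _unit_family(unit: PlacedUnit, level: str) -> str:
    if level == "domain":
        return unit.domain.pfam_acc
    return getattr(unit, "arch_string", "")


def _domain_list(unit: PlacedUnit, level: str,
                 domain_index: DomainIndex | None,
                 entry_id: str) -> list[DomainInstance]:
    if level == "domain":
        return [unit.domain]
    if domain_index is None:
        return []
    return domain_index.get((entry_id, unit.chain.asym_id), [])


def _hmm_side_map(doms_a: list[DomainInstance],
                  doms_b: list[DomainInstance],
                  hmm_cov_min: float):
    """Common-position maps for one side pair, or None below coverage.

    Chain level concatenates per-domain HMM maps in architecture order:
    the common coordinate is (domain index, HMM position).
    """
    if len(doms_a) != len(doms_b) or not doms_a:
        return None
    map_a: dict[int, object] = {}
    map_b: dict[int, object] = {}
    worst = 1.0
    for k, (da, db) in enumerate(zip(doms_a, doms_b)):
        if da.pfam_acc != db.pfam_acc:
            return None
        common = set(da.hmm_map.values()) & set(db.hmm_map.values())
        shorter = min(da.n_residues, db.n_residues)
        cov_a = sum(1 for h in da.hmm_map.values() if h in common)
        cov_b = sum(1 for h in db.hmm_map.values() if h in common)
        frac = min(cov_a, cov_b) / shorter if shorter else 0.0
        if frac < hmm_cov_min:
            return None
        worst = min(worst, frac)
        for pos, h in da.hmm_map.items():
            if h in common:
                map_a[pos] = (k, h)
        for pos, h in db.hmm_map.items():
            if h in common:
                map_b[pos] = (k, h)
    return map_a, map_b, worst


def build_correspondence(iface_a: Interface, iface_b: Interface,
                         domain_index: DomainIndex | None = None,
                         config: PipelineConfig | None = None,
                         ) -> Correspondence | None:
    """Residue correspondence between two same-level interfaces.

    Returns None ("no correspondence") when the family model does not
    cover 80% of the shorter domain and the sequences are not identical;
    such a pair has undefined Q and is never co-clustered.  Incompatible
    family keys raise ``ValueError``.
    """
    config = config or PipelineConfig()
    if iface_a.level != iface_b.level:
        raise ValueError("interfaces are at different levels")
    level = iface_a.level
    if iface_a.family_key != iface_b.family_key:
        raise ValueError(
            f"incompatible family keys {iface_a.family_key} vs "
            f"{iface_b.family_key}")

    units_a = (iface_a.unit_a, iface_a.unit_b)
    units_b = (iface_b.unit_a, iface_b.unit_b)
    fams_a = tuple(_unit_family(u, level) for u in units_a)
    fams_b = tuple(_unit_family(u, level) for u in units_b)

    orderings = [False]
    if fams_b[0] == fams_b[1]:
        orderings = [False, True]

    identity_pairings: list[Pairing] = []
    hmm_pairings: list[Pairing] = []
    for flip in orderings:
        b1, b2 = (units_b[1], units_b[0]) if flip else units_b
        f1, f2 = (fams_b[1], fams_b[0]) if flip else fams_b
        if (fams_a[0], fams_a[1]) != (f1, f2):
            continue
        if (units_a[0].chain.sequence == b1.chain.sequence
                and units_a[1].chain.sequence == b2.chain.sequence):
            ident = lambda u: {r.seq_pos: r.seq_pos
                               for r in u.chain.residues}
            identity_pairings.append(Pairing(
                ident(units_a[0]), ident(units_a[1]),
                ident(b1), ident(b2), flip, 1.0))
            continue
        res1 = _hmm_side_map(
            _domain_list(units_a[0], level, domain_index, iface_a.entry_id),
            _domain_list(b1, level, domain_index, iface_b.entry_id),
            config.hmm_cov_min)
        res2 = _hmm_side_map(
            _domain_list(units_a[1], level, domain_index, iface_a.entry_id),
            _domain_list(b2, level, domain_index, iface_b.entry_id),
            config.hmm_cov_min)
        if res1 is None or res2 is None:
            continue
        ma1, mb1, c1 = res1
        ma2, mb2, c2 = res2
        hmm_pairings.append(Pairing(ma1, ma2, mb1, mb2, flip,
                                    min(c1, c2)))
    if identity_pairings:
        return Correspondence("identity", identity_pairings)
    if hmm_pairings:
        return Correspondence("hmm", hmm_pairings)
    return None


def _mapped_pairs(iface: Interface, m1: dict, m2: dict,
                  flipped: bool) -> set:
    out = set()
    for (i, j) in iface.contacts.pairs:
        if flipped:
            if j in m1 and i in m2:
                out.add((m1[j], m2[i]))
        else:
            if i in m1 and j in m2:
                out.add((m1[i], m2[j]))
    return out


def q_score(iface_a: Interface, iface_b: Interface,
            corr: Correspondence,
            weight: Callable[[object, object], float] | None = None,
            ) -> float:
    """Q = weighted shared mapped contact pairs / union of pairs.

    With the default unit weights this is the plain Jaccard index of the
    two mapped contact-pair sets.  For same-family interfaces both side
    orderings are evaluated and the maximum taken, so the score does not
    depend on arbitrary chain labelling.
    """
    if corr is None:
        raise ValueError("no correspondence defined for this pair")
    w = weight or (lambda p, side=None: 1.0)
    best = None
    for pairing in corr.pairings:
        ca = _mapped_pairs(iface_a, pairing.map_a1, pairing.map_a2, False)
        cb = _mapped_pairs(iface_b, pairing.map_b1, pairing.map_b2,
                           pairing.flipped)
        union = ca | cb
        if not union:
            raise ValueError("Q undefined: empty union of mapped pairs")
        num = sum(w(p) for p in ca & cb)
        den = sum(w(p) for p in union)
        q = num / den
        best = q if best is None else max(best, q)
    if best is None:
        raise ValueError("no valid side pairing")
    return best


def q_or_none(iface_a: Interface, iface_b: Interface,
              domain_index: DomainIndex | None = None,
              config: PipelineConfig | None = None) -> float | None:
    """Q score, or None when the pair has no valid correspondence."""
    try:
        corr = build_correspondence(iface_a, iface_b, domain_index, config)
    except ValueError:
        return None
    if corr is None:
        return None
    try:
        return q_score(iface_a, iface_b, corr)
    except ValueError:
        return None


# ---------------------------------------------------------------------------
# average-linkage clustering


def average_linkage_cluster(q_matrix: np.ndarray,
                            threshold: float = 0.30,
                            member_ids: Sequence[str] | None = None,
                            ) -> list[list[int]]:
    """Agglomerative average-linkage with a similarity stopping rule.

    Starts from singletons and repeatedly merges the two clusters with the
    highest average pairwise Q while that average is >= ``threshold``.
    Undefined pairs must be encoded as 0 in ``q_matrix``.  Ties are broken
    by the smallest lexicographic member id.  Returns index lists sorted
    by decreasing size, then smallest member id.
    """
    q = np.asarray(q_matrix, dtype=float)
    n = len(q)
    if member_ids is None:
        member_ids = [f"{i:06d}" for i in range(n)]
    clusters: list[list[int]] = [[i] for i in range(n)]
    sums = q.copy()
    np.fill_diagonal(sums, 0.0)
    while len(clusters) > 1:
        sizes = np.array([len(c) for c in clusters], dtype=float)
        avg = sums / np.outer(sizes, sizes)
        iu = np.triu_indices(len(clusters), k=1)
        vals = avg[iu]
        best_avg = vals.max()
        if best_avg < threshold:
            break
        tied = np.flatnonzero(vals == best_avg)
        if len(tied) == 1:
            i, j = int(iu[0][tied[0]]), int(iu[1][tied[0]])
        else:
            # deterministic tie-break: smallest lexicographic member ids
            def tie_key(t):
                a, b = int(iu[0][t]), int(iu[1][t])
                return (tuple(sorted(member_ids[k]
                                     for k in clusters[a] + clusters[b])),
                        a, b)
            t = min(tied, key=tie_key)
            i, j = int(iu[0][t]), int(iu[1][t])
        clusters[i] = sorted(clusters[i] + clusters[j])
        sums[i, :] += sums[j, :]
        sums[:, i] += sums[:, j]
        del clusters[j]
        sums = np.delete(np.delete(sums, j, axis=0), j, axis=1)
    clusters.sort(key=lambda c: (-len(c),
                                 min(member_ids[k] for k in c)))
    return clusters


# ---------------------------------------------------------------------------
# interface clusters


@dataclass
class InterfaceCluster:
    cluster_id: str
    level: str
    family_key: tuple[str, str]
    members: list[Interface]
    n_crystal_forms: int = 0
    n_entries: int = 0
    n_uniprots: int = 0
    min_seq_identity: float | None = None
    mean_bsa: float | None = None
    q_avg_internal: float = 1.0
    author_fraction: float | None = None
    pisa_fraction: float | None = None
    member_forms: dict[str, str] = field(default_factory=dict)


def cluster_interfaces(interfaces: list[Interface],
                       domain_index: DomainIndex | None = None,
                       config: PipelineConfig | None = None,
                       ) -> list[InterfaceCluster]:
    """Cluster a census of interfaces within each family key.

    Interfaces flagged below the BSA cutoff are excluded.  Output clusters
    are ordered by (crystal-form count is filled later) size and smallest
    member id; ids are assigned per family key.
    """
    config = config or PipelineConfig()
    groups: dict[tuple[str, str], list[Interface]] = {}
    for iface in interfaces:
        if iface.below_bsa:
            continue
        groups.setdefault(iface.family_key, []).append(iface)
    clusters: list[InterfaceCluster] = []
    for fam_key in sorted(groups):
        members = sorted(groups[fam_key], key=lambda f: f.interface_id)
        n = len(members)
        q = np.zeros((n, n))
        for i in range(n):
            q[i, i] = 1.0
            for j in range(i + 1, n):
                val = q_or_none(members[i], members[j], domain_index,
                                config)
                q[i, j] = q[j, i] = 0.0 if val is None else val
        idx_clusters = average_linkage_cluster(
            q, threshold=config.q_cluster,
            member_ids=[m.interface_id for m in members])
        for ci, idxs in enumerate(idx_clusters, start=1):
            mem = [members[k] for k in idxs]
            if len(idxs) > 1:
                qs = [q[a, b] for ai, a in enumerate(idxs)
                      for b in idxs[ai + 1:]]
                q_avg = float(np.mean(qs))
            else:
                q_avg = 1.0
            cid = f"{'|'.join(fam_key)}:{ci}"
            clusters.append(InterfaceCluster(
                cluster_id=cid, level=mem[0].level, family_key=fam_key,
                members=mem, q_avg_internal=q_avg))
            for m in mem:
                m.cluster_id = cid
    return clusters


def _seq_identity(s1: str, s2: str) -> float:
    """Global-alignment identity: matches / alignment columns."""
    if s1 == s2:
        return 1.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -0.5
    aligner.extend_gap_score = -0.1
    aln = aligner.align(s1, s2)[0]
    counts = aln.counts()
    return counts.identities / aln.length


def annotate_cluster(cluster: InterfaceCluster,
                     forms: list[CrystalForm],
                     config: PipelineConfig | None = None,
                     ) -> InterfaceCluster:
    """Fill the evidence counts that make a cluster a hypothesis.

    n_crystal_forms / n_entries / n_uniprots, mean buried area, minimum
    pairwise sequence identity over the member proteins, and the fraction
    of members present in author and software-derived assemblies.
    """
    fmap = form_of_entry(forms)
    entries = {m.entry_id for m in cluster.members}
    missing = entries - set(fmap)
    if missing:
        raise ValueError(
            f"members without crystal-form assignment: {sorted(missing)}")
    cluster.member_forms = {m.interface_id: fmap[m.entry_id]
                            for m in cluster.members}
    cluster.n_entries = len(entries)
    cluster.n_crystal_forms = len({fmap[e] for e in entries})
    prots = set()
    seqs = set()
    for m in cluster.members:
        for u in (m.unit_a, m.unit_b):
            prots.add(u.chain.uniprot or u.chain.sequence)
            seqs.add(u.chain.sequence)
    cluster.n_uniprots = len(prots)
    bsas = [m.bsa for m in cluster.members if m.bsa is not None]
    cluster.mean_bsa = float(np.mean(bsas)) if bsas else None
    seqs = sorted(seqs)
    ident = 1.0
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            ident = min(ident, _seq_identity(seqs[i], seqs[j]))
    cluster.min_seq_identity = ident
    for attr, frac_attr in (("in_author_assembly", "author_fraction"),
                            ("in_pisa_assembly", "pisa_fraction")):
        flags = [getattr(m, attr) for m in cluster.members
                 if getattr(m, attr) is not None]
        setattr(cluster, frac_attr,
                (sum(flags) / len(flags)) if flags else None)
    return cluster


def sort_clusters(clusters: list[InterfaceCluster],
                  ) -> list[InterfaceCluster]:
    """Evidence ordering: crystal forms desc, then entries desc."""
    return sorted(clusters, key=lambda c: (-c.n_crystal_forms,
                                           -c.n_entries, c.cluster_id))
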