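"""Pipeline orchestration and the on-disk cluster store.

``run_pipeline`` drives the stages read -> expand -> interfaces ->
crystal forms -> cluster -> peptides -> ligands -> reports over a set of
entries, and writes a directory of TSV tables plus a JSON index (the
"cluster store") that the network-query commands read back.  Outputs are
deterministic given the inputs and config; entries that fail a stage are
quarantined with a logged reason and the run continues.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .clustering import (DomainIndex, InterfaceCluster, annotate_cluster,
                         cluster_interfaces, sort_clusters)
from .config import PipelineConfig
from .crystal_forms import (CrystalForm, EntryRecord, form_of_entry,
                            group_crystal_forms, merge_equivalent_forms)
from .interfaces import (Interface, enumerate_unique_interfaces,
                         flag_assembly_presence)
from .lattice import expand_lattice
from .ligands_nucleic import (LigandContactProfile, LigandSiteCluster,
                              cluster_ligand_sites, profile_entry_ligands,
                              select_nucleic_interface)
from .peptides import (PeptideCluster, cluster_peptide_interfaces,
                       find_peptide_interfaces)
from .structure_model import (CrystalEntry, DomainInstance,
                              NonCrystallographicError, derive_architectures,
                              ingest_annotations, read_annotation_table,
                              read_assembly_table, read_entry)

logger = logging.getLogger(__name__)

STAGES = ("read", "expand", "interfaces", "crystalforms", "cluster",
          "peptides", "ligands", "report")


@dataclass
class PipelineResult:
    """Everything one run produced, before/after writing the store."""
    config: PipelineConfig
    entries: dict[str, CrystalEntry] = field(default_factory=dict)
    domains: dict[str, list[DomainInstance]] = field(default_factory=dict)
    records: list[EntryRecord] = field(default_factory=list)
    chain_interfaces: dict[str, list[Interface]] = field(default_factory=dict)
    domain_interfaces: dict[str, list[Interface]] = field(default_factory=dict)
    forms: list[CrystalForm] = field(default_factory=list)
    chain_clusters: list[InterfaceCluster] = field(default_factory=list)
    domain_clusters: list[InterfaceCluster] = field(default_factory=list)
    peptide_clusters: list[PeptideCluster] = field(default_factory=list)
    ligand_profiles: list[LigandContactProfile] = field(default_factory=list)
    ligand_clusters: list[LigandSiteCluster] = field(default_factory=list)
    nucleic_profiles: list[LigandContactProfile] = field(default_factory=list)
    quarantined: dict[str, str] = field(default_factory=dict)
    stage_counts: dict[str, int] = field(default_factory=dict)

    @property
    def domain_index(self) -> DomainIndex:
        idx: DomainIndex = {}
        for eid, doms in self.domains.items():
            for d in doms:
                idx.setdefault((eid, d.chain_ref), []).append(d)
        for lst in idx.values():
            lst.sort(key=lambda d: d.start)
        return idx


def run_pipeline(entry_paths: list[str | Path],
                 annotation_table: str | Path | pd.DataFrame,
                 out_dir: str | Path,
                 assembly_table: str | Path | None = None,
                 config: PipelineConfig | None = None,
                 until: str = "report") -> PipelineResult:
    """Run the pipeline over a set of structure files and write the store.

    ``until`` stops after the named stage (one of ``STAGES``); earlier
    outputs are still written, so runs are resumable stage by stage.
    Rerunning on unchanged inputs rewrites byte-identical tables.
    """
    if not entry_paths:
        raise ValueError("no entries given")
    if until not in STAGES:
        raise ValueError(f"unknown stage {until!r}")
    config = config or PipelineConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    res = PipelineResult(config=config)
    last = STAGES.index(until)
    ann = (annotation_table
           if isinstance(annotation_table, pd.DataFrame)
           else read_annotation_table(annotation_table))

    # --- read
    for path in sorted(map(Path, entry_paths)):
        try:
            entry = read_entry(path)
            doms = ingest_annotations(entry, ann)
            if assembly_table is not None:
                read_assembly_table(entry, assembly_table)
            res.entries[entry.entry_id] = entry
            res.domains[entry.entry_id] = doms
            res.records.append(
                EntryRecord(entry, derive_architectures(entry, doms)))
        except Exception as exc:  # noqa: BLE001 - quarantine and continue
            logger.error("quarantined %s: %s", path, exc)
            res.quarantined[str(path)] = str(exc)
    if not res.entries:
        raise ValueError("every entry failed to read")
    res.stage_counts["read"] = len(res.entries)
    if last >= STAGES.index("interfaces"):
        _stage_interfaces(res, config)
    if last >= STAGES.index("crystalforms"):
        res.forms = merge_equivalent_forms(
            group_crystal_forms(res.records, config),
            res.chain_interfaces, config)
        res.stage_counts["crystalforms"] = len(res.forms)
    if last >= STAGES.index("cluster"):
        _stage_cluster(res, config)
    if last >= STAGES.index("peptides"):
        _stage_peptides(res, config)
    if last >= STAGES.index("ligands"):
        _stage_ligands(res, config)
    write_store(res, out_dir)
    return res


def _stage_interfaces(res: PipelineResult, config: PipelineConfig) -> None:
    for rec in res.records:
        entry = rec.entry
        doms = res.domains[entry.entry_id]
        try:
            placements = expand_lattice(entry)
        except NonCrystallographicError as exc:
            logger.warning("%s: %s (skipping lattice census)",
                           entry.entry_id, exc)
            res.chain_interfaces[entry.entry_id] = []
            res.domain_interfaces[entry.entry_id] = []
            continue
        chain_ifs = enumerate_unique_interfaces(
            entry, placements, "chain", config, domains=doms,
            architectures=rec.architectures)
        dom_ifs = enumerate_unique_interfaces(
            entry, placements, "domain", config, domains=doms,
            architectures=rec.architectures)
        flag_assembly_presence(chain_ifs, entry, config)
        flag_assembly_presence(dom_ifs, entry, config)
        res.chain_interfaces[entry.entry_id] = chain_ifs
        res.domain_interfaces[entry.entry_id] = dom_ifs
    res.stage_counts["interfaces"] = sum(
        len(v) for v in res.chain_interfaces.values())


def _stage_cluster(res: PipelineResult, config: PipelineConfig) -> None:
    idx = res.domain_index
    for attr, source in (("chain_clusters", res.chain_interfaces),
                         ("domain_clusters", res.domain_interfaces)):
        allifs = [f for lst in source.values() for f in lst]
        clusters = cluster_interfaces(allifs, idx, config)
        for c in clusters:
            annotate_cluster(c, res.forms, config)
        setattr(res, attr, sort_clusters(clusters))
    res.stage_counts["cluster"] = (len(res.chain_clusters)
                                   + len(res.domain_clusters))


def _stage_peptides(res: PipelineResult, config: PipelineConfig) -> None:
    pis = []
    for eid, entry in sorted(res.entries.items()):
        try:
            placements = expand_lattice(entry)
        except NonCrystallographicError:
            placements = None
        pis.extend(find_peptide_interfaces(entry, res.domains[eid],
                                           placements, config))
    res.peptide_clusters = cluster_peptide_interfaces(
        pis, config, form_of_entry(res.forms))
    res.stage_counts["peptides"] = len(res.peptide_clusters)


def _stage_ligands(res: PipelineResult, config: PipelineConfig) -> None:
    for eid, entry in sorted(res.entries.items()):
        res.ligand_profiles.extend(
            profile_entry_ligands(entry, res.domains[eid], config))
        res.nucleic_profiles.extend(
            select_nucleic_interface(entry, res.domains[eid], config))
    by_fam: dict[str, list[LigandContactProfile]] = {}
    for p in res.ligand_profiles:
        by_fam.setdefault(p.pfam, []).append(p)
    for fam in sorted(by_fam):
        res.ligand_clusters.extend(
            cluster_ligand_sites(by_fam[fam], config))
    res.stage_counts["ligands"] = len(res.ligand_profiles)


# ---------------------------------------------------------------------------
# store writing

IFACE_COLUMNS = ["interface_id", "entry_id", "cf_id", "level", "side_a",
                 "side_b", "n_cbeta12", "n_atom5", "bsa", "below_bsa",
                 "intra_chain", "in_author_assembly", "in_pisa_assembly",
                 "cluster_id"]
CLUSTER_SUMMARY_COLUMNS = ["cluster_id", "family_key", "n_members",
                           "n_crystal_forms", "n_entries", "n_uniprots",
                           "min_seq_identity", "mean_bsa",
                           "q_avg_internal", "author_fraction",
                           "pisa_fraction"]
CLUSTER_MEMBER_COLUMNS = ["cluster_id", "interface_id", "entry_id",
                          "cf_id", "uniprot_a", "uniprot_b", "species",
                          "bsa", "in_author_assembly", "in_pisa_assembly"]
PEPTIDE_COLUMNS = ["cluster_id", "pfam", "entry_id", "domain_id",
                   "peptide_chain", "peptide_sequence", "n_hmm_sites",
                   "n_cluster_entries", "n_cluster_forms", "shared_sites",
                   "rmsd_mean"]


def _fmt(x) -> str:
    if x is None:
        return ""
    if isinstance(x, (bool, np.bool_)):
        return str(int(x))
    if isinstance(x, (float, np.floating)):
        return f"{x:.3f}"
    return str(x)


def _iface_row(f: Interface, fmap: dict[str, str]) -> dict:
    return {
        "interface_id": f.interface_id, "entry_id": f.entry_id,
        "cf_id": fmap.get(f.entry_id, ""), "level": f.level,
        "side_a": f.unit_a.label, "side_b": f.unit_b.label,
        "n_cbeta12": f.contacts.n_cbeta12, "n_atom5": f.contacts.n_atom5,
        "bsa": _fmt(f.bsa), "below_bsa": _fmt(f.below_bsa),
        "intra_chain": _fmt(f.intra_chain),
        "in_author_assembly": _fmt(f.in_author_assembly),
        "in_pisa_assembly": _fmt(f.in_pisa_assembly),
        "cluster_id": f.cluster_id or ""}


def write_store(res: PipelineResult, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fmap = form_of_entry(res.forms)

    rows = []
    for rec in res.records:
        e = rec.entry
        rows.append({
            "entry_id": e.entry_id, "space_group": e.space_group or "",
            "cell": ";".join(f"{v:.3f}" for v in e.cell.params())
            if e.cell else "",
            "n_chains": len(e.chains), "arch_key": "|".join(rec.arch_key),
            "cf_id": fmap.get(e.entry_id, "")})
    pd.DataFrame(rows, columns=["entry_id", "space_group", "cell",
                                "n_chains", "arch_key", "cf_id"]).to_csv(
        out_dir / "entries.tsv", sep="\t", index=False)

    for level, source in (("chain", res.chain_interfaces),
                          ("domain", res.domain_interfaces)):
        rows = [_iface_row(f, fmap)
                for lst in source.values() for f in lst]
        pd.DataFrame(rows, columns=IFACE_COLUMNS).to_csv(
            out_dir / f"interfaces_{level}.tsv", sep="\t", index=False)

    rows = [{"cf_id": f.cf_id, "members": ";".join(f.member_entries),
             "space_group": f.space_group,
             "cell": ";".join(f"{v:.3f}"
                              for v in f.representative_cell.params())
             if f.representative_cell else "",
             "arch_key": "|".join(f.arch_key),
             "merged_from": ";".join(f.merged_from)}
            for f in res.forms]
    pd.DataFrame(rows, columns=["cf_id", "members", "space_group",
                                "cell", "arch_key", "merged_from"]).to_csv(
        out_dir / "crystal_forms.tsv", sep="\t", index=False)

    for level, clusters in (("chain", res.chain_clusters),
                            ("domain", res.domain_clusters)):
        member_rows, summary_rows = [], []
        for c in clusters:
            summary_rows.append({
                "cluster_id": c.cluster_id,
                "family_key": "|".join(c.family_key),
                "n_members": len(c.members),
                "n_crystal_forms": c.n_crystal_forms,
                "n_entries": c.n_entries, "n_uniprots": c.n_uniprots,
                "min_seq_identity": _fmt(c.min_seq_identity),
                "mean_bsa": _fmt(c.mean_bsa),
                "q_avg_internal": _fmt(c.q_avg_internal),
                "author_fraction": _fmt(c.author_fraction),
                "pisa_fraction": _fmt(c.pisa_fraction)})
            for m in c.members:
                member_rows.append({
                    "cluster_id": c.cluster_id,
                    "interface_id": m.interface_id,
                    "entry_id": m.entry_id,
                    "cf_id": c.member_forms.get(m.interface_id, ""),
                    "uniprot_a": m.unit_a.chain.uniprot or "",
                    "uniprot_b": m.unit_b.chain.uniprot or "",
                    "species": m.unit_a.chain.species or "",
                    "bsa": _fmt(m.bsa),
                    "in_author_assembly": _fmt(m.in_author_assembly),
                    "in_pisa_assembly": _fmt(m.in_pisa_assembly)})
        pd.DataFrame(summary_rows, columns=CLUSTER_SUMMARY_COLUMNS).to_csv(
            out_dir / f"clusters_{level}_summary.tsv", sep="\t",
            index=False)
        pd.DataFrame(member_rows, columns=CLUSTER_MEMBER_COLUMNS).to_csv(
            out_dir / f"clusters_{level}.tsv", sep="\t", index=False)

    rows = []
    for c in res.peptide_clusters:
        for m in c.members:
            rows.append({
                "cluster_id": c.cluster_id, "pfam": c.pfam,
                "entry_id": m.entry_id,
                "domain_id": m.domain.domain_id,
                "peptide_chain": m.peptide_unit.chain.asym_id,
                "peptide_sequence": m.peptide_sequence,
                "n_hmm_sites": len(m.hmm_sites),
                "n_cluster_entries": c.n_entries,
                "n_cluster_forms": c.n_crystal_forms,
                "shared_sites": ";".join(map(str,
                                             sorted(c.shared_hmm_sites))),
                "rmsd_mean": _fmt(c.rmsd_mean)})
    pd.DataFrame(rows, columns=PEPTIDE_COLUMNS).to_csv(
        out_dir / "peptide_clusters.tsv", sep="\t", index=False)

    rows = [{"pfam": p.pfam, "ligand": p.ligand_key,
             "entry_id": p.entry_id, "domain_id": p.domain.domain_id,
             "ligand_ref": p.ligand_ref,
             "n_contacts": p.n_atomic_contacts,
             "hmm_positions": ";".join(map(str, sorted(p.hmm_positions)))}
            for p in res.ligand_profiles + res.nucleic_profiles]
    pd.DataFrame(rows, columns=["pfam", "ligand", "entry_id",
                                "domain_id", "ligand_ref", "n_contacts",
                                "hmm_positions"]).to_csv(
        out_dir / "ligand_profiles.tsv", sep="\t", index=False)
    rows = [{"cluster_id": c.cluster_id, "pfam": c.pfam,
             "ligands": ";".join(c.ligand_groups),
             "n_members": len(c.members),
             "consensus_positions":
             ";".join(map(str, sorted(c.consensus_positions)))}
            for c in res.ligand_clusters]
    pd.DataFrame(rows, columns=["cluster_id", "pfam", "ligands",
                                "n_members", "consensus_positions"]).to_csv(
        out_dir / "ligand_clusters.tsv", sep="\t", index=False)

    index = {
        "config": dataclasses.asdict(res.config),
        "entries": sorted(res.entries),
        "quarantined": res.quarantined,
        "stage_counts": res.stage_counts,
        "tables": sorted(p.name for p in out_dir.glob("*.tsv")),
    }
    (out_dir / "index.json").write_text(json.dumps(index, indent=1,
                                                   sort_keys=True))


# ---------------------------------------------------------------------------
# network queries


def query_interaction_network(proteins: list[dict],
                              store_dir: str | Path,
                              mode: str = "all-to-all",
                              ppbd_list: list[str] | None = None,
                              ) -> pd.DataFrame:
    """Structural-evidence edges among a list of annotated proteins.

    Each protein is a dict with ``name`` and ``families`` (list of family
    accessions or architecture strings).  ``first-to-all`` restricts the
    pairs to those involving the first (hub) protein; ``all-to-all``
    considers every pair.  An edge is emitted when the store holds an
    interface cluster for some family pair of the two proteins, labelled
    with the largest cluster's crystal-form and entry counts.  When no
    structural cluster exists but one protein carries a family on the
    professional-peptide-binder list, a predicted peptide:PPBD edge is
    emitted instead, labelled from the peptide-cluster store.
    """
    if mode not in ("all-to-all", "first-to-all"):
        raise ValueError(f"unknown mode {mode!r}")
    store_dir = Path(store_dir)
    ppbd = set(ppbd_list or [])
    dom_sum = pd.read_csv(store_dir / "clusters_domain_summary.tsv",
                          sep="\t", dtype=str, keep_default_na=False)
    chain_sum = pd.read_csv(store_dir / "clusters_chain_summary.tsv",
                            sep="\t", dtype=str, keep_default_na=False)
    pep = pd.read_csv(store_dir / "peptide_clusters.tsv", sep="\t",
                      dtype=str, keep_default_na=False)
    best: dict[tuple[str, str], tuple[int, int, str]] = {}
    for df in (dom_sum, chain_sum):
        for _, row in df.iterrows():
            key = tuple(row["family_key"].split("|"))
            cand = (int(row["n_crystal_forms"]), int(row["n_entries"]),
                    row["cluster_id"])
            if key not in best or cand > best[key]:
                best[key] = cand
    pep_best: dict[str, tuple[int, int, str]] = {}
    for _, row in pep.iterrows():
        cand = (int(row["n_cluster_forms"]), int(row["n_cluster_entries"]),
                row["cluster_id"])
        if row["pfam"] not in pep_best or cand > pep_best[row["pfam"]]:
            pep_best[row["pfam"]] = cand

    edges = []
    pairs = []
    for i in range(len(proteins)):
        for j in range(i + 1, len(proteins)):
            if mode == "first-to-all" and i != 0:
                continue
            pairs.append((proteins[i], proteins[j]))
    for p1, p2 in pairs:
        fams1 = p1.get("families", [])
        fams2 = p2.get("families", [])
        if not fams1 or not fams2:
            logger.warning("protein without annotations: %s",
                           p1["name"] if not fams1 else p2["name"])
            continue
        hit = None
        for f1 in fams1:
            for f2 in fams2:
                key = tuple(sorted((f1, f2)))
                if key in best and (hit is None or best[key] > hit[1]):
                    hit = (key, best[key])
        if hit is not None:
            key, (ncf, ne, cid) = hit
            edges.append({"protein_a": p1["name"], "protein_b": p2["name"],
                          "kind": "structure", "family_pair": "|".join(key),
                          "cluster_id": cid, "n_crystal_forms": ncf,
                          "n_entries": ne})
            continue
        ppbd_fams = sorted({f for f in fams1 + fams2 if f in ppbd})
        if ppbd_fams:
            fam = ppbd_fams[0]
            label = pep_best.get(fam)
            edges.append({"protein_a": p1["name"], "protein_b": p2["name"],
                          "kind": "predicted-peptide:PPBD",
                          "family_pair": fam,
                          "cluster_id": label[2] if label else "",
                          "n_crystal_forms": label[0] if label else 0,
                          "n_entries": label[1] if label else 0})
    return pd.DataFrame(edges, columns=[
        "protein_a", "protein_b", "kind", "family_pair", "cluster_id",
        "n_crystal_forms", "n_entries"])


def read_protein_list(path: str | Path) -> list[dict]:
    """TSV with columns name, uniprot, families ("F1;F2")."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        out.append({"name": row["name"],
                    "uniprot": row.get("uniprot", ""),
                    "families": [f for f in row["families"].split(";")
                                 if f]})
    return out
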