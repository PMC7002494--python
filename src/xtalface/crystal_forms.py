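"""Crystal-form grouping and merging.

Entries belong to the same crystal form when they share (1) the entry-level
family architecture, (2) the space group, (3) the asymmetric-unit chain
stoichiometry and (4) cell edges and angles within 1%.  Because the 1%
tolerance is not transitive, forms are the connected components of the
pairwise relation.  Forms whose interface censuses are largely the same
interfaces (>= two thirds matched at Q >= q_high) are merged — the classic
case being the same lattice solved once with a monomeric and once with a
dimeric asymmetric unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .config import PipelineConfig
from .interfaces import Interface, identity_q
from .structure_model import (ChainArchitecture, CrystalEntry, UnitCell,
                              entry_arch_key, entry_stoichiometry)


@dataclass
class EntryRecord:
    """An entry together with its derived architecture signature."""
    entry: CrystalEntry
    architectures: dict[str, ChainArchitecture]

    @property
    def arch_key(self) -> tuple[str, ...]:
        return entry_arch_key(self.architectures)

    @property
    def stoichiometry(self) -> tuple[tuple[str, int], ...]:
        return entry_stoichiometry(self.architectures)


@dataclass
class CrystalForm:
    cf_id: str
    member_entries: list[str]
    arch_key: tuple[str, ...]
    space_group: str
    representative_cell: UnitCell
    stoichiometry: tuple[tuple[str, int], ...]
    merged_from: list[str] = field(default_factory=list)


def _cells_close(c1: UnitCell, c2: UnitCell, tol: float) -> bool:
    return all(abs(x1 - x2) / max(x1, x2) <= tol
               for x1, x2 in zip(c1.params(), c2.params()))


def same_crystal_form(r1: EntryRecord, r2: EntryRecord,
                      config: PipelineConfig | None = None) -> bool:
    """The four-condition crystal-form test.

    Cell variance is evaluated per parameter as |x1-x2|/max(x1,x2) <= 1%.
    """
    config = config or PipelineConfig()
    e1, e2 = r1.entry, r2.entry
    if r1.arch_key != r2.arch_key:
        return False
    if (e1.space_group or "") != (e2.space_group or ""):
        return False
    if r1.stoichiometry != r2.stoichiometry:
        return False
    if e1.cell is None or e2.cell is None:
        return e1.cell is e2.cell
    return _cells_close(e1.cell, e2.cell, config.cell_tol)


def group_crystal_forms(records: list[EntryRecord],
                        config: PipelineConfig | None = None,
                        ) -> list[CrystalForm]:
    """Partition entries into crystal forms (connected components of the
    pairwise relation); deterministic ids sorted by smallest member."""
    if not records:
        raise ValueError("no entries to group")
    config = config or PipelineConfig()
    g = nx.Graph()
    g.add_nodes_from(range(len(records)))
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            if same_crystal_form(records[i], records[j], config):
                g.add_edge(i, j)
    comps = sorted((sorted(c, key=lambda i: records[i].entry.entry_id)
                    for c in nx.connected_components(g)),
                   key=lambda c: records[c[0]].entry.entry_id)
    forms = []
    for n, comp in enumerate(comps, start=1):
        rep = records[comp[0]]
        forms.append(CrystalForm(
            cf_id=f"CF{n:04d}",
            member_entries=[records[i].entry.entry_id for i in comp],
            arch_key=rep.arch_key,
            space_group=rep.entry.space_group or "",
            representative_cell=rep.entry.cell,
            stoichiometry=rep.stoichiometry))
    return forms


def _match_fraction(ifaces1: list[Interface], ifaces2: list[Interface],
                    config: PipelineConfig) -> float:
    """Greedy best-Q matching; fraction of the smaller census matched at
    Q >= q_high."""
    if not ifaces1 or not ifaces2:
        return 0.0
    scored = []
    for i, f1 in enumerate(ifaces1):
        for j, f2 in enumerate(ifaces2):
            scored.append((identity_q(f1, f2), i, j))
    scored.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_i: set[int] = set()
    used_j: set[int] = set()
    matched = 0
    for q, i, j in scored:
        if q < config.q_high:
            break
        if i in used_i or j in used_j:
            continue
        used_i.add(i)
        used_j.add(j)
        matched += 1
    return matched / min(len(ifaces1), len(ifaces2))


def merge_equivalent_forms(forms: list[CrystalForm],
                           interfaces_by_entry: dict[str, list[Interface]],
                           config: PipelineConfig | None = None,
                           ) -> list[CrystalForm]:
    """Merge forms sharing >= cf_merge_fraction of their interfaces.

    Candidate pairs are restricted to equal entry architecture signatures;
    each form is represented by its first member's unique-interface census.
    Merging runs to a fixpoint and is idempotent.
    """
    config = config or PipelineConfig()
    forms = list(forms)
    g = nx.Graph()
    g.add_nodes_from(range(len(forms)))
    for i in range(len(forms)):
        for j in range(i + 1, len(forms)):
            if forms[i].arch_key != forms[j].arch_key:
                continue
            fi = interfaces_by_entry.get(forms[i].member_entries[0], [])
            fj = interfaces_by_entry.get(forms[j].member_entries[0], [])
            if _match_fraction(fi, fj, config) >= config.cf_merge_fraction:
                g.add_edge(i, j)
    merged: list[CrystalForm] = []
    comps = sorted((sorted(c) for c in nx.connected_components(g)),
                   key=lambda c: forms[c[0]].member_entries[0])
    for n, comp in enumerate(comps, start=1):
        rep = forms[comp[0]]
        members = sorted({e for i in comp for e in forms[i].member_entries})
        merged.append(CrystalForm(
            cf_id=f"CF{n:04d}",
            member_entries=members,
            arch_key=rep.arch_key,
            space_group=rep.space_group,
            representative_cell=rep.representative_cell,
            stoichiometry=rep.stoichiometry,
            merged_from=sorted(forms[i].cf_id for i in comp)
            if len(comp) > 1 else []))
    return merged


def form_of_entry(forms: list[CrystalForm]) -> dict[str, str]:
    return {e: f.cf_id for f in forms for e in f.member_entries}
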