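"""Contact detection, interaction rules, census dedup, BSA, assemblies."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from conftest import identity_placement, random_unit
from xtalface.config import PipelineConfig
from xtalface.fixtures import (FixtureSpec, build_synthetic_crystal,
                               designed_dimer, generate_toy_fold)
from xtalface.interfaces import (ContactSet, PlacedUnit,
                                 assembly_contains_interface,
                                 buried_surface_area, contact_set,
                                 enumerate_unique_interfaces,
                                 _deduplicate, is_interacting)
from xtalface.lattice import expand_lattice
from xtalface.structure_model import (AssemblyDef, Atom, CrystalEntry,
                                      PolymerChain, Residue, SymOp,
                                      UnitCell)


def brute_force_pairs(ua: PlacedUnit, ub: PlacedUnit,
                      config: PipelineConfig) -> dict:
    """Independent all-pairs O(n^2) oracle for contact_set."""
    out = {}
    ra = {r.seq_pos: r for r in ua.chain.residues}
    rb = {r.seq_pos: r for r in ub.chain.residues}
    for i, res_a in ra.items():
        pa = ua.placement.apply(np.array([a.pos for a in res_a.atoms]))
        cba = res_a.cbeta
        cba = None if cba is None else ua.placement.apply(cba[None])[0]
        for j, res_b in rb.items():
            pb = ub.placement.apply(np.array([a.pos for a in res_b.atoms]))
            d_atom = float(cdist(pa, pb).min())
            cbb = res_b.cbeta
            cbb = None if cbb is None else ub.placement.apply(cbb[None])[0]
            d_cb = (float(np.linalg.norm(cba - cbb))
                    if cba is not None and cbb is not None else None)
            if d_atom <= config.atom_cutoff or \
                    (d_cb is not None and d_cb <= config.cbeta_cutoff):
                out[(i, j)] = (d_atom, d_cb)
    return out


def test_contact_set_matches_brute_force(config):
    rng = np.random.default_rng(42)
    for _ in range(25):
        ua = random_unit(rng, "A", rng.integers(5, 30))
        ub = random_unit(rng, "B", rng.integers(5, 30))
        cs = contact_set(ua, ub, config)
        oracle = brute_force_pairs(ua, ub, config)
        assert set(cs.pairs) == set(oracle)
        for key, (d_atom, d_cb) in oracle.items():
            assert cs.pairs[key][0] == pytest.approx(d_atom, abs=1e-9)
            if d_cb is None:
                assert cs.pairs[key][1] is None
            else:
                assert cs.pairs[key][1] == pytest.approx(d_cb, abs=1e-9)


def test_contact_set_swap_symmetry(config):
    rng = np.random.default_rng(7)
    ua = random_unit(rng, "A", 15)
    ub = random_unit(rng, "B", 15)
    fwd = contact_set(ua, ub, config)
    rev = contact_set(ub, ua, config)
    assert fwd.pairs == rev.transpose().pairs
    assert (fwd.n_cbeta12, fwd.n_atom5) == (rev.n_cbeta12, rev.n_atom5)


def test_empty_unit_raises(config):
    rng = np.random.default_rng(1)
    ua = random_unit(rng, "A", 5)
    empty = PolymerChain(asym_id="E", auth_id="E", entity_id="",
                         sequence="A", polymer_type="polypeptide",
                         residues=[Residue("E", 1, "ALA", [])])
    with pytest.raises(ValueError):
        contact_set(ua, PlacedUnit(empty, identity_placement("E")), config)


@pytest.mark.parametrize("n_cb,n_at,expected", [
    (12, 1, True),   # first clause
    (10, 1, True),   # boundary of the C-beta clause
    (9, 5, True),    # second clause alone
    (11, 0, False),  # C-beta pairs but no atomic contact
    (9, 4, False),   # below both clauses
    (0, 5, True),    # atomic clause needs no C-beta support
])
def test_interaction_rule_truth_table(n_cb, n_at, expected, config):
    pairs = {}
    for k in range(n_at):
        pairs[(k + 1, 1)] = (4.0, 11.0 if k < n_cb else None)
    for k in range(n_at, max(n_cb, n_at)):
        pairs[(k + 1, 1)] = (7.0, 11.0)
    cs = ContactSet(pairs, config.atom_cutoff, config.cbeta_cutoff)
    assert (cs.n_cbeta12, cs.n_atom5) == (n_cb, n_at)
    assert is_interacting(cs, "chain", config) is expected
    assert is_interacting(cs, "domain", config) is expected


class TestCensus:
    def test_designed_interface_recovered(self, config):
        entry, truth = build_synthetic_crystal(
            FixtureSpec(seed=21, packing_gap=None))
        ifaces = enumerate_unique_interfaces(
            entry, expand_lattice(entry), "chain", config,
            compute_bsa=False)
        assert len(ifaces) == 1
        assert set(ifaces[0].contacts.pairs) == \
            {tuple(p) for p in truth["designed"]["pairs"]}

    def test_packing_contact_reported_once(self, config):
        entry, truth = build_synthetic_crystal(
            FixtureSpec(seed=22, packing_gap=3.2))
        ifaces = enumerate_unique_interfaces(
            entry, expand_lattice(entry), "chain", config,
            compute_bsa=False)
        # designed + one packing class, each a single representative
        assert len(ifaces) == 2
        assert len({f.signature() for f in ifaces}) == 2

    def test_screw_axis_dimer_needs_expansion(self, config):
        """The designed interface of the P21 fixture crosses the screw
        axis: invisible in the asymmetric unit, found in the lattice."""
        entry, truth = build_synthetic_crystal(
            FixtureSpec(seed=23, space_group="P 1 21 1"))
        assert len(entry.chains) == 1  # nothing to pair inside the ASU
        ifaces = enumerate_unique_interfaces(
            entry, expand_lattice(entry), "chain", config,
            compute_bsa=False)
        designed = {tuple(p) for p in truth["designed"]["pairs"]}
        sigs = [set(f.contacts.pairs) for f in ifaces]
        assert any(s == designed or s == {(j, i) for i, j in designed}
                   for s in sigs)

    def test_census_deterministic(self, config):
        entry, _ = build_synthetic_crystal(FixtureSpec(seed=24,
                                                       packing_gap=3.2))
        ids1 = [f.interface_id for f in enumerate_unique_interfaces(
            entry, expand_lattice(entry), "chain", config,
            compute_bsa=False)]
        ids2 = [f.interface_id for f in enumerate_unique_interfaces(
            entry, expand_lattice(entry), "chain", config,
            compute_bsa=False)]
        assert ids1 == ids2

    def test_dedup_idempotent(self, config):
        entry, _ = build_synthetic_crystal(FixtureSpec(seed=25,
                                                       packing_gap=3.2))
        ifaces = enumerate_unique_interfaces(
            entry, expand_lattice(entry), "chain", config,
            compute_bsa=False)
        assert _deduplicate(ifaces) == ifaces


class TestDomainLevel:
    def _two_domain_entry(self):
        """One chain made of two packed 32-residue halves."""
        seq, coords = generate_toy_fold(32, 31)
        a, b = designed_dimer(seq, coords)
        residues = []
        for r in a.residues:
            residues.append(Residue("A", r.seq_pos, r.name, r.atoms))
        for r in b.residues:
            residues.append(Residue("A", r.seq_pos + 32, r.name, r.atoms))
        chain = PolymerChain(asym_id="A", auth_id="A", entity_id="",
                             sequence=seq + seq,
                             polymer_type="polypeptide", residues=residues)
        cell = UnitCell(120, 120, 120, 90, 90, 90)
        entry = CrystalEntry(entry_id="2DOM", cell=cell, space_group="P 1",
                             sym_ops=[SymOp(np.eye(3), np.zeros(3))],
                             chains=[chain], ligands=[])
        from xtalface.structure_model import DomainInstance
        doms = [DomainInstance("d1", "PF1", "F1", None, "A", [(1, 32)],
                               {i: i for i in range(1, 33)}, 32),
                DomainInstance("d2", "PF2", "F2", None, "A", [(33, 64)],
                               {i + 32: i for i in range(1, 33)}, 32)]
        return entry, doms

    def test_intra_chain_domain_interface(self, config):
        entry, doms = self._two_domain_entry()
        placements = expand_lattice(entry)
        chain_ifs = enumerate_unique_interfaces(
            entry, placements, "chain", config, compute_bsa=False)
        dom_ifs = enumerate_unique_interfaces(
            entry, placements, "domain", config, domains=doms,
            compute_bsa=False)
        assert chain_ifs == []
        assert len(dom_ifs) == 1 and dom_ifs[0].intra_chain

    def test_domain_contacts_subset_of_chain(self, config):
        """Domain interfaces are carved out of chain-level contact sets."""
        entry, truth = build_synthetic_crystal(FixtureSpec(seed=26))
        from xtalface.structure_model import DomainInstance
        doms = [DomainInstance(f"d{c}", "PF1", "F1", None, c, [(1, 32)],
                               {i: i for i in range(1, 33)}, 32)
                for c in ("A", "B")]
        placements = expand_lattice(entry)
        chain_ifs = enumerate_unique_interfaces(
            entry, placements, "chain", config, compute_bsa=False)
        dom_ifs = enumerate_unique_interfaces(
            entry, placements, "domain", config, domains=doms,
            compute_bsa=False)
        chain_pairs = set().union(*(set(f.contacts.pairs)
                                    for f in chain_ifs))
        for f in dom_ifs:
            assert set(f.contacts.pairs) <= chain_pairs


class TestBuriedSurfaceArea:
    def test_non_touching_is_zero(self, config):
        rng = np.random.default_rng(3)
        ua = random_unit(rng, "A", 8, spread=5.0)
        ub = random_unit(rng, "B", 8, spread=5.0)
        for r in ub.chain.residues:
            for a in r.atoms:
                a.pos = a.pos + np.array([80.0, 0.0, 0.0])
        ub._cache.clear()
        from xtalface.interfaces import _make_interface
        iface = _make_interface("T", "chain", ua, ub,
                                ContactSet({}, 5, 12))
        assert buried_surface_area(iface, config) == pytest.approx(
            0.0, abs=0.5)

    def test_against_high_density_recomputation(self, config):
        """The 960-point default must agree with a 10x-density pass."""
        entry, _ = build_synthetic_crystal(FixtureSpec(seed=27))
        iface = enumerate_unique_interfaces(
            entry, expand_lattice(entry), "chain", config,
            compute_bsa=False)[0]
        b_default = buried_surface_area(iface, config)
        b_dense = buried_surface_area(
            iface, config.replace(sasa_points=9600))
        assert b_default == pytest.approx(b_dense, rel=0.02)

    def test_monotone_on_pull_apart(self, config):
        seq, coords = generate_toy_fold(32, 28)
        values = []
        for extra in (0.0, 1.0, 2.5, 5.0, 12.0):
            a, b = designed_dimer(seq, coords, sep=8.8 + extra)
            ua = PlacedUnit(a, identity_placement("A"))
            ub = PlacedUnit(b, identity_placement("B"))
            from xtalface.interfaces import _make_interface
            iface = _make_interface("T", "chain", ua, ub,
                                    ContactSet({}, 5, 12))
            values.append(buried_surface_area(iface, config))
        assert all(v1 >= v2 - 0.5 for v1, v2 in zip(values, values[1:]))
        assert values[0] > values[-1]


class TestAssemblyPresence:
    def test_author_dimer_contains_designed(self, config):
        entry, _ = build_synthetic_crystal(
            FixtureSpec(seed=29, packing_gap=None),
            crowder_seq="ADEFHIKLMNPQRSTVWYADEFHIKLMNPQRSTVW")
        asm = AssemblyDef("1", "author", [("A", 0, (0, 0, 0)),
                                          ("B", 0, (0, 0, 0))])
        entry.assemblies.append(asm)
        ifaces = enumerate_unique_interfaces(
            entry, expand_lattice(entry), "chain", config,
            compute_bsa=False)
        designed = [f for f in ifaces
                    if {f.unit_a.chain.asym_id,
                        f.unit_b.chain.asym_id} == {"A", "B"}]
        packing = [f for f in ifaces
                   if "C" in {f.unit_a.chain.asym_id,
                              f.unit_b.chain.asym_id}]
        assert designed and packing
        assert assembly_contains_interface(designed[0], asm, entry, config)
        assert not assembly_contains_interface(packing[0], asm, entry,
                                               config)

    def test_monomer_assembly_contains_nothing(self, config):
        entry, _ = build_synthetic_crystal(FixtureSpec(seed=30))
        asm = AssemblyDef("1", "author", [("A", 0, (0, 0, 0))])
        ifaces = enumerate_unique_interfaces(
            entry, expand_lattice(entry), "chain", config,
            compute_bsa=False)
        assert not assembly_contains_interface(ifaces[0], asm, entry,
                                               config)
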