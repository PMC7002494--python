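"""Parsing, validation and architecture derivation."""

import numpy as np
import pandas as pd
import pytest

from xtalface.config import PipelineConfig
from xtalface.fixtures import (FixtureSpec, build_ligand_entry,
                               build_nucleic_entry, build_synthetic_crystal)
from xtalface.structure_model import (AnnotationError, ChainArchitecture,
                                      DomainInstance,
                                      NonCrystallographicError,
                                      derive_architectures,
                                      ingest_annotations, read_entry,
                                      write_entry)


def _ann_row(entry_id="XE001", asym="A", pfam_acc="PF00001",
             pfam_id="Fam", intervals="1-30", hmm_length="30",
             hmm_map=None, clan="", uniprot="UP1", species="synthetic"):
    if hmm_map is None:
        hmm_map = ",".join(f"{i}:{i}" for i in range(1, 31))
    return {"entry_id": entry_id, "asym_id": asym, "pfam_acc": pfam_acc,
            "pfam_id": pfam_id, "clan": clan, "intervals": intervals,
            "hmm_length": hmm_length, "hmm_map": hmm_map,
            "uniprot": uniprot, "species": species}


@pytest.mark.parametrize("builder", [
    lambda: build_synthetic_crystal(FixtureSpec(seed=1))[0],
    lambda: build_ligand_entry(seed=2)[0],
    lambda: build_nucleic_entry(seed=3)[0],
])
def test_mmcif_round_trip(tmp_path, builder):
    """Writing then re-reading reproduces sequences, polymer types, cell
    parameters and the operator count exactly."""
    entry = builder()
    path = tmp_path / "e.cif"
    write_entry(entry, path)
    back = read_entry(path)
    assert [c.asym_id for c in back.chains] == \
        [c.asym_id for c in entry.chains]
    for c in entry.chains:
        assert back.chain(c.asym_id).sequence == c.sequence
        assert back.chain(c.asym_id).polymer_type == c.polymer_type
    assert np.allclose(back.cell.params(), entry.cell.params(), atol=1e-3)
    assert len(back.sym_ops) == len(entry.sym_ops)
    assert back.space_group == entry.space_group


def test_waters_flagged_and_identified(tmp_path):
    entry, _ = build_ligand_entry(seed=4)
    path = tmp_path / "lig.cif"
    write_entry(entry, path)
    back = read_entry(path)
    waters = [l for l in back.ligands if l.is_water]
    assert len(waters) == 1 and waters[0].comp_id == "HOH"
    assert {l.comp_id for l in back.ligands if not l.is_water} == \
        {"LG1", "LG2"}


def test_missing_space_group_is_non_crystallographic(tmp_path):
    entry, _ = build_ligand_entry(seed=5)
    entry.space_group = None
    entry.sym_ops = []
    path = tmp_path / "nosg.cif"
    write_entry(entry, path)
    back = read_entry(path)
    assert not back.is_crystallographic
    with pytest.raises(NonCrystallographicError):
        back.require_crystallographic()


def test_altloc_highest_occupancy_kept(tmp_path):
    pdb = (
        "CRYST1   50.000   50.000   50.000  90.00  90.00  90.00 P 1\n"
        "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40"
        "  0.00           C\n"
        "ATOM      2  CA BALA A   1       2.000   0.000   0.000  0.60"
        "  0.00           C\n"
        "ATOM      3  CB AALA A   1       0.000   1.000   0.000  0.50"
        "  0.00           C\n"
        "ATOM      4  CB BALA A   1       3.000   1.000   0.000  0.50"
        "  0.00           C\n"
        "END\n")
    path = tmp_path / "alt.pdb"
    path.write_text(pdb)
    entry = read_entry(path, dialect="pdb")
    res = entry.chains[0].residues[0]
    assert len(res.atoms) == 2
    # CA: occupancy 0.6 wins; CB: tie broken by first altloc code
    assert res.atom("CA").pos[0] == pytest.approx(2.0)
    assert res.atom("CB").pos[0] == pytest.approx(0.0)


class TestIngestAnnotations:
    def _entry(self):
        entry, _ = build_synthetic_crystal(FixtureSpec(seed=6),
                                           entry_id="XE001")
        return entry

    def test_basic_row_and_coverage(self):
        entry = self._entry()
        doms = ingest_annotations(entry, pd.DataFrame([_ann_row()]))
        assert len(doms) == 1
        d = doms[0]
        assert d.coverage == pytest.approx(1.0)
        assert d.intervals == [(1, 30)]
        assert entry.chain("A").uniprot == "UP1"

    def test_split_domain_two_intervals(self):
        row = _ann_row(intervals="1-10;20-30",
                       hmm_map=",".join(f"{i}:{i}" for i in
                                        list(range(1, 11))
                                        + list(range(20, 31))))
        doms = ingest_annotations(self._entry(), pd.DataFrame([row]))
        assert doms[0].intervals == [(1, 10), (20, 30)]
        assert doms[0].n_residues == 21

    def test_unknown_chain_rejected_with_row(self):
        with pytest.raises(AnnotationError, match="chain 'Z'"):
            ingest_annotations(self._entry(),
                               pd.DataFrame([_ann_row(asym="Z")]))

    def test_interval_beyond_chain_rejected(self):
        with pytest.raises(AnnotationError, match="beyond chain"):
            ingest_annotations(self._entry(),
                               pd.DataFrame([_ann_row(intervals="1-99")]))

    def test_hmm_position_out_of_model_rejected(self):
        row = _ann_row(hmm_map="1:45")
        with pytest.raises(AnnotationError, match="outside"):
            ingest_annotations(self._entry(), pd.DataFrame([row]))

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(AnnotationError, match="overlapping"):
            DomainInstance("d", "PF1", "F", None, "A",
                           [(1, 10), (5, 20)], {}, 30)


class TestArchitectures:
    def _domains(self, chain="A"):
        k = DomainInstance("d1", "PF69", "Pkinase", None, chain,
                           [(10, 290)], {}, 260)
        s = DomainInstance("d2", "PF17", "SH2", None, chain,
                           [(300, 380)], {}, 80)
        return k, s

    def test_order_by_interval_start(self):
        entry, _ = build_synthetic_crystal(FixtureSpec(seed=7, n_res=400))
        k, s = self._domains()
        archs = derive_architectures(entry, [k, s])
        assert archs["A"].arch_string == "(Pkinase)_(SH2)"
        assert archs["B"].arch_string == ""

    def test_input_permutation_invariant(self):
        entry, _ = build_synthetic_crystal(FixtureSpec(seed=7, n_res=400))
        k, s = self._domains()
        a1 = derive_architectures(entry, [k, s])
        a2 = derive_architectures(entry, [s, k])
        assert a1 == a2

    def test_tandem_repeat_not_collapsed(self):
        entry, _ = build_synthetic_crystal(FixtureSpec(seed=7, n_res=400))
        d1 = DomainInstance("d1", "PF9", "X", None, "A", [(1, 100)], {},
                            100)
        d2 = DomainInstance("d2", "PF9", "X", None, "A", [(150, 250)], {},
                            100)
        archs = derive_architectures(entry, [d2, d1])
        assert archs["A"].arch_string == "(X)_(X)"

    def test_singleton(self):
        assert ChainArchitecture(("ACT",)).arch_string == "(ACT)"


def test_thresholds_flow_from_config():
    """Overriding the C-beta cutoff (12 -> 8 A) must change downstream
    contact counts; no stage may hard-code the literal."""
    from xtalface.fixtures import designed_dimer, generate_toy_fold
    from xtalface.interfaces import PlacedUnit, contact_set
    from conftest import identity_placement

    seq, coords = generate_toy_fold(32, 1)
    a, b = designed_dimer(seq, coords)
    ua = PlacedUnit(a, identity_placement("A"))
    ub = PlacedUnit(b, identity_placement("B"))
    wide = contact_set(ua, ub, PipelineConfig())
    narrow = contact_set(PlacedUnit(a, identity_placement("A")),
                         PlacedUnit(b, identity_placement("B")),
                         PipelineConfig(cbeta_cutoff=8.0))
    assert narrow.n_cbeta12 < wide.n_cbeta12
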