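"""Peptide classification, superposition, RMSD_pep and mode clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from conftest import identity_placement
from xtalface.config import PipelineConfig
from xtalface.fixtures import (FixtureSpec, build_peptide_complex,
                               generate_toy_fold, make_chain)
from xtalface.interfaces import ContactSet, PlacedUnit
from xtalface.peptides import (PeptideInterface, cluster_peptide_interfaces,
                               find_peptide_interfaces, is_peptide,
                               is_peptide_interacting, peptide_rmsd,
                               superpose_by_hmm)
from xtalface.structure_model import (CrystalEntry, DomainInstance, SymOp,
                                      UnitCell, ingest_annotations)


def _complex(mode="plus", seed=0, entry_id="XP001", **kw):
    entry, rows = build_peptide_complex(mode=mode, seed=seed,
                                        entry_id=entry_id, **kw)
    doms = ingest_annotations(entry, pd.DataFrame(rows))
    return entry, doms


def quaternion_superpose(mobile, target):
    """Independent oracle: Horn's closed-form quaternion method."""
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    cm, ct = mobile.mean(0), target.mean(0)
    m = (mobile - cm).T @ (target - ct)
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz]])
    w, v = np.linalg.eigh(k)
    q = v[:, np.argmax(w)]
    rot = Rotation.from_quat([q[1], q[2], q[3], q[0]]).as_matrix()
    moved = (mobile - cm) @ rot.T + ct
    return float(np.sqrt(((moved - target) ** 2).sum(1).mean()))


class TestPeptideDefinition:
    @pytest.mark.parametrize("length,expected", [(29, True), (30, False)])
    def test_length_boundary_exact(self, length, expected, config):
        seq, coords = generate_toy_fold(length, 1)
        chain = make_chain("P", seq, coords)
        assert is_peptide(chain, config) is expected

    def test_unmodeled_residues_count(self, config):
        """Chain length is the declared polymer length, not the modeled
        residue count."""
        seq, coords = generate_toy_fold(30, 2)
        chain = make_chain("P", seq, coords)
        chain.residues = chain.residues[:20]  # 10 residues unmodeled
        assert not is_peptide(chain, config)

    @pytest.mark.parametrize("n_cb,n_at,expected", [
        (11, 0, True),   # C-beta clause alone suffices (OR rule)
        (0, 5, True),
        (9, 4, False),
    ])
    def test_or_rule(self, n_cb, n_at, expected, config):
        pairs = {}
        for k in range(n_at):
            pairs[(k + 1, 1)] = (4.0, 11.0 if k < n_cb else None)
        for k in range(n_at, max(n_cb, n_at)):
            pairs[(k + 1, 1)] = (7.0, 11.0)
        cs = ContactSet(pairs, config.atom_cutoff, config.cbeta_cutoff)
        assert is_peptide_interacting(cs, config) is expected


class TestFindPeptideInterfaces:
    def test_bound_peptide_found(self, config):
        entry, doms = _complex()
        pis = find_peptide_interfaces(entry, doms, config=config)
        assert len(pis) == 1
        assert pis[0].pfam == "PF99901"
        assert len(pis[0].hmm_sites) >= 3

    def test_thirty_residue_chain_is_not_a_peptide(self, config):
        entry, doms = _complex()
        pep = entry.chain("P")
        pep.sequence = pep.sequence + "A" * (30 - len(pep.sequence))
        assert find_peptide_interfaces(entry, doms, config=config) == []

    @staticmethod
    def _with_competitor(z_shift: float):
        """Add a second annotated chain Z grazing the peptide from the
        far side; z_shift tunes how many contacts Z captures."""
        entry, doms = _complex()
        seq2, coords2 = generate_toy_fold(34, 99)
        far = make_chain("Z", seq2, coords2)
        pep = entry.chain("P")
        pcen = np.vstack([a.pos for r in pep.residues
                          for a in r.atoms]).mean(0)
        dcen = np.vstack([a.pos for r in entry.chain("A").residues
                          for a in r.atoms]).mean(0)
        u = pcen - dcen
        u[2] = 0.0
        u /= np.linalg.norm(u)
        zcen = np.vstack([a.pos for r in far.residues
                          for a in r.atoms]).mean(0)
        delta = (pcen + 8.0 * u + np.array([0.0, 0.0, z_shift])) - zcen
        for r in far.residues:
            for a in r.atoms:
                a.pos = a.pos + delta
        entry.chains.append(far)
        doms = doms + [DomainInstance(
            "Zdom", "PF99902", "OtherFam", None, "Z", [(1, 34)],
            {i: i for i in range(1, 35)}, 34)]
        return entry, doms

    def test_dominant_chain_assignment(self, config):
        """A peptide with >= 75% of its atomic contacts on one chain is
        assigned to that chain only; the losing interface is dropped even
        though it satisfies the contact rule on its own."""
        entry, doms = self._with_competitor(z_shift=28.0)
        pis = find_peptide_interfaces(entry, doms, config=config)
        assert {p.domain_unit.chain.asym_id for p in pis} == {"A"}

    def test_no_dominant_chain_keeps_all(self, config):
        """Below the 75% threshold every qualifying interface is kept."""
        entry, doms = self._with_competitor(z_shift=20.0)
        pis = find_peptide_interfaces(entry, doms, config=config)
        assert {p.domain_unit.chain.asym_id for p in pis} == {"A", "Z"}


class TestSuperposition:
    def test_self_identity(self):
        _, doms = _complex()
        entry, _ = _complex()
        unit = PlacedUnit(entry.chain("A"), identity_placement("A"),
                          doms[0])
        rot, tran, rmsd, common = superpose_by_hmm(unit, unit)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(rot, np.eye(3))
        assert len(common) == 34

    def test_recovers_known_transform(self):
        entry, doms = _complex()
        entry2, doms2 = _complex()
        applied = Rotation.from_euler("xyz", [31, -54, 117],
                                      degrees=True).as_matrix()
        shift = np.array([5.0, -3.0, 11.0])
        for r in entry2.chain("A").residues:
            for a in r.atoms:
                a.pos = applied @ a.pos + shift
        u1 = PlacedUnit(entry.chain("A"), identity_placement("A"),
                        doms[0])
        u2 = PlacedUnit(entry2.chain("A"), identity_placement("A"),
                        doms2[0])
        rot, tran, rmsd, _ = superpose_by_hmm(u1, u2)
        assert rmsd < 1e-6
        assert np.allclose(rot @ applied, np.eye(3), atol=1e-6)

    def test_agrees_with_quaternion_oracle(self):
        rng = np.random.default_rng(8)
        mobile = rng.normal(0, 10, (20, 3))
        applied = Rotation.random(random_state=3).as_matrix()
        target = mobile @ applied.T + rng.normal(0, 0.5, (20, 3))
        from xtalface.geometry import kabsch
        _, _, r_kabsch = kabsch(mobile, target)
        r_quat = quaternion_superpose(mobile, target)
        assert r_kabsch == pytest.approx(r_quat, abs=1e-6)

    def test_too_few_common_positions(self):
        entry, doms = _complex()
        small = DomainInstance("s", "PF99901", "ToyFold", None, "A",
                               [(1, 34)], {1: 1, 2: 2}, 34)
        u1 = PlacedUnit(entry.chain("A"), identity_placement("A"), small)
        with pytest.raises(ValueError, match=">= 3"):
            superpose_by_hmm(u1, u1)


class TestPeptideRmsd:
    def test_self_zero_at_offset_zero(self, config):
        entry, doms = _complex()
        pi = find_peptide_interfaces(entry, doms, config=config)[0]
        r, off = peptide_rmsd(pi, pi, config)
        assert r == pytest.approx(0.0, abs=1e-9) and off == 0

    def test_leading_extension_found_at_offset(self, config):
        e1, d1 = _complex(seed=20, entry_id="XS001")
        e2, d2 = _complex(seed=20, entry_id="XS002", lead_extra=2)
        p1 = find_peptide_interfaces(e1, d1, config=config)[0]
        p2 = find_peptide_interfaces(e2, d2, config=config)[0]
        r, off = peptide_rmsd(p1, p2, config)
        assert r == pytest.approx(0.0, abs=1e-6)
        assert off == 2

    def test_opposite_faces_exceed_threshold(self, config):
        e1, d1 = _complex(mode="plus", seed=30, entry_id="XA")
        e2, d2 = _complex(mode="minus", seed=30, entry_id="XB")
        p1 = find_peptide_interfaces(e1, d1, config=config)[0]
        p2 = find_peptide_interfaces(e2, d2, config=config)[0]
        r, _ = peptide_rmsd(p1, p2, config)
        assert r > config.pep_max_rmsd

    def test_symmetry(self, config):
        e1, d1 = _complex(mode="plus", seed=31, entry_id="XA")
        e2, d2 = _complex(mode="plus", seed=32, entry_id="XB",
                          z_offset=2.0)
        p1 = find_peptide_interfaces(e1, d1, config=config)[0]
        p2 = find_peptide_interfaces(e2, d2, config=config)[0]
        assert peptide_rmsd(p1, p2, config)[0] == pytest.approx(
            peptide_rmsd(p2, p1, config)[0], abs=1e-6)


class TestPeptideClustering:
    def _interfaces(self, modes, seeds=None):
        pis = []
        for i, mode in enumerate(modes):
            seed = (seeds or range(100, 100 + len(modes)))[i]
            entry, doms = _complex(mode=mode, seed=seed,
                                   entry_id=f"XP{i + 1:03d}")
            pis.extend(find_peptide_interfaces(entry, doms))
        return pis

    def test_conserved_groove_one_cluster(self, config):
        pis = self._interfaces(["plus"] * 4)
        clusters = cluster_peptide_interfaces(pis, config)
        assert len(clusters) == 1 and len(clusters[0].members) == 4
        assert len(clusters[0].shared_hmm_sites) >= config.pep_min_nhmm

    def test_two_binding_modes_two_clusters(self, config):
        pis = self._interfaces(["plus", "plus", "minus", "minus"])
        clusters = cluster_peptide_interfaces(pis, config)
        assert len(clusters) == 2
        assert sorted(len(c.members) for c in clusters) == [2, 2]

    def test_two_shared_sites_never_merge(self, config):
        """N_hmm >= 3 is a hard floor even at RMSD 0."""
        pis = self._interfaces(["plus", "plus"])
        pis[0].hmm_sites = frozenset(list(pis[0].hmm_sites)[:2])
        clusters = cluster_peptide_interfaces(pis, config)
        assert len(clusters) == 2

    def test_permutation_invariance_and_audit(self, config):
        pis = self._interfaces(["plus", "minus", "plus", "plus"])
        c1 = cluster_peptide_interfaces(pis, config)
        c2 = cluster_peptide_interfaces(list(reversed(pis)), config)
        as_sets = lambda cl: sorted(
            sorted(m.interface_id for m in c.members) for c in cl)
        assert as_sets(c1) == as_sets(c2)
        for c in c1:  # post-hoc audit of the merge constraints
            for i, a in enumerate(c.members):
                for b in c.members[i + 1:]:
                    assert len(a.hmm_sites & b.hmm_sites) >= \
                        config.pep_min_nhmm
                    assert peptide_rmsd(a, b, config)[0] <= \
                        config.pep_max_rmsd
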