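"""Shared fixtures: synthetic benchmark sets and fabricated interfaces."""

from __future__ import annotations

import numpy as np
import pytest

from xtalface.config import PipelineConfig
from xtalface.fixtures import FixtureSpec, generate_benchmark_set
from xtalface.interfaces import ContactSet, Interface, PlacedUnit
from xtalface.lattice import SymmetryPlacement
from xtalface.pipeline import run_pipeline
from xtalface.structure_model import Atom, PolymerChain, Residue


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def benchmark_dir(tmp_path_factory):
    """Three homolog crystal forms sharing the designed dimer, plus one
    form without it."""
    out = tmp_path_factory.mktemp("bench")
    spec = FixtureSpec(seed=11)
    truth = generate_benchmark_set(spec, out, add_dimerless_form=True)
    return out, truth


@pytest.fixture(scope="session")
def benchmark_result(benchmark_dir, tmp_path_factory):
    out, truth = benchmark_dir
    store = tmp_path_factory.mktemp("store")
    res = run_pipeline(sorted(out.glob("*.cif")), out / "annotations.tsv",
                       store, assembly_table=out / "assemblies.tsv")
    return res, truth, store


# ---------------------------------------------------------------------------
# fabricated units: contact sets with hand-chosen residue pairs


def identity_placement(asym_id: str) -> SymmetryPlacement:
    return SymmetryPlacement(asym_id, 0, (0, 0, 0),
                             tuple(map(tuple, np.eye(3))), (0.0, 0.0, 0.0))


def toy_chain(asym_id: str, sequence: str,
              uniprot: str | None = None) -> PolymerChain:
    residues = [Residue(asym_id, i + 1, "ALA",
                        [Atom("CA", "C", np.zeros(3))])
                for i in range(len(sequence))]
    return PolymerChain(asym_id=asym_id, auth_id=asym_id, entity_id="",
                        sequence=sequence, polymer_type="polypeptide",
                        residues=residues, uniprot=uniprot)


def toy_interface(pairs, seq_a="A" * 40, seq_b=None, entry_id="TOY",
                  chain_a="A", chain_b="B", arch="(F)",
                  iface_id=None) -> Interface:
    """A chain-level interface with a fabricated residue-pair contact set."""
    seq_b = seq_a if seq_b is None else seq_b
    ua = PlacedUnit(toy_chain(chain_a, seq_a), identity_placement(chain_a))
    ub = PlacedUnit(toy_chain(chain_b, seq_b), identity_placement(chain_b))
    ua.arch_string = arch
    ub.arch_string = arch
    cs = ContactSet({(i, j): (4.0, 8.0) for i, j in pairs},
                    atom_cutoff=5.0, cbeta_cutoff=12.0)
    iid = iface_id or f"{entry_id}:chain:{chain_a}--{chain_b}"
    return Interface(interface_id=iid, entry_id=entry_id, level="chain",
                     unit_a=ua, unit_b=ub, contacts=cs)


def random_unit(rng: np.random.Generator, asym_id: str, n_res: int,
                spread: float = 15.0, atoms_per_res: int = 4) -> PlacedUnit:
    """A random residue cloud (with C-beta) for contact-detection tests."""
    residues = []
    for i in range(n_res):
        centre = rng.uniform(-spread, spread, 3)
        atoms = [Atom("CB" if k == 0 else f"C{k}", "C",
                      centre + rng.normal(0, 1.2, 3))
                 for k in range(atoms_per_res)]
        residues.append(Residue(asym_id, i + 1, "ALA", atoms))
    chain = PolymerChain(asym_id=asym_id, auth_id=asym_id, entity_id="",
                         sequence="A" * n_res, polymer_type="polypeptide",
                         residues=residues)
    return PlacedUnit(chain, identity_placement(asym_id))
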