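"""Crystal-lattice expansion: 27 unit cells around the reference cell.

Interfaces in a crystal are not confined to the deposited asymmetric unit:
symmetry mates in neighbouring cells make lattice contacts, and biologically
relevant dimers frequently form across symmetry axes.  This module places
every chain copy generated by the space-group operators in the 3x3x3 block
of unit cells around the reference cell, in the orthogonal frame, so the
interface census downstream can see every contact class.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .structure_model import CrystalEntry, PolymerChain

#: The 27 cell translations of the 3x3x3 block, lexicographic.
CELL_SHIFTS: tuple[tuple[int, int, int], ...] = tuple(
    itertools.product((-1, 0, 1), repeat=3))


@dataclass(frozen=True)
class SymmetryPlacement:
    """One symmetry-generated copy of a chain.

    ``transform`` maps deposited orthogonal coordinates to the copy's
    orthogonal coordinates: orthogonalization o (rotation + translation in
    fractional space) o fractionalization.  The identity operator with zero
    shift reproduces deposited coordinates exactly (bit-equal).
    """
    source_chain: str
    op_index: int
    shift: tuple[int, int, int]
    rot: tuple[tuple[float, float, float], ...]
    tran: tuple[float, float, float]

    @property
    def is_identity(self) -> bool:
        return (self.op_index == 0 and self.shift == (0, 0, 0))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        if self.is_identity:
            return np.asarray(coords, float)
        r = np.asarray(self.rot)
        t = np.asarray(self.tran)
        return np.asarray(coords, float) @ r.T + t

    @property
    def key(self) -> tuple[str, int, tuple[int, int, int]]:
        return (self.source_chain, self.op_index, self.shift)

    def label(self) -> str:
        i, j, k = self.shift
        return f"{self.source_chain}|{self.op_index}|{i},{j},{k}"


def _ordered_ops(entry: CrystalEntry):
    """Operators with the identity first (placement op_index 0)."""
    ops = list(entry.sym_ops)
    ident = [i for i, op in enumerate(ops) if op.is_identity]
    if ident and ident[0] != 0:
        ops.insert(0, ops.pop(ident[0]))
    return ops


def expand_lattice(entry: CrystalEntry) -> list[SymmetryPlacement]:
    """All chain placements of the 3x3x3 lattice block.

    Produces exactly ``len(chains) * len(sym_ops) * 27`` placements in
    deterministic (chain, op_index, shift) lexicographic order.  Raises
    :class:`NonCrystallographicError` for entries without cell/symmetry.
    """
    entry.require_crystallographic()
    orth = entry.cell.orth_matrix()
    frac = entry.cell.frac_matrix()
    ops = _ordered_ops(entry)
    placements: list[SymmetryPlacement] = []
    for chain in entry.chains:
        for op_index, op in enumerate(ops):
            rot = orth @ op.rot @ frac
            base_t = op.tran
            for shift in CELL_SHIFTS:
                if op_index == 0 and shift == (0, 0, 0):
                    r, t = np.eye(3), np.zeros(3)
                else:
                    t = orth @ (base_t + np.asarray(shift, float))
                    r = rot
                placements.append(SymmetryPlacement(
                    source_chain=chain.asym_id,
                    op_index=op_index,
                    shift=shift,
                    rot=tuple(map(tuple, r)),
                    tran=tuple(t)))
    placements.sort(key=lambda p: (p.source_chain, p.op_index, p.shift))
    return placements


def identity_placements(placements: list[SymmetryPlacement],
                        ) -> list[SymmetryPlacement]:
    return [p for p in placements if p.is_identity]


def _bounding_box(chain: PolymerChain, placement: SymmetryPlacement,
                  ) -> tuple[np.ndarray, np.ndarray]:
    coords, _ = chain.heavy_coords()
    moved = placement.apply(coords)
    return moved.min(axis=0), moved.max(axis=0)


def candidate_pairs(entry: CrystalEntry,
                    placements: list[SymmetryPlacement],
                    reference: list[SymmetryPlacement] | None = None,
                    prune_radius: float = 17.0,
                    ) -> list[tuple[SymmetryPlacement, SymmetryPlacement]]:
    """Bounding-box pruned placement pairs to test for contacts.

    Every returned pair joins a reference placement (by default the
    identity asymmetric-unit copies) with a lattice placement whose
    inflated bounding boxes overlap; the result is a guaranteed superset
    of all pairs that can interact at cutoffs <= ``prune_radius``.
    """
    if reference is None:
        reference = identity_placements(placements)
    chains = {c.asym_id: c for c in entry.chains}
    boxes = {}
    for p in placements:
        boxes[p.key] = _bounding_box(chains[p.source_chain], p)
    pairs = []
    for ref in reference:
        rmin, rmax = boxes[ref.key]
        for p in placements:
            if p.key == ref.key:
                continue
            pmin, pmax = boxes[p.key]
            if np.all(rmin - prune_radius <= pmax) and \
               np.all(pmin <= rmax + prune_radius):
                pairs.append((ref, p))
    return pairs


def export_lattice_pdb(entry: CrystalEntry,
                       placements: list[SymmetryPlacement],
                       path: str) -> None:
    """Debug export: each placement as one MODEL in a PDB file."""
    chains = {c.asym_id: c for c in entry.chains}
    with open(path, "w") as fh:
        for mi, p in enumerate(placements, start=1):
            fh.write(f"MODEL     {mi:4d}\n")
            chain = chains[p.source_chain]
            serial = 1
            for res in chain.residues:
                for a in res.atoms:
                    x, y, z = p.apply(a.pos[None, :])[0]
                    fh.write(
                        f"ATOM  {serial:5d} {a.name:<4.4s}{res.name:>3.3s} "
                        f"A{res.seq_pos:4d}    "
                        f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}  0.00"
                        f"          {a.element:>2.2s}\n")
                    serial += 1
            fh.write("ENDMDL\n")
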