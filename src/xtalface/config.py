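"""Pipeline-wide numeric thresholds.

Every distance cutoff, count threshold and similarity bound used anywhere in
the pipeline lives here, so that a single config object (optionally loaded
from YAML, optionally overridden per-field from the command line) controls
the behaviour of all stages.  No other module hard-codes a cutoff.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Numeric parameters of the interface pipeline.

    Distances are in angstroms, areas in A^2, fractions in (0, 1].

    Attributes
    ----------
    cbeta_cutoff:
        Maximum C-beta/C-beta distance counted as a residue contact (12 A).
    atom_cutoff:
        Maximum heavy-atom distance counted as an atomic contact (5 A).
    min_cbeta_pairs, min_atom_contacts:
        Interaction rule: a pair of chains or domains interacts iff it has
        at least ``min_cbeta_pairs`` C-beta pairs within ``cbeta_cutoff``
        and at least one atomic contact, or at least ``min_atom_contacts``
        atomic contacts within ``atom_cutoff``.
    ligand_cutoff:
        A ligand interaction needs one atomic contact within 4.5 A.
    min_bsa_chain, min_bsa_domain:
        Interfaces burying less area than this are excluded from clustering
        (kept in the census with a flag).
    q_cluster:
        Average-linkage merging stops when the best inter-cluster average
        Q score falls below this value (0.30).
    q_high:
        Q score above which two interfaces are considered "the same
        interface" for crystal-form merging and assembly containment.
    cell_tol:
        Relative tolerance on unit-cell edges and angles (1%) for the
        same-crystal-form test.
    cf_merge_fraction:
        Two crystal forms merge when at least this fraction (2/3) of the
        smaller form's interfaces are matched at Q >= q_high.
    hmm_cov_min:
        Minimum fraction of the shorter domain covered by the profile-HMM
        match for an HMM-position correspondence to be usable (80%).
    peptide_max_len:
        Polypeptide chains shorter than this (exclusive; 30) are peptides.
    peptide_assign_frac:
        A peptide touching several chains is assigned to the chain holding
        at least this fraction (75%) of its atomic contacts.
    pep_min_nhmm, pep_max_rmsd:
        Peptide-cluster merge constraints: >= 3 shared HMM contact sites
        and peptide RMSD <= 10 A.
    min_pep_overlap:
        Minimum residue overlap of an ungapped peptide-peptide alignment.
    ligand_site_jaccard:
        Minimum Jaccard overlap of contacted HMM positions for merging
        ligand-site clusters.
    sasa_probe, sasa_points:
        Solvent probe radius and sphere-sample count of the SASA method.
    prune_margin:
        Extra padding added to cbeta_cutoff for bounding-box pruning.
    """

    cbeta_cutoff: float = 12.0
    atom_cutoff: float = 5.0
    min_cbeta_pairs: int = 10
    min_atom_contacts: int = 5
    ligand_cutoff: float = 4.5
    min_bsa_chain: float = 100.0
    min_bsa_domain: float = 150.0
    q_cluster: float = 0.30
    q_high: float = 0.85
    cell_tol: float = 0.01
    cf_merge_fraction: float = 2.0 / 3.0
    hmm_cov_min: float = 0.80
    peptide_max_len: int = 30
    peptide_assign_frac: float = 0.75
    pep_min_nhmm: int = 3
    pep_max_rmsd: float = 10.0
    min_pep_overlap: int = 3
    ligand_site_jaccard: float = 0.5
    sasa_probe: float = 1.44
    sasa_points: int = 960
    prune_margin: float = 5.0

    def __post_init__(self) -> None:
        for f in ("cbeta_cutoff", "atom_cutoff", "ligand_cutoff",
                  "min_bsa_chain", "min_bsa_domain", "pep_max_rmsd",
                  "sasa_probe"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")
        for f in ("cf_merge_fraction", "hmm_cov_min", "peptide_assign_frac",
                  "ligand_site_jaccard", "cell_tol"):
            v = getattr(self, f)
            if not 0 < v <= 1:
                raise ValueError(f"{f} must lie in (0, 1]")

    @property
    def prune_radius(self) -> float:
        return self.cbeta_cutoff + self.prune_margin

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a config file; keyword arguments override file values."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update(overrides)
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))
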