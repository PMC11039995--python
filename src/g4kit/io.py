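"""PDB input/output and the in-memory coordinate model.

Curation policy of the study this package supports: for NMR (multi-model)
entries only the first model is analyzed; for X-ray entries every chain in
the file is analyzed, because the chains coexist in the crystal.  Each
chain becomes its own :class:`StructureModel`.

Parsing is delegated to Biopython's ``Bio.PDB``; this module only reshapes
the hierarchy into the flat residue/atom model the geometry code consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

__all__ = [
    "Residue",
    "StructureModel",
    "ExperimentKind",
    "CurationPolicy",
    "load_structures",
    "write_pdb",
    "is_guanine",
    "is_nucleotide",
    "EmptyInputError",
    "ParseError",
]


class ParseError(ValueError):
    """The file could not be read as PDB."""


class EmptyInputError(ValueError):
    """The file contains no nucleic-acid residues."""


class ExperimentKind(str, Enum):
    nmr = "nmr"
    xray = "xray"
    em = "em"
    synthetic = "synthetic"
    unknown = "unknown"


#: Base heavy atoms that define the guanine scaffold.
GUANINE_BASE_ATOMS = ("N9", "C8", "N7", "C5", "C6", "O6", "N1", "C2", "N2", "N3")

#: Residue names accepted as nucleotides (standard + common modified G).
_NUC_NAMES = {
    "A", "C", "G", "U", "T", "I",
    "DA", "DC", "DG", "DT", "DU", "DI",
    "GUA", "ADE", "CYT", "THY", "URA",
    # modified guanines seen in G4 entries
    "8OG", "BGM", "GF2", "LG", "GFL", "2PR",
}

_WATER_ION = {"HOH", "WAT", "K", "NA", "MG", "CL", "CA", "SR", "TL", "CS", "NH4"}


@dataclass(eq=False)  # identity semantics: residues are placeful objects
class Residue:
    """One residue: name, sequence position, atom-name -> xyz (Angstrom)."""

    name: str
    chain_id: str
    position: int
    icode: str = ""
    atoms: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.position, self.icode)

    def coord(self, atom: str) -> np.ndarray:
        try:
            return self.atoms[atom]
        except KeyError:
            raise KeyError(f"residue {self.name} {self.key} has no atom {atom!r}") from None

    def has(self, *atom_names: str) -> bool:
        return all(a in self.atoms for a in atom_names)

    def __repr__(self) -> str:  # compact; these appear in error messages
        return f"<{self.name} {self.chain_id}{self.position}{self.icode}>"


@dataclass
class StructureModel:
    """Parsed coordinates of one chain of one model of one PDB entry."""

    structure_id: str
    chain_id: str
    residues: list[Residue]
    experiment_kind: ExperimentKind = ExperimentKind.unknown
    hetero: list[Residue] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if len(keys) != len(set(keys)):
            raise ValueError(f"{self.structure_id}: duplicate residue keys in chain {self.chain_id}")

    @property
    def label(self) -> str:
        return f"{self.structure_id}:{self.chain_id}"

    def chain_rank(self, residue: Residue) -> int:
        """Rank of a residue in file (chain) order; used for strand direction."""
        return self._ranks()[residue.key]

    def _ranks(self) -> dict[tuple[str, int, str], int]:
        if not hasattr(self, "_rank_cache"):
            self._rank_cache = {r.key: i for i, r in enumerate(self.residues)}
        return self._rank_cache


def is_nucleotide(residue: Residue) -> bool:
    name = residue.name.strip().upper()
    if name in _WATER_ION:
        return False
    return name in _NUC_NAMES or residue.has("C1'", "N9") or residue.has("C1'", "N1")


def is_guanine(residue: Residue) -> bool:
    """True iff the residue carries the full guanine base-atom scaffold.

    Works by atom content, not residue name, so modified guanines (oxo-G,
    fluoro-G, ...) qualify while a guanine with a missing base atom does not.
    """
    return residue.has(*GUANINE_BASE_ATOMS)


@dataclass(frozen=True)
class CurationPolicy:
    """Which models/chains of a PDB file enter the analysis.

    ``model_policy='first'`` reproduces the study's rule for NMR (and EM)
    entries; ``'all'`` expands every model.  X-ray entries have one model, so
    both policies analyze all chains there.
    """

    model_policy: str = "first"  # 'first' | 'all'


def _experiment_kind(structure, n_models: int) -> ExperimentKind:
    method = (structure.header or {}).get("structure_method", "") or ""
    method = method.lower()
    if "nmr" in method:
        return ExperimentKind.nmr
    if "x-ray" in method or "diffraction" in method:
        return ExperimentKind.xray
    if "microscopy" in method:
        return ExperimentKind.em
    if "synthetic" in method:
        return ExperimentKind.synthetic
    # No header: several models is a solution-state ensemble in practice.
    return ExperimentKind.nmr if n_models > 1 else ExperimentKind.unknown


def _convert_residue(bio_res, chain_id: str) -> Residue:
    het, seq, icode = bio_res.id
    atoms: dict[str, np.ndarray] = {}
    for atom in bio_res.get_atoms():
        if atom.is_disordered():
            atom = atom.disordered_get()  # altloc 'A' or blank wins
        name = atom.get_name().replace("*", "'")
        if name not in atoms:
            atoms[name] = np.array(atom.get_coord(), dtype=float)
    return Residue(
        name=bio_res.get_resname().strip(),
        chain_id=chain_id,
        position=int(seq),
        icode=icode.strip(),
        atoms=atoms,
    )


def load_structures(
    path: str | Path,
    policy: CurationPolicy | None = None,
    structure_id: str | None = None,
) -> list[StructureModel]:
    """Read a PDB file and return one :class:`StructureModel` per chain.

    NMR/EM (multi-model) entries contribute the first model only, X-ray
    entries every chain, following the study's curation rule.  Waters and
    ions are kept on ``StructureModel.hetero``, never among ``residues``.
    """
    policy = policy or CurationPolicy()
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        try:
            structure = parser.get_structure(structure_id or path.stem, str(path))
        except Exception as exc:  # Bio.PDB raises assorted exceptions
            raise ParseError(f"cannot parse {path}: {exc}") from exc
    models = list(structure.get_models())
    if not models:
        raise ParseError(f"{path}: no coordinate models")
    kind = _experiment_kind(structure, len(models))
    if policy.model_policy == "first" or kind == ExperimentKind.xray:
        models = models[:1]
    out: list[StructureModel] = []
    for model_index, model in enumerate(models):
        for chain in model.get_chains():
            residues, hetero = [], []
            for bio_res in chain.get_residues():
                res = _convert_residue(bio_res, chain.id)
                (residues if is_nucleotide(res) else hetero).append(res)
            if not residues:
                continue
            suffix = f"/m{model_index + 1}" if len(models) > 1 else ""
            out.append(
                StructureModel(
                    structure_id=(structure_id or path.stem) + suffix,
                    chain_id=chain.id,
                    residues=residues,
                    experiment_kind=kind,
                    hetero=hetero,
                )
            )
    if not out:
        raise EmptyInputError(f"{path}: no nucleic-acid residues")
    return out


def write_pdb(models: StructureModel | Sequence[StructureModel], path: str | Path) -> Path:
    """Write models as standard PDB ATOM records (one chain each).

    Coordinates are emitted at PDB precision (3 decimals); a round trip
    through :func:`load_structures` preserves them at that precision.
    """
    if isinstance(models, StructureModel):
        models = [models]
    path = Path(path)
    lines: list[str] = []
    kinds = {m.experiment_kind for m in models}
    if kinds == {ExperimentKind.synthetic}:
        lines.append("EXPDTA    SYNTHETIC")
    serial = 1
    for model in models:
        for res in list(model.residues) + list(model.hetero):
            for atom_name, xyz in res.atoms.items():
                element = atom_name.strip("'0123456789")[:1]
                name_field = atom_name if len(atom_name) >= 4 else f" {atom_name:<3s}"
                lines.append(
                    f"ATOM  {serial:5d} {name_field:<4s} {res.name:<3s} {model.chain_id:1s}"
                    f"{res.position:4d}{res.icode or ' ':1s}   "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {element:>2s}"
                )
                serial += 1
        lines.append("TER")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


def concat_models(models: Iterable[StructureModel]) -> list[Residue]:
    """All nucleic residues across chains (used by partition checks)."""
    out: list[Residue] = []
    for m in models:
        out.extend(m.residues)
    return out
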