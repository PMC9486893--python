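"""Load conformer ensembles and resolve (chain, normalized residue, atom).

The interchange format is multi-model PDB: one MODEL per conformer,
identical atom ordering across models. Compressed MD formats (XTC/DCD)
are supported as an optional adapter behind the same contract when
MDAnalysis is importable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AbsentPositionError,
    InputError,
    MissingAtomError,
)
from .numbering import AlignParams, ReferenceProfile, build_residue_map, load_reference

__all__ = [
    "AtomRef",
    "ConformerEnsemble",
    "load_ensemble",
    "write_ensemble",
    "attach_numbering",
    "attach_identity_numbering",
]

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",
}


@dataclass(frozen=True)
class AtomRef:
    """Address of one atom: chain, normalized residue number, PDB atom name.

    Cγ is addressed as "CG" for Arg/Gln/His alike; branched side chains
    use their own PDB names (e.g. CG1 on Ile).
    """

    chain: str
    normalized: int
    atom: str

    def __str__(self) -> str:  # e.g. A/171:CG
        return f"{self.chain}/{self.normalized}:{self.atom}"


@dataclass
class ConformerEnsemble:
    """Frames x atoms with chain/residue/atom metadata.

    ``atoms`` has columns (chain, resid, resname, atom); ``coords`` is a
    float array of shape (n_frames, n_atoms, 3) in Angstroms.
    ``residue_maps`` maps chain id -> {normalized number: author resid}.
    """

    atoms: pd.DataFrame
    coords: np.ndarray
    frame_times: np.ndarray | None = None
    residue_maps: dict[str, dict[int, int]] = field(default_factory=dict)
    _index: dict[tuple[str, int, str], int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise InputError(f"coords must be (frames, atoms, 3), got {self.coords.shape}")
        if self.coords.shape[1] != len(self.atoms):
            raise InputError(
                f"coordinate atom count {self.coords.shape[1]} != atom table "
                f"length {len(self.atoms)}"
            )
        if not np.isfinite(self.coords).all():
            raise InputError("non-finite coordinates in ensemble")
        self._index = {
            (row.chain, row.resid, row.atom): i
            for i, row in enumerate(self.atoms.itertuples(index=False))
        }

    # -- basic introspection ------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def chains(self) -> list[str]:
        return list(dict.fromkeys(self.atoms["chain"]))

    def sequence(self, chain: str) -> tuple[str, list[int]]:
        """(one-letter sequence, author resids) for a chain, resid-ordered."""
        sub = self.atoms[self.atoms["chain"] == chain]
        if sub.empty:
            raise InputError(f"no such chain: {chain!r}")
        resids, letters = [], []
        for resid, grp in sub.groupby("resid", sort=True):
            resids.append(int(resid))
            letters.append(_THREE_TO_ONE.get(grp["resname"].iloc[0], "X"))
        return "".join(letters), resids

    # -- atom resolution ----------------------------------------------------
    def _resid_for(self, chain: str, normalized: int) -> int:
        if chain not in self.residue_maps:
            raise InputError(
                f"chain {chain!r} has no residue map attached; call "
                "attach_numbering or attach_identity_numbering first"
            )
        rmap = self.residue_maps[chain]
        if normalized not in rmap:
            raise AbsentPositionError(
                f"normalized position {normalized} is absent (deleted/unmapped) "
                f"in chain {chain}"
            )
        return rmap[normalized]

    def atom_index(self, ref: AtomRef) -> int:
        resid = self._resid_for(ref.chain, ref.normalized)
        key = (ref.chain, resid, ref.atom)
        if key not in self._index:
            sub = self.atoms[
                (self.atoms["chain"] == ref.chain) & (self.atoms["resid"] == resid)
            ]
            resname = sub["resname"].iloc[0] if len(sub) else "?"
            hint = ""
            if ref.atom == "CG" and resname == "GLY":
                hint = " (glycine has no side chain beyond CA)"
            raise MissingAtomError(
                f"atom {ref.atom} not present in {resname} {ref.chain}/{resid} "
                f"(normalized {ref.normalized}){hint}"
            )
        return self._index[key]

    def coordinates(self, ref: AtomRef, frame: int) -> np.ndarray:
        """Coordinates (Angstrom) of one atom in one frame."""
        if not -self.n_frames <= frame < self.n_frames:
            raise IndexError(
                f"frame {frame} out of range for ensemble with "
                f"{self.n_frames} frames"
            )
        return self.coords[frame, self.atom_index(ref)].copy()

    def coordinate_series(self, ref: AtomRef) -> np.ndarray:
        """(n_frames, 3) coordinates of one atom across all frames."""
        return self.coords[:, self.atom_index(ref)].copy()

    # -- derived ensembles --------------------------------------------------
    def frame(self, i: int) -> "ConformerEnsemble":
        return replace(
            self,
            coords=self.coords[i : i + 1].copy(),
            frame_times=None if self.frame_times is None else self.frame_times[i : i + 1],
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ConformerEnsemble":
        """Apply one rigid transform to every frame (x -> R x + t)."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        return replace(self, coords=self.coords @ rotation.T + translation)


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def _frame_atoms(model, skip_het: bool) -> tuple[list[tuple], np.ndarray]:
    meta, xyz = [], []
    for chain in model:
        for residue in chain:
            hetflag, resseq, icode = residue.id
            if skip_het and hetflag.strip() and residue.resname != "MSE":
                continue
            if icode.strip():
                raise InputError(
                    f"insertion-coded residue {chain.id}/{resseq}{icode} not "
                    "supported; renumber the structure first"
                )
            for atom in residue:
                if atom.is_disordered():
                    atom = max(atom.disordered_get_list(), key=lambda a: a.get_occupancy() or 0.0)
                if atom.element == "H":
                    continue
                meta.append((chain.id, int(resseq), residue.resname, atom.get_name()))
                xyz.append(atom.get_coord())
    return meta, np.asarray(xyz, dtype=float)


def load_ensemble(
    structure_path: str | Path,
    trajectory_path: str | Path | None = None,
    skip_het: bool = True,
) -> ConformerEnsemble:
    """Read a single- or multi-model PDB (one frame per MODEL).

    ``trajectory_path`` may add frames from a second multi-model PDB, or
    from an XTC/DCD file (optional MDAnalysis adapter); atom ordering
    must match the structure.
    """
    from Bio.PDB import PDBParser

    structure_path = Path(structure_path)
    if structure_path.suffix.lower() not in {".pdb", ".ent", ".pdb1"}:
        raise InputError(f"unknown structure format: {structure_path.name}")
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("ens", str(structure_path))
    models = list(structure)
    if not models:
        raise InputError(f"no models found in {structure_path}")

    meta0, xyz0 = _frame_atoms(models[0], skip_het)
    frames = [xyz0]
    for m in models[1:]:
        meta, xyz = _frame_atoms(m, skip_het)
        if meta != meta0:
            raise InputError(
                f"model {m.id + 1} atom set differs from model 1 "
                f"({len(meta)} vs {len(meta0)} atoms)"
            )
        frames.append(xyz)

    if trajectory_path is not None:
        trajectory_path = Path(trajectory_path)
        if trajectory_path.suffix.lower() in {".pdb", ".ent"}:
            extra = load_ensemble(trajectory_path, skip_het=skip_het)
            if extra.n_atoms != len(meta0):
                raise InputError(
                    f"trajectory atom count {extra.n_atoms} != structure atom "
                    f"count {len(meta0)}"
                )
            frames.extend(extra.coords)
        else:
            frames.extend(_mdanalysis_frames(structure_path, trajectory_path, len(meta0)))

    atoms = pd.DataFrame(meta0, columns=["chain", "resid", "resname", "atom"])
    return ConformerEnsemble(atoms=atoms, coords=np.stack(frames))


def _mdanalysis_frames(structure_path: Path, trajectory_path: Path, n_expected: int):
    try:
        import MDAnalysis as mda
    except ImportError as exc:  # pragma: no cover
        raise InputError(
            f"reading {trajectory_path.suffix} trajectories requires MDAnalysis"
        ) from exc
    u = mda.Universe(str(structure_path), str(trajectory_path))
    sel = u.select_atoms("protein and not name H*")
    if sel.n_atoms != n_expected:
        raise InputError(
            f"trajectory atom count {sel.n_atoms} != structure atom count {n_expected}"
        )
    return [sel.positions.astype(float).copy() for _ in u.trajectory]


def write_ensemble(ensemble: ConformerEnsemble, path: str | Path) -> Path:
    """Write a multi-model PDB (3-decimal coordinates, one MODEL per frame)."""
    path = Path(path)
    rows = list(ensemble.atoms.itertuples(index=False))
    with open(path, "w") as fh:
        for f in range(ensemble.n_frames):
            fh.write(f"MODEL     {f + 1:4d}\n")
            for i, row in enumerate(rows):
                x, y, z = ensemble.coords[f, i]
                name = row.atom if len(row.atom) == 4 else f" {row.atom:<3s}"
                fh.write(
                    f"ATOM  {i + 1:5d} {name}{'':1s}{row.resname:>3s} "
                    f"{row.chain:1s}{row.resid:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {row.atom[0]:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")
    return path


# ---------------------------------------------------------------------------
# numbering attachment
# ---------------------------------------------------------------------------

def attach_numbering(
    ensemble: ConformerEnsemble,
    reference: ReferenceProfile | None = None,
    sequences: Mapping[str, str] | None = None,
    align_params: AlignParams | None = None,
) -> ConformerEnsemble:
    """Populate per-chain normalized-number -> author-resid maps.

    Chain sequences are derived from the residue names unless supplied
    explicitly. Mapping goes through the numbering module's global
    alignment against the reference profile.
    """
    ref = reference or load_reference()
    for chain in ensemble.chains:
        seq, resids = ensemble.sequence(chain)
        if sequences is not None and chain in sequences:
            seq = sequences[chain]
            if len(seq) != len(resids):
                raise InputError(
                    f"supplied sequence for chain {chain} has length "
                    f"{len(seq)} but the chain has {len(resids)} residues"
                )
        rmap = build_residue_map(seq, ref, align_params=align_params, query_id=chain)
        ensemble.residue_maps[chain] = {
            n: resids[q - 1] for q, n in rmap.pairs
        }
    return ensemble


def attach_identity_numbering(ensemble: ConformerEnsemble) -> ConformerEnsemble:
    """Treat author residue numbers as normalized numbers (synthetic inputs)."""
    for chain in ensemble.chains:
        _, resids = ensemble.sequence(chain)
        ensemble.residue_maps[chain] = {r: r for r in resids}
    return ensemble
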