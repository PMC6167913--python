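"""Conformational ensembles: the in-memory container and multi-model PDB I/O.

An ensemble is an ordered set of coordinate frames over a fixed atom roster
(backbone atoms N, CA, C, O per residue).  Coordinates are stored in Angstrom;
analysis modules that report variances convert to nm.  Residues carry a chain
id, an integer residue number and an optional insertion code, so antibody
numbering such as 100B survives a PDB round trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .errors import EnsembleFormatError, InputError

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class ConformationalEnsemble:
    """Ordered coordinate frames over a shared backbone atom roster.

    Attributes
    ----------
    coords : (n_frames, n_atoms, 3) float array, Angstrom.
    atom_names : (n_atoms,) array of PDB atom names.
    res_index : (n_atoms,) integer array mapping each atom to its residue
        ordinal (0-based, consecutive).
    res_numbers : (n_residues,) integer residue numbers.
    ins_codes : (n_residues,) insertion-code strings ('' when absent).
    res_names : (n_residues,) three-letter residue names.
    chain_ids : (n_residues,) single-character chain identifiers.
    """

    coords: np.ndarray
    atom_names: np.ndarray
    res_index: np.ndarray
    res_numbers: np.ndarray
    ins_codes: np.ndarray
    res_names: np.ndarray
    chain_ids: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]
        if not np.isfinite(self.coords).all():
            raise InputError("ensemble coordinates must be finite")
        if self.coords.shape[0] < 1:
            raise InputError("ensemble needs at least one frame")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def n_residues(self) -> int:
        return len(self.res_numbers)

    def residue_labels(self) -> list[str]:
        """Residue labels in presentation form, e.g. '100B'."""
        return [f"{n}{i}" for n, i in zip(self.res_numbers, self.ins_codes)]

    def atom_mask_for_residues(self, residue_ordinals: np.ndarray) -> np.ndarray:
        """Boolean atom mask selecting every atom of the given residues."""
        return np.isin(self.res_index, np.asarray(residue_ordinals))

    def backbone_view(self) -> np.ndarray:
        """Coordinates reshaped to (n_frames, n_residues, 4, 3), N/CA/C/O order.

        Requires the roster to be exactly the four backbone atoms per residue
        in canonical order, which all generator output satisfies.
        """
        expected = np.tile(BACKBONE_ATOMS, self.n_residues)
        if self.n_atoms != 4 * self.n_residues or not np.array_equal(
                self.atom_names, expected):
            raise InputError("ensemble roster is not canonical N/CA/C/O backbone")
        return self.coords.reshape(self.n_frames, self.n_residues, 4, 3)

    def with_coords(self, coords: np.ndarray) -> "ConformationalEnsemble":
        """A copy of this ensemble with replaced coordinates."""
        return ConformationalEnsemble(
            coords=np.array(coords, dtype=float),
            atom_names=self.atom_names.copy(),
            res_index=self.res_index.copy(),
            res_numbers=self.res_numbers.copy(),
            ins_codes=self.ins_codes.copy(),
            res_names=self.res_names.copy(),
            chain_ids=self.chain_ids.copy(),
        )

    def frame(self, i: int) -> "ConformationalEnsemble":
        return self.with_coords(self.coords[i:i + 1])


def from_backbone(coords: np.ndarray, res_numbers=None, ins_codes=None,
                  res_names=None, chain_id: str = "H") -> ConformationalEnsemble:
    """Wrap (n_frames, n_res, 4, 3) or (n_res, 4, 3) backbone coordinates."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 3:
        coords = coords[None]
    n_res = coords.shape[1]
    if res_numbers is None:
        res_numbers = np.arange(1, n_res + 1)
    if ins_codes is None:
        ins_codes = np.array([""] * n_res, dtype=object)
    if res_names is None:
        res_names = np.array(["GLY"] * n_res, dtype=object)
    return ConformationalEnsemble(
        coords=coords.reshape(coords.shape[0], n_res * 4, 3),
        atom_names=np.tile(BACKBONE_ATOMS, n_res).astype(object),
        res_index=np.repeat(np.arange(n_res), 4),
        res_numbers=np.asarray(res_numbers, dtype=int),
        ins_codes=np.asarray(ins_codes, dtype=object),
        res_names=np.asarray(res_names, dtype=object),
        chain_ids=np.array([chain_id] * n_res, dtype=object),
    )


_ELEMENT = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C", "H": "H"}


def write_multimodel_pdb(ensemble: ConformationalEnsemble, path) -> None:
    """Write an ensemble as a multi-model PDB (one frame per MODEL block)."""
    n_atoms = ensemble.n_atoms
    arr = struc.AtomArray(n_atoms)
    arr.chain_id = np.asarray(ensemble.chain_ids, dtype="U4")[ensemble.res_index]
    arr.res_id = ensemble.res_numbers[ensemble.res_index]
    arr.ins_code = np.asarray(ensemble.ins_codes, dtype="U1")[ensemble.res_index]
    arr.res_name = np.asarray(ensemble.res_names, dtype="U5")[ensemble.res_index]
    arr.atom_name = np.asarray(ensemble.atom_names, dtype="U6")
    arr.element = np.array([_ELEMENT.get(a, a[0]) for a in ensemble.atom_names],
                           dtype="U2")
    arr.coord = ensemble.coords[0]
    stack = struc.stack([arr] * ensemble.n_frames)
    stack.coord = ensemble.coords.copy()
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def read_multimodel_pdb(path) -> ConformationalEnsemble:
    """Read a (multi-)model PDB into an ensemble.

    Every MODEL must present the same atom roster; a mismatch raises
    :class:`EnsembleFormatError` naming the offending model.  Residues missing
    any of N/CA/C/O are dropped with a warning.
    """
    import warnings

    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    try:
        stack = pdb.get_structure()
    except Exception as exc:
        # Locate the first model whose roster deviates from model 1.
        ref = pdb.get_structure(model=1)
        ref_key = list(zip(ref.chain_id, ref.res_id, ref.ins_code, ref.atom_name))
        for m in range(2, n_models + 1):
            arr = pdb.get_structure(model=m)
            key = list(zip(arr.chain_id, arr.res_id, arr.ins_code, arr.atom_name))
            if key != ref_key:
                raise EnsembleFormatError(
                    f"model {m} differs from model 1 in its atom roster"
                ) from exc
        raise EnsembleFormatError(f"inconsistent models in {path}") from exc
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])

    mask = np.isin(stack.atom_name, BACKBONE_ATOMS)
    stack = stack[..., mask]
    # Residue bookkeeping from the first frame's annotation order.
    keys = list(zip(stack.chain_id, stack.res_id, stack.ins_code))
    order: list[tuple] = []
    seen = set()
    for k in keys:
        if k not in seen:
            seen.add(k)
            order.append(k)
    keep_atoms = []
    res_numbers, ins_codes, res_names, chain_ids = [], [], [], []
    res_index = []
    for ordinal, k in enumerate(order):
        idx = [i for i, kk in enumerate(keys) if kk == k]
        names = list(stack.atom_name[idx])
        if not all(a in names for a in BACKBONE_ATOMS):
            warnings.warn(
                f"residue {k[0]}:{k[1]}{k[2]} lacks a backbone atom; skipped")
            continue
        picked = [idx[names.index(a)] for a in BACKBONE_ATOMS]
        keep_atoms.extend(picked)
        res_index.extend([len(res_numbers)] * 4)
        res_numbers.append(int(k[1]))
        ins_codes.append(str(k[2]))
        res_names.append(str(stack.res_name[picked[0]]))
        chain_ids.append(str(k[0]))
    if not res_numbers:
        raise EnsembleFormatError(f"no complete backbone residues in {path}")
    keep_atoms = np.asarray(keep_atoms)
    return ConformationalEnsemble(
        coords=stack.coord[:, keep_atoms, :],
        atom_names=np.tile(BACKBONE_ATOMS, len(res_numbers)).astype(object),
        res_index=np.asarray(res_index),
        res_numbers=np.asarray(res_numbers, dtype=int),
        ins_codes=np.asarray(ins_codes, dtype=object),
        res_names=np.asarray(res_names, dtype=object),
        chain_ids=np.asarray(chain_ids, dtype=object),
    )
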