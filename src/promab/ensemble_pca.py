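"""Ensemble superposition, coordinate PCA and CDR-3 projection ranking.

Frames are least-squares superposed (Kabsch rotation) onto the iteratively
refined mean structure, by default fitting on framework CA atoms so that
loop motion is measured relative to the scaffold.  PCA diagonalizes the
3N x 3N covariance of the superposed coordinates about the ensemble mean;
eigenvalues are reported in nm^2.  The contribution of atom ``a`` to
component ``k`` is the eigenvalue-weighted squared eigenvector mass

    c_k(a) = lambda_k * (v_k,ax^2 + v_k,ay^2 + v_k,az^2)   [nm^2]

so contributions over all atoms sum to the eigenvalue.  Residues are ranked
by their summed atom contributions to PC1 + PC2, identifying the loop
residues most correlated with the dominant collective motions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ensemble import ConformationalEnsemble
from .errors import InputError

ANG2_TO_NM2 = 0.01


def _kabsch_rotation(mobile: np.ndarray, target: np.ndarray):
    """Optimal rotation matrix and translation mapping mobile onto target."""
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, mc, tc


def superpose(ensemble: ConformationalEnsemble, fit_atoms=None,
              max_iter: int = 100,
              tol: float = 1e-10) -> ConformationalEnsemble:
    """Superpose all frames onto their iteratively converged mean structure.

    ``fit_atoms`` is a boolean mask or index array over atoms (default: all
    atoms).  Iteration stops when the mean structure shifts by less than
    ``tol`` Angstrom RMS or after ``max_iter`` rounds.
    """
    coords = ensemble.coords.copy()
    n_atoms = coords.shape[1]
    if fit_atoms is None:
        fit_idx = np.arange(n_atoms)
    else:
        fit_atoms = np.asarray(fit_atoms)
        fit_idx = np.flatnonzero(fit_atoms) if fit_atoms.dtype == bool \
            else fit_atoms.astype(int)
    if len(fit_idx) < 3:
        raise InputError("superposition needs at least 3 fit atoms")

    # Initialise from the ensemble mean: an already-superposed ensemble is
    # a fixed point of the iteration and passes through unchanged.
    mean = coords.mean(axis=0)
    for _ in range(max_iter):
        for f in range(coords.shape[0]):
            rot, mc, tc = _kabsch_rotation(coords[f, fit_idx],
                                           mean[fit_idx])
            coords[f] = (coords[f] - mc) @ rot.T + tc
        new_mean = coords.mean(axis=0)
        shift = np.sqrt(np.mean((new_mean - mean) ** 2))
        mean = new_mean
        if shift < tol:
            break
    return ensemble.with_coords(coords)


def framework_ca_mask(ensemble: ConformationalEnsemble,
                      loop_residues) -> np.ndarray:
    """Atom mask of CA atoms outside the given loop residues."""
    loop = set(np.asarray(loop_residues, dtype=int).tolist())
    is_ca = ensemble.atom_names == "CA"
    in_loop = np.isin(ensemble.res_index, list(loop))
    return is_ca & ~in_loop


@dataclass
class PCAResult:
    """Eigen-decomposition of the superposed coordinate covariance."""

    eigenvalues: np.ndarray         # nm^2, descending
    eigenvectors: np.ndarray        # (n_components, 3 * n_sel), orthonormal
    mean_coords: np.ndarray         # (n_sel, 3), Angstrom
    atom_indices: np.ndarray        # selection into the parent ensemble
    explained_fraction: np.ndarray

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


def pca(ensemble: ConformationalEnsemble, analysis_atoms=None) -> PCAResult:
    """PCA of the (superposed) ensemble's Cartesian coordinates.

    Components are obtained from the SVD of the centred frame matrix; the
    eigenvalues are sample variances (divisor F - 1) converted to nm^2.
    """
    if ensemble.n_frames < 2:
        raise InputError("PCA needs at least two frames")
    if analysis_atoms is None:
        sel = np.arange(ensemble.n_atoms)
    else:
        analysis_atoms = np.asarray(analysis_atoms)
        sel = np.flatnonzero(analysis_atoms) if analysis_atoms.dtype == bool \
            else analysis_atoms.astype(int)
    X = ensemble.coords[:, sel, :].reshape(ensemble.n_frames, -1)
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    eigval = (s ** 2) / (ensemble.n_frames - 1) * ANG2_TO_NM2
    total = eigval.sum()
    frac = eigval / total if total > 0 else np.zeros_like(eigval)
    return PCAResult(eigenvalues=eigval, eigenvectors=vt,
                     mean_coords=mean.reshape(-1, 3), atom_indices=sel,
                     explained_fraction=frac)


@dataclass
class RegionProjection:
    """Eigenvalue-weighted PC1/PC2 contributions of a region's atoms."""

    atom_indices: np.ndarray
    pc1_contribution: np.ndarray    # nm^2 per atom
    pc2_contribution: np.ndarray
    residue_ordinals: np.ndarray
    residue_labels: list
    residue_contribution: np.ndarray  # summed PC1 + PC2 per residue
    ranked_residues: list            # labels, most dynamic first


def atom_contributions(result: PCAResult, component: int) -> np.ndarray:
    """Per-atom nm^2 contribution of every analysed atom to one component."""
    v = result.eigenvectors[component].reshape(-1, 3)
    return result.eigenvalues[component] * np.sum(v ** 2, axis=1)


def project_region(result: PCAResult, ensemble: ConformationalEnsemble,
                   region_residues) -> RegionProjection:
    """Project a residue region onto PC1/PC2 and rank its residues."""
    region_residues = np.asarray(region_residues, dtype=int)
    if region_residues.size == 0:
        raise InputError("empty region")
    region_atoms = np.flatnonzero(
        np.isin(ensemble.res_index, region_residues))
    pos = {a: i for i, a in enumerate(result.atom_indices)}
    missing = [a for a in region_atoms if a not in pos]
    if missing:
        raise InputError("region atoms missing from the PCA selection")
    local = np.asarray([pos[a] for a in region_atoms])

    c1 = atom_contributions(result, 0)[local]
    c2 = atom_contributions(result, 1)[local] if result.n_components > 1 \
        else np.zeros_like(c1)

    labels_all = ensemble.residue_labels()
    res_of_atom = ensemble.res_index[region_atoms]
    res_contrib = np.zeros(len(region_residues))
    for i, r in enumerate(region_residues):
        m = res_of_atom == r
        res_contrib[i] = (c1[m] + c2[m]).sum()
    order = np.argsort(res_contrib)[::-1]
    ranked = [labels_all[region_residues[i]] for i in order]
    return RegionProjection(
        atom_indices=region_atoms, pc1_contribution=c1, pc2_contribution=c2,
        residue_ordinals=region_residues,
        residue_labels=[labels_all[r] for r in region_residues],
        residue_contribution=res_contrib, ranked_residues=ranked)
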