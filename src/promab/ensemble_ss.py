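"""Secondary-structure assignment and occupancy statistics over ensembles.

Per-residue states follow the hydrogen-bond pattern rules of Kabsch and
Sander: a backbone N-H...O=C hydrogen bond exists where the electrostatic
energy

    E = 0.084 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN) * 332  kcal/mol

falls below -0.5 kcal/mol (amide hydrogens, absent from the backbone
roster, are reconstructed 1.01 A from N, anti to the preceding carbonyl;
prolines donate nothing).  n-turns (n = 3, 4, 5) arise from (i, i+n)
bonds; helices (G/H/I) from consecutive n-turns; bridges and ladders (B/E)
from the parallel/antiparallel bond patterns; hydrogen-bonded turns give T
and wide CA-trace bends give S; everything else is coil.  The first and
last residues of a chain are never assigned helix or strand.

The eight detailed states collapse onto four reporting categories:
{E, B} -> Beta, {H, G, I} -> Helix, {T, S} -> Turn, {C} -> Coil.  Ensemble
occupancies are fractions of (frame, residue) observations per category,
with percentile bootstrap confidence intervals over frame resamples and a
frame-resampling bootstrap test for group contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ensemble import ConformationalEnsemble, read_multimodel_pdb  # noqa: F401
from .errors import InputError

DETAILED_STATES = ("H", "G", "I", "E", "B", "T", "S", "C")
CATEGORIES = ("Beta", "Helix", "Turn", "Coil")
CATEGORY_MAP = {"E": "Beta", "B": "Beta",
                "H": "Helix", "G": "Helix", "I": "Helix",
                "T": "Turn", "S": "Turn",
                "C": "Coil"}

HB_ENERGY_CUTOFF = -0.5          # kcal/mol
_Q = 0.084 * 332.0               # Kabsch-Sander coupling constant
_NH_BOND = 1.01                  # reconstructed amide H distance, Angstrom


def _hbond_matrix(bb: np.ndarray, is_pro: np.ndarray) -> np.ndarray:
    """Boolean (F, R, R) array: donor N-H of residue i bonds acceptor C=O j."""
    N, CA, C, O = bb[:, :, 0], bb[:, :, 1], bb[:, :, 2], bb[:, :, 3]
    F, R = N.shape[:2]
    # Reconstructed amide hydrogen; residue 0 has no donor H.
    H = np.full_like(N, np.nan)
    v = C[:, :-1] - O[:, :-1]
    H[:, 1:] = N[:, 1:] + _NH_BOND * v / np.linalg.norm(v, axis=-1,
                                                        keepdims=True)

    def dist(a, b):
        return np.linalg.norm(a[:, :, None, :] - b[:, None, :, :], axis=-1)

    with np.errstate(invalid="ignore", divide="ignore"):
        energy = _Q * (1.0 / dist(N, O) + 1.0 / dist(H, C)
                       - 1.0 / dist(H, O) - 1.0 / dist(N, C))
    energy = np.nan_to_num(energy, nan=0.0, posinf=0.0, neginf=0.0)
    hb = energy < HB_ENERGY_CUTOFF
    idx = np.arange(R)
    hb[:, idx, idx] = False
    # Exclude covalently adjacent pairs.
    hb[:, idx[:-1], idx[:-1] + 1] = False
    hb[:, idx[1:], idx[1:] - 1] = False
    hb[:, 0, :] = False                      # residue 0 has no amide H
    hb[:, is_pro, :] = False                 # proline donates no H-bond
    return hb


def assign_secondary_structure(ensemble: ConformationalEnsemble) -> np.ndarray:
    """Detailed per-frame, per-residue states as an (F, R) character array."""
    bb = ensemble.backbone_view()
    F, R = bb.shape[:2]
    states = np.full((F, R), "C", dtype="U1")
    if R < 3:
        return states
    is_pro = np.asarray([n == "PRO" for n in ensemble.res_names])
    hb = _hbond_matrix(bb, is_pro)

    i = np.arange(R)
    turn = {}
    for n in (3, 4, 5):
        t = np.zeros((F, R), dtype=bool)
        t[:, : R - n] = hb[:, i[: R - n] + n, i[: R - n]]
        turn[n] = t

    def mark(mask_fr, char):
        # assign char where no higher-priority state is present
        free = states == "C"
        states[mask_fr & free] = char

    # Helices from two consecutive n-turns; 4-helix (H) takes precedence.
    helix_masks = {}
    for n in (4, 3, 5):
        start = np.zeros((F, R), dtype=bool)
        start[:, 1:] = turn[n][:, 1:] & turn[n][:, :-1]
        run = np.zeros((F, R), dtype=bool)
        for k in range(n):
            run[:, k:] |= start[:, : R - k] if k else start
        helix_masks[n] = run
    mark(helix_masks[4], "H")

    # Bridges: parallel / antiparallel patterns between strands i < j.
    para = np.zeros((F, R, R), dtype=bool)
    anti = np.zeros((F, R, R), dtype=bool)
    ii = np.arange(1, R - 1)
    jj = np.arange(1, R - 1)
    I, J = np.meshgrid(ii, jj, indexing="ij")
    sep = np.abs(I - J) >= 3
    # parallel: [HB(i, j-1) & HB(j+1, i)] or [HB(j, i-1) & HB(i+1, j)]
    p1 = hb[:, I, J - 1] & hb[:, J + 1, I]
    p2 = hb[:, J, I - 1] & hb[:, I + 1, J]
    para[:, 1:R - 1, 1:R - 1] = (p1 | p2) & sep
    # antiparallel: [HB(j, i) & HB(i, j)] or [HB(j+1, i-1) & HB(i+1, j-1)]
    a1 = hb[:, J, I] & hb[:, I, J]
    a2 = hb[:, J + 1, I - 1] & hb[:, I + 1, J - 1]
    anti[:, 1:R - 1, 1:R - 1] = (a1 | a2) & sep

    bridge = para | anti
    # Ladder membership: a bridge (i, j) extends to (i+1, j+1) (parallel)
    # or (i+1, j-1) (antiparallel).
    ladder = np.zeros((F, R, R), dtype=bool)
    ext = np.zeros_like(para)
    ext[:, : R - 1, : R - 1] |= para[:, 1:, 1:]
    ext[:, 1:, 1:] |= para[:, : R - 1, : R - 1]
    ladder |= para & ext
    ext = np.zeros_like(anti)
    ext[:, : R - 1, 1:] |= anti[:, 1:, : R - 1]
    ext[:, 1:, : R - 1] |= anti[:, : R - 1, 1:]
    ladder |= anti & ext

    in_ladder = ladder.any(axis=2) | ladder.any(axis=1)
    in_bridge = bridge.any(axis=2) | bridge.any(axis=1)
    mark(in_ladder, "E")
    mark(in_bridge & ~in_ladder, "B")

    # Shorter 3-10 and pi helices only claim stretches not already taken by
    # a 4-helix or strand (left-to-right, as in the reference algorithm).
    for n, char in ((3, "G"), (5, "I")):
        start = np.zeros((F, R), dtype=bool)
        start[:, 1:] = turn[n][:, 1:] & turn[n][:, :-1]
        for i0 in range(1, R - n + 1):
            stretch = states[:, i0:i0 + n]
            free = ((stretch == "C") | (stretch == char)).all(axis=1)
            sel = start[:, i0] & free
            states[sel, i0:i0 + n] = char

    # Hydrogen-bonded turns: residues strictly inside any n-turn.
    t_mask = np.zeros((F, R), dtype=bool)
    for n in (3, 4, 5):
        for k in range(1, n):
            t_mask[:, k:] |= turn[n][:, : R - k]
    mark(t_mask, "T")

    # Bends: CA-trace direction change above 70 degrees.
    ca = bb[:, :, 1]
    u = ca[:, 2:-2] - ca[:, : R - 4]         # CA(i) - CA(i-2)
    w = ca[:, 4:] - ca[:, 2:-2]              # CA(i+2) - CA(i)
    cosang = np.sum(u * w, axis=-1) / (
        np.linalg.norm(u, axis=-1) * np.linalg.norm(w, axis=-1))
    bend = np.zeros((F, R), dtype=bool)
    bend[:, 2:-2] = cosang < np.cos(np.deg2rad(70.0))
    mark(bend, "S")

    # Chain termini carry too little context for helix/strand states.
    for col in (0, R - 1):
        terminal = np.isin(states[:, col], ("H", "G", "I", "E", "B"))
        states[terminal, col] = "C"
    return states


def to_categories(states: np.ndarray) -> np.ndarray:
    """Map detailed states onto the four reporting categories."""
    out = np.empty(states.shape, dtype="U5")
    for s, cat in CATEGORY_MAP.items():
        out[states == s] = cat
    if (out == "").any():
        bad = np.unique(states[out == ""])
        raise InputError(f"unmapped detailed states {bad}")
    return out


@dataclass
class OccupancyStats:
    """Per-category occupancy over (frames x region residues) with CIs."""

    probabilities: dict
    ci_low: dict
    ci_high: dict
    n_frames: int
    n_residues: int
    region_label: str = ""

    def as_array(self) -> np.ndarray:
        return np.array([self.probabilities[c] for c in CATEGORIES])


def _category_fractions(cat: np.ndarray) -> np.ndarray:
    """Per-frame category fractions, shape (F, 4)."""
    return np.stack([(cat == c).mean(axis=1) for c in CATEGORIES], axis=1)


def occupancy(assignments: np.ndarray, region_residues=None,
              n_boot: int = 100, seed: int = 0,
              region_label: str = "") -> OccupancyStats:
    """Normalised category probabilities for a residue region.

    ``assignments`` may be detailed states or categories, shaped (F, R);
    ``region_residues`` selects residue columns (default: all).  The 95%
    confidence interval comes from ``n_boot`` percentile-bootstrap resamples
    of frames.
    """
    states = np.asarray(assignments)
    if states.ndim != 2:
        raise InputError("assignments must be a (frames, residues) array")
    if region_residues is not None:
        region_residues = np.asarray(region_residues, dtype=int)
        if region_residues.size == 0:
            raise InputError("empty region")
        states = states[:, region_residues]
    if states.shape[1] == 0:
        raise InputError("empty region")
    cat = states if np.isin(states, CATEGORIES).all() \
        else to_categories(states)
    frac = _category_fractions(cat)
    point = frac.mean(axis=0)

    rng = np.random.default_rng(seed)
    F = frac.shape[0]
    idx = rng.integers(0, F, size=(n_boot, F))
    boot = frac[idx].mean(axis=1)            # (n_boot, 4)
    lo = np.minimum(np.percentile(boot, 2.5, axis=0), point)
    hi = np.maximum(np.percentile(boot, 97.5, axis=0), point)
    return OccupancyStats(
        probabilities=dict(zip(CATEGORIES, point)),
        ci_low=dict(zip(CATEGORIES, lo)),
        ci_high=dict(zip(CATEGORIES, hi)),
        n_frames=F, n_residues=states.shape[1], region_label=region_label)


@dataclass
class SetContrast:
    """Category-wise relative difference between two pooled frame groups."""

    relative_difference_pct: dict       # 100 * (p1 - p2) / p2
    p_values: dict
    group_sizes: tuple
    n_resamples: int
    method: str = "frame-resampling bootstrap, two-tailed"


def _pool_fractions(group) -> np.ndarray:
    """Stack per-frame category fractions of several assignment arrays."""
    fracs = []
    for assignments, region in group:
        states = np.asarray(assignments)
        if region is not None:
            states = states[:, np.asarray(region, dtype=int)]
        cat = states if np.isin(states, CATEGORIES).all() \
            else to_categories(states)
        fracs.append(_category_fractions(cat))
    return np.concatenate(fracs, axis=0)


def contrast_groups(group_a, group_b, n_resamples: int = 10_000,
                    seed: int = 0) -> SetContrast:
    """Contrast pooled category occupancy of two ensemble groups.

    Each group is a list of ``(assignments, region_residues_or_None)``
    pairs; frames are pooled and weighted equally within a group.  Group B
    is the reference of the relative difference.  Significance is a
    two-tailed bootstrap test: frames are resampled within each group and
    the p-value is the (add-one corrected) fraction of resampled
    differences crossing zero, doubled.
    """
    if not group_a or not group_b:
        raise InputError("both groups must be non-empty")
    fa = _pool_fractions(group_a)
    fb = _pool_fractions(group_b)
    pa, pb = fa.mean(axis=0), fb.mean(axis=0)

    rng = np.random.default_rng(seed)
    na, nb = fa.shape[0], fb.shape[0]
    rel = {}
    pvals = {}
    boot_a = fa[rng.integers(0, na, size=(n_resamples, na))].mean(axis=1)
    boot_b = fb[rng.integers(0, nb, size=(n_resamples, nb))].mean(axis=1)
    diffs = boot_a - boot_b
    for k, c in enumerate(CATEGORIES):
        rel[c] = float("nan") if pb[k] == 0 else \
            100.0 * (pa[k] - pb[k]) / pb[k]
        n_le = int(np.sum(diffs[:, k] <= 0))
        n_ge = int(np.sum(diffs[:, k] >= 0))
        pvals[c] = min(1.0, 2.0 * (min(n_le, n_ge) + 1) / (n_resamples + 1))
    return SetContrast(relative_difference_pct=rel, p_values=pvals,
                       group_sizes=(na, nb), n_resamples=n_resamples)
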