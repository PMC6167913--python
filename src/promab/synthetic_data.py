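"""Synthetic antibody panels and conformational ensembles with known truth.

Two generators back the analysis pipeline's tests and demonstrations:

* ``generate_antibody_set`` emits paired heavy/light variable-region
  sequences on fixed human germline-like frameworks, with designed CDR-3
  loops.  Promiscuous records carry CDR-H3 stems enriched in strong
  β-formers (V, I, M) and β-breakers confined to the loop apex — the
  hairpin-compatible architecture — while non-promiscuous records draw
  their loops from a scattered background composition.

* ``build_ideal_backbone`` and ``generate_ensemble`` produce backbone
  coordinate ensembles.  Conformers are sampled by perturbing backbone
  (φ, ψ) torsions and rebuilding the chain with fixed covalent geometry, so
  bond lengths are conserved by construction; an optional planted
  displacement mode (with a seeded amplitude schedule) makes one collective
  motion the dominant covariance direction, giving PCA a known answer.
  Frames violating the fractional bond-length tolerance are rejected and
  resampled.

Cysteine is excluded from generated loops: the extraction heuristic keys on
the conserved framework cysteine, and free loop cysteines are rare in real
CDR-H3s.  All randomness flows through explicit per-call seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _geometry as geom
from .cdr_annotation import AntibodyRecord
from .ensemble import ConformationalEnsemble, from_backbone
from .errors import ConfigurationError, GenerationError, InputError

# Fixed framework scaffolds (human VH3-23 / Vk1-39 style).  The H/L loop is
# inserted between the terminal framework-3 cysteine and the J motif, so
# anchor-based extraction recovers it exactly.
HEAVY_FRAMEWORK_PRE = ("EVQLVESGGGLVQPGGSLRLSCAASGFTFSSYAMSWVRQAPGKGLEWVS"
                       "AISGSGGSTYYADSVKGRFTISRDNSKNTLYLQMNSLRAEDTAVYYC")
HEAVY_FRAMEWORK_POST = "WGQGTLVTVSS"
LIGHT_FRAMEWORK_PRE = ("DIQMTQSPSSLSASVGDRVTITCRASQSISSYLNWYQQKPGKAPKLLIY"
                       "AASSLQSGVPSRFSGSGSGTDFTLTISSLQPEDFATYYC")
LIGHT_FRAMEWORK_POST = "FGQGTKVEIK"

STRONG_FORMERS = "VIM"
BREAKER_POOL = "HSKNPE"          # breakers plus the strong breaker
NEUTRAL_POOL = "FYTWLQRGAD"      # formers (minus C) and indifferent residues

# Position-independent breaker rate of the scattered (non-promiscuous)
# loop architecture.
SCATTERED_BREAKER_RATE = 0.4

_LIGHT_LOOP_POOL = "QSYNTGRLAD"


@dataclass(frozen=True)
class SequenceGenConfig:
    """Conditions for a synthetic antibody panel.

    Defaults mirror the study panel this generator emulates: ten antibodies,
    four promiscuous, with long CDR-H3 loops and a strong stem/apex
    composition contrast in the promiscuous subset.
    """

    n_promiscuous: int = 4
    n_nonpromiscuous: int = 6
    cdrh3_length_range: tuple = (12, 22)
    stem_former_bias: float = 0.9
    apex_breaker_bias: float = 0.8
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.cdrh3_length_range
        if self.n_promiscuous < 0 or self.n_nonpromiscuous < 0:
            raise ConfigurationError("record counts must be non-negative")
        if not (5 <= lo <= hi <= 40):
            raise ConfigurationError(
                "CDR-H3 length range must lie within [5, 40]")
        for name in ("stem_former_bias", "apex_breaker_bias"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")


def _segment_bounds(length: int) -> tuple:
    # Central-third apex, matching beta_propensity.segment_bounds.
    import math
    apex_len = math.ceil(length / 3)
    start = math.ceil((length - apex_len) / 2)
    return start, start + apex_len


def _draw(rng, pool: str) -> str:
    return pool[rng.integers(len(pool))]


def _promiscuous_h3(rng, length: int, cfg: SequenceGenConfig) -> str:
    a0, a1 = _segment_bounds(length)
    out = []
    for i in range(length):
        if a0 <= i < a1:      # apex: breakers concentrated here
            pool = BREAKER_POOL if rng.random() < cfg.apex_breaker_bias \
                else NEUTRAL_POOL
        else:                 # stems: strong formers, breakers excluded
            pool = STRONG_FORMERS if rng.random() < cfg.stem_former_bias \
                else NEUTRAL_POOL
        out.append(_draw(rng, pool))
    return "".join(out)


def _scattered_h3(rng, length: int) -> str:
    # Breakers scattered uniformly along the loop, stems included: the
    # architecture that frustrates hairpin hydrogen bonding.
    return "".join(
        _draw(rng, BREAKER_POOL) if rng.random() < SCATTERED_BREAKER_RATE
        else _draw(rng, NEUTRAL_POOL)
        for _ in range(length))


def _light_l3(rng) -> str:
    length = int(rng.integers(8, 12))
    return "QQ" + "".join(_draw(rng, _LIGHT_LOOP_POOL)
                          for _ in range(length - 4)) + "PT"


def generate_antibody_set(config: SequenceGenConfig,
                          id_prefix: str = "Ab") -> list:
    """Generate a labelled panel of paired-chain antibody records."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.cdrh3_length_range
    records = []
    total = config.n_promiscuous + config.n_nonpromiscuous
    for i in range(total):
        promiscuous = i < config.n_promiscuous
        length = int(rng.integers(lo, hi + 1))
        h3 = (_promiscuous_h3(rng, length, config) if promiscuous
              else _scattered_h3(rng, length))
        l3 = _light_l3(rng)
        records.append(AntibodyRecord(
            id=f"{id_prefix}{i + 1:02d}",
            heavy_seq=HEAVY_FRAMEWORK_PRE + h3 + HEAVY_FRAMEWORK_POST,
            light_seq=LIGHT_FRAMEWORK_PRE + l3 + LIGHT_FRAMEWORK_POST,
            phenotype="promiscuous" if promiscuous else "non_promiscuous"))
    return records


# ---------------------------------------------------------------------------
# Coordinate ensembles
# ---------------------------------------------------------------------------

# Ideal backbone torsions (degrees).  The four-residue hairpin turn was
# fitted once so that the two flanking strands close into a hydrogen-bonded
# antiparallel hairpin for any strand length; the values are frozen here.
HELIX_PHI_PSI = (-57.0, -47.0)
STRAND_PHI_PSI = (-139.0, 135.0)
HAIRPIN_TURN = ((1.2, 136.1), (25.5, 0.0), (167.7, 11.4), (-99.1, 43.5))

SS_TYPES = ("helix", "strand", "hairpin", "coil")


def build_ideal_backbone(ss_type: str, n_residues: int, seed: int = 0,
                         chain_id: str = "H",
                         res_numbers=None) -> ConformationalEnsemble:
    """Single-frame N/CA/CO backbone with prescribed secondary structure.

    ``helix`` repeats (-57, -47); ``strand`` repeats (-139, 135); ``hairpin``
    joins two antiparallel strands with a four-residue turn (needs >= 8
    residues); ``coil`` draws seeded torsions from a broad allowed region.
    """
    if ss_type not in SS_TYPES:
        raise InputError(f"unknown secondary-structure type {ss_type!r}")
    if n_residues < 4:
        raise InputError("backbones need at least 4 residues")
    if ss_type == "hairpin" and n_residues < 8:
        raise InputError("hairpins need at least 8 residues")
    if ss_type == "helix":
        phi = np.full(n_residues, HELIX_PHI_PSI[0])
        psi = np.full(n_residues, HELIX_PHI_PSI[1])
    elif ss_type == "strand":
        phi = np.full(n_residues, STRAND_PHI_PSI[0])
        psi = np.full(n_residues, STRAND_PHI_PSI[1])
    elif ss_type == "hairpin":
        phi = np.full(n_residues, STRAND_PHI_PSI[0])
        psi = np.full(n_residues, STRAND_PHI_PSI[1])
        t0 = (n_residues - 4) // 2
        for k, (p, s) in enumerate(HAIRPIN_TURN):
            phi[t0 + k], psi[t0 + k] = p, s
    else:                                   # coil
        # Random torsions from the broad allowed region occasionally fold
        # into compact, hydrogen-bonded conformers; since the construction
        # promises a coil ground truth, candidates are rejection-sampled
        # until the assigned structure carries (almost) no helix or strand.
        from .ensemble_ss import assign_secondary_structure
        rng = np.random.default_rng(seed)
        best, best_frac = None, np.inf
        for _ in range(100):
            phi = rng.uniform(-150.0, -60.0, n_residues)
            psi = rng.uniform(-70.0, 170.0, n_residues)
            frame = from_backbone(geom.build_backbone(phi, psi)[None])
            states = assign_secondary_structure(frame)[0]
            frac = np.isin(states, ("H", "G", "I", "E", "B")).mean()
            if frac < best_frac:
                best, best_frac = (phi, psi), frac
            if frac <= 1.0 / n_residues:
                break
        phi, psi = best
    coords = geom.build_backbone(phi, psi)
    return from_backbone(coords[None], res_numbers=res_numbers,
                         chain_id=chain_id)


@dataclass(frozen=True)
class PlantedMode:
    """A collective displacement field planted into an ensemble.

    ``vectors`` holds per-atom displacement directions in nm; frame ``t``
    receives ``amplitudes[t] * vectors``.  When no amplitude schedule is
    given, amplitudes are drawn uniformly from [-1, 1] with the ensemble
    seed, so the mode carries substantial, zero-mean variance.
    """

    vectors: np.ndarray
    amplitudes: np.ndarray | None = None


@dataclass(frozen=True)
class EnsembleGenConfig:
    """Conditions for torsion-space conformer generation."""

    n_conformers: int = 500
    backbone_noise: float = 4.0            # sd of torsion perturbation, deg
    planted_mode: PlantedMode | None = None
    constraint_tolerance: float = 0.05     # fractional bond-length bound
    seed: int = 0
    max_retries: int = 20

    def __post_init__(self):
        if self.n_conformers < 1:
            raise ConfigurationError("n_conformers must be >= 1")
        if not 0.0 < self.constraint_tolerance <= 0.1:
            raise ConfigurationError(
                "constraint_tolerance must lie in (0, 0.1]")
        if self.backbone_noise < 0:
            raise ConfigurationError("backbone_noise must be >= 0")


def _kabsch_align(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Least-squares superpose mobile onto target (both (n, 3))."""
    mc = mobile - mobile.mean(axis=0)
    tc = target - target.mean(axis=0)
    h = mc.T @ tc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return mc @ r.T + target.mean(axis=0)


def _bond_description(ensemble: ConformationalEnsemble, bond_idx: int) -> str:
    n_res = ensemble.n_residues
    labels = ensemble.residue_labels()
    if bond_idx < 3 * n_res:
        res, kind = divmod(bond_idx, 3)
        name = ("N-CA", "CA-C", "C-O")[kind]
        return f"{name} of residue {labels[res]}"
    res = bond_idx - 3 * n_res
    return f"C-N peptide bond {labels[res]}..{labels[res + 1]}"


def generate_ensemble(start: ConformationalEnsemble,
                      config: EnsembleGenConfig) -> ConformationalEnsemble:
    """Sample conformers around a single-frame start structure.

    Backbone torsions are perturbed with Gaussian noise (degrees) and the
    chain is rebuilt with the start's idealized covalent geometry, then
    superposed back onto the start.  An optional planted mode is added in
    Cartesian space.  Each frame must keep every covalent bond within the
    fractional tolerance of the start frame; violating frames are resampled
    up to ``max_retries`` times before a :class:`GenerationError` naming the
    offending bond is raised.
    """
    if start.n_frames != 1:
        raise InputError("generate_ensemble requires a single-frame start")
    rng = np.random.default_rng(config.seed)
    bb0 = start.backbone_view()[0]                      # (n_res, 4, 3)
    n_res = bb0.shape[0]
    phi0, psi0, omega0 = geom.measure_backbone_torsions(bb0)
    ref_bonds = geom.backbone_bond_lengths(bb0)

    mode = config.planted_mode
    if mode is not None:
        vectors = np.asarray(mode.vectors, dtype=float)
        if vectors.shape != (start.n_atoms, 3):
            raise ConfigurationError(
                f"planted mode shape {vectors.shape} does not match the "
                f"{start.n_atoms}-atom roster")
        if mode.amplitudes is not None:
            amplitudes = np.asarray(mode.amplitudes, dtype=float)
            if len(amplitudes) != config.n_conformers:
                raise ConfigurationError(
                    "amplitude schedule length must equal n_conformers")
        else:
            amplitudes = rng.uniform(-1.0, 1.0, config.n_conformers)
        mode_ang = vectors * 10.0                       # nm -> Angstrom

    frames = np.empty((config.n_conformers, start.n_atoms, 3))
    for t in range(config.n_conformers):
        last_bad = None
        for _attempt in range(config.max_retries):
            phi = phi0 + rng.normal(0.0, config.backbone_noise, n_res)
            psi = psi0 + rng.normal(0.0, config.backbone_noise, n_res)
            bb = geom.build_backbone(phi, psi, omega0)
            flat = _kabsch_align(bb.reshape(-1, 3), bb0.reshape(-1, 3))
            if mode is not None:
                flat = flat + amplitudes[t] * mode_ang
            dev = np.abs(geom.backbone_bond_lengths(
                flat.reshape(n_res, 4, 3)) / ref_bonds - 1.0)
            if dev.max() <= config.constraint_tolerance:
                frames[t] = flat
                break
            last_bad = int(np.argmax(dev))
        else:
            raise GenerationError(
                f"frame {t}: bond-length tolerance "
                f"{config.constraint_tolerance} still violated after "
                f"{config.max_retries} retries at "
                f"{_bond_description(start, last_bad)}")
    return start.with_coords(frames)


def make_tapered_mode(start: ConformationalEnsemble, residue_ordinals,
                      direction=(1.0, 0.0, 0.0),
                      peak_nm: float = 0.03) -> PlantedMode:
    """A smooth collective mode peaking over the given residues.

    The displacement is a raised-cosine envelope across the selected residue
    window (zero outside, ``peak_nm`` at the centre), applied to every atom
    of each residue along ``direction``.  The taper keeps boundary bond
    stretch well inside the generator's tolerance.
    """
    residue_ordinals = np.sort(np.asarray(residue_ordinals, dtype=int))
    if residue_ordinals.size == 0:
        raise InputError("planted mode needs at least one residue")
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    window = np.flatnonzero(np.isin(start.res_index, residue_ordinals))
    vectors = np.zeros((start.n_atoms, 3))
    if len(window) == 1:
        vectors[window[0]] = peak_nm * direction
    else:
        # per-atom raised cosine: zero at the window edges, peak centred
        x = np.linspace(0.0, 1.0, len(window))
        weight = 0.5 * (1.0 - np.cos(2.0 * np.pi * x))
        vectors[window] = weight[:, None] * peak_nm * direction
    return PlantedMode(vectors=vectors)
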