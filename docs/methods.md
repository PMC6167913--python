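# Methods

This note records the models, parameter choices and numerical conventions
behind each analysis stage, what the synthetic generators do and do not
emulate, and the known limitations.

## CDR-3 extraction and numbering

Full antibody numbering requires profile alignment against germline HMMs.
For third loops only, the classical anchor heuristic is adequate and
deterministic, so that is what `cdr_annotation` implements: CDR-H3 is the
span strictly between the conserved framework-3 cysteine and the
framework-4 `WG.G` motif (CDR-L3: Cys … `FG.G`). The conserved cysteine is
located as the *last* Cys N-terminal of the J motif; when several J-motif
matches exist the C-terminal-most is used and a warning logged. Chains
missing an anchor raise an extraction error — no guessing. Failure modes:
loops containing a cysteine would truncate the extracted span (the
synthetic generator therefore never emits loop cysteines, which are also
rare in real CDR-H3s), and heavily mutated framework 4 defeats the motif.

Chothia-style labels are presentation-layer only; internally everything is
0-based half-open. Loops map onto the canonical third-loop positions
(H: 95–102, L: 89–97); insertions receive letters after the canonical
insertion site near the loop centre (H100, L95), deletions are taken from
the centre outwards, C-terminal side first — deterministic, matching the
convention of opening gaps outwards from the loop centre.

## Kidera encoding and clustering

The ten Kidera factors (orthogonal components distilled from 188 physical
properties, standardized to mean ≈ 0 / variance ≈ 1 across the 20 amino
acids) are embedded as a packaged constant; the standardization property
is asserted at import (|mean| < 0.1, variance within 15% of 1; the
embedded table satisfies it to < 0.5%).

Per antibody, each loop is aggregated by the **per-factor mean** over its
residues, and the H3 and L3 10-vectors are concatenated (H3 first). The
mean is chosen because it is invariant to loop length, which varies
widely across CDR-H3s; a `sum` aggregate is available and recorded in
output metadata. Clustering is agglomerative with **complete linkage**
(the default of the clustering software this setup mirrors) under the
Minkowski metric of order p = 4; p and linkage are configurable and
written into the output. Tie-breaking follows the linkage
implementation's deterministic lowest-index convention, and flat cluster
labels are renumbered 1..k in order of first appearance so that output is
permutation-stable. Dendrograms export to Newick with branch lengths
derived from merge heights.

Enrichment reports give, per cluster, the percentage of its members of
each phenotype and, per phenotype, the percentage captured by each
cluster (columns sum to 100%). Simpler hydrophobicity/charge descriptors
are provided for comparison only; no separation claims are attached to
them.

## β-sheet propensity profile

Only the categorical propensity classes are used (strong formers {V,I,M},
formers {F,Y,C,T,W,L,Q}, indifferent {R,G,A,D}, breakers {H,S,K,N,P},
strong breaker {E}); no numeric P(β) values enter the analysis. "Stem"
and "apex" lack a standard quantitative definition, so the apex is
defined as the **central third** of the loop, rounded outward
(apex length = ⌈L/3⌉, never shorter), with the N-terminal stem taking the
extra residue when the stems cannot be equal; the fraction is
configurable (`--apex-frac`). `stem_breaker_score` is the fraction of
stem positions occupied by breakers or the strong breaker: 0 marks fully
hairpin-compatible stems, and the score is monotone non-decreasing under
replacing any stem former by a breaker.

## Secondary-structure assignment

The assigner re-implements the hydrogen-bond pattern rules of Kabsch and
Sander on backbone N/CA/C/O coordinates. Amide hydrogens are
reconstructed 1.01 Å from N, anti to the preceding carbonyl (first
residue and prolines donate nothing). A bond exists where the
electrostatic energy 0.084·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)·332
kcal/mol is below −0.5 kcal/mol; self and covalently adjacent pairs are
excluded. n-turns (n = 3, 4, 5) come from (i, i+n) bonds; two consecutive
n-turns make a minimal helix (4-helix → H first; 3₁₀ → G and π → I claim
only stretches not already occupied, left to right, as in the reference
algorithm); parallel/antiparallel bridge patterns give B, and bridges
extending to a neighbouring bridge (ladders) give E; hydrogen-bonded turn
interiors give T; CA-trace bends above 70° give S; the rest is C. β-bulge
joining is not implemented — on idealized fixtures bulges do not occur,
and the oracle-agreement suite bounds the consequence on such inputs.
Chain termini are never assigned helix or strand. The eight states map
exactly onto four reporting categories: {E,B} → Beta, {H,G,I} → Helix,
{T,S} → Turn, {C} → Coil. On ideal fixtures the per-residue categories
agree with an independent DSSP implementation at 100% in the test suite
(the acceptance bound is ≥ 90%).

## Occupancy statistics and group contrasts

Occupancy is the fraction of (frame × region-residue) observations per
category, so the four probabilities sum to 1 by construction. Confidence
intervals are percentile bootstrap at the 95% level over **frame**
resamples (100 by default) — frames are the natural exchangeable unit of
a conformational ensemble; intervals are clipped to bracket the point
estimate so degenerate resamples cannot invert them. Group contrasts pool
frames within each group (frames weighted equally), report the
category-wise relative difference 100·(p₁−p₂)/p₂ with group 2 as
reference (undefined when p₂ = 0, reported as such), and attach a
two-tailed significance from a seeded frame-resampling bootstrap (10 000
resamples by default; add-one correction, so the smallest reportable p is
2/(B+1) ≈ 2·10⁻⁴). The alternative of averaging per-antibody before
contrasting is available by passing one pooled assignment array per
antibody; pooled frames is the default.

## Superposition and PCA

Frames are superposed by the optimal-rotation (Kabsch) solution onto an
iteratively refined mean structure (initialised at the ensemble mean, so
an already-superposed ensemble is a fixed point; iteration stops below a
10⁻¹⁰ Å RMS mean shift or after 100 rounds). The default fit selection is
**framework CA atoms** — all CA outside the analysed loop — so loop
motion is measured relative to the scaffold; `--fit all` reproduces
whole-molecule fitting. PCA diagonalizes the 3N×3N covariance of the
superposed coordinates about the ensemble mean via SVD of the centred
frame matrix (sample covariance, divisor F−1), with eigenvalues converted
to nm². No mass weighting is applied: the ensembles are Monte-Carlo-style
conformer sets, not dynamical trajectories. The contribution of atom a to
component k is λ_k·(v²_ax+v²_ay+v²_az) (nm²), so atom contributions sum
exactly to the eigenvalue; residues are ranked by their summed PC1+PC2
contribution. Only PC1/PC2 are reported by default.

## Synthetic data: what it emulates, and what it does not

**Sequence panels.** The generator emulates a ten-antibody panel (4
promiscuous, 6 non-promiscuous by default) on fixed human germline-like
frameworks (VH3-23 / Vκ1-39 style). Promiscuous CDR-H3s draw stem
positions from the strong β-formers with probability `stem_former_bias`
(default 0.9) and apex positions from the breaker pool with
`apex_breaker_bias` (default 0.8); non-promiscuous loops draw breakers at
rate 0.4 uniformly along the loop — the "scattered" architecture —
otherwise from the neutral former/indifferent pool. Loop lengths are
uniform on 12–22 residues for both phenotypes (the real panels show no
length difference between phenotypes, only long loops overall). Light
loops follow a QQ…PT pattern of length 8–11 with no phenotype signal, so
separation must come from CDR-H3 content, as it does in real data. Not
emulated: somatic hypermutation of frameworks, loop cysteines, germline
gene diversity, and any antigen-binding ground truth beyond the
composition labels — passing tests show the pipeline recovers planted
composition contrasts, not that it would classify an arbitrary real
repertoire.

**Ensembles.** Conformers are sampled by perturbing backbone (φ,ψ)
torsions with Gaussian noise and rebuilding the chain with idealized
covalent geometry (N-CA 1.458 Å, CA-C 1.525 Å, C-N 1.329 Å, C-O 1.231 Å,
standard angles), then superposing back onto the start frame. Bond
lengths are therefore conserved exactly by construction; the fractional
bond-length tolerance (default 0.05, capped at 0.1) is stressed only by
planted Cartesian modes, is checked on every frame, and frames failing it
are resampled up to `max_retries` times before an error naming the
offending bond. This replaces constraint-based Monte Carlo sampling: the
analysis stages need ensembles with controlled structure, not a
particular sampling engine, so no solvation scoring or distance-constraint
machinery is reproduced, and the noise parameter is a breadth dial, not a
thermodynamic temperature.

Ideal starts use textbook torsions — helix (−57, −47), strand
(−139, 135); the hairpin joins two antiparallel strands with a
four-residue turn whose torsions were fitted once against cross-strand
hydrogen-bond formation and frozen ((1.2, 136.1), (25.5, 0), (167.7,
11.4), (−99.1, 43.5)); they yield clean hairpins for 8–30 residues. Coil
torsions are drawn from a broad allowed region (φ ∈ [−150, −60], ψ ∈
[−70, 170]) and rejection-sampled until the built frame carries (almost)
no helix or strand under the package's own assigner — unconstrained
random torsions occasionally fold into genuine hairpins, which would
violate the promised ground truth. Residues are glycine (no side chains
beyond the backbone; no hydrogens — the assigner reconstructs them).

**Planted modes** are raised-cosine displacement envelopes over a residue
window (per-atom, zero at the window edges, peak in nm at the centre)
with a seeded uniform [−1, 1] amplitude schedule. The taper keeps
boundary-bond stretch inside the generator's tolerance for peaks up to
≈ 0.03 nm over a ten-residue window.

## Study conditions used by the acceptance script and tests

Chosen once as the package's standard demonstration conditions:

* Panel: 4 + 6 antibodies, biases 0.9/0.8, lengths 12–22.
* Occupancy contrast: four hairpin-loop ensembles (18 residues, torsion
  noise 6°) versus six disordered-loop ensembles (noise 25° — a
  disordered loop is more flexible than a stable hairpin, and the broader
  sampling gives the reference group the nonzero Beta occupancy a
  relative difference needs), 500 conformers each, pooling to 2000 and
  3000 frames.
* PCA recovery: 20-residue hairpin, mode window residues 6–15, peak
  0.03 nm, torsion noise 0.05° (the planted mode must dominate the
  covariance for the recovery statement to be well-posed), 150 conformers
  per replicate, framework-CA fit.

## Known limitations

* Anchor-based extraction is not full Chothia numbering; labels away from
  the third loops are not produced at all.
* The loop-level aggregation ("mean per factor") and the linkage are
  conventions; enrichment percentages on small panels can shift under
  `sum` aggregation or other linkages, which is why both are recorded in
  output metadata.
* The assigner omits β-bulges and does not compute solvent accessibility;
  π-helix detection exists for mapping completeness but is not separately
  validated.
* Ensembles are torsion-noise constructs: they have no energetics, no
  side chains and no solvent, so occupancy contrasts quantify the
  machinery on controlled inputs rather than reproduce any particular
  molecular system's values.
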