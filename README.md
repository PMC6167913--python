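# promab

Sequence and ensemble analysis of promiscuous antibody CDR-3 loops.

Some antibodies bind many unrelated antigens ("promiscuous" binding), a
behaviour that matters both for autoimmunity and for therapeutic antibody
discovery. This package implements a pipeline that distinguishes
promiscuous from non-promiscuous antibodies from their third
complementarity-determining regions (CDR-H3 / CDR-L3), for computational
immunologists and structural bioinformaticians:

1. **CDR annotation** — anchor-motif extraction of CDR-3 loops (conserved
   Cys to `WG.G`/`FG.G`) with Chothia-style numbering and insertion codes
   (e.g. `100B`), plus loop-length distributions.
2. **Kidera clustering** — each antibody is encoded as the concatenation of
   the per-factor means of the 10 Kidera factors over its CDR-H3 and CDR-L3
   residues (a 20-vector), then clustered agglomeratively under the
   Minkowski metric `d(x,y) = (Σᵢ |xᵢ−yᵢ|⁴)^(1/4)` with complete linkage;
   cluster/phenotype enrichment is tabulated.
3. **β-propensity profiling** — residues are binned into the categorical
   β-sheet propensity classes (strong formers V/I/M … strong breaker E) and
   loops segmented into stem / apex / stem; hairpin-compatible loops keep
   breakers out of the stems (`stem_breaker_score`).
4. **Secondary-structure occupancy** — a Kabsch–Sander hydrogen-bond
   assigner (energy `E = 0.084·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)·332
   kcal/mol`, bond if `E < −0.5`) labels every residue of every conformer
   of a multi-model PDB ensemble; the eight DSSP states collapse to
   Beta/Helix/Turn/Coil, with frame-bootstrap 95% confidence intervals and
   a two-tailed bootstrap contrast between ensemble groups.
5. **Ensemble PCA** — iterative Kabsch superposition (framework-CA fit by
   default), eigen-decomposition of the 3N-coordinate covariance (nm²),
   and eigenvalue-weighted projection of CDR-3 atoms onto PC1/PC2 to rank
   the most dynamic residues.
6. **Synthetic data** — generators for labelled antibody panels (stem/apex
   composition under explicit biases) and for constraint-respecting
   backbone ensembles with planted collective modes, providing known
   ground truth for every stage.

## Worked example

```sh
promab simulate sequences --n-prom 4 --n-non 6 --seed 1 -o panel.fasta
promab annotate -i panel.fasta -o cdrs.tsv
promab cluster -i cdrs.tsv --p 4 --k 3 -o clust/
```

`cdrs.tsv` holds the extracted loops with their Chothia labels:

```
id     chain  phenotype    sequence           length  numbering
Ab01   H      promiscuous  QMMVMVHPSHKEVVVGM  17      95,96,...,100,100A,...,101,102
Ab01   L      promiscuous  QQGDYLSPT          9       89,90,...,97
```

Note the promiscuous architecture: V/I/M-rich stems, breakers (`HPSHK`)
at the apex. `clust/enrichment.json` reports, per cluster, the percentage
of each phenotype it captures; for this panel the k = 3 cut gives

```
cluster 1: 75% of promiscuous,        0% of non-promiscuous
cluster 2: 25% of promiscuous,        0% of non-promiscuous
cluster 3:  0% of promiscuous,      100% of non-promiscuous
```

i.e. the two binding phenotypes fall into disjoint clusters. For the
ensemble stages:

```sh
promab simulate ensemble --ss hairpin --n 200 --n-residues 18 --noise 6  --seed 2 -o hairpin.pdb
promab simulate ensemble --ss coil    --n 200 --n-residues 18 --noise 25 --seed 3 -o coil.pdb
echo hairpin.pdb > ga.list; echo coil.pdb > gb.list
promab stats --groups ga.list gb.list --seed 1 -o contrast.json
promab pca -i hairpin.pdb --region H:6-13 -o pcaout/
```

`contrast.json` shows the hairpin-architecture group strongly enriched in
Beta occupancy relative to the disordered group (bootstrap p ≈ 2·10⁻⁴,
the resolution floor of 10⁴ resamples), with Turn occupancy enriched in
the disordered group (−59%). `pcaout/ranked_residues.json` ranks loop
residues by their summed PC1+PC2 contribution — here residues 9 and 10,
the loop apex, lead.

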