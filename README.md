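# nkalloreact

Prediction of natural-killer (NK) cell alloreactivity from KIR and HLA
genotypes in allogeneic haematopoietic stem-cell transplantation, for
immunogeneticists and transplant physicians comparing donor-selection
strategies.

Many mutually incompatible models are used in the literature to predict
whether a donor's NK cells will be alloreactive toward a recipient.
`nkalloreact` implements 27 of them, across six families, scores them for
every donor/recipient (D/R) pair of a cohort, and compares them — against
each other (Spearman rank correlations) and against clinical outcomes
(cumulative incidence of death, relapse, acute and chronic GVHD under
competing risks, Gray's test).

## The models

For a D/R pair with ligand profiles derived from HLA class I (C1/C2 from
HLA-C residue 80; Bw4/Bw6 from HLA-B residues 77/80, with Bw4 also carried
by some HLA-A allotypes; A3/A11; HLA-B leader −21 M/T) and donor KIR gene
presence:

* **Ligand–ligand** (Bw4/Bw6, BwIPD, C1/C2, and their synthesis): GVH-direction
  mismatch when the donor carries an epitope class the recipient lacks,
  HVG-direction when the reverse holds. BwIPD is the Bw axis ignoring
  non-classical (HLA-A/-C) Bw carriers.
* **Receptor–ligand / missing-ligand** (2DL1-C2, 2DL2/3-C1, 3DL1-Bw4,
  3DL2-A3/11, quantitative and qualitative syntheses): donor inhibitory KIR
  whose cognate ligand is entirely absent from the recipient.
* **Educational** (Educ-2DL1, Educ-2DL2/3, Educ-3DL1, Educ-3DL2, Educ-DL
  synthesis, Educ-2DS1): as receptor–ligand but requiring licensed donor NK
  cells — the donor must also carry the cognate ligand; donors lacking the
  KIR gene or the self ligand are *uneducated*.
* **KIR haplotype-based** (Cen-B, Tel-B, B-pattern, KIR-B content score):
  centromeric/telomeric B-motif counts of the donor genotype
  (Cen-B ⇔ 2DL2/2DS2, Tel-B ⇔ 3DS1/2DS1) and the derived
  neutral/better/best donor category (best ⇔ Cen-B homozygous,
  better ⇔ ≥ 2 B motifs otherwise, neutral ⇔ ≤ 1).
* **Gene content** (donor aKIR, donor iKIR, R−D aKIR, R−D iKIR): activating
  and non-framework inhibitory KIR gene counts and recipient-vs-donor
  difference bins.
* **Allelic polymorphism** (3DL1 expression h/l/n, 2DL1 245 C/R, −21 B
  dimorphism): KIR3DL1 surface-density class (highest allele retained),
  presence of a strong-signalling KIR2DL1-R245 allele, and the donor HLA-B
  −21 M/T genotype steering KIR- vs NKG2A-based education.

Because cohort genotype data of this kind are rarely shareable, the package
includes a synthetic-cohort generator with explicit KIR- and HLA-haplotype
pools that reproduces the study design (sibling genoidentical pairs sharing
both HLA haplotypes, haploidentical pairs sharing one) and a cause-specific
exponential outcome simulator with death as the competing risk.

## Worked example

```
nkalloreact run-all --seed 20240917 --driver-model Cen-B \
    --log-hr-per-unit 1.0986 --out-dir results/cohort
```

or, step by step, the numbered scripts under `analysis/` (simulate → score
→ correlate → outcomes → marginal checks). On the default cohort
(43 genoidentical + 35 haploidentical pairs, aGVHD hazard ×3 per donor
Cen-B motif), `analysis/03_model_correlations.py` prints

```
--- genoidentical ---
  rho(2DL1-C2, Educ-2DL1) = -0.95
  rho(2DL2/3-C1, Educ-2DL2/3) = -1.00
  rho(3DL2-A3/11, Educ-3DL2) = -1.00
  rho(KIR-B content, Cen-B) = +0.73
  rho(B-pattern, Donor aKIR) = +0.93
```

— among HLA-identical pairs a missing-ligand prediction coincides exactly
with an unlicensed donor, so receptor–ligand and educational models are
perfectly anticorrelated (they read the same KIR–ligand interactions in
opposite directions), while haplotype-based scores track donor gene
content. `analysis/04_outcome_analysis.py` then ranks the model × event
Gray tests:

```
event  model          statistic  df  p_value   significant
agvhd  Cen-B          12.59      2   0.00185   True
agvhd  KIR-B content   7.98      2   0.01851   True
```

recovering the injected Cen-B → aGVHD effect; cumulative-incidence step
plots per model level and the full correlation heatmaps are written next
to the tables.

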