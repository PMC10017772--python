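# Methods

## Scope and data model

The unit of analysis is a donor/recipient (D/R) pair of an allogeneic
stem-cell transplant, typed at two-field resolution for HLA-A/-B/-C (class
II optional, used only for match verification) and for presence/absence of
the 13 KIR genes and 2 pseudogenes, with optional allele-level calls for
KIR3DL1/S1 and KIR2DL1. Pairs are *genoidentical* (sibling sharing both
HLA haplotypes; allele multisets identical at every typed locus) or
*haploidentical* (one shared haplotype; on unphased tables this is checked
as ≥ 1 shared allele per locus, the strongest condition flat genotype data
support — true single-haplotype sharing is only enforced inside the
simulator, where phase is known).

Every model returns a categorical label plus a documented ordinal code; a
pair whose required input is unknown yields an explicit *missing* result.
Blank KIR cells in input tables mean *unknown*, never *absent*: silent
defaults would bias the gene-count and haplotype models.

## Ligand annotation

Epitope assignment is table-driven, not sequence-driven at run time: small
curated TSVs (two-field allele → assignment, with a provenance column) ship
with the package and can be replaced by the user.

* HLA-C: C1 ⇔ Asn80, C2 ⇔ Lys80. C1 carried by rare HLA-B allotypes
  (B*46, B*73 lineages) is deliberately not counted — C1/C2 is read from
  HLA-C position 80 only — and those alleles are left out of the bundled
  HLA-B table.
* HLA-B: Bw4-80I / Bw4-80T / Bw6 from residues 77/80; the two tables
  (Bw and leader −21) cover the same allele set, so every annotatable
  genotype satisfies `bw4 + bw6 = 2` per individual.
* HLA-A Bw4 carriers default to the serology-derived allele groups A*23,
  A*24, A*25, A*32; HLA-C Bw6 carriers default to none (a hook accepts a
  user table). The `include_nonclassical_bw` switch of `annotate` turns
  both off, reproducing the behaviour of mismatch calculators that ignore
  non-classical Bw carriers (the BwIPD model scores on these strict
  profiles).
* Leader −21: M/T per allele; the genotype value is the multiset MM/MT/TT.
  The bundled table assigns M to the B7-lineage leaders (B*07, B*08,
  B*14, B*42 groups at the listed two-field alleles) and T elsewhere,
  following the reference protein sequences.

## The 27 models

Definitions as in the README. Non-obvious conventions:

* **Educational models**: donors lacking the KIR gene are classed
  *uneducated* and flagged `gene_absent`, rather than "no alloreactivity";
  the published count tables only add up under this convention, and the
  flag preserves the alternative reading.
* **2DL2/3 locus**: KIR2DL2 and KIR2DL3 are alleles of one locus; the
  receptor is "present" if either gene is, and validation requires at
  least one copy.
* **3DL1-Bw4 / Educ-3DL1** use Bw4 from any source locus, including HLA-A
  carriers.
* **Cen/Tel motifs**: Cen-B markers {2DL2, 2DS2}, Cen-A marker 2DL3; Tel-B
  markers {3DS1, 2DS1}, Tel-A marker 3DL1. A region counts 2 when only B
  markers are present, 0 when only the A marker, 1 for heterozygotes.
  When unknown gene calls make the count depend on their resolution, the
  result is missing (all 2^u resolutions of the unknowns are enumerated; a
  forced count is still reported). Genotypes with no marker of either
  haplotype in a region are flagged ambiguous; the content category is
  then missing.
* **KIR-B content score**: best ⇔ Cen-B = 2; better ⇔ B-pattern ≥ 2
  without Cen-B homozygosity; neutral ⇔ B-pattern ≤ 1. This
  reconstruction reproduces the published neutral/better/best marginals of
  both cohorts exactly from their B-pattern and Cen-B marginals (checked in
  the test suite and the acceptance script); the original web calculator
  was not re-run.
* **Gene content**: aKIR over {2DS1–2DS5, 3DS1} (2DS4 counts at gene level
  regardless of deletion variants); iKIR over {2DL1, 2DL2, 2DL3, 2DL5A,
  2DL5B, 3DL1}, the framework genes 2DL4/3DL2/3DL3 excluded, 2DL5A and
  2DL5B counted separately. R−D difference bins: R>D, R=D, D−R∈{1,2},
  D−R≥3; the fourth bin is retained for iKIR too (the published table
  shows only three iKIR bins because no donor exceeded +2 there).
* **3DL1 expression**: per-allele class from the bundled table
  (*004 null; *005/*007 low; *001/*002/*008/*015/*020 high); highest class
  retained across the two alleles; 3DS1 (surface-expressed but not
  Bw4-binding) groups with null when no expressed 3DL1 allele is present;
  3DL1-negative donors are `null_or_absent` without needing allele calls.
  Allele lists are best-effort and user-overridable.
* **2DL1 245**: R ⇔ *001/*002/*003, C ⇔ *004 in the bundled table;
  gene-absent donors fold into `no_R` (the published "No R allele" count
  exceeds the number of 2DL1-negative donors, implying this fold); calls
  outside the table give `ambiguous`, which has no ordinal code.
* **Ligand–ligand synthesis** combines the Bw4/Bw6 and C1/C2 models only;
  BwIPD is reported separately (the synthesis is defined across the HLA-B
  and HLA-C axes, and including a second Bw reading would double-weight
  that axis).

### Ordinal coding

Fixed, user-overridable: L/L single models HVG = −1, none = 0, GVH = +1
(a simultaneous bidirectional mismatch on one axis — impossible when D and
R share an allele at the locus — is labelled `both_mismatch`, coded 2);
L/L synthesis HVG_any = −1, none = 0, GVH_any = +1, both = 2; R/L no/yes
= 0/1; education uneducated = 0 < no_alloreactivity = 1 < alloreactivity
= 2; counts code as themselves; KIR-B neutral = 0 < better = 1 < best = 2;
R−D bins 0–3 in the order above; 3DL1 expression 0/1/2; 2DL1-245 no_R = 0,
at_least_one_R = 1, ambiguous = missing; −21 TT = 0, MT = 1, MM = 2. Signs
make GVH-direction/more-alloreactive levels positive.

## Statistics

* **Correlation**: Spearman with midrank ties, pairwise-complete
  observations (each cell uses the pairs where both models are
  non-missing; the published analysis's deletion rule is not stated, and
  pairwise-complete wastes the least data). Cells with a constant column
  or < 3 complete pairs are undefined and rendered blank, never imputed 0.
* **Cumulative incidence**: the Aalen–Johansen cause-specific estimator,
  CIF(t) = Σ_{u≤t} Ŝ(u−) d₁(u)/Y(u) with Ŝ the all-cause Kaplan–Meier.
  Implemented directly (≈ 15 lines) rather than through a fitter that
  jitters tied event times, so results are deterministic and the identity
  CIF = 1 − KM holds to machine precision when no competing events exist
  (property-tested against the lifelines Kaplan–Meier on random data).
* **Gray's K-sample test** (rho = 0, unweighted): subjects failing from
  the competing cause remain in the subdistribution risk set weighted by
  the within-group censoring-survival ratio Ĝ(t−)/Ĝ(X_i); the score for
  group k is Σ_t [d₁k(t) − R_k(t) d₁(t)/R(t)]. The variance is estimated
  from per-subject influence residuals
  η_ik = Σ_t (1{g_i=k} − π_k(t)) (dN₁i(t) − w_i(t) dΛ̂₁(t)) as Σ_i η_i η_iᵀ,
  and the statistic zᵀ V⁻ z referred to χ²(K−1). This robust-variance form
  differs from the 1988 closed-form estimator by O(1/n) terms; its
  finite-sample calibration is enforced by a Monte-Carlo property test
  (type-I error within [0.04, 0.06] at n = 200 over 2 000 null
  replicates) and its power by an injected-effect test (HR 3 per Cen-B
  motif, n = 300, ≥ 80% rejections over 200 replicates).
* **Death outcome**: analysed as all-cause survival (death cannot compete
  with itself); the competing-death status applies to relapse/aGVHD/cGVHD
  only. Ordinal models with > 2 levels are compared as K groups, one per
  observed level; no trend test is attempted.
* **Cohort comparison**: chi-square without continuity correction
  (Fisher's exact for 2×2 tables with any expected cell < 5); Student's t
  when Shapiro–Wilk does not reject normality in either cohort at 0.05,
  Mann–Whitney U otherwise.

No multiple-testing correction is applied: the model × event grid is
exploratory and p-values are reported unadjusted.

## Synthetic cohorts

The generator emulates the study design, not a population:

* **KIR pool** (6 haplotypes): Cen-A–Tel-A with high/low/null 3DL1 allele
  variants (frequencies 0.30/0.15/0.10), Cen-A–Tel-B1 (0.15),
  Cen-B1–Tel-A carrying 2DL1*004 (C245) (0.20), Cen-B2–Tel-B1 lacking
  2DL1 (0.10). Cen-B mass is therefore 0.30 (mean Cen-B motif count 0.6),
  and every allelic-polymorphism level is reachable.
* **HLA pool** (12 A-B-C haplotypes): spans C1/C1, C1/C2 and C2/C2
  genotypes, Bw4-80I/80T and Bw6, A3/A11 carriers and non-carriers, −21 M
  and T. Frequencies were chosen once for level coverage at n ≈ 50, not
  for population fidelity, and give each model's minority level a
  comfortable expected count.
* **Pairs**: genoidentical siblings inherit the same two parental HLA
  haplotypes; their KIR genotypes segregate independently from the same
  four parental KIR haplotypes (KIR is on chromosome 19, HLA on 6); an
  `identical_sibling_kir` mode forces KIR identity for tests needing it.
  Haploidentical donors share exactly one HLA haplotype.
* **Outcomes**: per event, latent exponential times with per-month
  baseline hazards (death 0.02, relapse 0.015, aGVHD 0.15, cGVHD 0.03 —
  aGVHD concentrated in the first months, the others of the order seen
  over a three-year window), administrative censoring at 36 months, and an
  optional log-linear effect of one model's score on one event's hazard.
  Every record for a non-fatal event is the first of (event, death,
  censoring), with death recorded as the competing risk.

What passing tests on these cohorts do **not** show: behaviour under
linkage disequilibrium between HLA and KIR (none simulated), rare-allele
annotation gaps (every simulated allele is in the bundled tables by
construction), KIR copy-number variation, or realistic censoring patterns
(administrative only).

## Problem sizes and numerical choices

The test suite exercises cohorts of 20–100 pairs, 10 000-genotype sweeps
for the haplotype identities, 2 000 null replicates for test calibration
and 200 for power, chosen to make the full suite run in a few minutes on
one CPU. Ties in ranks use midranks; Gray/chi-square p-values use the
asymptotic reference with no permutation fallback; the Gray variance
matrix is inverted with a pseudo-inverse to tolerate near-collinear
groups; all simulations run off a single seeded NumPy generator recorded
in the output directory.

## Known limitations

* Epitope and KIR-allele class tables cover common European-ancestry
  alleles; unknown alleles make dependent models missing rather than
  guessed (by design), so cohorts with other allele spectra need extended
  tables.
* The B-content categorisation is a reconstruction validated against
  published marginal counts, not against the original calculator.
* No Fine–Gray or Cox regression, no KIR3DL1/Bw4-80I subtype interaction
  model, and no HLA-E/NKG2A functional model beyond the −21 classifier.
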