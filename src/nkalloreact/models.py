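"""The 27 KIR/HLA-based NK-cell alloreactivity prediction models.

Six families of models are computed per donor/recipient pair:

* ligand-ligand (L/L): compares donor and recipient MHC epitope content
  only; alloreactivity in the graft-versus-host (GVH) direction is
  predicted when the donor carries an epitope class the recipient lacks,
  host-versus-graft (HVG) when the reverse holds.
* receptor-ligand / missing-ligand (R/L): donor inhibitory KIR whose
  cognate ligand is entirely absent from the recipient.
* educational: as R/L but additionally requiring the donor to carry the
  cognate ligand itself (licensed NK cells); donors lacking either the
  KIR gene or the self ligand are scored "uneducated".
* KIR haplotype-based: centromeric/telomeric B-motif counts of the donor
  and the derived neutral/better/best B-content category.
* gene content ("KIR matching"): counts of donor activating and
  (non-framework) inhibitory KIR genes and recipient-minus-donor
  differences.
* allelic polymorphism: KIR3DL1 surface-expression class, KIR2DL1
  transmembrane residue 245 (R/C), and the donor HLA-B -21 M/T leader
  dimorphism.

Each model yields a categorical label plus a documented ordinal code
(``DEFAULT_CODING``) used downstream for rank correlations; pairs whose
input is unknown yield an explicit missing result, never a default.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Mapping, Sequence

import pandas as pd

from .genotypes import DonorRecipientPair, KIRGenotype, Presence
from .ligands import (
    EpitopeTable,
    LigandProfile,
    MissingAnnotationError,
    annotate,
    load_default_tables,
)

__all__ = [
    "MODEL_IDS",
    "MODEL_CATEGORIES",
    "DEFAULT_CODING",
    "ModelResult",
    "CenTelGenotype",
    "ScoreMatrix",
    "PairAnnotations",
    "score_ligand_ligand",
    "synthesize_ligand_ligand",
    "score_receptor_ligand",
    "synthesize_receptor_ligand",
    "score_education",
    "synthesize_education",
    "score_educ_2ds1",
    "assign_cen_tel",
    "kir_b_content",
    "kir_b_content_from_marginals",
    "count_gene_content",
    "diff_gene_content",
    "classify_3dl1_expression",
    "classify_2dl1_245",
    "classify_minus21",
    "score_all",
    "score_cohort",
]

# model inventory, in reporting order
MODEL_CATEGORIES: dict[str, str] = {
    "Bw4/Bw6": "ligand_ligand",
    "BwIPD": "ligand_ligand",
    "C1/C2": "ligand_ligand",
    "L/L synthesis": "ligand_ligand",
    "2DL1-C2": "receptor_ligand",
    "3DL1-Bw4": "receptor_ligand",
    "3DL2-A3/11": "receptor_ligand",
    "2DL2/3-C1": "receptor_ligand",
    "R/L quantitative": "receptor_ligand",
    "R/L qualitative": "receptor_ligand",
    "Educ-2DL1": "educational",
    "Educ-2DL2/3": "educational",
    "Educ-3DL1": "educational",
    "Educ-3DL2": "educational",
    "Educ-DL synthesis": "educational",
    "Educ-2DS1": "educational",
    "B-pattern": "haplotype",
    "Cen-B": "haplotype",
    "Tel-B": "haplotype",
    "KIR-B content": "haplotype",
    "Donor aKIR": "gene_content",
    "R-D aKIR": "gene_content",
    "Donor iKIR": "gene_content",
    "R-D iKIR": "gene_content",
    "3DL1 expression": "allelic_polymorphism",
    "2DL1 245C/R": "allelic_polymorphism",
    "-21 B dimorphism": "allelic_polymorphism",
}
MODEL_IDS: tuple[str, ...] = tuple(MODEL_CATEGORIES)
assert len(MODEL_IDS) == 27

#: documented ordinal coding; counts code as themselves.  Signs are chosen
#: so that GVH-direction / more-alloreactive levels are positive.
DEFAULT_CODING: dict[str, dict[str, float]] = {
    "ligand_ligand_single": {
        "HVG_mismatch": -1, "no_mismatch": 0, "GVH_mismatch": 1, "both_mismatch": 2,
    },
    "ligand_ligand_synthesis": {"HVG_any": -1, "none": 0, "GVH_any": 1, "both": 2},
    "receptor_ligand": {"no": 0, "yes": 1},
    "education": {"uneducated": 0, "no_alloreactivity": 1, "alloreactivity": 2},
    "educ_2ds1": {"no": 0, "yes": 1},
    "kir_b_content": {"neutral": 0, "better": 1, "best": 2},
    "rd_bins": {"R>D": 0, "R=D": 1, "D-R=1-2": 2, "D-R>=3": 3},
    "3dl1_expression": {"null_or_absent": 0, "low": 1, "high": 2},
    "2dl1_245": {"no_R": 0, "at_least_one_R": 1},  # ambiguous -> missing code
    "minus21": {"TT": 0, "MT": 1, "MM": 2},
}

AKIR_GENES = ("KIR2DS1", "KIR2DS2", "KIR2DS3", "KIR2DS4", "KIR2DS5", "KIR3DS1")
IKIR_GENES = ("KIR2DL1", "KIR2DL2", "KIR2DL3", "KIR2DL5A", "KIR2DL5B", "KIR3DL1")

CEN_B_MARKERS = ("KIR2DL2", "KIR2DS2")
CEN_A_MARKER = "KIR2DL3"
TEL_B_MARKERS = ("KIR3DS1", "KIR2DS1")
TEL_A_MARKER = "KIR3DL1"

#: inhibitory KIR -> cognate ligand predicate on a LigandProfile
_RL_LIGANDS: dict[str, Callable[[LigandProfile], bool]] = {
    "2DL1": lambda p: p.has_c2,
    "2DL2/3": lambda p: p.has_c1,
    "3DL1": lambda p: p.has_bw4,  # any source locus
    "3DL2": lambda p: p.has_a3a11,
}
_RL_GENES: dict[str, tuple[str, ...]] = {
    "2DL1": ("KIR2DL1",),
    "2DL2/3": ("KIR2DL2", "KIR2DL3"),
    "3DL1": ("KIR3DL1",),
    "3DL2": ("KIR3DL2",),
}


@dataclass(frozen=True)
class ModelResult:
    model_id: str
    category: str
    label: str | None
    code: float | None
    missing: bool = False
    extras: Mapping[str, object] = field(default_factory=dict)

    @classmethod
    def of(cls, model_id: str, label: str, code: float, **extras) -> "ModelResult":
        return cls(model_id, MODEL_CATEGORIES[model_id], label, code, False, extras)

    @classmethod
    def missing_result(cls, model_id: str, reason: str = "") -> "ModelResult":
        return cls(
            model_id, MODEL_CATEGORIES[model_id], None, None, True,
            {"reason": reason} if reason else {},
        )


@dataclass(frozen=True)
class CenTelGenotype:
    cen_b_count: int
    tel_b_count: int
    ambiguous: bool = False

    @property
    def b_pattern(self) -> int:
        return self.cen_b_count + self.tel_b_count


class ModelInputMissing(Exception):
    """Internal: a required genotype input is unknown for this pair."""


def _presence(kir: KIRGenotype, gene: str) -> bool:
    p = kir[gene]
    if p is Presence.UNKNOWN:
        raise ModelInputMissing(gene)
    return p is Presence.PRESENT


def _locus_present(kir: KIRGenotype, genes: Sequence[str]) -> bool:
    """Presence of a (possibly multi-gene) KIR locus, e.g. 2DL2/3."""
    states = [kir[g] for g in genes]
    if Presence.PRESENT in states:
        return True
    if all(s is Presence.ABSENT for s in states):
        return False
    raise ModelInputMissing("/".join(genes))


@dataclass(frozen=True)
class PairAnnotations:
    """Ligand profiles of both individuals, in full and calculator-style
    (non-classical Bw carriers ignored) modes."""

    donor: LigandProfile
    recipient: LigandProfile
    donor_strict: LigandProfile
    recipient_strict: LigandProfile

    @classmethod
    def from_pair(cls, pair: DonorRecipientPair, tables: EpitopeTable):
        return cls(
            donor=annotate(pair.donor_hla, tables, include_nonclassical_bw=True),
            recipient=annotate(pair.recipient_hla, tables, include_nonclassical_bw=True),
            donor_strict=annotate(pair.donor_hla, tables, include_nonclassical_bw=False),
            recipient_strict=annotate(
                pair.recipient_hla, tables, include_nonclassical_bw=False
            ),
        )


# ---------------------------------------------------------------------------
# ligand-ligand models
# ---------------------------------------------------------------------------

def _epitope_sets(profile: LigandProfile, axis: str) -> set[str]:
    if axis == "bw":
        s = set()
        if profile.has_bw4:
            s.add("Bw4")
        if profile.has_bw6:
            s.add("Bw6")
        return s
    if axis == "c":
        s = set()
        if profile.has_c1:
            s.add("C1")
        if profile.has_c2:
            s.add("C2")
        return s
    raise ValueError(axis)


def score_ligand_ligand(
    ann: PairAnnotations, model: str
) -> ModelResult:
    """One L/L model: ``Bw4/Bw6``, ``BwIPD`` or ``C1/C2``.

    GVH mismatch: the donor carries an epitope class of the model's axis
    that the recipient lacks; HVG mismatch: the reverse.  ``BwIPD`` is the
    Bw axis ignoring HLA-A Bw4 / HLA-C Bw6 carriers.  The per-direction
    flags are kept in ``extras`` for the synthesis.
    """
    if model == "Bw4/Bw6":
        donor, recip, axis = ann.donor, ann.recipient, "bw"
    elif model == "BwIPD":
        donor, recip, axis = ann.donor_strict, ann.recipient_strict, "bw"
    elif model == "C1/C2":
        donor, recip, axis = ann.donor, ann.recipient, "c"
    else:
        raise ValueError(f"unknown ligand-ligand model {model!r}")
    d, r = _epitope_sets(donor, axis), _epitope_sets(recip, axis)
    gvh, hvg = bool(d - r), bool(r - d)
    label = {
        (False, False): "no_mismatch",
        (True, False): "GVH_mismatch",
        (False, True): "HVG_mismatch",
        (True, True): "both_mismatch",
    }[(gvh, hvg)]
    return ModelResult.of(
        model, label, DEFAULT_CODING["ligand_ligand_single"][label],
        gvh=gvh, hvg=hvg,
    )


def synthesize_ligand_ligand(
    bw_result: ModelResult, c_result: ModelResult
) -> ModelResult:
    """L/L synthesis over the HLA-B and HLA-C axes.

    Four levels: mismatch in the GVH direction only, in the HVG direction
    only, in both directions (across the two models), or none.  The
    calculator-style Bw variant is reported separately and excluded here.
    """
    if bw_result.missing or c_result.missing:
        return ModelResult.missing_result("L/L synthesis", "component missing")
    gvh = bool(bw_result.extras["gvh"] or c_result.extras["gvh"])
    hvg = bool(bw_result.extras["hvg"] or c_result.extras["hvg"])
    label = {
        (False, False): "none",
        (True, False): "GVH_any",
        (False, True): "HVG_any",
        (True, True): "both",
    }[(gvh, hvg)]
    return ModelResult.of(
        "L/L synthesis", label, DEFAULT_CODING["ligand_ligand_synthesis"][label]
    )


# ---------------------------------------------------------------------------
# receptor-ligand (missing-ligand) models
# ---------------------------------------------------------------------------

def score_receptor_ligand(
    pair: DonorRecipientPair, ann: PairAnnotations, kir: str
) -> ModelResult:
    """Missing-ligand model for one inhibitory KIR (2DL1, 2DL2/3, 3DL1, 3DL2).

    ``yes``: the donor possesses the inhibitory KIR and the recipient lacks
    its cognate ligand entirely (2DL1<->C2, 2DL2/3<->C1, 3DL1<->Bw4 from any
    locus, 3DL2<->A3/A11).
    """
    model_id = {"2DL1": "2DL1-C2", "2DL2/3": "2DL2/3-C1",
                "3DL1": "3DL1-Bw4", "3DL2": "3DL2-A3/11"}[kir]
    try:
        has_gene = _locus_present(pair.donor_kir, _RL_GENES[kir])
    except ModelInputMissing as exc:
        return ModelResult.missing_result(model_id, f"donor {exc} unknown")
    yes = has_gene and not _RL_LIGANDS[kir](ann.recipient)
    label = "yes" if yes else "no"
    return ModelResult.of(model_id, label, DEFAULT_CODING["receptor_ligand"][label])


def synthesize_receptor_ligand(
    results: Sequence[ModelResult],
) -> tuple[ModelResult, ModelResult]:
    """Quantitative (count of predicting models, 0-4) and qualitative
    (any model predicting) syntheses of the four missing-ligand models."""
    if any(r.missing for r in results):
        return (
            ModelResult.missing_result("R/L quantitative", "component missing"),
            ModelResult.missing_result("R/L qualitative", "component missing"),
        )
    count = sum(r.label == "yes" for r in results)
    qual = "yes" if count > 0 else "no"
    return (
        ModelResult.of("R/L quantitative", str(count), float(count)),
        ModelResult.of("R/L qualitative", qual, DEFAULT_CODING["receptor_ligand"][qual]),
    )


# ---------------------------------------------------------------------------
# educational models
# ---------------------------------------------------------------------------

def score_education(
    pair: DonorRecipientPair, ann: PairAnnotations, kir: str
) -> ModelResult:
    """Educational (licensing) model for one inhibitory KIR.

    Alloreactivity requires licensed donor NK cells — the donor carries
    both the inhibitory KIR and its cognate MHC ligand — while the
    recipient lacks that ligand.  Donors without the KIR gene are scored
    uneducated with ``gene_absent=True``; donors with the gene but without
    the self ligand are uneducated; matched ligand on both sides gives no
    alloreactivity.
    """
    model_id = {"2DL1": "Educ-2DL1", "2DL2/3": "Educ-2DL2/3",
                "3DL1": "Educ-3DL1", "3DL2": "Educ-3DL2"}[kir]
    try:
        has_gene = _locus_present(pair.donor_kir, _RL_GENES[kir])
    except ModelInputMissing as exc:
        return ModelResult.missing_result(model_id, f"donor {exc} unknown")
    if not has_gene:
        return ModelResult.of(
            model_id, "uneducated", DEFAULT_CODING["education"]["uneducated"],
            gene_absent=True,
        )
    donor_has = _RL_LIGANDS[kir](ann.donor)
    recip_has = _RL_LIGANDS[kir](ann.recipient)
    if not donor_has:
        label = "uneducated"
    elif recip_has:
        label = "no_alloreactivity"
    else:
        label = "alloreactivity"
    return ModelResult.of(
        model_id, label, DEFAULT_CODING["education"][label], gene_absent=False
    )


def synthesize_education(results: Sequence[ModelResult]) -> ModelResult:
    """Number of the four educational models predicting alloreactivity."""
    if any(r.missing for r in results):
        return ModelResult.missing_result("Educ-DL synthesis", "component missing")
    count = sum(r.label == "alloreactivity" for r in results)
    return ModelResult.of("Educ-DL synthesis", str(count), float(count))


def score_educ_2ds1(pair: DonorRecipientPair, ann: PairAnnotations) -> ModelResult:
    """Educational model of the activating KIR2DS1.

    Donor 2DS1+ C1+ NK cells are educated and recognise C2 on recipient
    cells; 2DS1+ C1- NK cells stay hyporesponsive.
    """
    try:
        has_2ds1 = _presence(pair.donor_kir, "KIR2DS1")
    except ModelInputMissing:
        return ModelResult.missing_result("Educ-2DS1", "donor KIR2DS1 unknown")
    yes = has_2ds1 and ann.donor.has_c1 and ann.recipient.has_c2
    label = "yes" if yes else "no"
    return ModelResult.of("Educ-2DS1", label, DEFAULT_CODING["educ_2ds1"][label])


# ---------------------------------------------------------------------------
# KIR haplotype-based models
# ---------------------------------------------------------------------------

def assign_cen_tel(kir: KIRGenotype) -> CenTelGenotype:
    """Count centromeric and telomeric B-motifs from gene presence.

    Region markers: Cen-B <-> 2DL2 and/or 2DS2, Cen-A <-> 2DL3;
    Tel-B <-> 3DS1 and/or 2DS1, Tel-A <-> 3DL1.  A region scores 2 when
    only B markers are present, 0 when only the A marker is present, and
    1 for heterozygotes.  ``ambiguous`` flags a region with no marker of
    either haplotype (count conventionally 1, content category missing).
    """
    def resolve(b: bool, a: bool) -> tuple[int, bool]:
        if b and not a:
            return 2, False
        if a and not b:
            return 0, False
        if a and b:
            return 1, False
        return 1, True  # neither motif's marker seen: ambiguous

    def region(b_markers: Sequence[str], a_marker: str) -> tuple[int, bool]:
        genes = (*b_markers, a_marker)
        unknown = [g for g in genes if kir[g] is Presence.UNKNOWN]
        # the count must be identical under every resolution of the unknowns
        outcomes = set()
        for states in itertools.product([False, True], repeat=len(unknown)):
            resolved = dict(zip(unknown, states))

            def present(g):
                return resolved[g] if g in resolved else kir[g] is Presence.PRESENT

            outcomes.add(resolve(any(present(g) for g in b_markers),
                                 present(a_marker)))
        if len(outcomes) > 1:
            raise ModelInputMissing(
                f"motif count indeterminate: {', '.join(unknown)} unknown"
            )
        return outcomes.pop()

    cen, cen_amb = region(CEN_B_MARKERS, CEN_A_MARKER)
    tel, tel_amb = region(TEL_B_MARKERS, TEL_A_MARKER)
    return CenTelGenotype(cen, tel, ambiguous=cen_amb or tel_amb)


def kir_b_content(cen_tel: CenTelGenotype) -> str:
    """Donor B-content category: neutral / better / best.

    best: Cen-B homozygous; better: >= 2 B motifs without Cen-B
    homozygosity; neutral: <= 1 B motif.
    """
    if cen_tel.ambiguous:
        raise ModelInputMissing("ambiguous Cen/Tel motif assignment")
    if cen_tel.cen_b_count == 2:
        return "best"
    if cen_tel.b_pattern >= 2:
        return "better"
    return "neutral"


def kir_b_content_from_marginals(
    b_pattern_counts: Mapping[int, int], cen_b_counts: Mapping[int, int]
) -> dict[str, int]:
    """Apply the B-content category rule to marginal count distributions.

    Given how many donors carry each B-pattern value (0-4) and each Cen-B
    value (0-2), the rule's categories are identifiable from the marginals
    alone: neutral = B-pattern <= 1, best = Cen-B = 2, better = remainder.
    """
    total = sum(b_pattern_counts.values())
    if total != sum(cen_b_counts.values()):
        raise ValueError("marginal distributions describe different donor totals")
    neutral = b_pattern_counts.get(0, 0) + b_pattern_counts.get(1, 0)
    best = cen_b_counts.get(2, 0)
    return {"neutral": neutral, "better": total - neutral - best, "best": best}


# ---------------------------------------------------------------------------
# gene content models
# ---------------------------------------------------------------------------

def count_gene_content(kir: KIRGenotype) -> tuple[int, int]:
    """(activating, inhibitory) KIR gene counts of one individual.

    aKIR over {2DS1..2DS5, 3DS1}; iKIR over {2DL1, 2DL2, 2DL3, 2DL5A,
    2DL5B, 3DL1} — the framework genes 2DL4, 3DL2, 3DL3 are excluded.
    2DS4 counts at gene level regardless of deletion-variant status.
    """
    akir = sum(_presence(kir, g) for g in AKIR_GENES)
    ikir = sum(_presence(kir, g) for g in IKIR_GENES)
    return akir, ikir


def _diff_bin(donor: int, recipient: int) -> str:
    d = donor - recipient
    if d < 0:
        return "R>D"
    if d == 0:
        return "R=D"
    if d <= 2:
        return "D-R=1-2"
    return "D-R>=3"


def diff_gene_content(pair: DonorRecipientPair) -> tuple[str, str]:
    """Recipient-vs-donor aKIR and iKIR difference bins."""
    d_akir, d_ikir = count_gene_content(pair.donor_kir)
    r_akir, r_ikir = count_gene_content(pair.recipient_kir)
    return _diff_bin(d_akir, r_akir), _diff_bin(d_ikir, r_ikir)


# ---------------------------------------------------------------------------
# allelic polymorphism models
# ---------------------------------------------------------------------------

def _load_allele_table(name: str) -> dict[str, str]:
    src = resources.files("nkalloreact.data") / name
    with resources.as_file(src) as p:
        df = pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)
    return dict(zip(df["allele"], df["assignment"]))

_3DL1_CLASSES = _load_allele_table("kir3dl1_expression.tsv")
_2DL1_245 = _load_allele_table("kir2dl1_245.tsv")

_EXPR_ORDER = {"null_or_absent": 0, "low": 1, "high": 2}


def _norm_kir_allele(name: str) -> str:
    """Reduce a KIR allele call to gene*3-digit protein resolution."""
    name = name.replace("KIR", "").strip()
    gene, _, fields = name.partition("*")
    return f"{gene}*{fields[:3]}"


def classify_3dl1_expression(kir: KIRGenotype) -> str:
    """Donor KIR3DL1 surface-expression class: null_or_absent / low / high.

    Per-allele classes come from the bundled table (e.g. *004 retained
    intracellularly, *005/*007 low, *001/*002/... high); with two alleles
    of different class the highest expression is retained.  3DS1 does not
    bind Bw4 and groups with null when no expressed 3DL1 allele is present.
    A donor lacking both 3DL1 and 3DS1 is null_or_absent without needing
    allele calls; a 3DL1-positive donor without allele-level typing is
    missing.
    """
    p_3dl1 = kir["KIR3DL1"]
    if p_3dl1 is Presence.UNKNOWN:
        raise ModelInputMissing("KIR3DL1 presence unknown")
    if p_3dl1 is Presence.ABSENT:
        return "null_or_absent"
    calls = [*kir.allele_calls("KIR3DL1"), *kir.allele_calls("KIR3DS1")]
    if not calls:
        raise ModelInputMissing("KIR3DL1 allele calls unavailable")
    best: str | None = None
    for call in calls:
        cls = _3DL1_CLASSES.get(_norm_kir_allele(call))
        if cls is None:
            raise ModelInputMissing(f"KIR3DL1/S1 allele {call} not in class table")
        level = "null_or_absent" if cls in ("null", "3DS1") else cls
        if best is None or _EXPR_ORDER[level] > _EXPR_ORDER[best]:
            best = level
    return best  # type: ignore[return-value]


def classify_2dl1_245(kir: KIRGenotype) -> str:
    """Donor KIR2DL1 transmembrane-245 dimorphism: no_R / at_least_one_R /
    ambiguous.

    Gene-absent donors fold into no_R; allele calls resolve residue 245
    through the bundled table; calls outside the table give ``ambiguous``.
    """
    p = kir["KIR2DL1"]
    if p is Presence.UNKNOWN:
        raise ModelInputMissing("KIR2DL1 presence unknown")
    if p is Presence.ABSENT:
        return "no_R"
    calls = kir.allele_calls("KIR2DL1")
    if not calls:
        raise ModelInputMissing("KIR2DL1 allele calls unavailable")
    residues = {_2DL1_245.get(_norm_kir_allele(c)) for c in calls}
    if None in residues:
        return "ambiguous"
    return "at_least_one_R" if "R" in residues else "no_R"


def classify_minus21(profile: LigandProfile) -> str:
    """Donor HLA-B -21 leader genotype: TT / MT / MM."""
    return profile.minus21


# ---------------------------------------------------------------------------
# full matrix
# ---------------------------------------------------------------------------

def score_all(
    pair: DonorRecipientPair, tables: EpitopeTable | None = None
) -> dict[str, ModelResult]:
    """Score every model for one pair; per-model failures become missing
    results and never abort the row."""
    if tables is None:
        tables = load_default_tables()
    try:
        ann = PairAnnotations.from_pair(pair, tables)
    except MissingAnnotationError as exc:
        return {
            m: ModelResult.missing_result(m, f"unannotatable alleles: {exc.alleles}")
            for m in MODEL_IDS
        }
    out: dict[str, ModelResult] = {}

    bw = score_ligand_ligand(ann, "Bw4/Bw6")
    bw_ipd = score_ligand_ligand(ann, "BwIPD")
    cc = score_ligand_ligand(ann, "C1/C2")
    out["Bw4/Bw6"], out["BwIPD"], out["C1/C2"] = bw, bw_ipd, cc
    out["L/L synthesis"] = synthesize_ligand_ligand(bw, cc)

    rl = [score_receptor_ligand(pair, ann, k) for k in ("2DL1", "3DL1", "3DL2", "2DL2/3")]
    out["2DL1-C2"], out["3DL1-Bw4"], out["3DL2-A3/11"], out["2DL2/3-C1"] = rl
    out["R/L quantitative"], out["R/L qualitative"] = synthesize_receptor_ligand(rl)

    educ = [score_education(pair, ann, k) for k in ("2DL1", "2DL2/3", "3DL1", "3DL2")]
    out["Educ-2DL1"], out["Educ-2DL2/3"], out["Educ-3DL1"], out["Educ-3DL2"] = educ
    out["Educ-DL synthesis"] = synthesize_education(educ)
    out["Educ-2DS1"] = score_educ_2ds1(pair, ann)

    try:
        ct = assign_cen_tel(pair.donor_kir)
        out["B-pattern"] = ModelResult.of("B-pattern", str(ct.b_pattern), float(ct.b_pattern))
        out["Cen-B"] = ModelResult.of("Cen-B", str(ct.cen_b_count), float(ct.cen_b_count))
        out["Tel-B"] = ModelResult.of("Tel-B", str(ct.tel_b_count), float(ct.tel_b_count))
        try:
            cat = kir_b_content(ct)
            out["KIR-B content"] = ModelResult.of(
                "KIR-B content", cat, DEFAULT_CODING["kir_b_content"][cat]
            )
        except ModelInputMissing as exc:
            out["KIR-B content"] = ModelResult.missing_result("KIR-B content", str(exc))
    except ModelInputMissing as exc:
        for m in ("B-pattern", "Cen-B", "Tel-B", "KIR-B content"):
            out[m] = ModelResult.missing_result(m, str(exc))

    try:
        akir, ikir = count_gene_content(pair.donor_kir)
        out["Donor aKIR"] = ModelResult.of("Donor aKIR", str(akir), float(akir))
        out["Donor iKIR"] = ModelResult.of("Donor iKIR", str(ikir), float(ikir))
    except ModelInputMissing as exc:
        out["Donor aKIR"] = ModelResult.missing_result("Donor aKIR", str(exc))
        out["Donor iKIR"] = ModelResult.missing_result("Donor iKIR", str(exc))
    try:
        akir_bin, ikir_bin = diff_gene_content(pair)
        out["R-D aKIR"] = ModelResult.of(
            "R-D aKIR", akir_bin, DEFAULT_CODING["rd_bins"][akir_bin]
        )
        out["R-D iKIR"] = ModelResult.of(
            "R-D iKIR", ikir_bin, DEFAULT_CODING["rd_bins"][ikir_bin]
        )
    except ModelInputMissing as exc:
        out["R-D aKIR"] = ModelResult.missing_result("R-D aKIR", str(exc))
        out["R-D iKIR"] = ModelResult.missing_result("R-D iKIR", str(exc))

    try:
        expr = classify_3dl1_expression(pair.donor_kir)
        out["3DL1 expression"] = ModelResult.of(
            "3DL1 expression", expr, DEFAULT_CODING["3dl1_expression"][expr]
        )
    except ModelInputMissing as exc:
        out["3DL1 expression"] = ModelResult.missing_result("3DL1 expression", str(exc))
    try:
        res = classify_2dl1_245(pair.donor_kir)
        code = DEFAULT_CODING["2dl1_245"].get(res, math.nan)
        out["2DL1 245C/R"] = ModelResult.of(
            "2DL1 245C/R", res, None if res == "ambiguous" else code
        )
    except ModelInputMissing as exc:
        out["2DL1 245C/R"] = ModelResult.missing_result("2DL1 245C/R", str(exc))

    m21 = classify_minus21(ann.donor)
    out["-21 B dimorphism"] = ModelResult.of(
        "-21 B dimorphism", m21, DEFAULT_CODING["minus21"][m21]
    )

    return {m: out[m] for m in MODEL_IDS}


class ScoreMatrix:
    """Pairs x 27-models matrix of :class:`ModelResult` cells."""

    def __init__(self, results: Mapping[str, Mapping[str, ModelResult]],
                 match_fashion: Mapping[str, str] | None = None):
        self.results = {pid: dict(row) for pid, row in results.items()}
        self.match_fashion = dict(match_fashion or {})
        for pid, row in self.results.items():
            if tuple(row) != MODEL_IDS:
                raise ValueError(f"pair {pid}: row does not cover the 27 models")

    @property
    def pair_ids(self) -> list[str]:
        return list(self.results)

    def labels_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                pid: {m: (r.label if not r.missing else None)
                      for m, r in row.items()}
                for pid, row in self.results.items()
            }
        ).T.reindex(columns=list(MODEL_IDS))

    def codes_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                pid: {m: (math.nan if r.missing or r.code is None else float(r.code))
                      for m, r in row.items()}
                for pid, row in self.results.items()
            }
        ).T.reindex(columns=list(MODEL_IDS))
        return df.astype(float)

    def to_csv(self, labels_path, codes_path) -> None:
        self.labels_frame().rename_axis("pair_id").to_csv(labels_path)
        self.codes_frame().rename_axis("pair_id").to_csv(codes_path)


def score_cohort(
    pairs: Sequence[DonorRecipientPair], tables: EpitopeTable | None = None
) -> ScoreMatrix:
    if tables is None:
        tables = load_default_tables()
    return ScoreMatrix(
        {p.pair_id: score_all(p, tables) for p in pairs},
        {p.pair_id: p.match_fashion for p in pairs},
    )
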