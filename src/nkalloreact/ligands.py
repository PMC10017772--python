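"""KIR-ligand epitope annotation of HLA genotypes.

HLA class I molecules act as ligands for inhibitory KIR through a small
number of epitope groups: HLA-C alleles split into C1 (Asn80, ligand of
KIR2DL2/3) and C2 (Lys80, ligand of KIR2DL1 and KIR2DS1); HLA-B alleles
split into Bw4 (80I or 80T, ligand of KIR3DL1) and Bw6 (not a KIR ligand)
by residues 77/80 of the alpha-1 domain; A*03/A*11 are the KIR3DL2
ligands; and the HLA-B leader-peptide dimorphism at position -21 (M/T)
governs HLA-E/NKG2A-based NK education.  Some HLA-A alleles also carry
the Bw4 epitope (and, in principle, some HLA-C alleles Bw6); whether
those non-classical carriers count is a switch on :func:`annotate`,
mirroring the behaviour of calculators that ignore them.

Assignment is table-driven: curated two-field lookup tables derived from
reference protein sequences ship with the package and can be replaced by
the user.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .genotypes import HLAAllele, HLAGenotype

__all__ = [
    "MissingAnnotationError",
    "EpitopeTable",
    "LigandProfile",
    "load_default_tables",
    "annotate",
]


class MissingAnnotationError(KeyError):
    """An HLA allele is absent from the bundled epitope tables."""

    def __init__(self, alleles):
        self.alleles = tuple(alleles)
        super().__init__(
            "no epitope annotation for allele(s): " + ", ".join(self.alleles)
        )


def _load_tsv(name: str, path: str | Path | None = None) -> dict[str, str]:
    if path is None:
        src = resources.files("nkalloreact.data") / name
        with resources.as_file(src) as p:
            df = pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df["allele"].duplicated().any():
        dup = df.loc[df["allele"].duplicated(), "allele"].iloc[0]
        raise ValueError(f"duplicate allele key {dup!r} in {name}")
    return dict(zip(df["allele"], df["assignment"]))


@dataclass(frozen=True)
class EpitopeTable:
    """Two-field allele → epitope lookups for all annotation axes."""

    c_c1c2: dict[str, str]        # C*xx:yy -> C1 | C2
    b_bw: dict[str, str]          # B*xx:yy -> Bw4-80I | Bw4-80T | Bw6
    a_bw4_groups: dict[str, str]  # A*xx (first field) -> Bw4
    b_minus21: dict[str, str]     # B*xx:yy -> M | T
    c_bw6_groups: dict[str, str]  # hook: C groups counted as Bw6 carriers

    def epitope_of_hla_c(self, allele: HLAAllele) -> str:
        """C1 (Asn80) or C2 (Lys80)."""
        if allele.locus != "C":
            raise ValueError(f"{allele} is not an HLA-C allele")
        try:
            return self.c_c1c2[allele.two_field]
        except KeyError:
            raise MissingAnnotationError([allele.two_field]) from None

    def epitope_of_hla_b(self, allele: HLAAllele) -> str:
        """Bw4-80I, Bw4-80T or Bw6, from residues 77/80."""
        if allele.locus != "B":
            raise ValueError(f"{allele} is not an HLA-B allele")
        try:
            return self.b_bw[allele.two_field]
        except KeyError:
            raise MissingAnnotationError([allele.two_field]) from None

    def minus21_of_b(self, allele: HLAAllele) -> str:
        """Leader-peptide residue -21: M or T."""
        if allele.locus != "B":
            raise ValueError(f"{allele} is not an HLA-B allele")
        try:
            return self.b_minus21[allele.two_field]
        except KeyError:
            raise MissingAnnotationError([allele.two_field]) from None

    def a_is_bw4(self, allele: HLAAllele) -> bool:
        return allele.group in self.a_bw4_groups

    def c_is_bw6(self, allele: HLAAllele) -> bool:
        return allele.group in self.c_bw6_groups


def load_default_tables(
    hla_c_path=None, hla_b_path=None, hla_a_path=None, minus21_path=None,
    c_bw6_path=None,
) -> EpitopeTable:
    """Load the bundled reference tables, any of which may be overridden."""
    return EpitopeTable(
        c_c1c2=_load_tsv("hla_c_c1c2.tsv", hla_c_path),
        b_bw=_load_tsv("hla_b_bw.tsv", hla_b_path),
        a_bw4_groups=_load_tsv("hla_a_bw4.tsv", hla_a_path),
        b_minus21=_load_tsv("hla_b_minus21.tsv", minus21_path),
        # no HLA-C Bw6 carriers by default; user hook only
        c_bw6_groups=_load_tsv("hla_a_bw4.tsv", c_bw6_path) if c_bw6_path else {},
    )


@dataclass(frozen=True)
class LigandProfile:
    """Derived KIR-ligand epitope content of one individual.

    Counts are per-allele over the two alleles of a locus, so
    ``c1_count + c2_count == 2`` and ``b_bw4_count + b_bw6_count == 2``
    for every annotatable genotype.  C1 carried by rare HLA-B alleles is
    deliberately not counted: C1/C2 is read from HLA-C position 80 only.
    """

    individual_id: str
    c1_count: int
    c2_count: int
    b_bw4_count: int
    b_bw6_count: int
    b_bw4_80i_count: int
    b_bw4_80t_count: int
    a_bw4_present: bool
    c_bw6_present: bool
    a3a11_present: bool
    minus21: str  # MM | MT | TT

    @property
    def has_c1(self) -> bool:
        return self.c1_count > 0

    @property
    def has_c2(self) -> bool:
        return self.c2_count > 0

    @property
    def has_bw4(self) -> bool:
        """Bw4 from any source locus (HLA-B or HLA-A carriers)."""
        return self.b_bw4_count > 0 or self.a_bw4_present

    @property
    def has_bw6(self) -> bool:
        return self.b_bw6_count > 0 or self.c_bw6_present

    @property
    def has_a3a11(self) -> bool:
        return self.a3a11_present


def annotate(
    genotype: HLAGenotype,
    tables: EpitopeTable,
    include_nonclassical_bw: bool = True,
) -> LigandProfile:
    """Compute the :class:`LigandProfile` of one individual.

    With ``include_nonclassical_bw=False`` the Bw4/Bw6 epitopes carried by
    HLA-A/HLA-C molecules are ignored (``a_bw4_present`` and
    ``c_bw6_present`` forced false); everything else is unchanged.
    Unresolvable alleles raise :class:`MissingAnnotationError` listing
    every offending allele.
    """
    missing: list[str] = []
    c_epitopes, b_epitopes, leaders = [], [], []
    for a in genotype.locus("C"):
        try:
            c_epitopes.append(tables.epitope_of_hla_c(a))
        except MissingAnnotationError:
            missing.append(a.two_field)
    for a in genotype.locus("B"):
        try:
            b_epitopes.append(tables.epitope_of_hla_b(a))
        except MissingAnnotationError:
            missing.append(a.two_field)
        try:
            leaders.append(tables.minus21_of_b(a))
        except MissingAnnotationError:
            missing.append(a.two_field + " (-21)")
    if missing:
        raise MissingAnnotationError(sorted(set(missing)))

    a_alleles = genotype.locus("A")
    a_bw4 = any(tables.a_is_bw4(a) for a in a_alleles)
    c_bw6 = any(tables.c_is_bw6(a) for a in genotype.locus("C"))
    if not include_nonclassical_bw:
        a_bw4 = False
        c_bw6 = False
    return LigandProfile(
        individual_id=genotype.individual_id,
        c1_count=sum(e == "C1" for e in c_epitopes),
        c2_count=sum(e == "C2" for e in c_epitopes),
        b_bw4_count=sum(e.startswith("Bw4") for e in b_epitopes),
        b_bw6_count=sum(e == "Bw6" for e in b_epitopes),
        b_bw4_80i_count=sum(e == "Bw4-80I" for e in b_epitopes),
        b_bw4_80t_count=sum(e == "Bw4-80T" for e in b_epitopes),
        a_bw4_present=a_bw4,
        c_bw6_present=c_bw6,
        a3a11_present=any(a.group in ("A*03", "A*11") for a in a_alleles),
        minus21="".join(sorted(leaders)),  # MM | MT | TT
    )
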