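"""Domain types, readers/writers and validation for genotype and pair tables.

The unit of analysis is the donor/recipient pair of an allogeneic
haematopoietic stem-cell transplant, typed for classical HLA class I
(and optionally class II) alleles and for the presence/absence of the
KIR genes and pseudogenes.  Input tables are plain delimited text
(comma or tab), one row per individual or per pair.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "HLA_LOCI",
    "REQUIRED_LOCI",
    "KIR_GENES",
    "FRAMEWORK_GENES",
    "Presence",
    "HLAAllele",
    "HLAGenotype",
    "KIRGenotype",
    "DonorRecipientPair",
    "OutcomeRecord",
    "MatchReport",
    "CohortError",
    "read_cohort",
    "write_cohort",
    "verify_match_fashion",
]

HLA_LOCI = (
    "A", "B", "C", "DRB1", "DQA1", "DQB1", "DPA1", "DPB1", "DRB3", "DRB4", "DRB5",
)
#: minimum typing required by every prediction model
REQUIRED_LOCI = ("A", "B", "C")

#: 13 KIR genes (2DL5 split into its A and B copies) plus 2 pseudogenes
KIR_GENES = (
    "KIR2DL1", "KIR2DL2", "KIR2DL3", "KIR2DL4", "KIR2DL5A", "KIR2DL5B",
    "KIR2DS1", "KIR2DS2", "KIR2DS3", "KIR2DS4", "KIR2DS5",
    "KIR3DL1", "KIR3DS1", "KIR3DL2", "KIR3DL3",
    "KIR2DP1", "KIR3DP1",
)

#: present on essentially every haplotype; excluded from iKIR counting
FRAMEWORK_GENES = ("KIR3DL2", "KIR3DL3", "KIR2DL4", "KIR3DP1")

EVENT_TYPES = ("death", "relapse", "agvhd", "cgvhd")
STATUS_VALUES = ("event", "censored", "competing_death")


class Presence(str, Enum):
    PRESENT = "present"
    ABSENT = "absent"
    UNKNOWN = "unknown"


class CohortError(ValueError):
    """Raised on malformed or inconsistent cohort input."""


_ALLELE_RE = re.compile(
    r"^(?P<locus>[A-Z]+[0-9]*)\*(?P<fields>[0-9]{2,4}(?::[0-9]{2,4})+[NLSCAQ]?)$"
)


@dataclass(frozen=True)
class HLAAllele:
    """One HLA allele in standard nomenclature, e.g. ``A*03:01``.

    ``fields`` keeps the ordered numeric name fields; epitope lookups use
    the two-field prefix only, higher-resolution suffixes are retained in
    ``raw_name`` and round-trip through the writer.
    """

    locus: str
    fields: tuple[str, ...]
    raw_name: str

    @classmethod
    def parse(cls, name: str) -> "HLAAllele":
        name = name.strip()
        m = _ALLELE_RE.match(name)
        if m is None:
            raise CohortError(f"unparseable HLA allele name: {name!r}")
        locus = m.group("locus")
        if locus not in HLA_LOCI:
            raise CohortError(f"unknown HLA locus {locus!r} in allele {name!r}")
        fields = tuple(f.rstrip("NLSCAQ") for f in m.group("fields").split(":"))
        if len(fields) < 2:
            raise CohortError(f"allele {name!r} below two-field resolution")
        return cls(locus=locus, fields=fields, raw_name=name)

    @property
    def two_field(self) -> str:
        """Two-field key used by the bundled epitope tables, e.g. ``B*07:02``."""
        return f"{self.locus}*{self.fields[0]}:{self.fields[1]}"

    @property
    def group(self) -> str:
        """First-field allele group, e.g. ``A*24``."""
        return f"{self.locus}*{self.fields[0]}"

    def __str__(self) -> str:  # round-trips the original string
        return self.raw_name


@dataclass(frozen=True)
class HLAGenotype:
    """Unphased HLA typing: exactly two alleles per typed locus."""

    individual_id: str
    alleles: Mapping[str, tuple[HLAAllele, HLAAllele]]

    def __post_init__(self):
        for locus in REQUIRED_LOCI:
            if locus not in self.alleles:
                raise CohortError(
                    f"{self.individual_id}: HLA-{locus} typing is required"
                )
        for locus, pair in self.alleles.items():
            if len(pair) != 2:
                raise CohortError(
                    f"{self.individual_id}: locus {locus} needs exactly 2 alleles"
                )

    def locus(self, locus: str) -> tuple[HLAAllele, HLAAllele]:
        return self.alleles[locus]


@dataclass(frozen=True)
class KIRGenotype:
    """KIR gene presence/absence with optional allele-level calls.

    ``KIR2DL2`` and ``KIR2DL3`` behave as alleles of one locus: at least one
    of the two must be present.  Framework genes must be present unless
    ``allow_missing_framework`` is set (e.g. partially typed data).
    """

    individual_id: str
    presence: Mapping[str, Presence]
    alleles: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    allow_missing_framework: bool = False

    def __post_init__(self):
        for gene in self.presence:
            if gene not in KIR_GENES:
                raise CohortError(f"{self.individual_id}: unknown KIR gene {gene}")
        if not self.allow_missing_framework:
            for gene in FRAMEWORK_GENES:
                if self.presence.get(gene, Presence.UNKNOWN) is Presence.ABSENT:
                    raise CohortError(
                        f"{self.individual_id}: framework gene {gene} marked absent"
                    )
            l2, l3 = self[("KIR2DL2")], self["KIR2DL3"]
            if Presence.PRESENT not in (l2, l3) and Presence.UNKNOWN not in (l2, l3):
                raise CohortError(
                    f"{self.individual_id}: KIR2DL2 and KIR2DL3 are alleles of one "
                    "locus; at least one must be present"
                )
        for gene, calls in self.alleles.items():
            if calls and self.presence.get(gene) is Presence.ABSENT:
                raise CohortError(
                    f"{self.individual_id}: allele calls given for absent gene {gene}"
                )

    def __getitem__(self, gene: str) -> Presence:
        return self.presence.get(gene, Presence.UNKNOWN)

    def allele_calls(self, gene: str) -> tuple[str, ...]:
        return tuple(self.alleles.get(gene, ()))


@dataclass(frozen=True)
class DonorRecipientPair:
    pair_id: str
    donor_hla: HLAGenotype
    donor_kir: KIRGenotype
    recipient_hla: HLAGenotype
    recipient_kir: KIRGenotype
    match_fashion: str  # "genoidentical" | "haploidentical"

    def __post_init__(self):
        if self.match_fashion not in ("genoidentical", "haploidentical"):
            raise CohortError(
                f"pair {self.pair_id}: match_fashion must be genoidentical or "
                f"haploidentical, got {self.match_fashion!r}"
            )
        if self.donor_hla.individual_id == self.recipient_hla.individual_id:
            raise CohortError(f"pair {self.pair_id}: donor and recipient ids equal")


@dataclass(frozen=True)
class OutcomeRecord:
    """One clinical event record with competing-risk semantics.

    Acute GVHD records represent grade >= II only; death records never carry
    ``competing_death`` status (death cannot compete with itself).
    """

    pair_id: str
    event: str
    time: float  # months from transplant
    status: str

    def __post_init__(self):
        if self.event not in EVENT_TYPES:
            raise CohortError(f"unknown event type {self.event!r}")
        if self.status not in STATUS_VALUES:
            raise CohortError(f"unknown status {self.status!r}")
        if self.time < 0:
            raise CohortError(f"negative event time for pair {self.pair_id}")
        if self.event == "death" and self.status == "competing_death":
            raise CohortError("death outcome cannot have competing_death status")


@dataclass
class MatchReport:
    consistent: bool
    offending_loci: list[str] = field(default_factory=list)


def verify_match_fashion(pair: DonorRecipientPair) -> MatchReport:
    """Check the declared D/R matching against the HLA typings.

    Genoidentical siblings are fully HLA matched, so the unphased allele
    multisets must be identical at every typed locus.  Haploidentical
    relatives share one haplotype; on unphased data this is checked as
    at least one shared allele per typed locus.
    """
    offending: list[str] = []
    loci = sorted(set(pair.donor_hla.alleles) & set(pair.recipient_hla.alleles))
    for locus in loci:
        d = sorted(a.two_field for a in pair.donor_hla.locus(locus))
        r = sorted(a.two_field for a in pair.recipient_hla.locus(locus))
        if pair.match_fashion == "genoidentical":
            ok = d == r
        else:
            ok = bool(set(d) & set(r))
        if not ok:
            offending.append(locus)
    return MatchReport(consistent=not offending, offending_loci=offending)


# ---------------------------------------------------------------------------
# file dialect
# ---------------------------------------------------------------------------

def _read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", dtype=str)


def _parse_individual(row: pd.Series, row_number: int) -> tuple[HLAGenotype, KIRGenotype]:
    ind = str(row["individual_id"])
    alleles: dict[str, tuple[HLAAllele, HLAAllele]] = {}
    for locus in HLA_LOCI:
        c1, c2 = f"{locus}_1", f"{locus}_2"
        if c1 in row.index and c2 in row.index:
            v1, v2 = row[c1], row[c2]
            if pd.isna(v1) and pd.isna(v2):
                continue
            if pd.isna(v1) or pd.isna(v2):
                raise CohortError(
                    f"row {row_number}: individual {ind} has a single allele at "
                    f"HLA-{locus}; homozygotes must list the allele twice"
                )
            try:
                alleles[locus] = (HLAAllele.parse(v1), HLAAllele.parse(v2))
            except CohortError as exc:
                raise CohortError(f"row {row_number}: {exc}") from exc
    for locus in REQUIRED_LOCI:
        if locus not in alleles:
            raise CohortError(
                f"row {row_number}: individual {ind} lacks HLA-{locus} typing"
            )
    presence: dict[str, Presence] = {}
    for gene in KIR_GENES:
        if gene not in row.index:
            presence[gene] = Presence.UNKNOWN
            continue
        v = row[gene]
        if pd.isna(v) or str(v).strip() == "":
            presence[gene] = Presence.UNKNOWN  # empty cell = unknown, not absent
        elif str(v).strip() in ("1", "present"):
            presence[gene] = Presence.PRESENT
        elif str(v).strip() in ("0", "absent"):
            presence[gene] = Presence.ABSENT
        else:
            raise CohortError(
                f"row {row_number}: bad presence code {v!r} for {gene} of {ind}"
            )
    allele_calls: dict[str, tuple[str, ...]] = {}
    for gene, col in (
        ("KIR3DL1", "KIR3DL1_alleles"),
        ("KIR3DS1", "KIR3DS1_alleles"),
        ("KIR2DL1", "KIR2DL1_alleles"),
    ):
        if col in row.index and not pd.isna(row[col]) and str(row[col]).strip():
            allele_calls[gene] = tuple(
                a.strip() for a in str(row[col]).split(";") if a.strip()
            )
    hla = HLAGenotype(individual_id=ind, alleles=alleles)
    kir = KIRGenotype(individual_id=ind, presence=presence, alleles=allele_calls)
    return hla, kir


def read_cohort(
    pairs_path: str | Path,
    genotypes_path: str | Path,
    outcomes_path: str | Path | None = None,
) -> tuple[list[DonorRecipientPair], list[OutcomeRecord]]:
    """Load a cohort from the pairs / genotypes (/ outcomes) file dialect.

    Returns pairs ordered by ``pair_id``.  Unknown KIR genes (blank cells)
    are recorded as unknown, never as absent.  Missing individuals,
    unparseable alleles and duplicate pair ids are hard errors.
    """
    geno = _read_table(genotypes_path)
    if "individual_id" not in geno.columns:
        raise CohortError("genotypes file lacks an individual_id column")
    individuals: dict[str, tuple[HLAGenotype, KIRGenotype]] = {}
    for i, (_, row) in enumerate(geno.iterrows(), start=2):  # 1-based + header
        ind = str(row["individual_id"])
        if ind in individuals:
            raise CohortError(f"duplicate individual_id {ind!r}")
        individuals[ind] = _parse_individual(row, i)

    pairs_df = _read_table(pairs_path)
    for col in ("pair_id", "donor_id", "recipient_id", "match_fashion"):
        if col not in pairs_df.columns:
            raise CohortError(f"pairs file lacks column {col!r}")
    if pairs_df["pair_id"].duplicated().any():
        dup = pairs_df.loc[pairs_df["pair_id"].duplicated(), "pair_id"].iloc[0]
        raise CohortError(f"duplicate pair_id {dup!r}")
    pairs: list[DonorRecipientPair] = []
    for _, row in pairs_df.iterrows():
        for role in ("donor_id", "recipient_id"):
            if str(row[role]) not in individuals:
                raise CohortError(
                    f"pair {row['pair_id']}: {role} {row[role]!r} has no genotype row"
                )
        d_hla, d_kir = individuals[str(row["donor_id"])]
        r_hla, r_kir = individuals[str(row["recipient_id"])]
        pairs.append(
            DonorRecipientPair(
                pair_id=str(row["pair_id"]),
                donor_hla=d_hla, donor_kir=d_kir,
                recipient_hla=r_hla, recipient_kir=r_kir,
                match_fashion=str(row["match_fashion"]),
            )
        )
    pairs.sort(key=lambda p: p.pair_id)

    outcomes: list[OutcomeRecord] = []
    if outcomes_path is not None:
        out_df = _read_table(outcomes_path)
        for col in ("pair_id", "event", "time_months", "status"):
            if col not in out_df.columns:
                raise CohortError(f"outcomes file lacks column {col!r}")
        known = {p.pair_id for p in pairs}
        for _, row in out_df.iterrows():
            if str(row["pair_id"]) not in known:
                raise CohortError(f"outcome for unknown pair {row['pair_id']!r}")
            outcomes.append(
                OutcomeRecord(
                    pair_id=str(row["pair_id"]),
                    event=str(row["event"]),
                    time=float(row["time_months"]),
                    status=str(row["status"]),
                )
            )
    return pairs, outcomes


def write_cohort(
    pairs: Sequence[DonorRecipientPair],
    pairs_path: str | Path,
    genotypes_path: str | Path,
    outcomes: Iterable[OutcomeRecord] = (),
    outcomes_path: str | Path | None = None,
) -> None:
    """Write a cohort back out in the same dialect ``read_cohort`` accepts."""
    individuals: dict[str, tuple[HLAGenotype, KIRGenotype]] = {}
    rows = []
    for p in pairs:
        individuals[p.donor_hla.individual_id] = (p.donor_hla, p.donor_kir)
        individuals[p.recipient_hla.individual_id] = (p.recipient_hla, p.recipient_kir)
        rows.append(
            {
                "pair_id": p.pair_id,
                "donor_id": p.donor_hla.individual_id,
                "recipient_id": p.recipient_hla.individual_id,
                "match_fashion": p.match_fashion,
            }
        )
    pd.DataFrame(rows).to_csv(pairs_path, index=False)

    geno_rows = []
    for ind, (hla, kir) in sorted(individuals.items()):
        row: dict[str, str] = {"individual_id": ind}
        for locus, (a1, a2) in hla.alleles.items():
            row[f"{locus}_1"], row[f"{locus}_2"] = a1.raw_name, a2.raw_name
        for gene in KIR_GENES:
            p = kir[gene]
            row[gene] = {"present": "1", "absent": "0", "unknown": ""}[p.value]
        for gene, col in (
            ("KIR3DL1", "KIR3DL1_alleles"),
            ("KIR3DS1", "KIR3DS1_alleles"),
            ("KIR2DL1", "KIR2DL1_alleles"),
        ):
            calls = kir.allele_calls(gene)
            if calls:
                row[col] = ";".join(calls)
        geno_rows.append(row)
    pd.DataFrame(geno_rows).to_csv(genotypes_path, index=False)

    if outcomes_path is not None:
        pd.DataFrame(
            [
                {
                    "pair_id": o.pair_id,
                    "event": o.event,
                    "time_months": o.time,
                    "status": o.status,
                }
                for o in outcomes
            ],
            columns=["pair_id", "event", "time_months", "status"],
        ).to_csv(outcomes_path, index=False)
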