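import numpy as np
import pytest

from nkalloreact.genotypes import (
    KIR_GENES,
    DonorRecipientPair,
    HLAAllele,
    HLAGenotype,
    KIRGenotype,
    Presence,
)
from nkalloreact.ligands import LigandProfile, load_default_tables


@pytest.fixture(scope="session")
def tables():
    return load_default_tables()


def make_hla(ind, a=("A*01:01", "A*02:01"), b=("B*07:02", "B*08:01"),
             c=("C*07:01", "C*07:02")):
    return HLAGenotype(
        individual_id=ind,
        alleles={
            "A": (HLAAllele.parse(a[0]), HLAAllele.parse(a[1])),
            "B": (HLAAllele.parse(b[0]), HLAAllele.parse(b[1])),
            "C": (HLAAllele.parse(c[0]), HLAAllele.parse(c[1])),
        },
    )


#: gene content of a common A/A-homozygous KIR genotype
AA_GENES = (
    "KIR3DL3", "KIR3DP1", "KIR2DL4", "KIR3DL2",
    "KIR2DL3", "KIR2DL1", "KIR2DP1", "KIR3DL1", "KIR2DS4",
)


def make_kir(ind, present=AA_GENES, unknown=(), alleles=None, **kwargs):
    presence = {}
    for g in KIR_GENES:
        if g in unknown:
            presence[g] = Presence.UNKNOWN
        elif g in present:
            presence[g] = Presence.PRESENT
        else:
            presence[g] = Presence.ABSENT
    return KIRGenotype(
        individual_id=ind, presence=presence, alleles=alleles or {}, **kwargs
    )


def make_pair(pair_id="P1", donor_hla=None, donor_kir=None,
              recipient_hla=None, recipient_kir=None,
              match_fashion="haploidentical"):
    return DonorRecipientPair(
        pair_id=pair_id,
        donor_hla=donor_hla or make_hla(f"{pair_id}-D"),
        donor_kir=donor_kir or make_kir(f"{pair_id}-D"),
        recipient_hla=recipient_hla or make_hla(f"{pair_id}-R"),
        recipient_kir=recipient_kir or make_kir(f"{pair_id}-R"),
        match_fashion=match_fashion,
    )


def make_profile(ind="x", c1=1, c2=1, bw4=1, bw6=1, bw4_80i=0,
                 a_bw4=False, c_bw6=False, a3a11=False, minus21="TT"):
    """LigandProfile stub for unit tests of model rules."""
    return LigandProfile(
        individual_id=ind, c1_count=c1, c2_count=c2,
        b_bw4_count=bw4, b_bw6_count=bw6,
        b_bw4_80i_count=bw4_80i, b_bw4_80t_count=bw4 - bw4_80i,
        a_bw4_present=a_bw4, c_bw6_present=c_bw6,
        a3a11_present=a3a11, minus21=minus21,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
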