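import itertools

import pytest

from nkalloreact import reference_cohort as ref
from nkalloreact.genotypes import Presence
from nkalloreact.models import (
    MODEL_IDS,
    CenTelGenotype,
    PairAnnotations,
    assign_cen_tel,
    classify_2dl1_245,
    classify_3dl1_expression,
    count_gene_content,
    diff_gene_content,
    kir_b_content,
    kir_b_content_from_marginals,
    score_all,
    score_education,
    score_educ_2ds1,
    score_ligand_ligand,
    score_receptor_ligand,
    synthesize_education,
    synthesize_ligand_ligand,
    synthesize_receptor_ligand,
)

from conftest import AA_GENES, make_hla, make_kir, make_pair, make_profile


def ann(donor_profile, recipient_profile):
    """PairAnnotations from two profile stubs (strict = full here)."""
    return PairAnnotations(
        donor=donor_profile, recipient=recipient_profile,
        donor_strict=donor_profile, recipient_strict=recipient_profile,
    )


class TestLigandLigand:
    def test_recipient_missing_donor_epitope_is_gvh(self):
        a = ann(make_profile(c1=1, c2=1), make_profile(c1=2, c2=0))
        assert score_ligand_ligand(a, "C1/C2").label == "GVH_mismatch"

    def test_identical_profiles_no_mismatch(self):
        p = make_profile()
        assert score_ligand_ligand(ann(p, p), "Bw4/Bw6").label == "no_mismatch"

    def test_recipient_only_epitope_is_hvg(self):
        d = make_profile(bw4=0, bw6=2)
        r = make_profile(bw4=1, bw6=1)
        assert score_ligand_ligand(ann(d, r), "Bw4/Bw6").label == "HVG_mismatch"

    def test_strict_variant_ignores_hla_a_bw4(self):
        d = make_profile(bw4=0, bw6=2, a_bw4=True)
        r = make_profile(bw4=0, bw6=2, a_bw4=False)
        full = PairAnnotations(
            donor=d, recipient=r,
            donor_strict=make_profile(bw4=0, bw6=2),
            recipient_strict=make_profile(bw4=0, bw6=2),
        )
        assert score_ligand_ligand(full, "Bw4/Bw6").label == "GVH_mismatch"
        assert score_ligand_ligand(full, "BwIPD").label == "no_mismatch"

    @pytest.mark.parametrize(
        "bw_label,c_label,expected",
        [
            ("no_mismatch", "no_mismatch", "none"),
            ("GVH_mismatch", "HVG_mismatch", "both"),
            ("GVH_mismatch", "no_mismatch", "GVH_any"),
            ("no_mismatch", "HVG_mismatch", "HVG_any"),
            ("GVH_mismatch", "GVH_mismatch", "GVH_any"),
        ],
    )
    def test_synthesis_labels(self, bw_label, c_label, expected):
        combos = {
            "no_mismatch": (make_profile(), make_profile()),
            "GVH_mismatch": (make_profile(c1=1, c2=1, bw4=1, bw6=1),
                             make_profile(c1=2, c2=0, bw4=0, bw6=2)),
            "HVG_mismatch": (make_profile(c1=2, c2=0, bw4=0, bw6=2),
                             make_profile(c1=1, c2=1, bw4=1, bw6=1)),
        }
        bw = score_ligand_ligand(ann(*combos[bw_label]), "Bw4/Bw6")
        cc = score_ligand_ligand(ann(*combos[c_label]), "C1/C2")
        assert bw.label == bw_label and cc.label == c_label
        assert synthesize_ligand_ligand(bw, cc).label == expected


class TestReceptorLigand:
    def test_missing_ligand_predicts_alloreactivity(self):
        pair = make_pair()
        a = ann(make_profile(), make_profile(c1=2, c2=0))
        assert score_receptor_ligand(pair, a, "2DL1").label == "yes"

    def test_no_receptor_no_mismatch(self):
        kir = make_kir("d", present=tuple(g for g in AA_GENES if g != "KIR3DL1"),
                       allow_missing_framework=True)
        pair = make_pair(donor_kir=kir)
        a = ann(make_profile(), make_profile(bw4=0, bw6=2))
        assert score_receptor_ligand(pair, a, "3DL1").label == "no"

    def test_ligand_present_no_mismatch(self):
        pair = make_pair()
        a = ann(make_profile(), make_profile(a3a11=True))
        assert score_receptor_ligand(pair, a, "3DL2").label == "no"

    def test_unknown_gene_presence_gives_missing(self):
        kir = make_kir("d", unknown=("KIR2DL1",))
        pair = make_pair(donor_kir=kir)
        a = ann(make_profile(), make_profile())
        assert score_receptor_ligand(pair, a, "2DL1").missing

    @pytest.mark.parametrize(
        "labels,quant,qual",
        [(("yes", "yes", "no", "no"), 2, "yes"),
         (("no", "no", "no", "no"), 0, "no"),
         (("yes", "yes", "yes", "yes"), 4, "yes")],
    )
    def test_synthesis_counts(self, labels, quant, qual):
        pair = make_pair()
        ligands = {"2DL1": dict(c2=0, c1=2), "3DL1": dict(bw4=0, bw6=2),
                   "3DL2": dict(a3a11=False), "2DL2/3": dict(c1=0, c2=2)}
        present = {"2DL1": dict(c2=1, c1=1), "3DL1": dict(bw4=1, bw6=1),
                   "3DL2": dict(a3a11=True), "2DL2/3": dict(c1=1, c2=1)}
        results = []
        for kir, lab in zip(("2DL1", "3DL1", "3DL2", "2DL2/3"), labels):
            kw = ligands[kir] if lab == "yes" else present[kir]
            results.append(
                score_receptor_ligand(pair, ann(make_profile(), make_profile(**kw)), kir)
            )
        q, ql = synthesize_receptor_ligand(results)
        assert float(q.code) == quant and ql.label == qual


class TestEducation:
    def test_licensed_donor_recipient_missing_ligand(self):
        pair = make_pair()
        a = ann(make_profile(c2=1), make_profile(c1=2, c2=0))
        assert score_education(pair, a, "2DL1").label == "alloreactivity"

    def test_unlicensed_donor_is_uneducated(self):
        pair = make_pair()
        a = ann(make_profile(c1=2, c2=0), make_profile(c1=2, c2=0))
        assert score_education(pair, a, "2DL1").label == "uneducated"

    def test_gene_absent_is_uneducated_with_flag(self):
        kir = make_kir("d", present=tuple(g for g in AA_GENES if g != "KIR3DL1"),
                       allow_missing_framework=True)
        pair = make_pair(donor_kir=kir)
        a = ann(make_profile(), make_profile())
        res = score_education(pair, a, "3DL1")
        assert res.label == "uneducated" and res.extras["gene_absent"] is True

    def test_education_receptor_ligand_truth_table(self):
        """Exhaustive equivalence over gene x donor-ligand x recipient-ligand:
        education=alloreactivity iff (receptor-ligand=yes AND donor has the
        self ligand AND the gene is present)."""
        axes = {"2DL1": "c2", "2DL2/3": "c1", "3DL1": "bw4", "3DL2": "a3a11"}
        locus_genes = {"2DL1": ("KIR2DL1",), "2DL2/3": ("KIR2DL2", "KIR2DL3"),
                       "3DL1": ("KIR3DL1",), "3DL2": ("KIR3DL2",)}
        for kir, axis in axes.items():
            genes = locus_genes[kir]
            for has_gene, d_lig, r_lig in itertools.product([0, 1], repeat=3):
                present = [g for g in AA_GENES if g not in genes] if not has_gene \
                    else list(set(AA_GENES) | set(genes))
                kirgt = make_kir("d", present=tuple(present),
                                 allow_missing_framework=True)
                pair = make_pair(donor_kir=kirgt)

                def prof(v):
                    if axis == "a3a11":
                        return make_profile(a3a11=bool(v))
                    if axis == "bw4":
                        return make_profile(bw4=v, bw6=2 - v)
                    return make_profile(**{axis: v, ("c1" if axis == "c2" else "c2"): 2 - v})

                a = ann(prof(d_lig), prof(r_lig))
                rl = score_receptor_ligand(pair, a, kir)
                ed = score_education(pair, a, kir)
                assert rl.label == ("yes" if has_gene and not r_lig else "no")
                if ed.label == "alloreactivity":
                    assert rl.label == "yes"
                if has_gene and d_lig and rl.label == "yes":
                    assert ed.label == "alloreactivity"

    def test_synthesis_counts_alloreactive_models(self):
        pair = make_pair()
        allo = score_education(pair, ann(make_profile(c2=1), make_profile(c1=2, c2=0)), "2DL1")
        none_ = score_education(pair, ann(make_profile(), make_profile()), "2DL2/3")
        assert float(synthesize_education([allo, none_, none_, none_]).code) == 1
        assert float(synthesize_education([none_] * 4).code) == 0


class TestEduc2DS1:
    def test_educated_donor_recognises_recipient_c2(self):
        kir = make_kir("d", present=AA_GENES + ("KIR2DS1",))
        pair = make_pair(donor_kir=kir)
        assert score_educ_2ds1(pair, ann(make_profile(c1=1, c2=1),
                                         make_profile(c1=1, c2=1))).label == "yes"

    def test_c1_negative_donor_stays_hyporesponsive(self):
        kir = make_kir("d", present=AA_GENES + ("KIR2DS1",))
        pair = make_pair(donor_kir=kir)
        assert score_educ_2ds1(pair, ann(make_profile(c1=0, c2=2),
                                         make_profile(c1=1, c2=1))).label == "no"

    def test_gene_absent_is_no(self):
        pair = make_pair()
        assert score_educ_2ds1(pair, ann(make_profile(), make_profile())).label == "no"


class TestCenTel:
    @pytest.mark.parametrize(
        "present,cen,tel",
        [
            # A/A homozygote
            (("KIR2DL3", "KIR3DL1"), 0, 0),
            # heterozygote in both regions
            (("KIR2DL3", "KIR2DS2", "KIR2DL2", "KIR3DL1", "KIR2DS1"), 1, 1),
            # Cen-B homozygote, Tel-A
            (("KIR2DL2", "KIR2DS2", "KIR3DL1"), 2, 0),
            # Tel-B homozygote
            (("KIR2DL3", "KIR3DS1", "KIR2DS1"), 0, 2),
        ],
    )
    def test_motif_counting(self, present, cen, tel):
        kir = make_kir("d", present=tuple(set(present) | {"KIR3DL3", "KIR3DL2",
                                                          "KIR2DL4", "KIR3DP1"}))
        ct = assign_cen_tel(kir)
        assert (ct.cen_b_count, ct.tel_b_count) == (cen, tel)
        assert ct.b_pattern == cen + tel
        assert not ct.ambiguous

    def test_no_region_marker_is_ambiguous(self):
        kir = make_kir("d", present=("KIR3DL3", "KIR3DL2", "KIR2DL4", "KIR3DP1",
                                     "KIR2DL3"))
        assert assign_cen_tel(kir).ambiguous  # telomeric markers all absent

    def test_b_pattern_identity_over_random_genotypes(self, rng):
        """cen+tel=b_pattern, counts in range, category partition; sampled
        over the full marker-presence space."""
        markers = ("KIR2DL2", "KIR2DL3", "KIR2DS2", "KIR3DL1", "KIR3DS1", "KIR2DS1")
        frame = ("KIR3DL3", "KIR3DL2", "KIR2DL4", "KIR3DP1")
        for _ in range(10_000):
            mask = rng.integers(0, 2, len(markers)).astype(bool)
            present = tuple(m for m, keep in zip(markers, mask) if keep) + frame
            kir = make_kir("d", present=present, allow_missing_framework=True)
            ct = assign_cen_tel(kir)
            assert ct.b_pattern == ct.cen_b_count + ct.tel_b_count
            assert 0 <= ct.cen_b_count <= 2 and 0 <= ct.tel_b_count <= 2
            if not ct.ambiguous:
                cat = kir_b_content(ct)
                assert (cat == "neutral") == (ct.b_pattern <= 1)
                assert (cat == "best") == (ct.cen_b_count == 2)


class TestKIRBContent:
    @pytest.mark.parametrize(
        "cen,tel,expected",
        [(2, 0, "best"), (0, 0, "neutral"), (1, 1, "better"),
         (2, 2, "best"), (0, 2, "better"), (1, 0, "neutral")],
    )
    def test_category_rule(self, cen, tel, expected):
        assert kir_b_content(CenTelGenotype(cen, tel)) == expected

    def test_rule_reproduces_published_marginal_counts(self):
        geno = kir_b_content_from_marginals(
            ref.GENOIDENTICAL_B_PATTERN, ref.GENOIDENTICAL_CEN_B
        )
        haplo = kir_b_content_from_marginals(
            ref.HAPLOIDENTICAL_B_PATTERN, ref.HAPLOIDENTICAL_CEN_B
        )
        assert geno == ref.GENOIDENTICAL_B_CONTENT
        assert haplo == ref.HAPLOIDENTICAL_B_CONTENT


class TestGeneContent:
    def test_all_activating_present(self):
        kir = make_kir("d", present=tuple(set(AA_GENES) | {
            "KIR2DS1", "KIR2DS2", "KIR2DS3", "KIR2DS5", "KIR3DS1", "KIR2DL2"}))
        akir, _ = count_gene_content(kir)
        assert akir == 6

    def test_aa_typical_genotype(self):
        akir, ikir = count_gene_content(make_kir("d"))
        assert (akir, ikir) == (1, 3)  # 2DS4; 2DL1+2DL3+3DL1, framework excluded

    def test_no_activating_genes(self):
        kir = make_kir("d", present=tuple(g for g in AA_GENES if g != "KIR2DS4"))
        assert count_gene_content(kir)[0] == 0

    @pytest.mark.parametrize(
        "d_extra,r_extra,akir_bin",
        [(("KIR2DS1", "KIR2DS2", "KIR2DS3", "KIR2DL2"), (), "D-R>=3"),
         ((), (), "R=D"),
         (("KIR2DS1",), (), "D-R=1-2"),
         ((), ("KIR2DS1",), "R>D")],
    )
    def test_difference_bins(self, d_extra, r_extra, akir_bin):
        pair = make_pair(
            donor_kir=make_kir("d", present=AA_GENES + d_extra),
            recipient_kir=make_kir("r", present=AA_GENES + r_extra),
        )
        assert diff_gene_content(pair)[0] == akir_bin


class TestAllelicPolymorphism:
    def test_highest_expression_retained(self):
        kir = make_kir("d", alleles={"KIR3DL1": ("3DL1*005", "3DL1*001")})
        assert classify_3dl1_expression(kir) == "high"

    def test_only_3ds1_groups_with_null(self):
        kir = make_kir(
            "d",
            present=tuple(g for g in AA_GENES if g != "KIR3DL1") + ("KIR3DS1",),
            alleles={"KIR3DS1": ("3DS1*013",)},
            allow_missing_framework=True,
        )
        assert classify_3dl1_expression(kir) == "null_or_absent"

    def test_null_homozygote(self):
        kir = make_kir("d", alleles={"KIR3DL1": ("3DL1*004", "3DL1*004")})
        assert classify_3dl1_expression(kir) == "null_or_absent"

    def test_2dl1_r245_detected(self):
        kir = make_kir("d", alleles={"KIR2DL1": ("2DL1*003",)})
        assert classify_2dl1_245(kir) == "at_least_one_R"

    def test_2dl1_absent_folds_into_no_r(self):
        kir = make_kir("d", present=tuple(g for g in AA_GENES if g != "KIR2DL1"))
        assert classify_2dl1_245(kir) == "no_R"

    def test_unlisted_2dl1_allele_is_ambiguous(self):
        kir = make_kir("d", alleles={"KIR2DL1": ("2DL1*099",)})
        assert classify_2dl1_245(kir) == "ambiguous"

    @pytest.mark.parametrize(
        "b,expected",
        [(("B*07:02", "B*08:01"), "MM"), (("B*27:05", "B*57:01"), "TT"),
         (("B*07:02", "B*07:02"), "MM"), (("B*07:02", "B*27:05"), "MT")],
    )
    def test_minus21_genotype(self, tables, b, expected):
        from nkalloreact.ligands import annotate

        assert annotate(make_hla("d", b=b), tables).minus21 == expected


class TestScoreAll:
    def test_row_covers_every_model_once(self):
        row = score_all(make_pair())
        assert tuple(row) == MODEL_IDS

    def test_self_pair_structural_zeroes(self):
        pair = make_pair(match_fashion="genoidentical")
        row = score_all(pair)
        for m in ("Bw4/Bw6", "BwIPD", "C1/C2"):
            assert row[m].label == "no_mismatch"
        assert row["L/L synthesis"].label == "none"
        assert float(row["Educ-DL synthesis"].code) == 0

    def test_aa_haplotype_donor(self):
        row = score_all(make_pair())
        assert float(row["B-pattern"].code) == 0
        assert row["KIR-B content"].label == "neutral"
        assert float(row["Donor aKIR"].code) == 1

    def test_unknown_gene_makes_dependent_cells_missing_only(self):
        kir = make_kir("d", unknown=("KIR2DS1",),
                       alleles={"KIR3DL1": ("3DL1*001",), "KIR2DL1": ("2DL1*003",)})
        pair = make_pair(donor_kir=kir)
        row = score_all(pair)
        assert row["Educ-2DS1"].missing
        assert row["Tel-B"].missing          # 2DS1 is a Tel-B marker
        assert row["Donor aKIR"].missing
        assert not row["2DL1-C2"].missing
        assert not row["Educ-2DL1"].missing
        assert not row["-21 B dimorphism"].missing

    def test_synthesis_cells_consistent_with_components(self):
        from nkalloreact.simulate import simulate_cohort

        for pair in simulate_cohort(10, 10, seed=9):
            row = score_all(pair)
            rl_sum = sum(row[m].label == "yes"
                         for m in ("2DL1-C2", "3DL1-Bw4", "3DL2-A3/11", "2DL2/3-C1"))
            assert float(row["R/L quantitative"].code) == rl_sum
            assert row["R/L qualitative"].label == ("yes" if rl_sum else "no")
            ed_sum = sum(row[m].label == "alloreactivity"
                         for m in ("Educ-2DL1", "Educ-2DL2/3", "Educ-3DL1", "Educ-3DL2"))
            assert float(row["Educ-DL synthesis"].code) == ed_sum
            assert float(row["B-pattern"].code) == (
                float(row["Cen-B"].code) + float(row["Tel-B"].code)
            )


def test_published_receptor_ligand_marginals_satisfy_count_identity():
    """The quantitative synthesis is the count of its four components, so the
    published per-model 'yes' totals must equal the count-weighted synthesis
    distribution in each cohort (50 genoidentical, 44 haploidentical)."""
    for yes, quant, total in (
        (ref.GENOIDENTICAL_RL_YES, ref.GENOIDENTICAL_RL_QUANT, 50),
        (ref.HAPLOIDENTICAL_RL_YES, ref.HAPLOIDENTICAL_RL_QUANT, 44),
    ):
        assert sum(yes.values()) == total
        assert sum(k * n for k, n in quant.items()) == total
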