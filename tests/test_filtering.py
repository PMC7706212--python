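"""Filter cascade, missense impact, tiering, PrDSM, INDELs, summaries."""

import numpy as np
import pytest

from endopanel.filtering import (
    FilterConfig,
    FilterReason,
    Impact,
    IndelDriverStatus,
    Tier,
    apply_standard_filters,
    assess_indel,
    predict_missense_impact,
    score_synonymous,
    summarize_sample,
    tier_sample,
    tier_variant,
)
from endopanel.model import (
    AnnotationDB,
    AnnotationRecord,
    DbcidEntry,
    DbcidStatus,
    ValidationError,
    VariantCall,
)

def vc(pos=100, *, effect="missense", var_class="SNV", ref="C", alt="A",
       caller_p=0.01, gene="PTEN"):
    return VariantCall(
        sample_id="S01", tissue="tumor", chrom="chr1", pos=pos, ref=ref, alt=alt,
        gene=gene, var_class=var_class, effect=effect, tumor_af=0.4,
        caller_p=caller_p, depth=500,
    )


def ann(pos=100, **kw):
    return AnnotationRecord(chrom="chr1", pos=pos, ref=kw.pop("ref", "C"),
                            alt=kw.pop("alt", "A"), gene=kw.pop("gene", "PTEN"), **kw)


class TestStandardFilters:
    @pytest.mark.parametrize(
        "caller_p,maf,expected_reasons",
        [
            (0.06, 0.0, [FilterReason.CALLER_P]),
            (0.01, 0.02, [FilterReason.MAF]),
            (0.06, 0.02, [FilterReason.CALLER_P, FilterReason.MAF]),
        ],
    )
    def test_removals_carry_reasons(self, caller_p, maf, expected_reasons):
        v = vc(caller_p=caller_p)
        db = AnnotationDB([ann(pop_maf=maf)])
        kept, syn, removed = apply_standard_filters([v], db)
        assert kept == [] and syn == []
        assert removed[0][1] == expected_reasons

    def test_boundary_values_retained(self):
        # strict inequalities: p exactly 0.05 and MAF exactly 1% survive
        v = vc(caller_p=0.05)
        db = AnnotationDB([ann(pop_maf=0.01)])
        kept, _, removed = apply_standard_filters([v], db)
        assert kept == [v] and removed == []

    def test_synonymous_routed_not_removed(self):
        v = vc(effect="synonymous")
        kept, syn, removed = apply_standard_filters([v], AnnotationDB())
        assert kept == [] and syn == [v] and removed == []


class TestMissenseImpact:
    @pytest.mark.parametrize(
        "sift,polyphen,expected",
        [
            (0.2, 0.3, Impact.BENIGN_CONCORDANT),
            (0.01, 0.9, Impact.DELETERIOUS_CONCORDANT),
            (0.2, 0.9, Impact.DISCORDANT),
            (0.01, 0.3, Impact.DISCORDANT),
            (0.05, 0.3, Impact.DISCORDANT),   # boundary SIFT is not benign
            (0.01, 0.5, Impact.DELETERIOUS_CONCORDANT),  # PolyPhen boundary is deleterious
            (None, 0.9, Impact.NOT_APPLICABLE),
            (0.2, None, Impact.NOT_APPLICABLE),
        ],
    )
    def test_truth_table(self, sift, polyphen, expected):
        assert predict_missense_impact(sift, polyphen) is expected

    def test_score_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            predict_missense_impact(1.2, 0.5)


class TestTierAssignment:
    def test_clinvar_pathogenic_dominates_even_with_benign_scores(self):
        t = tier_variant(vc(), ann(clinvar="pathogenic", sift=0.9, polyphen=0.1),
                         Impact.BENIGN_CONCORDANT)
        assert t.tier is Tier.PATHOGENIC

    def test_clinvar_benign_removes_from_candidate_stream(self):
        t = tier_variant(vc(), ann(clinvar="benign", sift=0.01, polyphen=0.9),
                         Impact.DELETERIOUS_CONCORDANT)
        assert t.tier is Tier.FILTERED_OUT
        assert t.clinvar_benign

    @pytest.mark.parametrize(
        "cosmic,expected",
        [(501, Tier.PATHOGENIC), (500, Tier.CANDIDATE), (499, Tier.CANDIDATE),
         (1, Tier.CANDIDATE), (0, Tier.VUS)],
    )
    def test_cosmic_count_boundaries(self, cosmic, expected):
        t = tier_variant(vc(), ann(cosmic_count=cosmic), Impact.NOT_APPLICABLE)
        assert t.tier is expected

    def test_deleterious_concordant_is_candidate(self):
        t = tier_variant(vc(), ann(sift=0.01, polyphen=0.9), Impact.DELETERIOUS_CONCORDANT)
        assert t.tier is Tier.CANDIDATE

    def test_benign_concordant_filtered_out(self):
        t = tier_variant(vc(), ann(sift=0.2, polyphen=0.3), Impact.BENIGN_CONCORDANT)
        assert t.tier is Tier.FILTERED_OUT
        assert FilterReason.BENIGN_PREDICTION in t.filter_reasons

    def test_no_evidence_is_vus(self):
        t = tier_variant(vc(), ann(), Impact.NOT_APPLICABLE)
        assert t.tier is Tier.VUS
        assert t.trace == ["no_annotative_evidence"]

    def test_discordant_without_deleterious_call_falls_through(self):
        # SIFT exactly at the cutoff with benign PolyPhen: discordant but
        # neither predictor calls deleterious
        t = tier_variant(vc(), ann(sift=0.05, polyphen=0.3), Impact.DISCORDANT)
        assert t.tier is Tier.VUS


class TestSynonymousScoring:
    def test_mean_and_threshold(self):
        res = score_synonymous(0.5, 0.5, 0.5)
        assert res.score == pytest.approx(0.5)
        assert res.deleterious is True

    def test_low_scores_not_deleterious(self):
        assert score_synonymous(0.1, 0.1, 0.1).deleterious is False

    def test_exact_threshold_not_deleterious(self):
        res = score_synonymous(0.308, 0.308, 0.308)
        assert res.score == pytest.approx(0.308)
        assert res.deleterious is False

    def test_missing_component_gives_unscored_result(self):
        res = score_synonymous(0.5, None, 0.5)
        assert not res.scored and res.score is None and res.deleterious is None


class TestIndelAssessment:
    def _db(self):
        return AnnotationDB(
            [
                ann(pos=950, ref="ATACT", alt="A", gene="PTEN",
                    dbcid=DbcidEntry(status=DbcidStatus.EXACT, gene="PTEN")),
                AnnotationRecord(
                    gene="PIK3R1", hgvs_c="dbcid:PIK3R1",
                    dbcid=DbcidEntry(status=DbcidStatus.OVERLAP, gene="PIK3R1",
                                     start=1690, end=1700),
                ),
            ]
        )

    def test_exact_catalog_entry(self):
        v = vc(pos=950, ref="ATACT", alt="A", var_class="DEL", effect="frameshift")
        assert assess_indel(v, self._db()) is IndelDriverStatus.DRIVER_EXACT

    def test_overlapping_locus_with_different_allele(self):
        v = vc(pos=1695, ref="TGG", alt="T", var_class="DEL", effect="frameshift",
               gene="PIK3R1")
        assert assess_indel(v, self._db()) is IndelDriverStatus.DRIVER_OVERLAP

    def test_novel_indel_is_none(self):
        v = vc(pos=5000, ref="TGG", alt="T", var_class="DEL", effect="frameshift")
        assert assess_indel(v, self._db()) is IndelDriverStatus.NONE

    def test_snv_input_rejected(self):
        with pytest.raises(ValidationError):
            assess_indel(vc(), self._db())


class TestSampleSummary:
    def test_counting_and_sum_invariants(self):
        retained = [vc(pos=100 + i) for i in range(10)]
        retained += [vc(pos=300 + i, ref="AT", alt="A", var_class="DEL",
                        effect="frameshift") for i in range(2)]
        db = AnnotationDB(
            [ann(pos=100, clinvar="pathogenic"),
             ann(pos=101, clinvar="pathogenic"),
             ann(pos=102, clinvar="pathogenic"),
             ann(pos=103, cosmic_count=10), ann(pos=104, cosmic_count=10),
             ann(pos=105, cosmic_count=10), ann(pos=106, cosmic_count=10)]
        )
        tiered, _, _ = tier_sample(retained, db)
        s = summarize_sample("S01", retained, tiered)
        assert s.n_unfiltered == 12
        assert s.n_unfiltered_snv == 10
        assert s.n_unfiltered_indel == 2
        assert sum(s.spectrum.values()) == 10
        assert s.n_pathogenic == 3
        assert s.n_candidate == 4
        assert s.n_path_plus_cand == 7
        assert s.n_filtered_snv >= s.n_pathogenic + s.n_candidate - s.n_filtered_indel

    def test_candidate_msh2_hit_sets_gene_flag(self):
        v = vc(gene="MSH2")
        db = AnnotationDB([ann(gene="MSH2", sift=0.01, polyphen=0.95)])
        tiered, _, _ = tier_sample([v], db)
        s = summarize_sample("S01", [v], tiered)
        assert s.gene_hits["MSH2"] is True
        assert not any(s.gene_hits[g] for g in s.gene_hits if g != "MSH2")


class TestRulePartitionProperties:
    def test_every_variant_has_exactly_one_fate(self):
        rng = np.random.default_rng(3)
        variants, db = random_fixture(rng, n=40)
        kept, syn, removed = apply_standard_filters(variants, db)
        assert len(kept) + len(syn) + len(removed) == len(variants)
        tiered, syn_scored, removed2 = tier_sample(variants, db)
        tiers = [t.tier for t in tiered]
        assert all(t in (Tier.PATHOGENIC, Tier.CANDIDATE, Tier.VUS, Tier.FILTERED_OUT)
                   for t in tiers)
        assert len(tiered) + len(syn_scored) + len(removed2) == len(variants)

    def test_threshold_monotonicity(self):
        """Raising the MAF cutoff never shrinks the filtered set; raising
        the COSMIC pathogenic threshold never grows the pathogenic set."""
        rng = np.random.default_rng(4)
        variants, db = random_fixture(rng, n=60)
        for lo, hi in [(0.005, 0.01), (0.01, 0.05), (0.05, 0.2)]:
            kept_lo, _, _ = apply_standard_filters(variants, db, FilterConfig(maf_max=lo))
            kept_hi, _, _ = apply_standard_filters(variants, db, FilterConfig(maf_max=hi))
            assert {v.key for v in kept_lo} <= {v.key for v in kept_hi}
        for lo, hi in [(100, 500), (500, 2000)]:
            path_lo = _n_pathogenic(variants, db, FilterConfig(cosmic_pathogenic_gt=lo))
            path_hi = _n_pathogenic(variants, db, FilterConfig(cosmic_pathogenic_gt=hi))
            assert path_hi <= path_lo

    def test_matches_flat_oracle_on_random_fixtures(self):
        from fixtures import random_tier_fixture, tiering_mismatches

        rng = np.random.default_rng(5)
        for _ in range(30):
            variants, db = random_tier_fixture(rng, n=int(rng.integers(1, 50)))
            assert tiering_mismatches(variants, db) == 0

    def test_planted_drivers_all_tier_pathogenic_or_candidate(self, analysed):
        cohort = analysed["cohort"]
        for pair in cohort.pairs:
            truth = cohort.truth.samples[pair.sample_id]
            tiered = {t.variant.key: t for t in analysed["artifacts"][pair.sample_id]["tiered"]}
            for event, key in truth.planted_drivers.items():
                t = tiered.get(key)
                assert t is not None, (pair.sample_id, event)
                assert t.tier in (Tier.PATHOGENIC, Tier.CANDIDATE)


def _n_pathogenic(variants, db, cfg):
    tiered, _, _ = tier_sample(variants, db, cfg)
    return sum(1 for t in tiered if t.tier is Tier.PATHOGENIC)


def random_fixture(rng, n=30):
    from fixtures import random_tier_fixture

    return random_tier_fixture(rng, n)
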