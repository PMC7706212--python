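"""Spectra, quartiles, group assignment, hypermutation, POLE, pathways."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from endopanel.classify import (
    ClassifierConfig,
    PathwayPattern,
    PoleStatus,
    ResolvedThresholds,
    assign_cohort,
    assign_group,
    detect_hypermutated,
    nearest_rank_quantile,
    pathway_pattern,
    pole_hotspot_assessment,
    quartile_thresholds,
    substitution_spectrum,
)
from endopanel.filtering import SampleSummary
from endopanel.model import AnnotationDB, ValidationError, VariantCall
from endopanel.simulate import (
    DRIVER_CATALOG,
    POLE_BENIGN_CATALOG,
    POLE_PASSENGER_CATALOG,
    _combined_default_panel,
    _catalog_record,
)

from oracles import nearest_rank_quantile_oracle, oracle_group


def snv(ref, alt, pos=100):
    return VariantCall(
        sample_id="S01", tissue="tumor", chrom="chr1", pos=pos, ref=ref, alt=alt,
        gene="PTEN", var_class="SNV", effect="missense", tumor_af=0.3, depth=500,
    )


def summary(sid="S01", burden=60, ca=5, cg=2, snvs=None, hits=(), hyper=False):
    n_snv = snvs if snvs is not None else burden
    rest = n_snv - ca - cg
    spectrum = {"C>A": ca, "C>G": cg, "C>T": max(rest, 0), "T>A": 0, "T>C": 0, "T>G": 0}
    gene_hits = {g: g in hits for g in
                 ("PTEN", "PIK3CA", "PIK3R1", "PIK3R3", "TP53",
                  "MLH1", "MSH2", "MSH6", "PMS2")}
    return SampleSummary(
        sample_id=sid, n_unfiltered=burden, n_unfiltered_snv=n_snv,
        spectrum=spectrum, gene_hits=gene_hits, hypermutated=hyper,
    )


FIXED = ResolvedThresholds(570.0, 9.0, 1.0, "fixed")


class TestSpectrum:
    def test_complement_collapse(self):
        counts = substitution_spectrum([snv("C", "A", 1), snv("C", "A", 2), snv("G", "T", 3)])
        assert counts["C>A"] == 3

    def test_empty_input_all_zero(self):
        counts = substitution_spectrum([])
        assert set(counts.values()) == {0}
        assert len(counts) == 6

    def test_conservation_of_total(self):
        rng = np.random.default_rng(0)
        bases = "ACGT"
        calls = []
        for i in range(1000):
            ref, alt = rng.choice(list(bases), 2, replace=False)
            calls.append(snv(str(ref), str(alt), pos=i + 1))
        assert sum(substitution_spectrum(calls).values()) == 1000

    def test_collapse_involution(self):
        """Collapsing an already-collapsed spectrum changes nothing."""
        rng = np.random.default_rng(1)
        calls = [snv(*rng.choice(list("ACGT"), 2, replace=False), pos=i + 1)
                 for i in range(200)]
        once = substitution_spectrum(calls, collapse=True)
        pyrimidine_only = [
            snv(*cls.split(">"), pos=i + 1)
            for i, cls in enumerate(
                c for c, n in once.items() for _ in range(n)
            )
        ]
        again = substitution_spectrum(pyrimidine_only, collapse=True)
        assert again == once

    def test_non_snv_rejected(self):
        bad = VariantCall(sample_id="S", tissue="tumor", chrom="chr1", pos=1,
                          ref="AT", alt="A", gene="G", var_class="DEL",
                          effect="frameshift")
        with pytest.raises(ValidationError):
            substitution_spectrum([bad])

    def test_no_collapse_keeps_raw_classes(self):
        counts = substitution_spectrum([snv("G", "T")], collapse=False)
        assert counts["G>T"] == 1
        assert counts["C>A"] == 0


class TestQuartiles:
    def test_nearest_rank_q3_of_1_to_8(self):
        assert nearest_rank_quantile(list(range(1, 9)), 0.75) == 6

    def test_degenerate_distribution(self):
        assert nearest_rank_quantile([7, 7, 7, 7], 0.25) == 7
        assert nearest_rank_quantile([7, 7, 7, 7], 0.75) == 7

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        values=st.lists(st.integers(0, 1000), min_size=1, max_size=40),
        p=st.sampled_from([0.25, 0.5, 0.75]),
    )
    def test_matches_sort_based_oracle(self, values, p):
        assert nearest_rank_quantile(values, p) == nearest_rank_quantile_oracle(values, p)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(values=st.lists(st.integers(0, 100), min_size=4, max_size=20))
    def test_permutation_invariance(self, values):
        rng = np.random.default_rng(0)
        shuffled = list(values)
        rng.shuffle(shuffled)
        assert nearest_rank_quantile(values, 0.75) == nearest_rank_quantile(shuffled, 0.75)

    def test_cohort_thresholds(self):
        summaries = [summary(f"S{i}", burden=b, ca=c, cg=g)
                     for i, (b, c, g) in enumerate([(40, 4, 1), (60, 6, 2),
                                                    (80, 8, 3), (100, 10, 4)])]
        t = quartile_thresholds(summaries, ClassifierConfig(mode="quartile"))
        assert t.burden_gt == 80
        assert t.ca_gt == 8
        assert t.cg_lt == 1

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValidationError):
            quartile_thresholds([summary()], ClassifierConfig(mode="quartile"))


class TestGroupAssignment:
    def test_ultramutated_profile_is_group_1(self):
        a = assign_group(summary(burden=600, ca=12, cg=0), FIXED)
        assert a.group == 1
        assert a.fired_rules

    def test_mmr_precedes_tp53(self):
        a = assign_group(summary(burden=80, hits=("MSH2", "TP53")), FIXED)
        assert a.group == 2

    def test_tp53_only_is_group_3_and_pi3k_only_group_4(self):
        assert assign_group(summary(hits=("TP53",)), FIXED).group == 3
        assert assign_group(summary(hits=("PTEN",)), FIXED).group == 4

    def test_missing_spectrum_rejected(self):
        s = summary()
        s.spectrum = {}
        with pytest.raises(ValidationError):
            assign_group(s, FIXED)

    def test_precedence_override(self):
        s = summary(burden=600, ca=12, cg=0, hits=("MSH2",))
        assert assign_group(s, FIXED).group == 1
        cfg = ClassifierConfig(precedence=(2, 1, 3, 4))
        assert assign_group(s, FIXED, cfg).group == 2

    def test_matches_flat_oracle(self):
        rng = np.random.default_rng(9)
        genes = ("PTEN", "TP53", "MLH1", "MSH2", "MSH6", "PMS2")
        for _ in range(300):
            burden = int(rng.integers(0, 800))
            ca = int(rng.integers(0, 30))
            cg = int(rng.integers(0, 5))
            hits = tuple(g for g in genes if rng.random() < 0.3)
            s = summary(burden=max(burden, ca + cg), ca=ca, cg=cg, hits=hits)
            got = assign_group(s, FIXED).group
            mmr = any(g in hits for g in ("MLH1", "MSH2", "MSH6", "PMS2"))
            expected = oracle_group(s.n_unfiltered, ca, cg, mmr, "TP53" in hits)
            assert got == expected

    def test_cohort_order_invariance_in_quartile_mode(self):
        rng = np.random.default_rng(2)
        summaries = [summary(f"S{i:02d}", burden=int(rng.integers(30, 400)),
                             ca=int(rng.integers(0, 40)), cg=int(rng.integers(0, 6)))
                     for i in range(20)]
        cfg = ClassifierConfig(mode="quartile")
        forward = {a.sample_id: a.group for a in assign_cohort(summaries, cfg)}
        backward = {a.sample_id: a.group for a in assign_cohort(summaries[::-1], cfg)}
        assert forward == backward


class TestHypermutationDetection:
    def test_planted_cohort_recovered_exactly(self, analysed):
        truth = analysed["cohort"].truth
        assert analysed["hyper"] == truth.hypermutated_ids()

    def test_artifact_heavy_samples_never_flagged(self, analysed):
        truth = analysed["cohort"].truth
        assert not (analysed["hyper"] & truth.of_profile("artifact_heavy"))

    def test_uniform_cohort_has_no_flags(self):
        rng = np.random.default_rng(0)
        summaries = [summary(f"S{i}", burden=int(rng.poisson(65))) for i in range(47)]
        assert detect_hypermutated(summaries) == set()

    def test_small_cohort_rejected(self):
        with pytest.raises(ValidationError):
            detect_hypermutated([summary()] * 4)

    def test_fixed_cutoff_mode(self):
        summaries = [summary("A", snvs=50, burden=50), summary("B", snvs=200, burden=200),
                     summary("C", snvs=60, burden=60), summary("D", snvs=61, burden=61),
                     summary("E", snvs=62, burden=62)]
        cfg = ClassifierConfig(hypermutation_mode="fixed")
        assert detect_hypermutated(summaries, cfg) == {"B"}


def pole_call(spec, caller_p=0.01, region="exonic", effect=None):
    panel = _combined_default_panel()
    chrom, start, _ = panel.gene_regions["POLE"]
    return VariantCall(
        sample_id="S01", tissue="tumor", chrom=chrom, pos=start + spec.offset,
        ref=spec.ref, alt=spec.alt, gene="POLE", var_class="SNV",
        effect=effect or spec.effect, hgvs_c=spec.hgvs_c, hgvs_p=spec.hgvs_p,
        tumor_af=0.4, depth=500, caller_p=caller_p, region=region,
        domain=spec.domain,
    )


@pytest.fixture(scope="module")
def pole_db():
    panel = _combined_default_panel()
    records = [_catalog_record(s, panel) for s in DRIVER_CATALOG.values()]
    records += [_catalog_record(s, panel)
                for s in POLE_PASSENGER_CATALOG + POLE_BENIGN_CATALOG]
    return AnnotationDB(records)


class TestPoleAssessment:
    def test_hotspot_dominates(self, pole_db):
        calls = [pole_call(DRIVER_CATALOG["POLE_P286R"]),
                 pole_call(POLE_BENIGN_CATALOG[0])]
        res = pole_hotspot_assessment("S01", calls, pole_db)
        assert res.status is PoleStatus.HOTSPOT

    def test_benign_only(self, pole_db):
        res = pole_hotspot_assessment("S01", [pole_call(POLE_BENIGN_CATALOG[0])], pole_db)
        assert res.status is PoleStatus.BENIGN_ONLY

    def test_stoploss_outside_domain(self, pole_db):
        calls = [pole_call(DRIVER_CATALOG["POLE_X2287W"]),
                 pole_call(POLE_BENIGN_CATALOG[1])]
        res = pole_hotspot_assessment("S01", calls, pole_db)
        assert res.status is PoleStatus.UNKNOWN_OUTSIDE_DOMAIN

    def test_unknown_in_domain_outranks_outside(self, pole_db):
        calls = [pole_call(DRIVER_CATALOG["POLE_X2287W"]),
                 pole_call(POLE_PASSENGER_CATALOG[2])]  # Asp1211Gly, in domain
        res = pole_hotspot_assessment("S01", calls, pole_db)
        assert res.status is PoleStatus.UNKNOWN_IN_DOMAIN

    def test_p_value_filter_is_inclusive_at_005(self, pole_db):
        ok = pole_call(DRIVER_CATALOG["POLE_P286R"], caller_p=0.05)
        res = pole_hotspot_assessment("S01", [ok], pole_db)
        assert res.status is PoleStatus.HOTSPOT
        high = pole_call(DRIVER_CATALOG["POLE_P286R"], caller_p=0.051)
        assert pole_hotspot_assessment("S01", [high], pole_db).status is PoleStatus.NONE

    def test_non_exonic_and_synonymous_excluded(self, pole_db):
        non_exonic = pole_call(DRIVER_CATALOG["POLE_P286R"], region="non_exonic")
        syn = pole_call(POLE_BENIGN_CATALOG[0], effect="synonymous")
        res = pole_hotspot_assessment("S01", [non_exonic, syn], pole_db)
        assert res.status is PoleStatus.NONE
        assert res.examined == []


class TestPathwayPattern:
    @pytest.mark.parametrize(
        "hits,expected",
        [
            (("PTEN",), PathwayPattern.PI3K_ONLY),
            (("TP53",), PathwayPattern.TP53_ONLY),
            (("PIK3CA", "TP53"), PathwayPattern.BOTH),
            ((), PathwayPattern.NEITHER),
        ],
    )
    def test_four_way_label(self, hits, expected):
        assert pathway_pattern(summary(hits=hits)) is expected
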