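"""Domain-type validation and round-trip guarantees of the TSV formats."""

import pytest
from hypothesis import given, settings, strategies as st

from endopanel.io import (
    load_annotation_db,
    read_clinical_table,
    read_variant_table,
    write_annotation_db,
    write_clinical_table,
    write_variant_table,
)
from endopanel.model import (
    AnnotationDB,
    AnnotationRecord,
    DbcidEntry,
    DbcidStatus,
    SampleVariantSet,
    ValidationError,
    VariantCall,
)
from endopanel.panel import default_panel, read_panel_bed


def make_call(**kw):
    base = dict(
        sample_id="S01", tissue="tumor", chrom="chr10", pos=1000,
        ref="C", alt="A", gene="PTEN", var_class="SNV", effect="missense",
        tumor_af=0.4, depth=500, caller_p=0.01,
    )
    base.update(kw)
    return VariantCall(**base)


class TestVariantCallInvariants:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(pos=0),
            dict(ref="C", alt="C"),
            dict(tumor_af=1.3),
            dict(caller_p=-0.1),
            dict(normal_af=2.0),
            dict(depth=-1),
            dict(ref="CA", alt="C", var_class="SNV"),      # not a 1-bp change
            dict(ref="C", alt="A", var_class="DEL"),        # 1-bp change is an SNV
            dict(ref="C", alt="Z"),
        ],
    )
    def test_invalid_calls_rejected(self, kw):
        with pytest.raises(ValidationError):
            make_call(**kw)

    def test_duplicate_key_in_set_rejected(self):
        v = make_call()
        with pytest.raises(ValidationError, match="duplicate"):
            SampleVariantSet("S01", "tumor", "P", [v, make_call()])

    def test_tissue_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="tissue"):
            SampleVariantSet("S01", "normal", "P", [make_call()])


class TestVariantTableIO:
    def test_three_row_round_trip(self, tmp_path):
        calls = [
            make_call(),
            make_call(pos=2000, ref="T", alt="G", effect="synonymous"),
            # an INDEL with a multi-base ref must survive exactly
            make_call(pos=3000, ref="ATACT", alt="A", var_class="DEL",
                      effect="frameshift", hgvs_c="c.950_953delTACT"),
        ]
        varset = SampleVariantSet("S01", "tumor", "P", calls)
        path = tmp_path / "v.tsv"
        write_variant_table(varset, path)
        back = read_variant_table(path, "tumor")
        assert len(back) == 3
        assert back.variants == calls

    def test_header_only_file_is_empty_valid_set(self, tmp_path):
        path = tmp_path / "v.tsv"
        write_variant_table(SampleVariantSet("S01", "tumor", "P", []), path)
        back = read_variant_table(path, "tumor")
        assert len(back) == 0

    def test_out_of_range_fraction_names_line(self, tmp_path):
        path = tmp_path / "v.tsv"
        write_variant_table(SampleVariantSet("S01", "tumor", "P", [make_call()]), path)
        text = path.read_text().replace("0.4", "1.3")
        path.write_text(text)
        with pytest.raises(ValidationError, match=r":2:"):
            read_variant_table(path, "tumor")

    def test_missing_header_column_rejected(self, tmp_path):
        path = tmp_path / "v.tsv"
        path.write_text("sample_id\tchrom\tpos\n")
        with pytest.raises(ValidationError, match="missing columns"):
            read_variant_table(path, "tumor")


@st.composite
def variant_sets(draw):
    n = draw(st.integers(min_value=0, max_value=12))
    calls = []
    seen = set()
    for i in range(n):
        pos = draw(st.integers(min_value=1, max_value=10_000))
        ref = draw(st.sampled_from(["A", "C", "G", "T", "AT", "ACG"]))
        alt = draw(st.sampled_from(["A", "C", "G", "T", "ATTA"]))
        if ref == alt or (pos, ref, alt) in seen:
            continue
        seen.add((pos, ref, alt))
        if len(ref) == 1 and len(alt) == 1:
            vc = "SNV"
        elif len(ref) > len(alt):
            vc = "DEL"
        elif len(alt) > len(ref):
            vc = "INS"
        else:
            vc = "MNV"
        calls.append(
            make_call(
                pos=pos, ref=ref, alt=alt, var_class=vc,
                effect=draw(st.sampled_from(["missense", "synonymous", "frameshift", "other"])),
                tumor_af=draw(st.floats(0, 1, allow_nan=False)),
                normal_af=draw(st.floats(0, 1, allow_nan=False)),
                normal_af_observed=draw(st.booleans()),
                caller_p=draw(st.floats(0, 1, allow_nan=False)),
                quality=draw(st.sampled_from(["pass", "low_quality", "sequencing_error"])),
            )
        )
    return SampleVariantSet("S01", "tumor", "P", calls)


@settings(max_examples=50, derandomize=True, deadline=None)
@given(varset=variant_sets())
def test_variant_table_round_trip_property(tmp_path_factory, varset):
    """read(write(x)) reproduces any valid variant set field-for-field."""
    path = tmp_path_factory.mktemp("rt") / "v.tsv"
    write_variant_table(varset, path)
    back = read_variant_table(path, "tumor")
    assert back.variants == varset.variants


class TestAnnotationDB:
    def _db(self):
        return AnnotationDB(
            [
                AnnotationRecord(
                    gene="PTEN", hgvs_c="c.950_953delTACT",
                    chrom="chr10", pos=950, ref="ATACT", alt="A",
                    clinvar="pathogenic",
                    dbcid=DbcidEntry(status=DbcidStatus.EXACT, gene="PTEN"),
                ),
                AnnotationRecord(gene="KRAS", hgvs_c="c.35G>A", cosmic_count=501),
            ]
        )

    def test_exact_dbcid_entry_lookup(self):
        db = self._db()
        v = make_call(chrom="chr10", pos=950, ref="ATACT", alt="A",
                      var_class="DEL", effect="frameshift", gene="PTEN",
                      hgvs_c="c.950_953delTACT")
        assert db.lookup(v).dbcid.status is DbcidStatus.EXACT

    def test_hgvs_fallback_when_coordinates_differ(self):
        db = self._db()
        v = make_call(gene="KRAS", hgvs_c="c.35G>A", chrom="chr12", pos=25398284,
                      ref="G", alt="A")
        assert db.lookup(v).cosmic_count == 501

    def test_unknown_variant_gets_absent_sentinel(self):
        rec = self._db().lookup(make_call(pos=99999))
        assert rec.is_absent

    def test_round_trip_tsv_and_json(self, tmp_path):
        db = self._db()
        for name in ("db.tsv", "db.json"):
            path = tmp_path / name
            write_annotation_db(db, path)
            back = load_annotation_db(path)
            assert len(back) == 2
            assert back.records[1].cosmic_count == 501
            assert back.records[0].dbcid.status is DbcidStatus.EXACT

    def test_score_out_of_range_is_hard_error(self, tmp_path):
        path = tmp_path / "db.json"
        path.write_text('[{"gene": "PTEN", "hgvs_c": "c.1A>G", "sift": 1.7}]')
        with pytest.raises(ValidationError):
            load_annotation_db(path)


class TestClinicalTable:
    def test_cohort_round_trip_and_histology_counts(self, tmp_path, default_cohort):
        path = tmp_path / "clin.tsv"
        write_clinical_table(default_cohort.clinical, path)
        back = read_clinical_table(path)
        assert len(back) == 47
        counts = {"EAC": 0, "USC": 0}
        for r in back:
            counts[r.histology.value] += 1
        assert counts == {"EAC": 34, "USC": 13}
        assert back == default_cohort.clinical

    def test_unknown_histology_token_rejected(self, tmp_path, default_cohort):
        path = tmp_path / "clin.tsv"
        write_clinical_table(default_cohort.clinical[:1], path)
        path.write_text(path.read_text().replace("EAC", "carcinosarcoma"))
        with pytest.raises(ValidationError):
            read_clinical_table(path)

    def test_stage_iv_with_recurrence_accepted(self, tmp_path, default_cohort):
        import dataclasses

        rec = dataclasses.replace(
            default_cohort.clinical[0], stage="IV", recurrence=True
        )
        path = tmp_path / "clin.tsv"
        write_clinical_table([rec], path)
        assert read_clinical_table(path)[0].stage.value == "IV"


class TestPanel:
    def test_bed_converts_to_one_based_closed(self, tmp_path):
        bed = tmp_path / "p.bed"
        bed.write_text("chr1\t999\t2000\tPTEN\nchr2\t0\t100\tTP53\n")
        panel = read_panel_bed(bed, "P")
        assert ("chr1", 1000, 2000) in panel.target_regions
        assert ("chr2", 1, 100) in panel.target_regions
        assert panel.gene_symbols == {"PTEN", "TP53"}

    def test_empty_interval_rejected(self, tmp_path):
        bed = tmp_path / "p.bed"
        bed.write_text("chr1\t100\t100\tPTEN\n")
        with pytest.raises(ValidationError):
            read_panel_bed(bed, "P")

    def test_default_panel_has_156_genes_and_valid_regions(self):
        panel = default_panel()
        assert len(panel.gene_symbols) == 156
        assert all(end >= start >= 1 for _, start, end in panel.target_regions)

    def test_simulated_variants_lie_on_the_panel(self, default_cohort):
        from endopanel.simulate import _combined_default_panel

        panel = _combined_default_panel()
        for pair in default_cohort.pairs[:5]:
            for v in pair.tumor:
                assert v.gene in panel.gene_symbols
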