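"""Prioritization order, filtering, review bookkeeping and lossless
export/import round trips."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trioscope.model import (
    AnnotationBundle,
    ClinVarAssertion,
    ClinVarSignificance,
    Impact,
    InheritanceCall,
    InheritanceMode,
    PopulationRecord,
    ReviewSignificance,
    VariantKey,
    Verdict,
)
from trioscope.rank_review import (
    AnalysisRecord,
    ReviewStore,
    export_analysis,
    filter_records,
    import_analysis,
    rank,
    sort_key,
)


def record(
    pos=100,
    clinvar=None,
    mode=None,
    impact=None,
    af="absent",
    contig="chr1",
    ref="A",
    alt="G",
):
    bundle = AnnotationBundle(
        consequence="missense_variant" if impact is not None else "",
        impact=impact,
        clinvar=ClinVarAssertion(clinvar) if clinvar is not None else None,
        population=(
            None if af == "absent" else PopulationRecord(allele_frequency=af)
        ),
    )
    inheritance = InheritanceCall(mode) if mode is not None else None
    return AnalysisRecord(
        key=VariantKey(contig, pos, ref, alt), bundle=bundle, inheritance=inheritance
    )


class TestSortKey:
    def test_pathogenic_denovo_before_uncertain_dominant(self):
        a = record(clinvar=ClinVarSignificance.PATHOGENIC, mode=InheritanceMode.DENOVO)
        b = record(
            clinvar=ClinVarSignificance.UNCERTAIN,
            mode=InheritanceMode.AUTOSOMAL_DOMINANT,
        )
        assert sort_key(a) < sort_key(b)

    def test_coordinate_tie_break(self):
        a = record(pos=100)
        b = record(pos=200)
        assert sort_key(a) < sort_key(b)

    def test_reviewed_significant_dominates_unreviewed_pathogenic(self):
        benign = record(clinvar=ClinVarSignificance.BENIGN)
        pathogenic = record(pos=200, clinvar=ClinVarSignificance.PATHOGENIC)
        reviews = ReviewStore()
        rev = reviews.set_review(benign.key, "Significant", "curated")
        assert sort_key(benign, rev) < sort_key(pathogenic, None)

    def test_not_observed_ranks_rarest(self):
        absent = record(af="absent")
        rare = record(pos=200, af=1e-6)
        assert sort_key(absent) < sort_key(rare)

    def test_rank_orders_full_list(self):
        """ClinVar tier dominates mode: pathogenic first, then uncertain,
        then a no-assertion de novo (assertion tiers 0, 3, 4)."""
        records = [
            record(pos=300, clinvar=ClinVarSignificance.UNCERTAIN),
            record(pos=200, clinvar=ClinVarSignificance.PATHOGENIC),
            record(pos=100, mode=InheritanceMode.DENOVO),
        ]
        ranked = rank(records)
        assert [r.key.pos for r in ranked] == [200, 300, 100]

    @settings(max_examples=200, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(
                st.sampled_from([None] + list(ClinVarSignificance)),
                st.sampled_from([None] + list(InheritanceMode)),
                st.sampled_from([None] + list(Impact)),
                st.one_of(st.none(), st.floats(min_value=0, max_value=1)),
                st.integers(min_value=1, max_value=500),
            ),
            min_size=2,
            max_size=8,
        )
    )
    def test_total_order(self, data):
        """sort_key induces a total order: comparable tuples, transitive,
        and antisymmetric up to key equality."""
        records = [
            record(
                pos=pos,
                clinvar=clin,
                mode=mode,
                impact=impact,
                af="absent" if af is None else af,
            )
            for clin, mode, impact, af, pos in data
        ]
        keys = [sort_key(r) for r in records]
        ranked = sorted(keys)
        for a, b, c in zip(ranked, ranked[1:], ranked[2:]):
            assert a <= b <= c and a <= c
        for k1, k2 in zip(keys, keys[1:]):
            assert (k1 <= k2) or (k2 <= k1)


class TestFilter:
    def test_af_criterion_counts_removals(self):
        records = [record(af=0.12), record(pos=200, af=0.001), record(pos=300)]
        kept, removed = filter_records(records, max_af=0.01)
        assert [r.key.pos for r in kept] == [200, 300]
        assert removed["af"] == 1

    def test_empty_criteria_identity(self):
        records = [record(), record(pos=200)]
        kept, removed = filter_records(records)
        assert kept == records
        assert sum(removed.values()) == 0

    def test_min_impact(self):
        records = [
            record(impact=Impact.HIGH),
            record(pos=200, impact=Impact.LOW),
            record(pos=300, impact=Impact.MODERATE),
        ]
        kept, _ = filter_records(records, min_impact="MODERATE")
        assert [r.key.pos for r in kept] == [100, 300]

    def test_mode_and_clinvar_criteria(self):
        records = [
            record(mode=InheritanceMode.DENOVO),
            record(pos=200, mode=InheritanceMode.UNKNOWN),
            record(pos=300, mode=InheritanceMode.DENOVO,
                   clinvar=ClinVarSignificance.PATHOGENIC),
        ]
        kept, _ = filter_records(records, modes=["denovo"], clinvar_only=True)
        assert [r.key.pos for r in kept] == [300]


class TestReviewStore:
    def test_set_then_get_round_trip(self):
        store = ReviewStore()
        key = VariantKey("chr1", 100, "A", "G")
        store.set_review(key, "Significant", "note text")
        rev = store.get_review(key)
        assert rev.significance == ReviewSignificance.SIGNIFICANT
        assert rev.note == "note text"

    def test_latest_wins_history_retained(self):
        store = ReviewStore()
        key = VariantKey("chr1", 100, "A", "G")
        store.set_review(key, "Poor quality", "first")
        store.set_review(key, "Significant", "second")
        assert store.get_review(key).note == "second"
        assert len(store.history(key)) == 2

    def test_unknown_significance_lists_allowed(self):
        store = ReviewStore()
        key = VariantKey("chr1", 100, "A", "G")
        with pytest.raises(ValueError, match="Significant"):
            store.set_review(key, "Probably fine", "")


def _random_record(rng: random.Random, pos: int) -> AnalysisRecord:
    clin = rng.choice([None] + list(ClinVarSignificance))
    pop = rng.choice(
        [
            None,
            PopulationRecord(allele_frequency=round(rng.random(), 6),
                             het_count=rng.randrange(1000),
                             hom_alt_count=rng.randrange(100)),
        ]
    )
    inheritance = rng.choice(
        [None] + [InheritanceCall(m, reason="why, indeed") for m in InheritanceMode
                  if m != InheritanceMode.DENOVO]
    )
    return AnalysisRecord(
        key=VariantKey("chr1", pos, "A", rng.choice("CGT")),
        bundle=AnnotationBundle(
            consequence=rng.choice(["missense_variant", "stop_gained", ""]),
            impact=rng.choice([None] + list(Impact)),
            revel=rng.choice([None, round(rng.random(), 3)]),
            hgvs_c=rng.choice([None, "c.100A>G"]),
            dbsnp_id=rng.choice([None, f"rs{rng.randrange(10**6)}"]),
            clinvar=ClinVarAssertion(clin, "criteria provided") if clin else None,
            population=pop,
        ),
        inheritance=inheritance,
        verdict=rng.choice([None] + list(Verdict)),
        filters=rng.choice([(), ("PASS",), ("LowQual",)]),
    )


NASTY_NOTE = 'He said "wow", twice;\nsecond line with, commas | pipes & =equals'


class TestExportImport:
    @pytest.mark.parametrize("fmt,ext", [("csv", "csv"), ("vcf", "vcf")])
    def test_round_trip_reproduces_state(self, tmp_path, fmt, ext):
        rng = random.Random(11)
        records = [_random_record(rng, 100 + i) for i in range(12)]
        reviews = ReviewStore()
        reviews.set_review(records[0].key, "Significant", NASTY_NOTE)
        reviews.set_review(records[3].key, "Poor quality", "short")
        path = tmp_path / f"analysis.{ext}"
        export_analysis(records, reviews, fmt, path)
        back_records, back_reviews = import_analysis(path)
        assert back_records == records
        assert back_reviews.get_review(records[0].key).note == NASTY_NOTE
        assert (
            back_reviews.get_review(records[3].key).significance
            == ReviewSignificance.POOR_QUALITY
        )

    def test_csv_has_header_and_cardinality(self, tmp_path):
        records = [record(pos=100 + i) for i in range(12)]
        path = tmp_path / "a.csv"
        export_analysis(records, None, "csv", path)
        lines = path.read_text().splitlines()
        assert lines[0].startswith("contig,pos,ref,alt,")
        # 12 data rows; quoted embedded newlines would not apply here
        assert len(lines) == 13

    def test_vcf_export_declares_info_tags(self, tmp_path):
        records = [record(clinvar=ClinVarSignificance.PATHOGENIC,
                          mode=InheritanceMode.DENOVO, af=0.12)]
        path = tmp_path / "a.vcf"
        export_analysis(records, None, "vcf", path)
        text = path.read_text()
        for tag in ("MOI", "DN_VERDICT", "CLNSIG_JOIN", "GN_AF",
                    "REVIEW_SIG", "REVIEW_NOTE"):
            assert f"##INFO=<ID={tag}" in text

    def test_foreign_file_error_names_line(self, tmp_path):
        bad = tmp_path / "foreign.csv"
        bad.write_text("a,b,c\n1,2,3\n")
        with pytest.raises(ValueError, match="line 1"):
            import_analysis(bad)
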