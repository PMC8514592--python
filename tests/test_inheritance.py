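"""Segregation modes, Mendelian-violation detection against a brute-force
transmission oracle, and the per-family variant matrix."""

import itertools

import pytest

from trioscope.inheritance import (
    family_matrix,
    mendelian_violation,
    mode_of_inheritance,
    parse_ped,
)
from trioscope.model import (
    Affected,
    GenomicRegion,
    GenotypeCall,
    Individual,
    InheritanceMode,
    Pedigree,
    Sex,
)
from trioscope.normalize import decompose
from trioscope.region_io import VariantRecord, fetch_variants


def gt(sample, *alleles):
    return GenotypeCall(sample, alleles=tuple(alleles))


TRIO = Pedigree(
    members=(
        Individual("father", sex=Sex.MALE, affected=Affected.NO),
        Individual("mother", sex=Sex.FEMALE, affected=Affected.NO),
        Individual("proband", sex=Sex.MALE, affected=Affected.YES,
                   mother_id="mother", father_id="father"),
    ),
    proband_id="proband",
)

QUARTET = Pedigree(
    members=TRIO.members + (
        Individual("sibling", sex=Sex.FEMALE, affected=Affected.NO,
                   mother_id="mother", father_id="father"),
    ),
    proband_id="proband",
)


def trio_genotypes(p, m, f, sib=None):
    out = {
        "proband": gt("proband", *p),
        "mother": gt("mother", *m),
        "father": gt("father", *f),
    }
    if sib is not None:
        out["sibling"] = gt("sibling", *sib)
    return out


class TestModeOfInheritance:
    def test_denovo_het_child_homref_parents(self):
        call = mode_of_inheritance(trio_genotypes((0, 1), (0, 0), (0, 0)), TRIO, "chr1")
        assert call.mode == InheritanceMode.DENOVO
        assert not call.violation

    def test_autosomal_recessive_with_het_unaffected_sib(self):
        g = trio_genotypes((1, 1), (0, 1), (0, 1), sib=(0, 1))
        call = mode_of_inheritance(g, QUARTET, "chr1")
        assert call.mode == InheritanceMode.AUTOSOMAL_RECESSIVE

    def test_recessive_blocked_by_homalt_unaffected_sib(self):
        g = trio_genotypes((1, 1), (0, 1), (0, 1), sib=(1, 1))
        call = mode_of_inheritance(g, QUARTET, "chr1")
        assert call.mode == InheritanceMode.UNKNOWN

    def test_x_linked_recessive_male(self):
        g = trio_genotypes((1,), (0, 1), (0,))
        call = mode_of_inheritance(g, TRIO, "chrX")
        assert call.mode == InheritanceMode.X_LINKED_RECESSIVE

    def test_male_chrx_het_flagged_artifact(self):
        g = trio_genotypes((0, 1), (0, 1), (0,))
        call = mode_of_inheritance(g, TRIO, "chrX")
        assert call.mode == InheritanceMode.UNKNOWN
        assert "artifact" in call.reason

    def test_dominant_requires_affected_carrier_parent(self):
        ped = Pedigree(
            members=(
                Individual("father", sex=Sex.MALE, affected=Affected.YES),
                Individual("mother", sex=Sex.FEMALE, affected=Affected.NO),
                Individual("proband", sex=Sex.FEMALE, affected=Affected.YES,
                           mother_id="mother", father_id="father"),
            ),
            proband_id="proband",
        )
        g = trio_genotypes((0, 1), (0, 0), (0, 1))
        assert mode_of_inheritance(g, ped, "chr1").mode == InheritanceMode.AUTOSOMAL_DOMINANT
        # proband-only-affected trio: lone het child under a het unaffected
        # parent stays unknown rather than dominant
        g = trio_genotypes((0, 1), (0, 0), (0, 1))
        assert mode_of_inheritance(g, TRIO, "chr1").mode == InheritanceMode.UNKNOWN

    def test_no_alt_in_proband_is_none(self):
        g = trio_genotypes((0, 0), (0, 1), (0, 0))
        assert mode_of_inheritance(g, TRIO, "chr1").mode == InheritanceMode.NONE

    def test_missing_parent_degrades_denovo(self):
        g = trio_genotypes((0, 1), (None, None), (0, 0))
        call = mode_of_inheritance(g, TRIO, "chr1")
        assert call.mode == InheritanceMode.UNKNOWN
        assert "parent uncalled" in call.reason

    def test_violation_yields_unknown_with_reason(self):
        g = trio_genotypes((0, 1), (1, 1), (1, 1))
        call = mode_of_inheritance(g, TRIO, "chr1")
        assert call.mode == InheritanceMode.UNKNOWN
        assert call.violation
        assert "violation" in call.reason.lower()

    def test_stable_under_decomposition(self):
        """A biallelic-equivalent multi-allelic record classifies the same
        before and after decomposition."""
        rec = VariantRecord(
            contig="chr1", pos=100, ref="A", alts=("G", "T"),
            genotypes={
                "proband": GenotypeCall("proband", (0, 1), n_alleles=3),
                "mother": GenotypeCall("mother", (0, 0), n_alleles=3),
                "father": GenotypeCall("father", (0, 0), n_alleles=3),
            },
        )
        first_alt = decompose(rec)[0]
        before = mode_of_inheritance(rec.genotypes, TRIO, "chr1")
        after = mode_of_inheritance(first_alt.genotypes, TRIO, "chr1")
        assert before.mode == after.mode == InheritanceMode.DENOVO


def _oracle_consistent(child, mother, father):
    """Independent transmission oracle: enumerate every (maternal gamete,
    paternal gamete) pair."""
    return any(
        sorted((m, f)) == sorted(child)
        for m in set(mother)
        for f in set(father)
    )


GENOTYPES = [(0, 0), (0, 1), (1, 1)]


class TestMendelianViolation:
    def test_fig4d_pattern(self):
        violated, reason = mendelian_violation(
            gt("c", 0, 1), gt("m", 1, 1), gt("f", 1, 1), "chr1", Sex.FEMALE
        )
        assert violated
        assert "impossible" in reason

    def test_forced_heterozygote_consistent(self):
        violated, _ = mendelian_violation(
            gt("c", 0, 1), gt("m", 0, 0), gt("f", 1, 1), "chr1", Sex.MALE
        )
        assert not violated

    def test_homalt_child_of_homref_parent(self):
        violated, _ = mendelian_violation(
            gt("c", 1, 1), gt("m", 0, 0), gt("f", 0, 1), "chr1", Sex.MALE
        )
        assert violated

    def test_all_27_autosomal_combinations_match_oracle(self):
        for c, m, f in itertools.product(GENOTYPES, repeat=3):
            violated, _ = mendelian_violation(
                gt("c", *c), gt("m", *m), gt("f", *f), "chr1", Sex.FEMALE
            )
            assert violated == (not _oracle_consistent(c, m, f)), (c, m, f)

    def test_chrx_combinations_by_child_sex(self):
        # male child: hemizygous, allele must come from the mother
        for c in [(0,), (1,)]:
            for m, f in itertools.product(GENOTYPES, [(0,), (1,)]):
                violated, _ = mendelian_violation(
                    gt("c", *c), gt("m", *m), gt("f", *f), "chrX", Sex.MALE
                )
                assert violated == (c[0] not in set(m)), (c, m, f)
        # female child: diploid with the father contributing his single allele
        for c, m, f in itertools.product(GENOTYPES, GENOTYPES, [(0,), (1,)]):
            violated, _ = mendelian_violation(
                gt("c", *c), gt("m", *m), gt("f", *f), "chrX", Sex.FEMALE
            )
            assert violated == (not _oracle_consistent(c, m, f)), (c, m, f)

    def test_missing_genotype_untestable(self):
        violated, reason = mendelian_violation(
            gt("c", 0, None), gt("m", 0, 0), gt("f", 0, 0), "chr1", Sex.MALE
        )
        assert not violated
        assert "untestable" in reason


class TestFamilyMatrix:
    def test_cardinality(self):
        records = [
            VariantRecord(
                contig="chr1", pos=100 + i, ref="A", alts=("G",),
                genotypes=trio_genotypes((0, 1), (0, 0), (0, 0)),
            )
            for i in range(4)
        ]
        matrix = family_matrix(records, TRIO)
        assert len(matrix) == 12  # trio x 4 variants
        assert family_matrix([], TRIO).empty

    def test_fig4d_fixture_has_exactly_one_violation_row(self, fixture_dir, manifest):
        ped = parse_ped(fixture_dir / "family.ped")
        site = manifest["scenarios"]["fig4d"]["site"]
        records = fetch_variants(
            fixture_dir / "family.vcf.gz",
            GenomicRegion(site["contig"], site["pos"] - 10, site["pos"] + 10),
        )
        matrix = family_matrix(records, ped)
        flagged = matrix[matrix["violation"]]
        assert list(flagged["sample"]) == ["sibling"]

    def test_denovo_proband_row_not_flagged(self):
        records = [
            VariantRecord(
                contig="chr1", pos=100, ref="A", alts=("G",),
                genotypes=trio_genotypes((0, 1), (0, 0), (0, 0)),
            )
        ]
        matrix = family_matrix(records, TRIO)
        proband_row = matrix[matrix["sample"] == "proband"].iloc[0]
        assert proband_row["mode"] == "denovo"
        assert not proband_row["violation"]


def test_parse_ped_fixture(fixture_dir):
    ped = parse_ped(fixture_dir / "family.ped")
    assert ped.proband_id == "proband"
    assert ped.proband.sex == Sex.MALE
    assert ped.proband.mother_id == "mother"
    assert len(ped.members) == 4
    assert ped["sibling"].affected == Affected.NO
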