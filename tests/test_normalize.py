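"""Decomposition and left-align/trim normalization.

The key oracles: a constructive spelling enumerator (equivalent paddings /
right-shifts of a variant against a known reference must all normalize to
one canonical key) and, for file-level agreement, `bcftools norm` as an
independent implementation.
"""

import random
import subprocess

import pysam
import pytest

from trioscope.model import GenomicRegion, GenotypeCall, VariantKey
from trioscope.normalize import (
    NormalizationError,
    decompose,
    left_align_trim,
    normalize_all,
)
from trioscope.region_io import VariantRecord, fetch_variants

from conftest import string_fetch


def _call(sample, alleles, ad=None, n_alleles=2):
    return GenotypeCall(sample, alleles=alleles, allele_depths=ad, n_alleles=n_alleles)


class TestDecompose:
    def test_triallelic_genotype_remap(self):
        rec = VariantRecord(
            contig="chr1", pos=100, ref="A", alts=("G", "T"),
            info={"AF": (0.1, 0.2)},
            genotypes={"p": _call("p", (1, 2), ad=(3, 8, 9), n_alleles=3)},
        )
        out = decompose(rec)
        assert [(r.alts, r.genotypes["p"].gt_string()) for r in out] == [
            (("G",), "1/."),
            (("T",), "./1"),
        ]
        # per-alt INFO split by position; AD subset to (ref, this alt)
        assert [r.info["AF"] for r in out] == [0.1, 0.2]
        assert [r.genotypes["p"].allele_depths for r in out] == [(3, 8), (3, 9)]

    def test_decompose_preserves_total_alt_depth(self):
        rec = VariantRecord(
            contig="chr1", pos=100, ref="A", alts=("G", "T", "C"),
            genotypes={"p": _call("p", (1, 2), ad=(5, 7, 11, 2), n_alleles=4)},
        )
        out = decompose(rec)
        total = sum(r.genotypes["p"].allele_depths[1] for r in out)
        assert total == 7 + 11 + 2

    def test_hom_ref_stays_hom_ref_at_triallelic_site(self):
        rec = VariantRecord(
            contig="chr1", pos=100, ref="A", alts=("G", "T"),
            genotypes={"p": _call("p", (0, 0), n_alleles=3)},
        )
        assert [r.genotypes["p"].gt_string() for r in decompose(rec)] == ["0/0", "0/0"]

    def test_biallelic_identity(self):
        rec = VariantRecord(
            contig="chr1", pos=100, ref="A", alts=("G",),
            genotypes={"p": _call("p", (0, 1))},
        )
        assert decompose(rec) == [rec]

    def test_spanning_deletion_dropped_and_symbolic_flagged(self):
        rec = VariantRecord(contig="chr1", pos=100, ref="A", alts=("G", "*"))
        assert [r.alts for r in decompose(rec)] == [("G",)]
        sym = VariantRecord(contig="chr1", pos=100, ref="A", alts=("<DEL>",))
        (out,) = decompose(sym)
        assert "symbolic_unnormalized" in out.flags


#  ctg: 0-based    0         1
#                  0123456789012345678
_REF = "GGGTACGTACCCCCCTAGCATTTTGCAGGCATGCAGGA" + "ACGT" * 20
_FETCH = string_fetch(_REF)


def _spell(key: VariantKey) -> str:
    """Apply a variant spelling to the reference (the equivalence oracle:
    two spellings are the same variant iff they produce the same string)."""
    i = key.pos - 1
    assert _REF[i : i + len(key.ref)] == key.ref
    return _REF[:i] + key.alt + _REF[i + len(key.ref) :]


class TestLeftAlignTrim:
    def test_snv_passthrough(self):
        key = VariantKey("ctg", 5, "A", "G")
        assert left_align_trim(key, _FETCH).key == key

    def test_shared_terminal_then_leading_trim(self):
        # CTCC>CCC at the TACGT.. context equivalent: hand-trace of the
        # truncate/trim loop gives CT>C at the same position
        ref = "CTCC"
        fetch = string_fetch("AACTCCGG")
        out = left_align_trim(VariantKey("ctg", 3, "CTCC", "CCC"), fetch)
        assert (out.key.pos, out.key.ref, out.key.alt) == (3, "CT", "C")

    def test_homopolymer_deletion_left_aligned(self):
        # one-C deletion spelled at the right end of the C6 run (pos 10-15,
        # 1-based; 'A' at 9): every equivalent spelling reaches the
        # anchored left-most form (9, AC, A)
        canonical = left_align_trim(VariantKey("ctg", 14, "CC", "C"), _FETCH).key
        assert (canonical.pos, canonical.ref, canonical.alt) == (9, "AC", "A")
        target = _spell(VariantKey("ctg", 14, "CC", "C"))
        for pos in range(10, 15):
            key = VariantKey("ctg", pos, _REF[pos - 1 : pos + 1], _REF[pos - 1])
            assert _spell(key) == target  # equivalent spelling by oracle
            assert left_align_trim(key, _FETCH).key == canonical

    def test_ref_mismatch_raises_with_position(self):
        with pytest.raises(NormalizationError, match="ctg:5"):
            left_align_trim(VariantKey("ctg", 5, "T", "G"), _FETCH)

    def test_idempotent_on_fuzzed_variants(self):
        rng = random.Random(7)
        for _ in range(500):
            pos = rng.randrange(5, len(_REF) - 10)
            kind = rng.choice(["snv", "ins", "del"])
            ref_base = _REF[pos - 1]
            if kind == "snv":
                alt = rng.choice([b for b in "ACGT" if b != ref_base])
                key = VariantKey("ctg", pos, ref_base, alt)
            elif kind == "ins":
                ins = "".join(rng.choice("ACGT") for _ in range(rng.randrange(1, 4)))
                key = VariantKey("ctg", pos, ref_base, ref_base + ins)
            else:
                d = rng.randrange(1, 4)
                key = VariantKey("ctg", pos, _REF[pos - 1 : pos + d], ref_base)
            once = left_align_trim(key, _FETCH).key
            assert left_align_trim(once, _FETCH).key == once


class TestNormalizeAll:
    def test_sorted_and_empty(self):
        assert normalize_all([], _FETCH) == []
        recs = [
            VariantRecord(contig="ctg", pos=20, ref=_REF[19], alts=("A" if _REF[19] != "A" else "C",)),
            VariantRecord(contig="ctg", pos=5, ref=_REF[4], alts=("G" if _REF[4] != "G" else "T",)),
        ]
        out = normalize_all(recs, _FETCH)
        assert [r.pos for r in out] == sorted(r.pos for r in out)

    def test_equivalent_spellings_merge(self):
        spellings = [
            VariantRecord(
                contig="ctg", pos=14, ref="CC", alts=("C",),
                genotypes={"p": _call("p", (0, 1))},
            ),
            VariantRecord(
                contig="ctg", pos=12, ref="CC", alts=("C",),
                genotypes={"m": _call("m", (0, 1))},
            ),
        ]
        out = normalize_all(spellings, _FETCH)
        assert len(out) == 1
        assert (out[0].pos, out[0].ref, out[0].alts) == (9, "AC", ("A",))
        assert sorted(out[0].genotypes) == ["m", "p"]
        assert out[0].info["OLD_VARIANT"]

    def test_conflicting_duplicates_kept_flagged(self):
        spellings = [
            VariantRecord(
                contig="ctg", pos=14, ref="CC", alts=("C",),
                genotypes={"p": _call("p", (0, 1))},
            ),
            VariantRecord(
                contig="ctg", pos=12, ref="CC", alts=("C",),
                genotypes={"p": _call("p", (1, 1))},
            ),
        ]
        out = normalize_all(spellings, _FETCH)
        assert len(out) == 2
        assert all("conflicting_duplicates" in r.flags for r in out)


def test_agrees_with_bcftools_norm(tmp_path, fixture_dir):
    """Independent oracle: bcftools norm -m- -f ref produces the same
    normalized keys on the fixture family VCF."""
    out_vcf = tmp_path / "norm.vcf"
    subprocess.run(
        [
            "bcftools", "norm", "-m-", "-f", str(fixture_dir / "ref.fa"),
            "-o", str(out_vcf), str(fixture_dir / "family.vcf.gz"),
        ],
        check=True,
        capture_output=True,
    )
    with pysam.VariantFile(str(out_vcf)) as vf:
        oracle = sorted(
            (rec.contig, rec.pos, rec.ref, rec.alts[0]) for rec in vf
        )
    region_all = [
        r
        for contig, span in (("chr1", (0, 49_999)), ("chrX", (0, 29_999)))
        for r in fetch_variants(
            fixture_dir / "family.vcf.gz", GenomicRegion(contig, *span)
        )
    ]

    def fetch(region):
        from trioscope.region_io import fetch_reference

        return fetch_reference(fixture_dir / "ref.fa", region)

    ours = sorted(
        (r.contig, r.pos, r.ref, r.alts[0]) for r in normalize_all(region_all, fetch)
    )
    assert ours == oracle
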