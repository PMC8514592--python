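import json
from pathlib import Path

import pysam
import pytest

from trioscope import fixtures
from trioscope.model import GenomicRegion
from trioscope.region_io import fetch_reference

SEED = 1


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory) -> Path:
    """All planted scenarios, generated once per session."""
    out = tmp_path_factory.mktemp("scenarios")
    fixtures.generate(fixtures.SCENARIOS, SEED, out)
    return out


@pytest.fixture(scope="session")
def manifest(fixture_dir) -> dict:
    return json.loads((fixture_dir / "manifest.json").read_text())


@pytest.fixture(scope="session")
def ref_fetch(fixture_dir):
    fasta = fixture_dir / "ref.fa"

    def fetch(region: GenomicRegion) -> str:
        return fetch_reference(fasta, region)

    return fetch


def string_fetch(seq: str, contig: str = "ctg"):
    """Reference fetcher over an in-memory sequence (for normalization
    tests that need no files)."""

    def fetch(region: GenomicRegion) -> str:
        assert region.contig == contig
        return seq[region.start : region.end].upper()

    return fetch


def make_bam(path: Path, reads, contigs: dict[str, int]) -> Path:
    """Write reads [(qname, contig, 0-based start, seq, qual, mapq)] as a
    sorted, indexed BAM via an intermediate text SAM."""
    sam = path.with_suffix(".sam")
    with open(sam, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for name, length in contigs.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for qname, contig, start, seq, qual, mapq in sorted(
            reads, key=lambda r: (r[1], r[2])
        ):
            fh.write(
                f"{qname}\t0\t{contig}\t{start + 1}\t{mapq}\t{len(seq)}M"
                f"\t*\t0\t0\t{seq}\t{qual}\n"
            )
    bam = path.with_suffix(".bam")
    pysam.sort("-o", str(bam), str(sam))
    pysam.index(str(bam))
    return bam
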