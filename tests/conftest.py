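import pytest

from utrintrons.annotation import GenomeInterval, TranscriptModel


def make_tx(
    tid="t1",
    exons=((100, 200), (300, 400)),
    chrom="chr1",
    strand="+",
    cds=None,
    stop=None,
    start=None,
    gene="g1",
    attrs=None,
):
    """Compact TranscriptModel builder for tests."""
    return TranscriptModel(
        transcript_id=tid,
        gene_id=gene,
        chrom=chrom,
        strand=strand,
        exons=tuple(GenomeInterval(chrom, a, b, strand) for a, b in exons),
        cds=tuple(GenomeInterval(chrom, a, b, strand) for a, b in cds)
        if cds else None,
        stop_codon=GenomeInterval(chrom, *stop, strand) if stop else None,
        start_codon=GenomeInterval(chrom, *start, strand) if start else None,
        attributes=attrs or {},
    )


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """One shared 20-gene synthetic fixture."""
    from utrintrons.simulate import default_spec, make_fixture

    out = tmp_path_factory.mktemp("fixture")
    return make_fixture(default_spec(11, n_genes=20), out)
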