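import pytest

from nestedgenes.annotation import AnnotationSet, GeneModel, GenomicInterval


def make_gene(gene_id, chrom, strand, exons, biotype="protein_coding"):
    return GeneModel.from_exons(
        gene_id, biotype, [GenomicInterval(chrom, s, e, strand) for s, e in exons]
    )


@pytest.fixture
def toy_annotation():
    """A hand-built chromosome: one host with an intronic gene on the
    opposite strand, one exon-overlapping gene, and two isolated genes."""
    ann = AnnotationSet(species="toy")
    # external host: exons [999,2000) and [8999,10000), intron [2000,8999)
    ann.add(make_gene("HOST", "chr1", "+", [(999, 2000), (8999, 10000)]))
    # internal gene wholly inside the host intron, opposite strand
    ann.add(make_gene("INNER", "chr1", "-", [(2999, 4000)]))
    # overlaps the host's first exon -> neither nested nor unnested
    ann.add(make_gene("EXONOVL", "chr1", "+", [(1499, 2500)]))
    # isolated genes on two chromosomes
    ann.add(make_gene("LONE1", "chr1", "+", [(50_000, 51_000)]))
    ann.add(make_gene("LONE2", "chr2", "-", [(100, 900)]))
    return ann


@pytest.fixture
def toy_gtf(tmp_path):
    """Two transcripts of one gene whose exons union to [1000,2000] and
    [9000,10000] (1-based inclusive), plus a lncRNA that the biotype
    filter should drop."""
    lines = []

    def rec(chrom, feature, start, end, strand, gene_id, biotype, tx=None):
        attrs = f'gene_id "{gene_id}"; gene_biotype "{biotype}";'
        if tx:
            attrs = f'gene_id "{gene_id}"; transcript_id "{tx}"; gene_biotype "{biotype}";'
        lines.append(
            f"{chrom}\ttest\t{feature}\t{start}\t{end}\t.\t{strand}\t.\t{attrs}"
        )

    rec("chr1", "gene", 1000, 10000, "+", "G1", "protein_coding")
    rec("chr1", "exon", 1000, 1500, "+", "G1", "protein_coding", tx="T1")
    rec("chr1", "exon", 9000, 10000, "+", "G1", "protein_coding", tx="T1")
    rec("chr1", "exon", 1200, 2000, "+", "G1", "protein_coding", tx="T2")
    rec("chr1", "exon", 9000, 9500, "+", "G1", "protein_coding", tx="T2")
    rec("chr1", "gene", 20000, 21000, "-", "G2", "lncRNA")
    rec("chr1", "exon", 20000, 21000, "-", "G2", "lncRNA", tx="T3")
    path = tmp_path / "toy.gtf"
    path.write_text("\n".join(lines) + "\n")
    return path
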