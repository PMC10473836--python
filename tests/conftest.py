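import numpy as np
import pytest

from forksplice import Gene, GenomeModel, simulate_genome


@pytest.fixture
def two_exon_gene() -> Gene:
    """Plus-strand toy gene: exons [0,100) and [145,300), one 45-bp intron."""
    return Gene(gene_id="toy", chrom="c1", strand="+", exons=((0, 100), (145, 300)))


@pytest.fixture
def tiny_genome() -> GenomeModel:
    """Hand-built genome: 'AAA' exon / lowercase-style intron / 'CCC' exon."""
    chrom = "AAA" + "GTATGTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTAG" + "CCC"
    gene = Gene(
        gene_id="mini",
        chrom="c1",
        strand="+",
        exons=((0, 3), (len(chrom) - 3, len(chrom))),
    )
    return GenomeModel(chromosomes={"c1": chrom}, genes=[gene])


@pytest.fixture(scope="session")
def sim_genome() -> GenomeModel:
    """Session-wide simulated genome with a GC-dip group."""
    return simulate_genome(
        n_genes=10, seed=11, gc_dip_group=frozenset({"g001", "g002", "g003"})
    )


def mirror_genome(genome: GenomeModel) -> GenomeModel:
    """The same genome seen from the opposite strand: every chromosome
    reverse-complemented and every gene's coordinates mirrored."""
    from forksplice import reverse_complement

    chroms = {n: reverse_complement(s) for n, s in genome.chromosomes.items()}
    genes = []
    for g in genome.genes:
        L = len(genome.chromosomes[g.chrom])
        exons = tuple((L - e, L - s) for s, e in g.exons)
        genes.append(
            Gene(
                gene_id=g.gene_id,
                chrom=g.chrom,
                strand="-" if g.strand == "+" else "+",
                exons=exons,
                cds_start_offset=g.cds_start_offset,
            )
        )
    return GenomeModel(chromosomes=chroms, genes=genes)
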