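from collections import Counter

import pytest
from hypothesis import settings

import genecontext as gc

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

TOY_GENES = """\
gene_id\tgenome_id\tcontig_id\tstart\tend\tstrand\tdomains
g1\tG1\tc1\t100\t400\t+\tPF00001
g2\tG1\tc1\t600\t900\t-\t
g3\tG2\tc2\t6000\t6300\t+\tPF00001;PF00002
"""

TOY_TAXONOMY = """\
genome_id\tphylum\tclass\torder\tfamily\tgenus
G1\tProteobacteria\tGammaproteobacteria\tEnterobacterales\tEnterobacteriaceae\tEscherichia
G2\tProteobacteria\tGammaproteobacteria\tEnterobacterales\tEnterobacteriaceae\tSalmonella
"""


@pytest.fixture
def toy_paths(tmp_path):
    gp = tmp_path / "genes.tsv"
    tp = tmp_path / "taxonomy.tsv"
    gp.write_text(TOY_GENES)
    tp.write_text(TOY_TAXONOMY)
    return gp, tp


@pytest.fixture
def toy_db(toy_paths):
    return gc.load_database(*toy_paths)


@pytest.fixture(scope="session")
def small_planted_db():
    """A compact planted-association database shared across test modules."""
    spec = gc.FixtureSpec(
        n_genomes=40,
        genes_per_genome=300,
        domain_pool_size=60,
        background_freq=0.01,
        query_prevalence=0.8,
        planted_partners=(("PF00001", 0.9, 3),),
        seed=11,
    )
    db, truth = gc.build_database(spec)
    return spec, db, truth


def make_neighborhood(name, domains, genome_id="G0000", counts=None):
    """Neighborhood stub with a prescribed domain tally, for clustering and
    correction tests that do not need real gene records."""
    tally = Counter(counts) if counts else Counter(set(domains))
    genes = [
        gc.GeneRecord(
            gene_id=f"{name}_m{i}",
            genome_id=genome_id,
            contig_id="c1",
            start=1 + 10 * i,
            end=5 + 10 * i,
            strand="+",
            domains=frozenset([d]),
        )
        for i, d in enumerate(sorted(tally.elements()))
    ]
    return gc.Neighborhood(
        query_gene_id=name,
        genome_id=genome_id,
        contig_id="c1",
        member_genes=genes,
    )
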