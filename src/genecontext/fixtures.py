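"""Synthetic multi-genome annotation databases with controlled structure.

The generator emulates the shape of a large prokaryotic annotation store:
many genomes, each a single contig of non-overlapping genes with sampled
lengths and intergenic gaps, each gene carrying an independent background
sample of Pfam domains.  On top of that background it can plant a query
domain in a chosen fraction of genomes and, in those genomes, co-localize
partner domains within a bounded gene offset of the query with a chosen
probability — the ground truth a neighborhood-enrichment analysis should
recover.  A genus-level sampling skew (many genomes of one genus, few of
another) exercises the subtaxon-averaging correction.

Everything is driven by one integer seed and is byte-reproducible; a truth
record (JSON) lists every planted placement so tests can compute expected
counts analytically.  No nucleotide or protein sequence is generated —
only coordinates and domain annotations, which is all the method consumes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FixtureSpecError
from .genome_db import GenomeDatabase, TaxonomyLineage, load_database


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic database.

    Defaults describe the standard planted-association condition: 200
    genomes of 1,000 genes, a 300-domain pool at per-gene frequency 0.005
    (~1.5 background domains per gene), the query domain in 75% of genomes
    and one partner domain planted within ±3 genes of the query with
    probability 0.8.  Gene geometry (mean length 900 bp, mean gap 100 bp)
    gives roughly one gene per kilobase, so a ±5,000 bp window holds about
    10 genes, matching typical prokaryotic gene density.
    """

    n_genomes: int = 200
    genes_per_genome: int = 1000
    mean_gene_len: int = 900
    mean_intergenic: int = 100
    domain_pool_size: int = 300
    background_freq: float = 0.005
    query_domain: str = "PF99999"
    query_prevalence: float = 0.75
    planted_partners: tuple[tuple[str, float, int], ...] = (("PF00001", 0.8, 3),)
    #: restrict planting to query genomes of these genera (None = all)
    planted_in_genera: frozenset[str] | None = None
    taxon_skew: tuple[tuple[str, int], ...] | None = None
    same_strand_prob: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        probs = [self.background_freq, self.query_prevalence, self.same_strand_prob]
        probs += [p for _, p, _ in self.planted_partners]
        if any(not (0 <= p <= 1) for p in probs):
            raise FixtureSpecError("all probabilities must lie in [0, 1]")
        if self.n_genomes < 1 or self.genes_per_genome < 1:
            raise FixtureSpecError("n_genomes and genes_per_genome must be >= 1")
        if self.mean_gene_len < 60 or self.mean_intergenic < 1:
            raise FixtureSpecError("mean_gene_len must be >= 60, mean_intergenic >= 1")
        for name, _, off in self.planted_partners:
            if off < 1 or 2 * off + 1 > self.genes_per_genome:
                raise FixtureSpecError(
                    f"partner {name}: offset {off} impossible with "
                    f"{self.genes_per_genome} genes per genome"
                )
        if self.taxon_skew is not None:
            tot = sum(n for _, n in self.taxon_skew)
            if tot != self.n_genomes:
                raise FixtureSpecError(
                    f"taxon_skew genome counts sum to {tot}, expected {self.n_genomes}"
                )

    def genera(self) -> list[str]:
        """Genus of each genome index, following taxon_skew exactly."""
        if self.taxon_skew is None:
            return ["GenusA"] * self.n_genomes
        out: list[str] = []
        for name, n in self.taxon_skew:
            out.extend([name] * n)
        return out


def generate_tables(spec: FixtureSpec) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate (gene table, taxonomy table, truth record) as DataFrames.

    The gene table uses the loader's TSV schema with ``domains`` as a
    semicolon-joined string.  Coordinates within each contig are strictly
    increasing and non-overlapping by construction: gene lengths are
    ``60 + Geometric(mean - 60)`` and intergenic gaps ``Geometric(mean)``
    (shifted geometric distributions with the stated means).
    """
    rng = np.random.default_rng(spec.seed)
    ng, npg = spec.n_genomes, spec.genes_per_genome
    total = ng * npg

    # --- geometry -----------------------------------------------------
    min_len = 60
    lens = min_len + rng.geometric(1.0 / max(spec.mean_gene_len - min_len, 1), size=(ng, npg))
    gaps = rng.geometric(1.0 / spec.mean_intergenic, size=(ng, npg))
    ends = np.cumsum(lens + gaps, axis=1)
    starts = ends - lens + 1

    # --- strands: Markov chain with P(same as previous) ---------------
    first = rng.integers(0, 2, size=(ng, 1))
    flips = rng.random(size=(ng, npg - 1)) >= spec.same_strand_prob
    parity = np.concatenate([first, flips], axis=1).cumsum(axis=1) % 2
    strands = np.where(parity == 0, "+", "-")

    # --- background domains -------------------------------------------
    pool = [f"PF{i:05d}" for i in range(1, spec.domain_pool_size + 1)]
    dom_lists: list[list[str]] = [[] for _ in range(total)]
    for dname in pool:
        n_carry = rng.binomial(total, spec.background_freq)
        if n_carry == 0:
            continue
        for idx in rng.choice(total, size=n_carry, replace=False):
            dom_lists[idx].append(dname)

    # --- planted query + partners -------------------------------------
    genera = spec.genera()
    n_query = int(round(spec.query_prevalence * ng))
    query_genomes = np.sort(rng.choice(ng, size=n_query, replace=False))
    truth_placements = []
    query_gene_idx: dict[int, int] = {}
    for g in query_genomes:
        qi = int(rng.integers(npg))
        query_gene_idx[int(g)] = qi
        dom_lists[g * npg + qi].append(spec.query_domain)
    for partner, p_coloc, max_off in spec.planted_partners:
        for g in query_genomes:
            g = int(g)
            if spec.planted_in_genera is not None and genera[g] not in spec.planted_in_genera:
                continue
            qi = query_gene_idx[g]
            colocalized = bool(rng.random() < p_coloc)
            if colocalized:
                offsets = [
                    o for o in range(-max_off, max_off + 1)
                    if o != 0 and 0 <= qi + o < npg
                ]
                off = int(offsets[rng.integers(len(offsets))])
                target = qi + off
            else:
                off = None
                target = int(rng.integers(npg))
            dom_lists[g * npg + target].append(partner)
            truth_placements.append(
                {
                    "genome_index": g,
                    "partner": partner,
                    "colocalized": colocalized,
                    "gene_index": target,
                    "offset": off,
                }
            )

    # --- assemble tables ----------------------------------------------
    genome_ids = [f"G{g:04d}" for g in range(ng)]
    gene_genome = np.repeat(genome_ids, npg)
    gene_ids = [f"G{g:04d}_{i:05d}" for g in range(ng) for i in range(npg)]
    genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "genome_id": gene_genome,
            "contig_id": [f"{gid}_c1" for gid in gene_genome],
            "start": starts.ravel(),
            "end": ends.ravel(),
            "strand": strands.ravel(),
            "domains": [";".join(sorted(set(d))) for d in dom_lists],
        }
    )
    taxonomy = pd.DataFrame(
        {
            "genome_id": genome_ids,
            "phylum": ["PhylumA"] * ng,
            "class": ["ClassA"] * ng,
            "order": ["OrderA"] * ng,
            "family": [f"Family_{g}" for g in genera],
            "genus": genera,
        }
    )
    truth = {
        "spec": _spec_to_json(spec),
        "query_genomes": [genome_ids[g] for g in query_genomes],
        "query_genes": {
            genome_ids[g]: f"{genome_ids[g]}_{qi:05d}" for g, qi in query_gene_idx.items()
        },
        "placements": [
            {
                **pl,
                "genome_id": genome_ids[pl["genome_index"]],
                "gene_id": f"{genome_ids[pl['genome_index']]}_{pl['gene_index']:05d}",
            }
            for pl in truth_placements
        ],
    }
    return genes, taxonomy, truth


def _spec_to_json(spec: FixtureSpec) -> dict:
    d = dataclasses.asdict(spec)
    if d.get("planted_in_genera") is not None:
        d["planted_in_genera"] = sorted(d["planted_in_genera"])
    return d


def write_database(spec: FixtureSpec, outdir) -> dict[str, Path]:
    """Write genes.tsv, taxonomy.tsv and truth.json; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes, taxonomy, truth = generate_tables(spec)
    paths = {
        "genes": outdir / "genes.tsv",
        "taxonomy": outdir / "taxonomy.tsv",
        "truth": outdir / "truth.json",
    }
    genes.to_csv(paths["genes"], sep="\t", index=False)
    taxonomy.to_csv(paths["taxonomy"], sep="\t", index=False)
    paths["truth"].write_text(json.dumps(truth, indent=1))
    return paths


def build_database(spec: FixtureSpec) -> tuple[GenomeDatabase, dict]:
    """Generate a database in memory (no file round-trip); returns (db, truth).

    Produces exactly the same database as :func:`write_database` followed by
    :func:`~genecontext.genome_db.load_database` — the round-trip identity
    is covered by tests.
    """
    genes, taxonomy, truth = generate_tables(spec)
    genes = genes.copy()
    genes["domains"] = genes["domains"].map(
        lambda s: frozenset(s.split(";")) if s else frozenset()
    )
    tax = {
        row.genome_id: TaxonomyLineage(
            genome_id=row.genome_id,
            phylum=row.phylum,
            class_=row[2],
            order=row.order,
            family=row.family,
            genus=row.genus,
        )
        for row in taxonomy.itertuples(index=False)
    }
    db = GenomeDatabase(genes=genes, taxonomy=tax)
    return db, truth


# ----------------------------------------------------------------------
# canonical study conditions

def standard_spec(seed: int = 0) -> FixtureSpec:
    """Planted-association condition: defaults of :class:`FixtureSpec`."""
    return FixtureSpec(seed=seed)


def null_spec(seed: int = 0) -> FixtureSpec:
    """No planted association; calibration condition.

    A compact 50-domain pool at per-gene frequency 0.04 puts every domain's
    expected neighborhood count near 60, so Monte-Carlo noise on a 20-seed
    mean (about 1/sqrt(20*lambda) relative) is far below the 10% band the
    calibration check uses — the check then probes the expectation formula,
    not sampling noise.
    """
    return FixtureSpec(
        n_genomes=200,
        genes_per_genome=500,
        domain_pool_size=50,
        background_freq=0.04,
        planted_partners=(),
        seed=seed,
    )


def skewed_spec(seed: int = 0) -> FixtureSpec:
    """Uneven genus sampling: GenusA (50 genomes) carries the planted
    partner association, GenusB (30 genomes) does not."""
    return FixtureSpec(
        n_genomes=80,
        genes_per_genome=500,
        domain_pool_size=100,
        taxon_skew=(("GenusA", 50), ("GenusB", 30)),
        planted_in_genera=frozenset({"GenusA"}),
        seed=seed,
    )
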