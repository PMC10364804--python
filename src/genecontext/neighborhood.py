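"""Query resolution and extraction of genomic neighborhoods.

A neighborhood is the set of genes on the query gene's contig whose
``[start, end]`` interval overlaps the window ``[query.start - r,
query.end + r]`` for a radius ``r`` in base pairs (default 5,000 bp each
direction, which in typical prokaryotic gene density holds about 10 genes).
Membership is by interval overlap, not start-coordinate containment, so a
long gene straddling the window edge is still counted.  The query gene is
always a member of its own neighborhood.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, QueryResolutionError
from .genome_db import GeneRecord, GenomeDatabase, RANKS

DEFAULT_RADIUS_BP = 5000

STRAND_MODES = ("all", "same", "opposite")


@dataclass(frozen=True)
class QuerySpec:
    """How to turn user input into a list of query genes.

    Exactly one of ``pfam_id`` / ``gene_ids`` must be set.  ``strand_mode``
    restricts neighbors to the query's strand (``same``), the other strand
    (``opposite``) or keeps both (``all``); the query gene itself is always
    kept.
    """

    pfam_id: str | None = None
    gene_ids: tuple[str, ...] | None = None
    radius_bp: int = DEFAULT_RADIUS_BP
    strand_mode: str = "all"
    taxon_filter: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if (self.pfam_id is None) == (self.gene_ids is None):
            raise ParameterError("exactly one of pfam_id / gene_ids must be given")
        if self.gene_ids is not None and len(self.gene_ids) == 0:
            raise ParameterError("gene_ids must be a nonempty list")
        if self.radius_bp <= 0:
            raise ParameterError(f"radius_bp must be positive, got {self.radius_bp}")
        if self.strand_mode not in STRAND_MODES:
            raise ParameterError(
                f"strand_mode must be one of {STRAND_MODES}, got {self.strand_mode!r}"
            )
        if self.taxon_filter is not None and self.taxon_filter[0] not in RANKS:
            raise ParameterError(f"taxon_filter rank must be one of {RANKS}")

    @property
    def mode(self) -> str:
        return "pfam_domain" if self.pfam_id is not None else "gene_list"


@dataclass
class Neighborhood:
    """Genes within the window around one query gene, with domain tallies.

    ``domain_multiset`` maps each domain to the number of member genes
    carrying it (per-gene presence); ``domain_set`` is its key set.
    """

    query_gene_id: str
    genome_id: str
    contig_id: str
    member_genes: list[GeneRecord]
    domain_multiset: Counter = field(default_factory=Counter)

    def __post_init__(self) -> None:
        if not self.domain_multiset:
            tally: Counter = Counter()
            for g in self.member_genes:
                tally.update(g.domains)
            self.domain_multiset = tally

    @property
    def n_genes(self) -> int:
        return len(self.member_genes)

    @property
    def domain_set(self) -> frozenset[str]:
        return frozenset(self.domain_multiset)


@dataclass
class QueryResolution:
    """Outcome of resolving a query: matched genes plus diagnostics."""

    genes: list[GeneRecord]
    unmatched: list[str] = field(default_factory=list)
    found: bool = True


def resolve_query(db: GenomeDatabase, spec: QuerySpec) -> QueryResolution:
    """Translate a query spec into the list of query genes.

    Pfam mode returns every gene carrying the domain (optionally taxon
    restricted); an absent domain yields an empty result with
    ``found=False`` rather than an exception.  Gene-list mode returns the
    records for the listed IDs; unknown IDs are collected in ``unmatched``
    and are fatal only when *all* IDs are unknown.
    """
    if spec.mode == "pfam_domain":
        genes, found = db.genes_with_domain(spec.pfam_id, spec.taxon_filter)
        return QueryResolution(genes=genes, found=found and bool(genes))
    id_to_row = {gid: row for row, gid in enumerate(db.genes["gene_id"])}
    genes, unmatched = [], []
    for gid in spec.gene_ids:
        row = id_to_row.get(gid)
        if row is None:
            unmatched.append(gid)
        else:
            genes.append(db.record(row))
    if not genes:
        raise QueryResolutionError(
            f"none of the {len(spec.gene_ids)} query gene IDs are in the database"
        )
    return QueryResolution(genes=genes, unmatched=unmatched)


def extract_neighborhood(
    db: GenomeDatabase,
    gene: GeneRecord,
    radius_bp: int = DEFAULT_RADIUS_BP,
    strand_mode: str = "all",
) -> Neighborhood:
    """Extract the ±``radius_bp`` neighborhood of one query gene.

    Members are genes on the same contig overlapping
    ``[gene.start - radius_bp, gene.end + radius_bp]``, ordered by start
    coordinate.  Strand filtering never removes the query gene itself.
    """
    if strand_mode not in STRAND_MODES:
        raise ParameterError(f"strand_mode must be one of {STRAND_MODES}")
    idx = db.contig_rows(gene.genome_id, gene.contig_id)
    win_lo = gene.start - radius_bp
    win_hi = gene.end + radius_bp
    mask = (idx["start"] <= win_hi) & (idx["end"] >= win_lo)
    rows = idx["rows"][mask]
    members = db.records(rows)
    if strand_mode != "all":
        want = gene.strand if strand_mode == "same" else ("-" if gene.strand == "+" else "+")
        members = [g for g in members if g.strand == want or g.gene_id == gene.gene_id]
    return Neighborhood(
        query_gene_id=gene.gene_id,
        genome_id=gene.genome_id,
        contig_id=gene.contig_id,
        member_genes=members,
    )


def extract_all(
    db: GenomeDatabase,
    genes: list[GeneRecord],
    radius_bp: int = DEFAULT_RADIUS_BP,
    strand_mode: str = "all",
) -> list[Neighborhood]:
    """One neighborhood per query gene, in input order.

    Overlapping windows of nearby query genes stay separate entries: the
    statistic models each neighborhood as an independent draw, as does the
    underlying method.
    """
    if not genes:
        raise ParameterError("extract_all requires a nonempty gene list")
    return [extract_neighborhood(db, g, radius_bp, strand_mode) for g in genes]


def mean_neighborhood_size(neighborhoods: list[Neighborhood]) -> float:
    """Mean number of genes per neighborhood (symbol Nl, in genes)."""
    if not neighborhoods:
        raise ParameterError("mean_neighborhood_size requires >= 1 neighborhood")
    return float(np.mean([n.n_genes for n in neighborhoods]))
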