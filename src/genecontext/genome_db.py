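"""Indexed store of gene annotations and taxonomy for many genomes.

The database holds one row per protein-coding gene: its genomic location
(genome, contig, 1-based inclusive start/end, strand) and the set of Pfam
domains annotated on the encoded protein.  Two global quantities feed the
enrichment statistic: ``Sd``, the total number of genes, and ``Nod[d]``,
the number of genes carrying domain ``d``.  A domain repeated within one
protein counts once — occurrence is per-gene presence, which guarantees
``Nod <= Sd``.

Coordinates follow the GFF convention (1-based, inclusive).  Taxonomy is a
flat five-rank lineage (phylum, class, order, family, genus) matched by
exact string; missing ranks are stored as the explicit sentinel
:data:`MISSING_RANK`, never dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    EmptyDatabaseError,
    EmptySubsetError,
    IntegrityError,
    ParameterError,
    ParseError,
    SchemaError,
)

logger = logging.getLogger("genecontext")

#: Sentinel for an absent taxonomic rank.
MISSING_RANK = "unclassified"

#: The five supported taxonomic ranks, broadest first.
RANKS = ("phylum", "class", "order", "family", "genus")

GENE_TABLE_COLUMNS = (
    "gene_id",
    "genome_id",
    "contig_id",
    "start",
    "end",
    "strand",
    "domains",
)

_STRAND_ALIASES = {"+": "+", "-": "-", "−": "-"}  # accept unicode minus


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene: location plus the set of Pfam domains it carries."""

    gene_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    domains: frozenset[str]

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise IntegrityError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise IntegrityError(f"gene {self.gene_id}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class TaxonomyLineage:
    """Five-rank lineage of one genome; absent ranks hold :data:`MISSING_RANK`."""

    genome_id: str
    phylum: str = MISSING_RANK
    class_: str = MISSING_RANK
    order: str = MISSING_RANK
    family: str = MISSING_RANK
    genus: str = MISSING_RANK

    def rank(self, rank: str) -> str:
        if rank not in RANKS:
            raise KeyError(f"unknown rank {rank!r}; expected one of {RANKS}")
        return getattr(self, "class_" if rank == "class" else rank)

    @classmethod
    def missing(cls, genome_id: str) -> "TaxonomyLineage":
        return cls(genome_id=genome_id)


def _parse_domains(cell: str) -> frozenset[str]:
    """Split a semicolon- or comma-separated accession list; empty cell allowed."""
    cell = cell.strip()
    if not cell:
        return frozenset()
    return frozenset(
        tok.strip() for tok in cell.replace(",", ";").split(";") if tok.strip()
    )


@dataclass
class GenomeDatabase:
    """Gene annotations indexed by contig position and by domain.

    Attributes
    ----------
    genes:
        One row per gene with the :data:`GENE_TABLE_COLUMNS` schema;
        ``domains`` holds frozensets.  Row order is the load order.
    taxonomy:
        genome_id -> :class:`TaxonomyLineage`; genomes absent from the
        taxonomy table get an all-missing lineage.
    """

    genes: pd.DataFrame
    taxonomy: dict[str, TaxonomyLineage] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._build_indexes()

    # ------------------------------------------------------------------
    # indexes and cached counts
    def _build_indexes(self) -> None:
        g = self.genes
        self._sd = int(len(g))
        # per-domain gene counts (presence, not hit copies)
        nod: dict[str, int] = {}
        domain_rows: dict[str, list[int]] = {}
        for row, doms in enumerate(g["domains"].to_numpy()):
            for d in doms:
                nod[d] = nod.get(d, 0) + 1
                domain_rows.setdefault(d, []).append(row)
        self._nod = nod
        self._domain_rows = {d: np.asarray(r, dtype=np.intp) for d, r in domain_rows.items()}
        # per-contig positional index, sorted by start
        self._contig_index: dict[tuple[str, str], dict[str, np.ndarray]] = {}
        by = g.groupby(["genome_id", "contig_id"], sort=False).indices
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        for key, rows in by.items():
            rows = np.asarray(rows, dtype=np.intp)
            order = np.argsort(starts[rows], kind="stable")
            rows = rows[order]
            self._contig_index[key] = {
                "rows": rows,
                "start": starts[rows],
                "end": ends[rows],
            }

    # ------------------------------------------------------------------
    @property
    def sd(self) -> int:
        """Total number of genes in the database (symbol Sd)."""
        return self._sd

    @property
    def nod_index(self) -> dict[str, int]:
        """domain -> number of genes carrying it (symbol Nod)."""
        return dict(self._nod)

    def nod(self, domain: str) -> int:
        return self._nod.get(domain, 0)

    def has_domain(self, domain: str) -> bool:
        return domain in self._nod

    @property
    def genome_ids(self) -> list[str]:
        return list(dict.fromkeys(self.genes["genome_id"]))

    def lineage(self, genome_id: str) -> TaxonomyLineage:
        return self.taxonomy.get(genome_id, TaxonomyLineage.missing(genome_id))

    def record(self, row: int) -> GeneRecord:
        r = self.genes.iloc[row]
        return GeneRecord(
            gene_id=r["gene_id"],
            genome_id=r["genome_id"],
            contig_id=r["contig_id"],
            start=int(r["start"]),
            end=int(r["end"]),
            strand=r["strand"],
            domains=r["domains"],
        )

    def records(self, rows) -> list[GeneRecord]:
        return [self.record(int(r)) for r in rows]

    def contig_rows(self, genome_id: str, contig_id: str) -> dict[str, np.ndarray]:
        """Sorted positional index (rows, start, end) for one contig."""
        return self._contig_index[(genome_id, contig_id)]

    # ------------------------------------------------------------------
    def genes_with_domain(
        self,
        domain: str,
        taxon_filter: tuple[str, str] | None = None,
    ) -> tuple[list[GeneRecord], bool]:
        """All genes carrying ``domain``, optionally restricted to a taxon.

        Returns ``(records, found)``: an absent domain yields an empty list
        with ``found=False`` rather than an exception, so callers can
        distinguish "no such domain" from "domain exists but filtered out".
        Order is deterministic: (genome_id, contig_id, start).
        """
        found = domain in self._domain_rows
        rows = self._domain_rows.get(domain, np.empty(0, dtype=np.intp))
        sub = self.genes.iloc[rows]
        if taxon_filter is not None:
            rank, name = taxon_filter
            keep = sub["genome_id"].map(lambda gid: self.lineage(gid).rank(rank) == name)
            sub = sub[keep.to_numpy(dtype=bool)] if len(sub) else sub
        sub = sub.sort_values(["genome_id", "contig_id", "start"], kind="stable")
        # self.genes carries a RangeIndex, so index labels are row positions
        return self.records(sub.index), found

    def subset_by_taxon(self, rank: str, name: str) -> "GenomeDatabase":
        """New database restricted to genomes whose lineage matches at ``rank``.

        ``Sd`` and the domain counts are recomputed over the subset.
        """
        if rank not in RANKS:
            raise ParameterError(f"unknown rank {rank!r}; expected one of {RANKS}")
        keep_genomes = {
            gid for gid in self.genes["genome_id"].unique()
            if self.lineage(gid).rank(rank) == name
        }
        if not keep_genomes:
            raise EmptySubsetError(f"no genomes with {rank}={name!r}")
        mask = self.genes["genome_id"].isin(keep_genomes).to_numpy()
        sub = self.genes[mask].reset_index(drop=True)
        tax = {gid: lin for gid, lin in self.taxonomy.items() if gid in keep_genomes}
        return GenomeDatabase(genes=sub, taxonomy=tax)


# ----------------------------------------------------------------------
# loaders

def load_gene_table(path, dialect: str = "tsv") -> GenomeDatabase:
    """Load and validate a gene annotation table into a :class:`GenomeDatabase`.

    ``dialect='tsv'`` expects a header row with columns
    ``gene_id genome_id contig_id start end strand domains`` (domains =
    semicolon- or comma-separated Pfam accessions, possibly empty).
    ``dialect='gff3'`` reads GFF3 ``gene``/``CDS`` features, mapping the
    ``ID`` attribute to gene_id and a ``pfam=`` attribute to domains.
    """
    if dialect == "gff3":
        frame = _read_gff3(path)
    elif dialect == "tsv":
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    else:
        raise SchemaError(f"unknown gene-table dialect {dialect!r}")
    missing = [c for c in GENE_TABLE_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"gene table missing column(s): {', '.join(missing)}")
    if len(frame) == 0:
        raise EmptyDatabaseError(f"gene table {path} contains no rows")

    frame = frame.loc[:, list(GENE_TABLE_COLUMNS)].copy()
    try:
        frame["start"] = frame["start"].astype(np.int64)
        frame["end"] = frame["end"].astype(np.int64)
    except ValueError as exc:
        raise ParseError(f"non-integer coordinate in gene table: {exc}") from exc

    frame["strand"] = frame["strand"].map(lambda s: _STRAND_ALIASES.get(s.strip()))
    bad_strand = frame["strand"].isna()
    if bad_strand.any():
        ids = frame.loc[bad_strand, "gene_id"].tolist()[:5]
        raise IntegrityError(f"unknown strand for gene(s): {', '.join(ids)}")
    bad_coord = (frame["start"] > frame["end"]) | (frame["start"] < 1)
    if bad_coord.any():
        ids = frame.loc[bad_coord, "gene_id"].tolist()[:5]
        raise IntegrityError(
            f"start > end or start < 1 for gene(s): {', '.join(ids)}"
        )
    dup = frame["gene_id"].duplicated(keep=False)
    if dup.any():
        ids = sorted(set(frame.loc[dup, "gene_id"]))[:5]
        raise IntegrityError(f"duplicate gene_id(s): {', '.join(ids)}")

    # duplicate (gene_id, domain) pairs collapse naturally into the set
    frame["domains"] = frame["domains"].map(_parse_domains)
    return GenomeDatabase(genes=frame.reset_index(drop=True))


def _read_gff3(path) -> pd.DataFrame:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    rows = []
    for feat in db.all_features():
        if feat.featuretype not in ("gene", "CDS"):
            continue
        gene_id = (feat.attributes.get("ID") or [feat.id])[0]
        pfam = ";".join(feat.attributes.get("pfam", []))
        rows.append(
            {
                "gene_id": gene_id,
                "genome_id": (feat.attributes.get("genome") or [feat.seqid])[0],
                "contig_id": feat.seqid,
                "start": str(feat.start),
                "end": str(feat.end),
                "strand": feat.strand,
                "domains": pfam,
            }
        )
    return pd.DataFrame(rows, columns=list(GENE_TABLE_COLUMNS), dtype=str)


def load_taxonomy(path) -> dict[str, TaxonomyLineage]:
    """Load the taxonomy TSV ``genome_id phylum class order family genus``.

    Blank rank cells become :data:`MISSING_RANK`.  Duplicate genome rows are
    an integrity error; malformed rows raise :class:`ParseError` with the
    line number.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    expected = ["genome_id", *RANKS]
    missing = [c for c in expected if c not in frame.columns]
    if missing:
        raise SchemaError(f"taxonomy table missing column(s): {', '.join(missing)}")
    dup = frame["genome_id"].duplicated(keep=False)
    if dup.any():
        ids = sorted(set(frame.loc[dup, "genome_id"]))[:5]
        raise IntegrityError(f"duplicate taxonomy rows for genome(s): {', '.join(ids)}")
    out: dict[str, TaxonomyLineage] = {}
    for i in range(len(frame)):
        gid = str(frame["genome_id"].iat[i]).strip()
        if not gid:
            raise ParseError(f"taxonomy line {i + 2}: empty genome_id")
        vals = {}
        for rank in RANKS:
            v = str(frame[rank].iat[i]).strip()
            vals["class_" if rank == "class" else rank] = v or MISSING_RANK
        out[gid] = TaxonomyLineage(genome_id=gid, **vals)
    return out


def load_database(gene_path, taxonomy_path=None, dialect: str = "tsv") -> GenomeDatabase:
    """Load genes and (optionally) taxonomy into one database.

    Genomes present in the gene table but absent from the taxonomy table get
    an all-missing lineage and a logged warning.
    """
    db = load_gene_table(gene_path, dialect=dialect)
    if taxonomy_path is not None:
        tax = load_taxonomy(taxonomy_path)
        for gid in db.genes["genome_id"].unique():
            if gid not in tax:
                logger.warning("genome %s has no taxonomy row; lineage set to missing", gid)
                tax[gid] = TaxonomyLineage.missing(gid)
        db.taxonomy = tax
    return db
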