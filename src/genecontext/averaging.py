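"""Subtaxon averaging: equalize each subtaxon's neighborhood contribution.

Genome databases oversample some taxa (e.g. thousands of near-identical
pathogen strains).  A domain co-localization private to one oversampled
genus can then dominate a database-wide analysis.  The averaging procedure
groups the query neighborhoods by the query genome's lineage at a chosen
rank, keeps only subtaxa represented by at least ``min_genomes`` genomes in
the database (default 25), finds the subtaxon with the most neighborhoods
(n_sub_max) and tops every other subtaxon up to n_sub_max by drawing
neighborhoods from it at random with replacement.  Every retained subtaxon
then contributes exactly n_sub_max neighborhood entries to the enrichment.

Only the neighborhood set is balanced; the background counts (Nod, Sd) are
taken, unweighted, from the genomes of the retained subtaxa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptySubsetError, ParameterError
from .genome_db import MISSING_RANK, GenomeDatabase, RANKS
from .neighborhood import Neighborhood, QuerySpec, extract_all, resolve_query

DEFAULT_MIN_GENOMES = 25


@dataclass
class SubtaxonGroup:
    """Neighborhoods whose query genomes share one taxon name at a rank."""

    rank: str
    name: str
    neighborhoods: list[Neighborhood]
    n_genomes: int  # genomes of this subtaxon in the database

    @property
    def n_sub(self) -> int:
        return len(self.neighborhoods)


def group_by_subtaxon(
    db: GenomeDatabase,
    neighborhoods: list[Neighborhood],
    rank: str,
    min_genomes: int = DEFAULT_MIN_GENOMES,
) -> list[SubtaxonGroup]:
    """Partition neighborhoods by the query genome's lineage at ``rank``.

    Subtaxa whose *database* genome count (not neighborhood count) is below
    ``min_genomes`` are dropped, as are neighborhoods from genomes with a
    missing rank; both removals are logged.  Raises
    :class:`EmptySubsetError` when nothing survives.
    """
    if rank not in RANKS:
        raise ParameterError(f"rank must be one of {RANKS}")
    import logging

    log = logging.getLogger("genecontext")
    genome_counts: dict[str, int] = {}
    for gid in db.genes["genome_id"].unique():
        name = db.lineage(gid).rank(rank)
        genome_counts[name] = genome_counts.get(name, 0) + 1

    buckets: dict[str, list[Neighborhood]] = {}
    n_missing = 0
    for nb in neighborhoods:
        name = db.lineage(nb.genome_id).rank(rank)
        if name == MISSING_RANK:
            n_missing += 1
            continue
        buckets.setdefault(name, []).append(nb)
    if n_missing:
        log.info("averaging: dropped %d neighborhoods with missing %s", n_missing, rank)

    groups = []
    for name in sorted(buckets):
        n_gen = genome_counts.get(name, 0)
        if n_gen < min_genomes:
            log.info(
                "averaging: subtaxon %s=%s dropped (%d genomes < %d)",
                rank, name, n_gen, min_genomes,
            )
            continue
        groups.append(
            SubtaxonGroup(rank=rank, name=name, neighborhoods=buckets[name], n_genomes=n_gen)
        )
    if not groups:
        raise EmptySubsetError(
            f"no subtaxon at rank {rank!r} retains neighborhoods "
            f"(min_genomes={min_genomes})"
        )
    return groups


def balance_subtaxa(
    groups: list[SubtaxonGroup], seed: int
) -> tuple[list[Neighborhood], pd.DataFrame]:
    """Top every subtaxon up to the largest one by resampling.

    Let ``n_max = max n_sub``.  Each group contributes its original
    neighborhoods plus ``n_max - n_sub`` draws *with replacement* from the
    same group, so every group contributes exactly ``n_max`` entries and
    the balanced total is ``len(groups) * n_max``.  Returns the balanced
    list and a sidecar report
    ``rank subtaxon n_genomes n_neighborhoods n_contributed seed``.
    """
    if not groups:
        raise ParameterError("balance_subtaxa requires >= 1 group")
    rng = np.random.default_rng(seed)
    n_max = max(g.n_sub for g in groups)
    balanced: list[Neighborhood] = []
    report = []
    for g in groups:
        entries = list(g.neighborhoods)
        deficit = n_max - g.n_sub
        if deficit > 0:
            picks = rng.integers(0, g.n_sub, size=deficit)
            entries.extend(g.neighborhoods[i] for i in picks)
        balanced.extend(entries)
        report.append(
            {
                "rank": g.rank,
                "subtaxon": g.name,
                "n_genomes": g.n_genomes,
                "n_neighborhoods": g.n_sub,
                "n_contributed": len(entries),
                "seed": seed,
            }
        )
    return balanced, pd.DataFrame(report)


def averaged_enrich(
    db: GenomeDatabase,
    spec: QuerySpec,
    rank: str,
    params,
    seed: int,
    min_genomes: int = DEFAULT_MIN_GENOMES,
):
    """Run the full subtaxon-averaged enrichment pipeline.

    resolve query -> extract neighborhoods -> group by ``rank`` ->
    balance -> enrich, with background counts (Nod, Sd) recomputed over
    the genomes of the retained subtaxa only.  Returns
    ``(rows, sidecar_report)``.
    """
    from .enrichment import enrich

    res = resolve_query(db, spec)
    if not res.genes:
        raise EmptySubsetError("query resolved to no genes")
    neighborhoods = extract_all(db, res.genes, spec.radius_bp, spec.strand_mode)
    groups = group_by_subtaxon(db, neighborhoods, rank, min_genomes=min_genomes)
    balanced, report = balance_subtaxa(groups, seed=seed)
    retained = {g.name for g in groups}
    keep_genomes = {
        gid for gid in db.genes["genome_id"].unique()
        if db.lineage(gid).rank(rank) in retained
    }
    mask = db.genes["genome_id"].isin(keep_genomes).to_numpy()
    background = GenomeDatabase(
        genes=db.genes[mask].reset_index(drop=True),
        taxonomy={g: l for g, l in db.taxonomy.items() if g in keep_genomes},
    )
    rows = enrich(background, balanced, params, query_domain=spec.pfam_id)
    return rows, report
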