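"""Poisson upper-tail enrichment of domain occurrences in query neighborhoods.

For each candidate target domain the observed occurrence count ``k`` (genes
carrying the domain, summed over all query neighborhoods) is compared with
its expectation under random placement,

    lambda = Nn * Nl * Nod / Sd,

where ``Nn`` is the number of query neighborhoods, ``Nl`` the mean
neighborhood size in genes, ``Nod`` the number of genes in the database
carrying the domain and ``Sd`` the database size in genes.  Each of the
``Nn * Nl`` gene slots is approximately an independent Bernoulli(Nod/Sd)
trial, so under the null ``E[k] = lambda`` exactly and the Poisson tail

    P score = P(X >= k),  X ~ Poisson(lambda)

is a (slightly conservative) significance score.  Domains observed less
often than expected (``k < lambda``) are excluded before multiple-testing
correction; the retained set is corrected (Bonferroni or
Benjamini-Hochberg) and filtered by the P-score cutoff and the minimum
fraction of neighborhoods in which the domain must appear.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError
from .genome_db import GenomeDatabase
from .neighborhood import Neighborhood, mean_neighborhood_size

CORRECTIONS = ("none", "bonferroni", "benjamini_hochberg")

DEFAULT_PSCORE_CUTOFF = 1e-5
DEFAULT_MIN_PRESENCE = 0.05


@dataclass(frozen=True)
class EnrichmentParams:
    """Significance thresholds and options of one enrichment run.

    ``pscore_cutoff`` (default 1e-5) and ``min_presence_fraction`` (default
    0.05, i.e. present in at least 5% of query neighborhoods) define which
    rows reach the final table.
    """

    pscore_cutoff: float = DEFAULT_PSCORE_CUTOFF
    min_presence_fraction: float = DEFAULT_MIN_PRESENCE
    correction: str = "none"
    radius_bp: int = 5000
    strand_mode: str = "all"

    def __post_init__(self) -> None:
        if not (0 < self.pscore_cutoff <= 1):
            raise ParameterError("pscore_cutoff must be in (0, 1]")
        if not (0 <= self.min_presence_fraction <= 1):
            raise ParameterError("min_presence_fraction must be in [0, 1]")
        if self.correction not in CORRECTIONS:
            raise ParameterError(f"correction must be one of {CORRECTIONS}")


@dataclass
class EnrichmentRow:
    """Statistics for one target domain in the query neighborhoods."""

    domain: str
    k: int
    nod: int
    lam: float
    p_score: float
    p_corrected: float
    presence_fraction: float
    is_query: bool = False
    name: str = ""
    description: str = ""
    go_terms: list = field(default_factory=list)


def expected_lambda(nn: int, nl: float, nod: int, sd: int) -> float:
    """Expected occurrences of a domain in the query neighborhoods."""
    if sd < 1:
        raise ParameterError("Sd must be >= 1")
    if nn < 1 or nl <= 0:
        raise ParameterError("Nn must be >= 1 and Nl > 0")
    if not (0 <= nod <= sd):
        raise ParameterError(f"Nod must be in [0, Sd], got Nod={nod}, Sd={sd}")
    return nn * nl * nod / sd


def poisson_pscore(k: int, lam: float) -> float:
    """Upper-tail Poisson probability P(X >= k) for X ~ Poisson(lam).

    Uses the survival function (regularized incomplete gamma), not naive
    ``1 - sum``: finite and accurate for k up to 1e4 and lam up to 1e3 and
    beyond, where term-by-term summation in double precision cancels
    catastrophically.
    """
    if k < 0 or lam < 0:
        raise ParameterError("k and lambda must be non-negative")
    if k == 0:
        return 1.0
    return float(stats.poisson.sf(k - 1, lam))


def count_in_neighborhoods(
    neighborhoods: list[Neighborhood], domain: str
) -> tuple[int, float]:
    """Occurrence count ``k`` and presence fraction of one domain.

    ``k`` sums per-gene presence over neighborhoods (a domain carried by
    three member genes of one neighborhood contributes 3, matching the
    per-gene convention of ``Nod``); the presence fraction is the share of
    neighborhoods containing the domain at least once.
    """
    if not neighborhoods:
        raise ParameterError("count_in_neighborhoods requires >= 1 neighborhood")
    k = sum(n.domain_multiset.get(domain, 0) for n in neighborhoods)
    present = sum(1 for n in neighborhoods if domain in n.domain_multiset)
    return int(k), present / len(neighborhoods)


def correct_pvalues(p: list[float], method: str = "none") -> list[float]:
    """Multiple-testing adjustment of a p-value vector.

    ``bonferroni`` -> min(1, m*p); ``benjamini_hochberg`` -> step-up
    adjusted values; ``none`` -> identity.
    """
    if method not in CORRECTIONS:
        raise ParameterError(f"correction must be one of {CORRECTIONS}")
    arr = np.asarray(p, dtype=float)
    if arr.size and (arr.min() < 0 or arr.max() > 1):
        raise ParameterError("p-values must lie in [0, 1]")
    if method == "none" or arr.size == 0:
        return [float(x) for x in arr]
    sm_method = "bonferroni" if method == "bonferroni" else "fdr_bh"
    _, adjusted, _, _ = multipletests(arr, alpha=0.05, method=sm_method)
    return [float(x) for x in adjusted]


def compute_candidate_stats(
    db: GenomeDatabase,
    neighborhoods: list[Neighborhood],
    query_domain: str | None = None,
) -> pd.DataFrame:
    """Raw statistics for every candidate domain, before any filtering.

    Candidates are the union of the neighborhoods' domain sets.  Columns:
    domain, k, nod, lam, p_score, presence_fraction, is_query.  Useful for
    calibration studies; :func:`enrich` applies the exclusion, correction
    and reporting thresholds on top of this table.
    """
    if not neighborhoods:
        raise ParameterError("enrichment requires >= 1 neighborhood")
    nn = len(neighborhoods)
    nl = mean_neighborhood_size(neighborhoods)
    sd = db.sd
    ks: dict[str, int] = {}
    present: dict[str, int] = {}
    for nb in neighborhoods:
        for d, c in nb.domain_multiset.items():
            ks[d] = ks.get(d, 0) + c
            present[d] = present.get(d, 0) + 1
    domains = sorted(ks)
    k_arr = np.array([ks[d] for d in domains], dtype=np.int64)
    nod_arr = np.array([db.nod(d) for d in domains], dtype=np.int64)
    lam_arr = nn * nl * nod_arr / sd
    # vectorized survival function; k=0 rows are P=1 by definition
    p_arr = stats.poisson.sf(k_arr - 1, lam_arr)
    p_arr = np.where(k_arr == 0, 1.0, p_arr)
    return pd.DataFrame(
        {
            "domain": domains,
            "k": k_arr,
            "nod": nod_arr,
            "lam": lam_arr,
            "p_score": p_arr,
            "presence_fraction": np.array([present[d] for d in domains]) / nn,
            "is_query": [d == query_domain for d in domains],
        }
    )


def enrich(
    db: GenomeDatabase,
    neighborhoods: list[Neighborhood],
    params: EnrichmentParams = EnrichmentParams(),
    query_domain: str | None = None,
    pfam_metadata: pd.DataFrame | None = None,
) -> list[EnrichmentRow]:
    """Full enrichment table for one set of query neighborhoods.

    Pipeline: candidate stats -> drop domains with ``k < lambda`` (observed
    less often than a random neighborhood would show) -> multiple-testing
    correction over the retained set -> keep rows passing the P-score
    cutoff and minimum presence fraction -> sort by ascending p_score,
    ties broken by descending k then accession.
    """
    table = compute_candidate_stats(db, neighborhoods, query_domain=query_domain)
    table = table[table["k"] >= table["lam"]].reset_index(drop=True)
    table["p_corrected"] = correct_pvalues(table["p_score"].tolist(), params.correction)
    keep = (table["p_score"] < params.pscore_cutoff) & (
        table["presence_fraction"] >= params.min_presence_fraction
    )
    table = table[keep]
    table = table.sort_values(
        ["p_score", "k", "domain"], ascending=[True, False, True], kind="stable"
    )
    meta = {}
    if pfam_metadata is not None:
        meta = {
            r["accession"]: (r.get("name", ""), r.get("description", ""))
            for _, r in pfam_metadata.iterrows()
        }
    rows = []
    for r in table.itertuples(index=False):
        name, desc = meta.get(r.domain, ("", ""))
        rows.append(
            EnrichmentRow(
                domain=r.domain,
                k=int(r.k),
                nod=int(r.nod),
                lam=float(r.lam),
                p_score=float(r.p_score),
                p_corrected=float(r.p_corrected),
                presence_fraction=float(r.presence_fraction),
                is_query=bool(r.is_query),
                name=name,
                description=desc,
            )
        )
    return rows


def rows_to_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    """Serialize enrichment rows to the output CSV schema."""
    return pd.DataFrame(
        {
            "domain": [r.domain for r in rows],
            "name": [r.name for r in rows],
            "description": [r.description for r in rows],
            "p_score": [r.p_score for r in rows],
            "p_corrected": [r.p_corrected for r in rows],
            "k": [r.k for r in rows],
            "Nod": [r.nod for r in rows],
            "lambda": [r.lam for r in rows],
            "percentage_in_neighborhoods": [100.0 * r.presence_fraction for r in rows],
            "is_query": [r.is_query for r in rows],
            "go_ids": [";".join(t.go_id for t in r.go_terms) for r in rows],
            "go_terms": [";".join(t.name for t in r.go_terms) for r in rows],
        }
    )


def taxonomy_report(db: GenomeDatabase, query_genes) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Where the query was found: per-gene lineage rows + per-rank genome counts.

    Returns ``(per_gene, per_rank)``.  ``per_gene`` has one row per query
    gene with its genome and full lineage; ``per_rank`` counts distinct
    query-carrying genomes per taxon name at each rank.
    """
    recs = []
    for g in query_genes:
        lin = db.lineage(g.genome_id)
        recs.append(
            {
                "gene_id": g.gene_id,
                "genome_id": g.genome_id,
                "phylum": lin.phylum,
                "class": lin.class_,
                "order": lin.order,
                "family": lin.family,
                "genus": lin.genus,
            }
        )
    per_gene = pd.DataFrame(
        recs, columns=["gene_id", "genome_id", "phylum", "class", "order", "family", "genus"]
    )
    counts = []
    if len(per_gene):
        unique_genomes = per_gene.drop_duplicates("genome_id")
        for rank in ("phylum", "class", "order", "family", "genus"):
            for name, cnt in unique_genomes[rank].value_counts().items():
                counts.append({"rank": rank, "name": name, "n_genomes": int(cnt)})
    per_rank = pd.DataFrame(counts, columns=["rank", "name", "n_genomes"])
    return per_gene, per_rank
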