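"""Jaccard similarity of neighborhood domain compositions and single-linkage
clustering.

Each neighborhood is reduced to its set of domains (presence, not counts);
two neighborhoods are compared by the Jaccard index J = |A∩B| / |A∪B| and
clustered on the distance d = 1 − J with single (minimum) linkage.  Two
neighborhoods with no annotated domains at all get J = 0 by convention
(with a warning): an empty composition is no evidence of similarity, and a
silent 0/0 → 1 would glue all unannotated neighborhoods together.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .errors import ParameterError
from .genome_db import GenomeDatabase
from .neighborhood import Neighborhood

DEFAULT_FEATURED_THRESHOLD = 0.9


def jaccard_index(a: frozenset, b: frozenset) -> float:
    """|A∩B| / |A∪B|; both sets empty → 0.0 with a warning."""
    union = len(a | b)
    if union == 0:
        warnings.warn(
            "Jaccard index of two empty domain sets defined as 0", stacklevel=2
        )
        return 0.0
    return len(a & b) / union


@dataclass
class SimilarityMatrix:
    """Pairwise Jaccard indices over neighborhoods plus their linkage tree."""

    labels: list[str]
    values: np.ndarray  # symmetric, [0,1], diagonal 1 for nonempty sets
    linkage: np.ndarray  # scipy linkage matrix on d = 1 - J
    order: list[int]  # leaf ordering of the tree

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def similarity_matrix(neighborhoods: list[Neighborhood]) -> SimilarityMatrix:
    """All-pairs Jaccard similarity on the neighborhoods' domain sets.

    Label order is input order; labels are query gene IDs.  Computed via a
    binary membership matrix so the all-pairs step is a single matrix
    product.
    """
    if len(neighborhoods) < 2:
        raise ParameterError("similarity_matrix requires >= 2 neighborhoods")
    labels = [n.query_gene_id for n in neighborhoods]
    sets = [n.domain_set for n in neighborhoods]
    vocab = sorted(set().union(*sets))
    if vocab:
        m = np.zeros((len(sets), len(vocab)), dtype=np.float64)
        pos = {d: j for j, d in enumerate(vocab)}
        for i, s in enumerate(sets):
            for d in s:
                m[i, pos[d]] = 1.0
        inter = m @ m.T
        sizes = m.sum(axis=1)
        union = sizes[:, None] + sizes[None, :] - inter
        with np.errstate(invalid="ignore"):
            values = np.where(union > 0, inter / np.maximum(union, 1e-300), 0.0)
    else:
        warnings.warn("all neighborhoods have empty domain sets; similarities set to 0")
        values = np.zeros((len(sets), len(sets)))
    if any(len(s) == 0 for s in sets) and vocab:
        warnings.warn("neighborhood(s) with empty domain sets: their similarities are 0")
    np.fill_diagonal(values, [1.0 if len(s) else 0.0 for s in sets])

    dist = 1.0 - values
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="single")
    from scipy.cluster.hierarchy import leaves_list

    order = [int(i) for i in leaves_list(z)]
    return SimilarityMatrix(labels=labels, values=values, linkage=z, order=order)


def single_linkage_cluster(
    matrix: SimilarityMatrix, cut: tuple[str, float]
) -> np.ndarray:
    """Flat clusters from the single-linkage tree.

    ``cut`` is ``('distance', t)`` — merge everything at cophenetic distance
    ``<= t`` in d = 1 − J — or ``('maxclust', n)`` for a target cluster
    count.  Cluster IDs are renumbered deterministically by first
    appearance in input order, starting at 1.
    """
    kind, value = cut
    if kind == "distance":
        if not (0 <= value <= 1 + 1e-9):
            raise ParameterError("distance cut must lie in [0, 1]")
        raw = fcluster(matrix.linkage, t=value, criterion="distance")
    elif kind == "maxclust":
        if value < 1 or int(value) != value:
            raise ParameterError("maxclust cut must be a positive integer")
        raw = fcluster(matrix.linkage, t=int(value), criterion="maxclust")
    else:
        raise ParameterError("cut must be ('distance', t) or ('maxclust', n)")
    remap: dict[int, int] = {}
    labels = np.empty(len(raw), dtype=np.int64)
    for i, c in enumerate(raw):
        if c not in remap:
            remap[c] = len(remap) + 1
        labels[i] = remap[c]
    return labels


def linkage_to_newick(matrix: SimilarityMatrix) -> str:
    """Serialize the merge tree as a Newick string with branch heights."""
    z = matrix.linkage
    n = len(matrix.labels)
    heights = {i: 0.0 for i in range(n)}
    nodes = {i: matrix.labels[i] for i in range(n)}
    for i, (a, b, h, _) in enumerate(z):
        a, b = int(a), int(b)
        la = h - heights[a]
        lb = h - heights[b]
        nodes[n + i] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
        heights[n + i] = h
    return nodes[n + len(z) - 1] + ";"


def annotate_clusters(
    neighborhoods: list[Neighborhood],
    labels: np.ndarray,
    db: GenomeDatabase,
    featured_threshold: float = DEFAULT_FEATURED_THRESHOLD,
) -> pd.DataFrame:
    """Per-cluster size, taxonomic composition and featured domains.

    Composition percentages (genus and family) sum to 100 within each
    cluster; "featured domains" are those present in at least
    ``featured_threshold`` of the cluster's neighborhoods (default 90%).
    """
    if len(labels) != len(neighborhoods):
        raise ParameterError("labels and neighborhoods must align")
    rows = []
    for cluster_id in sorted(set(int(c) for c in labels)):
        members = [nb for nb, c in zip(neighborhoods, labels) if int(c) == cluster_id]
        size = len(members)
        genus = pd.Series([db.lineage(nb.genome_id).genus for nb in members])
        family = pd.Series([db.lineage(nb.genome_id).family for nb in members])
        genus_pct = {k: 100.0 * v / size for k, v in genus.value_counts().items()}
        family_pct = {k: 100.0 * v / size for k, v in family.value_counts().items()}
        domain_presence: dict[str, int] = {}
        for nb in members:
            for d in nb.domain_set:
                domain_presence[d] = domain_presence.get(d, 0) + 1
        featured = sorted(
            d for d, c in domain_presence.items() if c / size >= featured_threshold
        )
        rows.append(
            {
                "cluster_id": cluster_id,
                "size": size,
                "genus_composition": ";".join(
                    f"{k}={v:.1f}%" for k, v in sorted(genus_pct.items())
                ),
                "family_composition": ";".join(
                    f"{k}={v:.1f}%" for k, v in sorted(family_pct.items())
                ),
                "featured_domains": ";".join(featured),
            }
        )
    return pd.DataFrame(rows)
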