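"""Pfam → Gene Ontology decoration of enrichment results.

Parses the GeneOntology ``external2go``-style pfam2go mapping, e.g.::

    ! comment lines start with "!"
    Pfam:PF00255 GSHPx > GO:glutathione peroxidase activity ; GO:0004602

A domain may map to zero or many terms.  GO aspect (molecular_function /
biological_process / cellular_component) is not derivable from pfam2go
alone; it is filled only when an optional GO metadata TSV
(``go_id aspect name``) is supplied.  Annotation is a pure decoration: it
never changes a row's statistics or the ordering of the table.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace

import pandas as pd

from .errors import FormatError

logger = logging.getLogger("genecontext")

_LINE_RE = re.compile(
    r"^Pfam:(?P<acc>PF\d{5})\s*(?P<pfname>\S*)\s*>\s*GO:(?P<goname>.*?)\s*;\s*(?P<goid>GO:\d{7})\s*$"
)


@dataclass(frozen=True)
class GoTerm:
    go_id: str
    name: str
    aspect: str = ""


def load_pfam2go(path, go_metadata: pd.DataFrame | None = None) -> dict[str, list[GoTerm]]:
    """Parse a pfam2go file into accession → list of GO terms.

    ``!`` comment lines are skipped; malformed lines are logged and counted,
    and a file with zero parsable lines raises :class:`FormatError`.
    """
    aspect_of: dict[str, str] = {}
    if go_metadata is not None:
        aspect_of = dict(zip(go_metadata["go_id"], go_metadata["aspect"]))
    mapping: dict[str, list[GoTerm]] = {}
    n_ok = n_bad = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("!"):
                continue
            m = _LINE_RE.match(line)
            if m is None:
                n_bad += 1
                logger.warning("pfam2go: skipping malformed line: %s", line[:120])
                continue
            n_ok += 1
            term = GoTerm(
                go_id=m["goid"],
                name=m["goname"],
                aspect=aspect_of.get(m["goid"], ""),
            )
            mapping.setdefault(m["acc"], []).append(term)
    if n_bad:
        logger.warning("pfam2go: skipped %d malformed line(s), parsed %d", n_bad, n_ok)
    if n_ok == 0:
        raise FormatError(f"{path}: no parsable pfam2go lines")
    return mapping


def annotate_results(rows, mapping: dict[str, list[GoTerm]]):
    """Fill ``go_terms`` on enrichment rows where a mapping exists.

    Rows are otherwise returned unchanged and in the same order; domains
    absent from the mapping keep an empty term list.  Idempotent.
    """
    return [replace(r, go_terms=list(mapping.get(r.domain, []))) for r in rows]
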