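"""Druggability annotation of causal genes.

Intersects a causal-gene list with a druggable-gene list (one symbol per
line) and summarises drug-gene interactions from a user-supplied table.
Symbol matching is exact after upper-casing; no alias resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

__all__ = ["DruggableAnnotation", "intersect_druggable", "load_druggable_list"]

log = logging.getLogger(__name__)


@dataclass
class DruggableAnnotation:
    gene: str
    druggable: bool
    interacting_drugs: list[str] = field(default_factory=list)


def load_druggable_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def intersect_druggable(causal_genes, druggable_list,
                        interactions: pd.DataFrame | None = None
                        ) -> tuple[list[DruggableAnnotation], dict]:
    """Flag druggable causal genes and collect their interacting drugs.

    Returns per-gene annotations (input order preserved, case-normalised
    symbols) and a summary: n_causal, n_druggable, n_drugs (deduplicated
    over druggable genes).  Duplicate symbols in the druggable list are
    deduplicated with a logged count.
    """
    causal = [str(g).upper() for g in causal_genes]
    raw = [str(g).upper() for g in druggable_list]
    druggable = set(raw)
    if len(druggable) < len(raw):
        log.info("deduplicated %d repeated druggable symbols",
                 len(raw) - len(druggable))

    drug_map: dict[str, list[str]] = {}
    if interactions is not None and len(interactions):
        tbl = interactions.copy()
        tbl["gene"] = tbl["gene"].astype(str).str.upper()
        for gene, grp in tbl.groupby("gene"):
            drug_map[gene] = sorted(set(grp["drug"].astype(str)))

    annotations = []
    seen = set()
    for g in causal:
        if g in seen:
            continue
        seen.add(g)
        flag = g in druggable
        annotations.append(DruggableAnnotation(
            gene=g, druggable=flag,
            interacting_drugs=drug_map.get(g, []) if flag else []))

    flagged = [a for a in annotations if a.druggable]
    all_drugs = sorted({d for a in flagged for d in a.interacting_drugs})
    summary = {"n_causal": len(annotations), "n_druggable": len(flagged),
               "n_drugs": len(all_drugs)}
    return annotations, summary
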