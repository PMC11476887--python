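"""Exercise-induced miRNA-target regulatory network.

An edge (miRNA, gene) enters the network iff both members are differentially
expressed with *opposite* log2 fold-change signs (the canonical signature of
target degradation) and the pair appears in a prediction table treated as a
whitelist.  No magnitude threshold is applied beyond the DE call itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

__all__ = ["RegulatoryNetwork", "build_network", "network_stats",
           "write_edges"]

log = logging.getLogger(__name__)


@dataclass
class RegulatoryNetwork:
    """Directed miRNA -> gene edges with expression-direction annotations."""

    edges: pd.DataFrame  # mirna, gene, mirna_lfc, gene_lfc, prediction_id
    mirna_lfc: dict[str, float] = field(default_factory=dict)
    gene_lfc: dict[str, float] = field(default_factory=dict)
    n_malformed_predictions: int = 0

    @property
    def edge_set(self) -> set[tuple[str, str]]:
        return set(zip(self.edges["mirna"], self.edges["gene"]))


def _de_lfc(results: pd.DataFrame, padj_threshold: float) -> dict[str, float]:
    sig = results[(results["padj"] < padj_threshold) & (results["log2fc"] != 0)]
    return dict(zip(sig["feature"], sig["log2fc"]))


def build_network(degs: pd.DataFrame, demirs: pd.DataFrame,
                  predictions: pd.DataFrame,
                  padj_threshold: float = 0.05) -> RegulatoryNetwork:
    """Intersect opposite-sign DE pairs with the prediction whitelist.

    ``degs``/``demirs`` are differential-expression result tables (columns
    ``feature``, ``log2fc``, ``padj``); ``predictions`` needs ``mirna`` and
    ``gene`` columns and optionally ``prediction_id``.  Malformed prediction
    rows (missing identifiers) are skipped and counted.  Empty DE sets give
    an empty network.
    """
    gene_lfc = _de_lfc(degs, padj_threshold)
    mirna_lfc = _de_lfc(demirs, padj_threshold)

    preds = predictions.copy()
    if "prediction_id" not in preds.columns:
        preds["prediction_id"] = [f"row{i}" for i in range(len(preds))]
    ok = preds["mirna"].notna() & preds["gene"].notna()
    ok &= preds["mirna"].astype(str).str.len().gt(0)
    ok &= preds["gene"].astype(str).str.len().gt(0)
    n_bad = int((~ok).sum())
    if n_bad:
        log.warning("skipped %d malformed prediction rows", n_bad)
    preds = preds[ok]

    rows = []
    seen: set[tuple[str, str]] = set()
    for pid, m, g in zip(preds["prediction_id"], preds["mirna"], preds["gene"]):
        if (m, g) in seen:
            continue
        lm = mirna_lfc.get(m)
        lg = gene_lfc.get(g)
        if lm is None or lg is None:
            continue
        if lm * lg < 0:  # opposite signs only
            rows.append((m, g, lm, lg, pid))
            seen.add((m, g))
    edges = pd.DataFrame(rows, columns=["mirna", "gene", "mirna_lfc",
                                        "gene_lfc", "prediction_id"])
    edges = edges.sort_values(["mirna", "gene"]).reset_index(drop=True)
    return RegulatoryNetwork(edges=edges, mirna_lfc=mirna_lfc,
                             gene_lfc=gene_lfc,
                             n_malformed_predictions=n_bad)


def network_stats(net: RegulatoryNetwork) -> dict:
    """Summary counts and degree distributions of a built network."""
    edges = net.edges
    mirna_deg = edges["mirna"].value_counts().to_dict()
    gene_deg = edges["gene"].value_counts().to_dict()
    return {
        "n_mirnas": int(edges["mirna"].nunique()),
        "n_targets": int(edges["gene"].nunique()),
        "n_edges": int(len(edges)),
        "mirna_degree": mirna_deg,
        "target_degree": gene_deg,
    }


def write_edges(net: RegulatoryNetwork, path, two_column: bool = False) -> None:
    """Edge list TSV; ``two_column`` writes just (mirna, gene) for graph tools."""
    cols = ["mirna", "gene"] if two_column else list(net.edges.columns)
    net.edges[cols].to_csv(path, sep="\t", index=False,
                           header=not two_column)
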