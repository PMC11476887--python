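"""Hypergeometric enrichment around the regulatory network.

Three flavours share one upper-tail hypergeometric primitive:

* upstream transcription factors of the network's miRNAs against a
  background miRNA universe (raw p < 0.05 by convention);
* trait-associated SNPs falling in transcriptional regulatory regions
  (TRRs: the +/-20 kb window around each gene's TSS), with BH FDR across
  traits;
* generic gene-set libraries for a query gene list (a local stand-in for
  web enrichment services), BH-adjusted.

Coordinate convention: SNP catalogs are 1-based positions; TRRs are
0-based half-open intervals, so a SNP at 1-based position p hits [s, e)
iff s <= p-1 < e.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import hypergeom

from .diffexpr import bh_adjust

__all__ = ["Trr", "make_trrs", "hypergeom_upper", "tf_enrichment",
           "map_snps_to_trrs", "trr_snp_enrichment", "geneset_enrichment",
           "load_catalog", "trrs_to_bed", "trrs_from_bed",
           "GENOME_WIDE_P", "TRR_FLANK"]

log = logging.getLogger(__name__)

GENOME_WIDE_P = 5e-8
TRR_FLANK = 20_000


@dataclass(frozen=True)
class Trr:
    """Transcriptional regulatory region: TSS +/- flank, clipped at 0."""

    gene: str
    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    strand: str = "+"


def make_trrs(annotation: pd.DataFrame, flank: int = TRR_FLANK) -> list[Trr]:
    """Build symmetric TSS windows from an annotation table.

    ``annotation`` needs columns gene, chrom, tss (1-based), strand.  Strand
    is carried through but ignored for window construction (windows are
    symmetric).  The window covers 1-based positions tss-flank .. tss+flank,
    i.e. the half-open 0-based interval [tss-1-flank, tss+flank), clipped at 0.
    """
    trrs = []
    for r in annotation.itertuples(index=False):
        tss0 = int(r.tss) - 1
        trrs.append(Trr(gene=str(r.gene), chrom=str(r.chrom),
                        start=max(0, tss0 - flank), end=tss0 + flank + 1,
                        strand=str(getattr(r, "strand", "+"))))
    return trrs


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws)."""
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ValueError(f"invalid hypergeometric bounds k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def tf_enrichment(network_mirnas, tf_table: pd.DataFrame, background_mirnas,
                  p_threshold: float = 0.05) -> pd.DataFrame:
    """Per-TF enrichment of the network miRNA set within a background universe.

    For each TF: N = background size, K = background miRNAs the TF regulates,
    n = network miRNAs, k = network miRNAs the TF regulates.  TFs regulating
    no background miRNA are skipped.  Flagged at raw p < ``p_threshold``.
    """
    network = set(network_mirnas)
    background = set(background_mirnas)
    if not network <= background:
        raise ValueError("background must contain every network miRNA")
    N, n = len(background), len(network)
    rows = []
    for tf, grp in tf_table.groupby("tf"):
        regulated = set(grp["mirna"]) & background
        K = len(regulated)
        if K == 0:
            continue
        k = len(regulated & network)
        p = hypergeom_upper(k, K, n, N)
        rows.append((tf, k, K, n, N, p))
    res = pd.DataFrame(rows, columns=["term", "k_in", "K_total", "n_draws",
                                      "N_pop", "p"])
    if len(res):
        res["significant"] = res["p"] < p_threshold
        res = res.sort_values(["p", "term"]).reset_index(drop=True)
    return res


def _trr_trees(trrs: list[Trr]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for t in trrs:
        if t.end <= t.start:
            continue
        trees.setdefault(t.chrom, IntervalTree()).addi(t.start, t.end, t.gene)
    return trees


def map_snps_to_trrs(catalog: pd.DataFrame, trrs: list[Trr]) -> pd.DataFrame:
    """Annotate each catalog SNP with whether it falls in any TRR.

    Returns the catalog plus ``in_trr`` (bool) and ``trr_genes``
    (comma-joined gene list).  SNPs on chromosomes absent from the TRR set
    are dropped with a logged count.
    """
    trees = _trr_trees(trrs)
    known = catalog["chrom"].isin(trees.keys())
    n_dropped = int((~known).sum())
    if n_dropped:
        log.warning("dropped %d catalog SNPs on unknown chromosomes", n_dropped)
    kept = catalog[known].copy()
    hits, genes = [], []
    for chrom, pos in zip(kept["chrom"], kept["pos"]):
        found = trees[chrom][int(pos) - 1]  # 1-based -> 0-based point query
        hits.append(bool(found))
        genes.append(",".join(sorted(iv.data for iv in found)))
    kept["in_trr"] = hits
    kept["trr_genes"] = genes
    return kept.reset_index(drop=True)


def trr_snp_enrichment(catalog: pd.DataFrame, trrs_network: list[Trr],
                       trrs_background: list[Trr],
                       fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Per-trait enrichment of catalog SNPs in network TRRs vs background TRRs.

    N = all-trait SNPs mappable to background TRRs, K = the trait's SNPs in
    background TRRs, n = all-trait SNPs in network TRRs, k = the trait's
    SNPs in network TRRs; p by the upper-tail hypergeometric, BH FDR across
    traits.
    """
    bg = map_snps_to_trrs(catalog, trrs_background)
    nw = map_snps_to_trrs(catalog, trrs_network)
    in_bg = bg[bg["in_trr"]]
    in_nw = nw[nw["in_trr"]]
    N = len(in_bg)
    n = len(in_nw)
    rows = []
    for trait in sorted(catalog["trait"].unique()):
        K = int((in_bg["trait"] == trait).sum())
        k = int((in_nw["trait"] == trait).sum())
        if N == 0 or K == 0:
            continue
        p = hypergeom_upper(k, K, n, N)
        rows.append((trait, k, K, n, N, p))
    res = pd.DataFrame(rows, columns=["term", "k_in", "K_total", "n_draws",
                                      "N_pop", "p"])
    if len(res):
        res["fdr"] = bh_adjust(res["p"].to_numpy())
        res["significant"] = res["fdr"] < fdr_threshold
        res = res.sort_values(["p", "term"]).reset_index(drop=True)
    return res


def geneset_enrichment(query_genes, library: dict[str, set], universe,
                       padj_threshold: float = 0.05) -> pd.DataFrame:
    """Hypergeometric over-representation of a query gene list in named sets."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query_genes) & universe
    if not set(query_genes) <= universe:
        raise ValueError("universe must contain every query gene")
    N, n = len(universe), len(query)
    rows = []
    for name, members in library.items():
        K = len(set(members) & universe)
        if K == 0:
            continue
        k = len(set(members) & query)
        rows.append((name, k, K, n, N, hypergeom_upper(k, K, n, N)))
    res = pd.DataFrame(rows, columns=["term", "k_in", "K_total", "n_draws",
                                      "N_pop", "p"])
    if len(res):
        res["fdr"] = bh_adjust(res["p"].to_numpy())
        res["significant"] = res["fdr"] < padj_threshold
        res = res.sort_values(["p", "term"]).reset_index(drop=True)
    return res


def load_catalog(path, p_max: float = GENOME_WIDE_P) -> pd.DataFrame:
    """Read a SNP-trait catalog TSV and apply the genome-wide filter p <= p_max."""
    cat = pd.read_csv(path, sep="\t")
    required = {"snp", "chrom", "pos", "trait", "p"}
    missing = required - set(cat.columns)
    if missing:
        raise ValueError(f"catalog missing columns: {sorted(missing)}")
    return cat[cat["p"] <= p_max].reset_index(drop=True)


def trrs_to_bed(trrs: list[Trr], path) -> None:
    with open(path, "w") as fh:
        for t in trrs:
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t{t.gene}\t0\t{t.strand}\n")


def trrs_from_bed(path) -> list[Trr]:
    trrs = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            chrom, start, end, gene = parts[0], int(parts[1]), int(parts[2]), parts[3]
            strand = parts[5] if len(parts) > 5 else "+"
            trrs.append(Trr(gene=gene, chrom=chrom, start=start, end=end,
                            strand=strand))
    return trrs
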