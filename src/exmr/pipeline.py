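"""End-to-end orchestration with config, logging and a reproducible report.

The pipeline chains: (optional) synthetic-study generation -> differential
expression on gene and miRNA counts -> miRNA-target network -> TF and
trait-SNP enrichment -> per-gene instrument selection and MR against every
outcome -> Bonferroni selection with sensitivity gates -> cross-phenotype
consistency -> druggable-gene intersection.  Every filter stage logs its
in/out counts and all outputs are TSV with ``#``-prefixed header metadata
(seed and config hash), so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotate, diffexpr, enrich, ivselect, mirnet, mrcore, synthio

__all__ = ["PipelineConfig", "run_all", "load_config", "save_config",
           "default_config"]

log = logging.getLogger("exmr.pipeline")


@dataclass
class PipelineConfig:
    """Every tunable of one pipeline run; round-trips through YAML."""

    seed: int = 0
    simulate: bool = True
    input_dir: str | None = None      # used when simulate is False
    # synthetic study size (desk-scale defaults)
    sim: dict = field(default_factory=lambda: {
        "n_genes": 400, "n_mirnas": 80, "n_samples_per_group": 4,
        "de_fraction": 0.15, "demir_fraction": 0.2, "lfc_magnitude": 1.5,
        "nb_dispersion": 0.05, "n_panel": 200, "n_blocks": 12,
        "snps_per_block": 8, "block_rho": 0.8, "n_exp": 588,
        "n_out": 20000, "theta": 0.35, "binary_outcome": True,
        "flip_fraction": 0.1,
    })
    n_mr_genes: int = 12
    n_causal: int = 4
    # thresholds (defaults mirror the analysis conventions)
    padj_de: float = 0.05
    cis_window: float = 1e6
    p_iv: float = 5e-8
    clump_r2: float = 0.05
    clump_kb: float = 10.0
    f_min: float = 10.0
    palindrome_tol: float = 0.08
    alpha_family: float = 0.05
    sens_alpha: float = 0.05
    boot: int = 1000
    phi: float = 1.0
    tf_p: float = 0.05
    trait_fdr: float = 0.05
    trr_flank: int = 20_000

    def validate(self) -> None:
        checks = [
            0 < self.padj_de < 1, self.cis_window > 0, 0 < self.p_iv < 1,
            0 <= self.clump_r2 <= 1, self.clump_kb > 0, self.f_min >= 0,
            0 <= self.palindrome_tol < 0.5, 0 < self.alpha_family < 1,
            0 < self.sens_alpha < 1, self.boot > 0, self.phi > 0,
        ]
        if not all(checks):
            raise synthio.ConfigError("pipeline thresholds out of range")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]


def default_config() -> PipelineConfig:
    return PipelineConfig()


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    cfg = PipelineConfig(**data)
    cfg.validate()
    return cfg


def save_config(cfg: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def _write_tsv(df: pd.DataFrame, path: Path, cfg: PipelineConfig,
               index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# exmr seed={cfg.seed} config={cfg.digest()}\n")
        df.to_csv(fh, sep="\t", index=index)


def _sim_config(cfg: PipelineConfig) -> synthio.SimConfig:
    return synthio.SimConfig(seed=cfg.seed, trr_flank=cfg.trr_flank,
                             **cfg.sim)


def run_all(cfg: PipelineConfig, outdir) -> dict:
    """Execute every stage; returns a summary dict and writes the report."""
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("exmr")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run_all_inner(cfg, outdir)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run_all_inner(cfg: PipelineConfig, outdir: Path) -> dict:
    log.info("pipeline start: seed=%d config=%s", cfg.seed, cfg.digest())

    # ---- inputs -----------------------------------------------------------
    if cfg.simulate:
        study = synthio.simulate_study(_sim_config(cfg),
                                       n_mr_genes=cfg.n_mr_genes,
                                       n_causal=cfg.n_causal)
        synthio.write_study(study, outdir / "inputs")
    else:
        if not cfg.input_dir:
            raise FileNotFoundError("input_dir required when simulate is false")
        study = _load_study(cfg)

    # ---- differential expression -----------------------------------------
    groups = pd.Series({s: s.split("_")[0] for s in study.gene_counts.columns})
    degs = diffexpr.nb_wald_test(study.gene_counts, groups)
    demirs = diffexpr.nb_wald_test(study.mirna_counts, groups)
    _write_tsv(degs, outdir / "de_genes.tsv", cfg)
    _write_tsv(demirs, outdir / "de_mirnas.tsv", cfg)
    g_up, g_dn, g_tot = diffexpr.sign_split(degs, cfg.padj_de)
    m_up, m_dn, m_tot = diffexpr.sign_split(demirs, cfg.padj_de)
    log.info("DE genes: %d (%d up + %d down) of %d", g_tot, g_up, g_dn,
             len(degs))
    log.info("DE miRNAs: %d (%d up + %d down) of %d", m_tot, m_up, m_dn,
             len(demirs))

    # ---- network ----------------------------------------------------------
    net = mirnet.build_network(degs, demirs, study.predictions, cfg.padj_de)
    stats = mirnet.network_stats(net)
    _write_tsv(net.edges, outdir / "network_edges.tsv", cfg)
    log.info("network: %d miRNAs -> %d targets, %d edges",
             stats["n_mirnas"], stats["n_targets"], stats["n_edges"])

    # ---- enrichment -------------------------------------------------------
    net_mirnas = sorted(set(net.edges["mirna"]))
    background_mirnas = list(study.mirna_counts.index)
    tf_res = enrich.tf_enrichment(net_mirnas, study.tf_table,
                                  background_mirnas, cfg.tf_p)
    _write_tsv(tf_res, outdir / "tf_enrichment.tsv", cfg)

    trrs_bg = enrich.make_trrs(study.annotation, cfg.trr_flank)
    net_genes = set(net.edges["gene"])
    trrs_net = [t for t in trrs_bg if t.gene in net_genes]
    catalog = study.catalog[study.catalog["p"] <= enrich.GENOME_WIDE_P]
    trait_res = enrich.trr_snp_enrichment(catalog, trrs_net, trrs_bg,
                                          cfg.trait_fdr)
    _write_tsv(trait_res, outdir / "trait_enrichment.tsv", cfg)
    enrich.trrs_to_bed(trrs_net, outdir / "network_trrs.bed")

    # ---- MR ---------------------------------------------------------------
    results_rows, sens_rows = [], []
    tables: dict[str, mrcore.CausalGeneTable] = {}
    for outcome, out_stats in study.outcomes.items():
        binary = study.outcome_binary.get(outcome, False)
        per_gene_results, per_gene_sens = [], []
        audit_all = []
        for gene, exp_stats in study.exposures.items():
            hset, counts = ivselect.select_instruments(
                exp_stats, out_stats, study.panel.dosages,
                tss=study.gene_tss[gene], gene=gene, outcome=outcome,
                cis_window=int(cfg.cis_window), p_thresh=cfg.p_iv,
                r2_max=cfg.clump_r2, window_kb=cfg.clump_kb,
                f_min=cfg.f_min, palindrome_eaf_tol=cfg.palindrome_tol)
            log.info("IVs %s vs %s: %s", gene, outcome,
                     " -> ".join(f"{k}:{v}" for k, v in counts.items()))
            audit_all.extend(dict(a, gene=gene) for a in hset.audit)
            if len(hset) == 0:
                log.info("gene %s untestable for %s (no instruments)",
                         gene, outcome)
                continue
            steiger = ivselect.steiger_filter(hset, alpha=cfg.sens_alpha)
            res, sens = mrcore.run_gene(hset, steiger=steiger, binary=binary,
                                        n_boot=cfg.boot, phi=cfg.phi,
                                        seed=cfg.seed)
            per_gene_results.append(res)
            per_gene_sens.append(sens)
            results_rows.extend(r.to_row() for r in res)
            sens_rows.append(dataclasses.asdict(sens))
        if per_gene_results:
            tables[outcome] = mrcore.select_causal(
                per_gene_results, per_gene_sens,
                m_tested=len(per_gene_results), outcome=outcome,
                alpha_family=cfg.alpha_family, sens_alpha=cfg.sens_alpha)
            log.info("%s: tested %d genes, selected %d at alpha=%.3g",
                     outcome, len(per_gene_results),
                     len(tables[outcome].selected), tables[outcome].alpha)
        if audit_all:
            _write_tsv(pd.DataFrame(audit_all),
                       outdir / f"iv_audit_{outcome}.tsv", cfg)

    _write_tsv(pd.DataFrame(results_rows), outdir / "mr_results.tsv", cfg)
    _write_tsv(pd.DataFrame(sens_rows), outdir / "mr_sensitivity.tsv", cfg)
    for outcome, table in tables.items():
        _write_tsv(table.selected, outdir / f"causal_{outcome}.tsv", cfg)
        # forest-plot-ready: gene, nsnp, estimate, CI
        forest = table.selected[["gene", "nsnp", "estimate"]].copy()
        forest["ci_low"] = table.selected["estimate"] - 1.96 * table.selected["se"]
        forest["ci_high"] = table.selected["estimate"] + 1.96 * table.selected["se"]
        _write_tsv(forest, outdir / f"forest_{outcome}.tsv", cfg)

    shared = None
    if len(tables) >= 2:
        binary_set = {o for o, b in study.outcome_binary.items() if b}
        shared = mrcore.cross_phenotype(tables, binary_outcomes=binary_set)
        log.info("cross-phenotype: %d unique causal genes, %d in all outcomes",
                 shared["n_unique"], shared["n_triple"])

    # ---- druggability -----------------------------------------------------
    causal_union = sorted({g for t in tables.values()
                           for g in t.selected["gene"]})
    annotations, drug_summary = annotate.intersect_druggable(
        causal_union, study.druggable)
    drug_df = pd.DataFrame(
        [{"gene": a.gene, "druggable": a.druggable,
          "drugs": ";".join(a.interacting_drugs)} for a in annotations])
    _write_tsv(drug_df, outdir / "druggable_annotation.tsv", cfg)

    summary = {
        "seed": cfg.seed, "config_hash": cfg.digest(),
        "de": {"genes": [g_up, g_dn, g_tot], "mirnas": [m_up, m_dn, m_tot]},
        "network": {k: stats[k] for k in ("n_mirnas", "n_targets", "n_edges")},
        "tf_significant": int(tf_res["significant"].sum()) if len(tf_res) else 0,
        "traits_flagged": sorted(trait_res.loc[trait_res["significant"], "term"])
        if len(trait_res) else [],
        "mr": {o: {"tested": t.m_tested, "selected": len(t.selected),
                   "alpha": t.alpha} for o, t in tables.items()},
        "cross_phenotype": shared,
        "druggable": drug_summary,
    }
    _write_report(summary, outdir / "report.md")
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    log.info("pipeline done")
    return summary


def _load_study(cfg: PipelineConfig) -> synthio.SyntheticStudy:
    """Load a previously written study directory (the TSV external interface)."""
    d = Path(cfg.input_dir)
    if not d.is_dir():
        raise FileNotFoundError(f"input directory not found: {d}")

    def _req(name: str) -> Path:
        p = d / name
        if not p.exists():
            raise FileNotFoundError(f"missing input file: {p}")
        return p

    gene_counts = pd.read_csv(_req("gene_counts.tsv"), sep="\t", index_col=0)
    mirna_counts = pd.read_csv(_req("mirna_counts.tsv"), sep="\t", index_col=0)
    panel = synthio.GenotypePanel(
        dosages=pd.read_csv(_req("panel_genotypes.tsv"), sep="\t", index_col=0),
        meta=pd.read_csv(_req("panel_snps.tsv"), sep="\t"))
    exposures = {}
    gene_tss = {}
    for p in sorted(d.glob("eqtl_*.tsv")):
        gene = p.stem.removeprefix("eqtl_")
        tab = pd.read_csv(p, sep="\t")
        exposures[gene] = tab
        gene_tss[gene] = int(tab["pos"].median())
    outcomes = {p.stem.removeprefix("gwas_"): pd.read_csv(p, sep="\t")
                for p in sorted(d.glob("gwas_*.tsv"))}
    scfg = _sim_config(cfg)
    return synthio.SyntheticStudy(
        cfg=scfg, gene_counts=gene_counts, mirna_counts=mirna_counts,
        panel=panel, exposures=exposures, gene_tss=gene_tss,
        outcomes=outcomes,
        outcome_binary={o: (scfg.binary_outcome and i == 0)
                        for i, o in enumerate(outcomes)},
        catalog=pd.read_csv(_req("snp_catalog.tsv"), sep="\t"),
        annotation=pd.read_csv(_req("gene_annotation.tsv"), sep="\t"),
        tf_table=pd.read_csv(_req("tf_mirna.tsv"), sep="\t"),
        predictions=pd.read_csv(_req("mirna_targets.tsv"), sep="\t"),
        druggable=annotate.load_druggable_list(_req("druggable_genes.txt")),
        truth=synthio.SynthTruth())


def _write_report(summary: dict, path: Path) -> None:
    lines = ["# Pipeline report", ""]
    de = summary["de"]
    lines += [
        f"Seed {summary['seed']}, config {summary['config_hash']}.", "",
        "## Differential expression",
        f"- genes: {de['genes'][2]} DE ({de['genes'][0]} up, {de['genes'][1]} down)",
        f"- miRNAs: {de['mirnas'][2]} DE ({de['mirnas'][0]} up, {de['mirnas'][1]} down)",
        "",
        "## Regulatory network",
        "- {n_mirnas} miRNAs, {n_targets} targets, {n_edges} edges".format(
            **summary["network"]),
        "",
        "## Enrichment",
        f"- TFs enriched (p<0.05): {summary['tf_significant']}",
        f"- traits enriched (FDR<0.05): {', '.join(summary['traits_flagged']) or 'none'}",
        "", "## Mendelian randomization",
    ]
    for o, m in summary["mr"].items():
        lines.append(f"- {o}: {m['selected']} causal of {m['tested']} tested "
                     f"(Bonferroni alpha = {m['alpha']:.3g})")
    shared = summary.get("cross_phenotype")
    if shared:
        lines += ["",
                  f"- unique causal genes: {shared['n_unique']} "
                  f"({shared['n_exactly_two']} in two outcomes, "
                  f"{shared['n_exactly_three']} in all three)"]
    drug = summary["druggable"]
    lines += ["", "## Druggability",
              f"- {drug['n_druggable']} of {drug['n_causal']} causal genes "
              f"are druggable ({drug['n_drugs']} drugs)", ""]
    path.write_text("\n".join(lines))
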