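"""Synthetic study generator with known ground truth.

Every input the analysis pipeline consumes can be generated here:
negative-binomial count matrices with planted fold changes, a block-LD
genotype reference panel, marginal eQTL/GWAS summary statistics produced
under a known gene -> outcome causal model (optionally with directional
pleiotropy and a binary liability-threshold outcome), SNP-trait catalogs
with planted enrichment around transcription start sites, TF->miRNA and
miRNA-target prediction tables, and a druggable-gene list.

All randomness flows through one :class:`numpy.random.Generator` derived
from ``SimConfig.seed``; a fixed seed reproduces every table byte for byte.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfigError",
    "SimConfig",
    "SynthTruth",
    "GenotypePanel",
    "simulate_counts",
    "simulate_panel",
    "simulate_gene_summary",
    "simulate_outcome_summary",
    "simulate_catalog_and_annotation",
    "simulate_study",
    "write_study",
    "SUMMARY_COLUMNS",
]

#: Sarcopenia (EWGSOP low grip strength) GWAS design constants used for the
#: default binary-outcome prevalence: 48,596 cases among 256,523 individuals.
SARCOPENIA_CASES = 48_596
SARCOPENIA_CONTROLS = 207_927
SARCOPENIA_N = SARCOPENIA_CASES + SARCOPENIA_CONTROLS

#: Canonical column order for marginal summary-statistic tables.
SUMMARY_COLUMNS = [
    "snp", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "p", "n",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class ConfigError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass
class SimConfig:
    """Parameters of one synthetic study.

    Defaults mirror the emulated study design: a 4-vs-4 two-group RNA-seq
    comparison, a skeletal-muscle eQTL sample of 588 individuals, and a
    binary outcome whose prevalence equals the sarcopenia GWAS case
    fraction (48,596 / 256,523).
    """

    seed: int = 0
    # expression
    n_genes: int = 2000
    n_mirnas: int = 300
    n_samples_per_group: int = 4
    de_fraction: float = 0.10
    demir_fraction: float = 0.15
    lfc_magnitude: float = 1.5
    nb_dispersion: float = 0.05
    mean_range: tuple[float, float] = (20.0, 2000.0)
    # genotypes / LD
    n_panel: int = 200
    n_blocks: int = 10
    snps_per_block: int = 8
    block_rho: float = 0.8
    maf_range: tuple[float, float] = (0.05, 0.5)
    snp_spacing: int = 2000
    block_gap: int = 100_000
    # summary statistics
    n_exp: int = 588
    n_out: int = 20_000
    theta: float = 0.3
    pleiotropy_alpha: float = 0.0
    exposure_noise_sd: float = 1.0
    #: residual (polygenic + environmental) outcome SD; the default keeps a
    #: single gene's contribution to the outcome variance near 1%, typical
    #: for expression-instrumented complex-trait MR
    outcome_noise_sd: float = 3.0
    binary_outcome: bool = False
    prevalence: float = SARCOPENIA_CASES / SARCOPENIA_N
    flip_fraction: float = 0.10
    # catalog / annotation
    n_traits: int = 8
    n_enriched_traits: int = 2
    #: the emulated catalog averages ~1600 SNPs per trait; 300 keeps the
    #: same per-trait statistical regime at desk scale
    snps_per_trait: int = 300
    enrichment_factor: float = 5.0
    trr_flank: int = 20_000

    def validate(self) -> None:
        if min(self.n_genes, self.n_mirnas, self.n_samples_per_group) <= 0:
            raise ConfigError("expression dimensions must be positive")
        if not (0.0 <= self.de_fraction <= 1.0 and 0.0 <= self.demir_fraction <= 1.0):
            raise ConfigError("DE fractions must lie in [0, 1]")
        if self.de_fraction * self.n_genes < 1 and self.de_fraction > 0:
            raise ConfigError("de_fraction * n_genes must be >= 1 when nonzero")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")
        if not (0.0 <= self.block_rho < 1.0):
            raise ConfigError("block_rho must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if min(self.n_blocks, self.snps_per_block, self.n_panel) <= 0:
            raise ConfigError("panel dimensions must be positive")
        if not (0.0 < self.prevalence < 1.0):
            raise ConfigError("prevalence must lie in (0, 1)")
        if not (0.0 <= self.flip_fraction <= 1.0):
            raise ConfigError("flip_fraction must lie in [0, 1]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class SynthTruth:
    """Planted ground truth: the oracle that acceptance checks score against."""

    de_genes: dict[str, float] = field(default_factory=dict)
    de_mirnas: dict[str, float] = field(default_factory=dict)
    true_edges: set[tuple[str, str]] = field(default_factory=set)
    causal_theta: dict[str, float] = field(default_factory=dict)
    pleiotropic_snps: set[str] = field(default_factory=set)
    enriched_traits: set[str] = field(default_factory=set)
    corrupted_snps: dict[str, str] = field(default_factory=dict)


@dataclass
class GenotypePanel:
    """0/1/2 dosage matrix (individuals x SNPs) plus per-SNP metadata.

    ``meta`` carries 1-based positions on a single synthetic chromosome,
    canonical effect/other alleles, block membership, and the population MAF
    used to generate the genotypes.
    """

    dosages: pd.DataFrame
    meta: pd.DataFrame

    @property
    def snps(self) -> list[str]:
        return list(self.meta["snp"])


# ---------------------------------------------------------------------------
# counts

def simulate_counts(cfg: SimConfig, kind: str = "gene",
                    rng: np.random.Generator | None = None
                    ) -> tuple[pd.DataFrame, dict[str, float]]:
    """Simulate an NB count matrix with planted two-group fold changes.

    Returns the counts (features x 2*n_samples_per_group, groups ``old`` and
    ``oldEx``) and a map feature -> signed log2 fold change for the planted
    DE features.  Per-feature dispersions are gamma-scattered around
    ``cfg.nb_dispersion`` and column size factors are log-uniform in
    [0.5, 2], so library sizes differ between samples.
    """
    cfg.validate()
    if kind not in ("gene", "mirna"):
        raise ConfigError(f"unknown count kind {kind!r}")
    rng = cfg.rng() if rng is None else rng

    if kind == "gene":
        n_feat, frac, prefix = cfg.n_genes, cfg.de_fraction, "GENE"
    else:
        n_feat, frac, prefix = cfg.n_mirnas, cfg.demir_fraction, "miR"
    features = [f"{prefix}{i + 1:04d}" for i in range(n_feat)]

    n_per = cfg.n_samples_per_group
    samples = [f"old_{i + 1}" for i in range(n_per)] + \
              [f"oldEx_{i + 1}" for i in range(n_per)]

    lo, hi = cfg.mean_range
    base_mean = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_feat))
    dispersion = np.maximum(
        rng.gamma(shape=4.0, scale=cfg.nb_dispersion / 4.0, size=n_feat), 1e-4)
    size_factors = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=2 * n_per))

    n_de = int(round(frac * n_feat))
    de_idx = rng.choice(n_feat, size=n_de, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    lfc = np.zeros(n_feat)
    lfc[de_idx] = signs * cfg.lfc_magnitude

    # group means: oldEx = old * 2^lfc
    mu = np.empty((n_feat, 2 * n_per))
    mu[:, :n_per] = base_mean[:, None]
    mu[:, n_per:] = (base_mean * 2.0 ** lfc)[:, None]
    mu = mu * size_factors[None, :]

    # NB with mean mu and dispersion a: var = mu + a mu^2
    a = dispersion[:, None]
    counts = rng.negative_binomial(n=1.0 / a, p=1.0 / (1.0 + a * mu))
    mat = pd.DataFrame(counts, index=pd.Index(features, name="feature"),
                       columns=samples)
    truth = {features[i]: float(lfc[i]) for i in de_idx}
    return mat, truth


# ---------------------------------------------------------------------------
# genotypes

def _block_structure(cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP block index and 1-based positions on one synthetic chromosome."""
    m = cfg.n_blocks * cfg.snps_per_block
    block = np.repeat(np.arange(cfg.n_blocks), cfg.snps_per_block)
    within = np.tile(np.arange(cfg.snps_per_block), cfg.n_blocks)
    pos = 1 + block * (cfg.snps_per_block * cfg.snp_spacing + cfg.block_gap) \
        + within * cfg.snp_spacing
    assert pos.shape == (m,)
    return block, pos


def _draw_dosages(n: int, maf: np.ndarray, block: np.ndarray, rho: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Draw 0/1/2 genotypes with AR(1) latent correlation within blocks.

    Each of the two haplotypes is an independent latent Gaussian AR(1)
    sequence thresholded at the MAF-matched quantile, so Hardy-Weinberg
    holds marginally while adjacent SNPs within a block are correlated.
    """
    m = maf.size
    thresh = stats.norm.ppf(maf)
    geno = np.zeros((n, m), dtype=np.int8)
    if rho == 0.0:
        return rng.binomial(2, maf[None, :], size=(n, m)).astype(np.int8)
    for _ in range(2):  # two haplotypes
        z = rng.standard_normal((n, m))
        for b in np.unique(block):
            idx = np.flatnonzero(block == b)
            for j in range(1, idx.size):
                z[:, idx[j]] = rho * z[:, idx[j - 1]] + \
                    np.sqrt(1.0 - rho ** 2) * z[:, idx[j]]
        geno += (z < thresh[None, :]).astype(np.int8)
    return geno


def _assign_alleles(m: int, rng: np.random.Generator,
                    palindromic_fraction: float = 0.1
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Canonical effect/other alleles; a small fraction palindromic (A/T, G/C)."""
    bases = np.array(list("ACGT"))
    eff = np.empty(m, dtype="<U1")
    oth = np.empty(m, dtype="<U1")
    pal = rng.random(m) < palindromic_fraction
    for j in range(m):
        if pal[j]:
            a = bases[rng.integers(4)]
            eff[j], oth[j] = a, _COMPLEMENT[a]
        else:
            a = bases[rng.integers(4)]
            choices = [b for b in bases if b != a and b != _COMPLEMENT[a]]
            eff[j], oth[j] = a, choices[rng.integers(len(choices))]
    return eff, oth


def simulate_panel(cfg: SimConfig, rng: np.random.Generator | None = None
                   ) -> GenotypePanel:
    """Simulate the LD reference panel (stand-in for an external haplotype panel)."""
    cfg.validate()
    if cfg.n_panel < 50:
        raise ConfigError("n_panel must be >= 50 for a usable LD reference")
    rng = cfg.rng() if rng is None else rng

    block, pos = _block_structure(cfg)
    m = block.size
    lo, hi = cfg.maf_range
    maf = rng.uniform(lo, hi, size=m)
    eff, oth = _assign_alleles(m, rng)
    geno = _draw_dosages(cfg.n_panel, maf, block, cfg.block_rho, rng)

    snps = [f"rs{100000 + i}" for i in range(m)]
    meta = pd.DataFrame({
        "snp": snps, "chrom": "chrS", "pos": pos,
        "effect_allele": eff, "other_allele": oth,
        "maf": maf, "block": block,
    })
    dosages = pd.DataFrame(geno, columns=snps)
    dosages.index.name = "individual"
    return GenotypePanel(dosages=dosages, meta=meta)


# ---------------------------------------------------------------------------
# summary statistics

def _marginal_ols(geno: np.ndarray, y: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised per-SNP simple linear regression of y on dosage."""
    n = y.size
    gc = geno - geno.mean(axis=0)
    yc = y - y.mean()
    sgg = (gc ** 2).sum(axis=0)
    sgy = gc.T @ yc
    syy = float(yc @ yc)
    sgg = np.where(sgg == 0, np.nan, sgg)
    beta = sgy / sgg
    sse = np.maximum(syy - sgy ** 2 / sgg, 0.0)
    se = np.sqrt(sse / (n - 2) / sgg)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    beta = np.nan_to_num(beta)
    se = np.where(np.isfinite(se) & (se > 0), se, 1.0)
    p = np.nan_to_num(p, nan=1.0)
    return beta, se, np.clip(p, np.finfo(float).tiny, 1.0)


def _marginal_logistic(geno: np.ndarray, case: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP logistic regression (log-odds scale) of case status on dosage."""
    import statsmodels.api as sm

    m = geno.shape[1]
    beta = np.zeros(m)
    se = np.ones(m)
    p = np.ones(m)
    for j in range(m):
        x = sm.add_constant(geno[:, j].astype(float))
        try:
            fit = sm.Logit(case, x).fit(disp=0, maxiter=50)
            beta[j] = fit.params[1]
            se[j] = fit.bse[1]
            p[j] = fit.pvalues[1]
        except Exception:  # separation / monomorphic
            pass
    return beta, se, np.clip(p, np.finfo(float).tiny, 1.0)


def _summary_frame(panel_meta: pd.DataFrame, beta, se, p, eaf, n) -> pd.DataFrame:
    out = panel_meta[["snp", "chrom", "pos", "effect_allele", "other_allele"]].copy()
    out["eaf"] = eaf
    out["beta"] = beta
    out["se"] = se
    out["p"] = p
    out["n"] = n
    return out.reset_index(drop=True)[SUMMARY_COLUMNS]


def simulate_gene_summary(cfg: SimConfig, panel: GenotypePanel,
                          gamma: np.ndarray | pd.Series,
                          rng: np.random.Generator | None = None
                          ) -> pd.DataFrame:
    """Marginal cis-eQTL summary statistics for one gene.

    Expression is ``x = G @ gamma + N(0, sigma^2)`` on ``n_exp`` fresh
    genotype draws (never the panel individuals, preserving the two-sample
    assumption), standardised before the per-SNP regressions so reported
    betas are on the expression-SD scale, as is conventional for eQTL data.
    """
    cfg.validate()
    rng = cfg.rng() if rng is None else rng
    gamma = np.asarray(pd.Series(gamma).reindex(panel.snps).fillna(0.0)
                       if isinstance(gamma, (pd.Series, dict)) else gamma,
                       dtype=float)
    if gamma.shape != (len(panel.snps),):
        raise ConfigError("gamma must be indexed by the panel SNPs")
    if np.all(gamma == 0) and cfg.theta != 0:
        warnings.warn("gamma is all zero with theta != 0: no instrument signal",
                      stacklevel=2)

    block = panel.meta["block"].to_numpy()
    maf = panel.meta["maf"].to_numpy()
    geno = _draw_dosages(cfg.n_exp, maf, block, cfg.block_rho, rng).astype(float)
    x = geno @ gamma + rng.normal(0.0, cfg.exposure_noise_sd, size=cfg.n_exp)
    x = (x - x.mean()) / x.std(ddof=0)
    beta, se, p = _marginal_ols(geno, x)
    eaf = geno.mean(axis=0) / 2.0
    return _summary_frame(panel.meta, beta, se, p, np.clip(eaf, 1e-4, 1 - 1e-4),
                          cfg.n_exp)


def _corrupt_alleles(summary: pd.DataFrame, cfg: SimConfig,
                     rng: np.random.Generator) -> tuple[pd.DataFrame, dict[str, str]]:
    """Report a fraction of SNPs allele-swapped or strand-complemented.

    Both corruptions are recoverable by harmonisation against the clean
    exposure records (for non-palindromic SNPs); a swap negates the reported
    beta and flips eaf, a strand flip relabels both alleles.
    """
    out = summary.copy()
    actions: dict[str, str] = {}
    u = rng.random(len(out))
    swap = u < cfg.flip_fraction / 2.0
    flip = (u >= cfg.flip_fraction / 2.0) & (u < cfg.flip_fraction)
    ea = out["effect_allele"].to_numpy().copy()
    oa = out["other_allele"].to_numpy().copy()
    beta = out["beta"].to_numpy().copy()
    eaf = out["eaf"].to_numpy().copy()
    for i in np.flatnonzero(swap):
        ea[i], oa[i] = oa[i], ea[i]
        beta[i] = -beta[i]
        eaf[i] = 1.0 - eaf[i]
        actions[out.at[i, "snp"]] = "swapped"
    for i in np.flatnonzero(flip):
        ea[i] = _COMPLEMENT[ea[i]]
        oa[i] = _COMPLEMENT[oa[i]]
        actions[out.at[i, "snp"]] = "strand_flipped"
    out["effect_allele"] = ea
    out["other_allele"] = oa
    out["beta"] = beta
    out["eaf"] = eaf
    return out, actions


def simulate_outcome_summary(cfg: SimConfig, panel: GenotypePanel,
                             gammas: dict[str, np.ndarray | pd.Series],
                             theta: dict[str, float] | None = None,
                             rng: np.random.Generator | None = None,
                             corrupt: bool = True
                             ) -> tuple[pd.DataFrame, SynthTruth]:
    """Marginal GWAS summary statistics for one outcome.

    The outcome is generated on ``n_out`` fresh individuals as
    ``y = sum_g theta_g * x_g_std + sum_j alpha_j * g_j +
    N(0, outcome_noise_sd^2)`` where each
    exposure ``x_g`` follows the same generative model as the eQTL sample.
    For a binary outcome, y is a liability and cases are the top
    ``prevalence`` fraction; per-SNP logistic regressions then give log-odds.
    A ``flip_fraction`` of SNPs is reported allele-swapped or on the opposite
    strand to exercise harmonisation.
    """
    cfg.validate()
    rng = cfg.rng() if rng is None else rng
    theta = theta if theta is not None else {g: cfg.theta for g in gammas}

    snps = panel.snps
    block = panel.meta["block"].to_numpy()
    maf = panel.meta["maf"].to_numpy()
    geno = _draw_dosages(cfg.n_out, maf, block, cfg.block_rho, rng).astype(float)

    y = rng.normal(0.0, cfg.outcome_noise_sd, size=cfg.n_out)
    for gene, gamma in gammas.items():
        gvec = np.asarray(pd.Series(gamma).reindex(snps).fillna(0.0)
                          if isinstance(gamma, (pd.Series, dict)) else gamma,
                          dtype=float)
        x = geno @ gvec + rng.normal(0.0, cfg.exposure_noise_sd, size=cfg.n_out)
        y += theta.get(gene, 0.0) * (x - x.mean()) / x.std(ddof=0)

    pleiotropic: set[str] = set()
    if cfg.pleiotropy_alpha != 0.0:
        y += geno.sum(axis=1) * cfg.pleiotropy_alpha
        pleiotropic = set(snps)

    if cfg.binary_outcome:
        cut = np.quantile(y, 1.0 - cfg.prevalence)
        case = (y > cut).astype(int)
        beta, se, p = _marginal_logistic(geno, case)
    else:
        beta, se, p = _marginal_ols(geno, y)

    eaf = np.clip(geno.mean(axis=0) / 2.0, 1e-4, 1 - 1e-4)
    summary = _summary_frame(panel.meta, beta, se, p, eaf, cfg.n_out)
    actions: dict[str, str] = {}
    if corrupt and cfg.flip_fraction > 0:
        summary, actions = _corrupt_alleles(summary, cfg, rng)
    truth = SynthTruth(causal_theta=dict(theta), pleiotropic_snps=pleiotropic,
                       corrupted_snps=actions)
    return summary, truth


# ---------------------------------------------------------------------------
# catalogs, annotation, network tables

def simulate_catalog_and_annotation(
        cfg: SimConfig,
        de_genes: dict[str, float],
        de_mirnas: dict[str, float],
        rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame,
           list[str], SynthTruth]:
    """Simulate the file-based side tables: SNP catalog, gene annotation
    with TSS, TF->miRNA table, miRNA-target prediction table, druggable list.

    True regulatory edges connect oppositely-signed DE miRNA/gene pairs; the
    prediction table is those edges plus decoy pairs.  For each enriched
    trait, catalog SNPs fall inside the +/-``trr_flank`` TSS windows of
    network genes at ``enrichment_factor`` times the background rate.
    """
    cfg.validate()
    rng = cfg.rng() if rng is None else rng
    genes = [f"GENE{i + 1:04d}" for i in range(cfg.n_genes)]
    mirnas = [f"miR{i + 1:04d}" for i in range(cfg.n_mirnas)]

    # annotation: TSS spaced along one synthetic chromosome, away from 0
    spacing = 3 * cfg.trr_flank
    tss = 50_000 + spacing * np.arange(cfg.n_genes)
    strand = rng.choice(["+", "-"], size=cfg.n_genes)
    annotation = pd.DataFrame({
        "gene": genes, "chrom": "chrA", "tss": tss.astype(np.int64),
        "strand": strand,
    })

    # true edges: oppositely-signed DE pairs
    up_m = [m for m, l in de_mirnas.items() if l > 0]
    dn_m = [m for m, l in de_mirnas.items() if l < 0]
    up_g = [g for g, l in de_genes.items() if l > 0]
    dn_g = [g for g, l in de_genes.items() if l < 0]
    true_edges: set[tuple[str, str]] = set()
    for m_list, g_list in ((up_m, dn_g), (dn_m, up_g)):
        for m in m_list:
            if not g_list:
                continue
            k = int(rng.integers(1, max(2, min(8, len(g_list)))))
            targets = rng.choice(g_list, size=min(k, len(g_list)), replace=False)
            true_edges.update((m, g) for g in targets)

    n_decoys = max(50, 3 * len(true_edges))
    decoys: set[tuple[str, str]] = set()
    while len(decoys) < n_decoys:
        pair = (mirnas[rng.integers(cfg.n_mirnas)], genes[rng.integers(cfg.n_genes)])
        if pair not in true_edges:
            decoys.add(pair)
    pred_pairs = sorted(true_edges) + sorted(decoys)
    predictions = pd.DataFrame(pred_pairs, columns=["mirna", "gene"])
    predictions.insert(0, "prediction_id",
                       [f"PRED{i + 1:05d}" for i in range(len(predictions))])

    # TF table: each TF regulates a random miRNA subset; one planted TF
    # preferentially covers the true-network miRNAs.
    net_mirnas = sorted({m for m, _ in true_edges})
    tf_rows = []
    for t in range(6):
        size = int(rng.integers(5, max(6, cfg.n_mirnas // 4)))
        for m in rng.choice(mirnas, size=size, replace=False):
            tf_rows.append((f"TF{t + 1:02d}", m))
    planted_targets = net_mirnas[: max(1, int(0.8 * len(net_mirnas)))]
    extra = rng.choice(mirnas, size=5, replace=False)
    for m in list(planted_targets) + list(extra):
        tf_rows.append(("TF_PLANTED", m))
    tf_table = pd.DataFrame(sorted(set(tf_rows)), columns=["tf", "mirna"])

    # SNP catalog: traits place SNPs either inside network-gene TSS windows
    # ("in") or anywhere on the chromosome ("out")
    net_genes = sorted({g for _, g in true_edges})
    net_tss = annotation.set_index("gene").loc[net_genes, "tss"].to_numpy() \
        if net_genes else np.array([], dtype=np.int64)
    chrom_len = int(tss[-1] + spacing)
    background_rate = 0.05
    enriched = [f"trait_enriched_{i + 1}" for i in range(cfg.n_enriched_traits)]
    nulls = [f"trait_null_{i + 1}"
             for i in range(cfg.n_traits - cfg.n_enriched_traits)]
    rows = []
    snp_counter = 0
    for trait in enriched + nulls:
        rate = background_rate * (cfg.enrichment_factor if trait in enriched else 1.0)
        for _ in range(cfg.snps_per_trait):
            snp_counter += 1
            if net_tss.size and rng.random() < rate:
                center = int(net_tss[rng.integers(net_tss.size)])
                pos = int(center + rng.integers(-cfg.trr_flank, cfg.trr_flank + 1))
            else:
                pos = int(rng.integers(1, chrom_len))
            rows.append((f"cat_rs{snp_counter:06d}", "chrA", max(1, pos), trait,
                         10.0 ** -rng.uniform(8.0, 30.0)))
    catalog = pd.DataFrame(rows, columns=["snp", "chrom", "pos", "trait", "p"])

    # druggable list: some network genes plus random others
    n_drug = max(5, cfg.n_genes // 10)
    pool = net_genes[: n_drug // 2] + list(
        rng.choice(genes, size=n_drug, replace=False))
    druggable = sorted(set(pool))[:n_drug]

    truth = SynthTruth(de_genes=dict(de_genes), de_mirnas=dict(de_mirnas),
                       true_edges=true_edges, enriched_traits=set(enriched))
    return catalog, annotation, tf_table, predictions, druggable, truth


# ---------------------------------------------------------------------------
# whole-study bundle

@dataclass
class SyntheticStudy:
    """Every table one end-to-end pipeline run consumes, plus the truth."""

    cfg: SimConfig
    gene_counts: pd.DataFrame
    mirna_counts: pd.DataFrame
    panel: GenotypePanel
    exposures: dict[str, pd.DataFrame]          # gene -> eQTL summary stats
    gene_tss: dict[str, int]                    # MR genes -> TSS on chrS
    outcomes: dict[str, pd.DataFrame]           # outcome -> GWAS summary stats
    outcome_binary: dict[str, bool]
    catalog: pd.DataFrame
    annotation: pd.DataFrame
    tf_table: pd.DataFrame
    predictions: pd.DataFrame
    druggable: list[str]
    truth: SynthTruth


def simulate_study(cfg: SimConfig, n_mr_genes: int = 12,
                   n_causal: int = 4,
                   outcomes: tuple[str, ...] = ("sarcopenia", "ALM", "HGS"),
                   ) -> SyntheticStudy:
    """Generate one complete synthetic study.

    ``n_mr_genes`` genes are given their own LD block of cis-eQTLs (three
    causal SNPs per block); ``n_causal`` of them carry the true effect
    ``cfg.theta`` on every outcome (sign-flipped for the continuous traits,
    emulating risk genes that lower lean mass and grip strength), the rest
    are null.  The first outcome is binary when ``cfg.binary_outcome``.
    """
    cfg.validate()
    rng = cfg.rng()
    if n_mr_genes > cfg.n_blocks:
        raise ConfigError("need at least one LD block per MR gene")

    gene_counts, de_genes = simulate_counts(cfg, "gene", rng)
    mirna_counts, de_mirnas = simulate_counts(cfg, "mirna", rng)
    catalog, annotation, tf_table, predictions, druggable, truth = \
        simulate_catalog_and_annotation(cfg, de_genes, de_mirnas, rng)

    panel = simulate_panel(cfg, rng)
    net_genes = sorted({g for _, g in truth.true_edges})
    mr_genes = net_genes[:n_mr_genes]
    if len(mr_genes) < n_mr_genes:  # pad with other DE genes
        extra = [g for g in sorted(de_genes) if g not in mr_genes]
        mr_genes += extra[: n_mr_genes - len(mr_genes)]

    blocks = panel.meta["block"].to_numpy()
    maf = panel.meta["maf"].to_numpy()
    exposures: dict[str, pd.DataFrame] = {}
    gene_tss: dict[str, int] = {}
    gammas: dict[str, np.ndarray] = {}
    causal_set = set(mr_genes[:n_causal])
    for b, gene in enumerate(mr_genes):
        in_block = blocks == b
        gamma = np.zeros(len(panel.snps))
        causal_idx = np.flatnonzero(in_block)
        chosen = rng.choice(causal_idx, size=min(3, causal_idx.size), replace=False)
        gamma[chosen] = rng.uniform(0.2, 0.5, size=chosen.size) / np.sqrt(
            2 * maf[chosen] * (1 - maf[chosen]))
        gammas[gene] = gamma
        block_pos = panel.meta.loc[in_block, "pos"]
        gene_tss[gene] = int(block_pos.median())
        exposures[gene] = simulate_gene_summary(cfg, panel, gamma, rng)

    theta_map = {g: (cfg.theta if g in causal_set else 0.0) for g in mr_genes}
    truth.causal_theta = dict(theta_map)

    out_tables: dict[str, pd.DataFrame] = {}
    out_binary: dict[str, bool] = {}
    for i, name in enumerate(outcomes):
        binary = cfg.binary_outcome and i == 0
        # risk genes raise the binary trait but lower lean mass / grip strength
        sign = 1.0 if i == 0 else -1.0
        th = {g: sign * v for g, v in theta_map.items()}
        ocfg = cfg.replace(binary_outcome=binary)
        table, otruth = simulate_outcome_summary(ocfg, panel, gammas, th, rng)
        out_tables[name] = table
        out_binary[name] = binary
        truth.pleiotropic_snps |= otruth.pleiotropic_snps
        truth.corrupted_snps.update(otruth.corrupted_snps)

    return SyntheticStudy(cfg=cfg, gene_counts=gene_counts,
                          mirna_counts=mirna_counts, panel=panel,
                          exposures=exposures, gene_tss=gene_tss,
                          outcomes=out_tables, outcome_binary=out_binary,
                          catalog=catalog, annotation=annotation,
                          tf_table=tf_table, predictions=predictions,
                          druggable=druggable, truth=truth)


# ---------------------------------------------------------------------------
# writers

def write_study(study: SyntheticStudy, outdir: str | Path) -> dict[str, Path]:
    """Write every study table as TSV (annotation also as BED); returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _tsv(name: str, df: pd.DataFrame, index: bool = False) -> None:
        p = outdir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=index)
        paths[name] = p

    _tsv("gene_counts", study.gene_counts, index=True)
    _tsv("mirna_counts", study.mirna_counts, index=True)
    sheet = pd.DataFrame({
        "sample": study.gene_counts.columns,
        "group": [s.split("_")[0] for s in study.gene_counts.columns],
    })
    _tsv("samples", sheet)
    _tsv("panel_genotypes", study.panel.dosages, index=True)
    _tsv("panel_snps", study.panel.meta)
    for gene, df in study.exposures.items():
        _tsv(f"eqtl_{gene}", df)
    for name, df in study.outcomes.items():
        _tsv(f"gwas_{name}", df)
    _tsv("snp_catalog", study.catalog)
    _tsv("gene_annotation", study.annotation)
    _tsv("tf_mirna", study.tf_table)
    _tsv("mirna_targets", study.predictions)

    drug = outdir / "druggable_genes.txt"
    drug.write_text("\n".join(study.druggable) + "\n")
    paths["druggable"] = drug

    # BED export: 0-based half-open, one TSS row per gene
    bed = outdir / "gene_tss.bed"
    with bed.open("w") as fh:
        for _, r in study.annotation.iterrows():
            fh.write(f"{r.chrom}\t{r.tss - 1}\t{r.tss}\t{r.gene}\t0\t{r.strand}\n")
    paths["tss_bed"] = bed
    return paths
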