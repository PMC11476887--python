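# Methods

This note documents the models, defaults and design choices behind `exmr`,
in the order the pipeline runs them, and what the synthetic validation does
and does not establish.

## Synthetic study generator (`exmr.synthio`)

The generator emulates the statistical structure the analysis assumes, not
the molecular detail of any real dataset.

**Counts.** Gene and miRNA matrices are negative binomial with per-feature
dispersions gamma-scattered around `nb_dispersion` (default 0.05, a typical
bulk RNA-seq scale), per-feature means log-uniform on [20, 2000], and column
size factors log-uniform on [0.5, 2]. A fraction `de_fraction` of features
receives a signed log2 fold change of magnitude `lfc_magnitude` between the
two groups (`old` vs `oldEx`, `n_samples_per_group` = 4 per group,
matching the emulated two-group four-replicate design).

**Genotypes.** The reference panel and all study samples are drawn from the
same population model: two latent Gaussian haplotypes per individual with
AR(1) correlation `block_rho` inside each LD block (independent across
blocks), thresholded at MAF-matched quantiles and summed to 0/1/2 dosages.
This gives controllable, desk-scale LD without a coalescent simulator;
Hardy–Weinberg holds marginally. SNP positions sit on one synthetic
chromosome with configurable spacing, 1-based.

**Summary statistics.** Exposure: x = Gγ + N(0, σₓ²) on `n_exp` fresh
individuals (default 588, the emulated muscle eQTL sample size),
standardised in-sample before vectorised per-SNP marginal regressions — so
reported betas are on the expression-SD scale, as eQTL data are. Outcome:
y = Σ_g θ_g·x_g,std + α·Σ_j g_j + N(0, σ_y²) on `n_out` disjoint individuals
(two-sample assumption is strict; the overlap of real eQTL and GWAS samples
is unknown, and non-overlap is assumed). The residual outcome SD defaults to
σ_y = 3 so that a single gene with θ = 0.3 explains about 1% of the outcome
variance — the realistic regime for expression-instrumented complex traits;
at σ_y = 1 a single gene would explain ~8% of a trait like grip strength,
which no eQTL-MR application resembles. Binary outcomes use a liability
threshold at the configured prevalence (default = the emulated sarcopenia
GWAS case fraction, 48 596/256 523) followed by per-SNP logistic
regressions, so betas are log-odds. A configurable fraction of outcome
records (default 10%) is reported allele-swapped or strand-complemented so
harmonisation is always exercised; the injected actions are recorded in the
truth object.

**Catalogs and tables.** True regulatory edges join oppositely-signed DE
miRNA/gene pairs; the prediction table is those edges plus ≥3× decoys.
The SNP catalog holds `snps_per_trait` SNPs per trait (default 300; the
emulated catalog averages ~1600 per trait, and far smaller catalogs make
even strong planted enrichment underpowered for trivial reasons), with
enriched traits placed inside network-gene TSS windows at
`enrichment_factor` (default 5) times the background rate. One planted TF
preferentially regulates the network's miRNAs.

**What passing does not show.** The generator has no realistic allele
frequency spectrum, no population structure, no trans effects, no
correlated pleiotropy (α is constant across SNPs when used), no
winner's-curse in instrument discovery, and NB counts with a single
dispersion scale. Recovery here demonstrates correctness of the machinery
under its stated assumptions, not performance on real data.

## Differential expression (`exmr.diffexpr`)

Median-of-ratios size factors; per-feature NB dispersion by method of
moments on normalised counts (floored at 1e-8); NB GLM with a group
indicator (statsmodels IRLS) and the size factors as offsets; Wald test on
the group coefficient referred to a **t distribution with residual degrees
of freedom** (n_samples − 2). With 4-vs-4 replicates the per-feature
dispersion estimate is noisy and a normal reference is visibly
anti-conservative (empirical type-I ≈ 0.10 at nominal 0.05); the t
reference restores calibration (measured 0.043–0.055 across seeds). BH
adjustment across features; the DE call is padj < 0.05 with no fold-change
cutoff. Shrinkage-based DE machinery (dispersion trend fitting, effect
shrinkage) is deliberately not replicated: the module's contract is
calibrated recovery of planted effects, not concordance with any specific
DE package. miRNA counts reuse the same test unchanged.

## Network and enrichment (`exmr.mirnet`, `exmr.enrich`)

An edge (miRNA, gene) requires: both DE at the padj threshold, strictly
opposite log2FC signs (no magnitude cutoff), and presence in the prediction
whitelist; zero-lfc features are excluded and duplicate pairs collapse.
miRNA arm/family identifiers are taken verbatim (no collapsing rule is
defined).

Enrichment is one upper-tail hypergeometric primitive. TRRs are the ±20 kb
TSS windows, clipped at 0, strand-ignored (symmetric window), stored
0-based half-open: a 1-based SNP at p hits [s, e) iff s ≤ p−1 < e, so the
window spans 40 001 positions. TF enrichment uses raw p < 0.05 (field
convention for this test); trait-SNP enrichment uses BH FDR < 0.05 across
traits; both thresholds configurable. The background universes default to
all annotated miRNAs / TRRs of all annotated genes and are overridable;
cross-species liftover is out of scope — TRRs must already be in the
catalog's coordinate system. Catalog loading applies the genome-wide filter
p ≤ 5×10⁻⁸. The generic gene-set enrichment is the same primitive with BH
padj, a local replacement for web enrichment services.

## Instrument selection (`exmr.ivselect`)

Fixed, logged order: cis (|pos − TSS| ≤ 1 Mb) → significance (p < 5×10⁻⁸,
strict) → greedy clumping → weak filter (F = (β/σ)² ≥ 10, boundary kept) →
harmonisation → Steiger. Choices worth flagging:

- The printed inclusion rule "F < 10" in the emulated protocol is read as
  the universal F ≥ 10 exclusion of weak instruments; the literal reading
  would deliberately select weak instruments and contradicts the method's
  own robustness claims. `f_min` is configurable.
- The clump window is 10 kb exactly as stated (many tools default to
  10 Mb); with r² < 0.05 this is a lenient pruning, consistent with the
  protocol's own description. Window and r² are configurable; ties in p
  break by position then SNP id, making the output invariant to row order.
- Palindromic (A/T, G/C) SNPs are oriented by allele frequency only when
  both |EAF − 0.5| > 0.08 and the orientations agree; otherwise dropped.
  The 0.08 tolerance is the common MAF < 0.42 rule.
- Per-SNP sample sizes come from the summary files; Steiger uses the
  *summed* per-instrument r² (r²ⱼ = t²ⱼ/(t²ⱼ + n − 2)) on each side and the
  two-independent-samples Fisher-z test; a gene passes when the exposure
  side wins at p < 0.05.

## MR estimation and selection (`exmr.mrcore`)

Primary: Wald ratio (1 SNP) or fixed-effect IVW (≥2) with the unscaled SE
(Σβ̂ₓ²/σᵧ²)^(−1/2) — the fixed-effect convention, exactly reducing to the
Wald ratio at k = 1. Secondary estimators need ≥3 instruments (software
convention). MR-Egger orients β̂ₓ ≥ 0, fits WLS with intercept, scales SEs
by s = √(RSS_w/(k−2)) and uses t_{k−2} p-values; the multiplicative floor
max(1, s) seen in some implementations is available (`se_floor=True`) but
off by default because it makes the intercept test conservative (analytic
null rejection ≈ 2% at k = 10) and breaks its calibration. Egger's point
estimates dilute toward the intercept when instrument strengths are
estimated noisily (low I²_GX); the validation therefore scores the
intercept by CI coverage, not point recovery. Weighted median interpolates
the ratio at cumulative weight 0.5; modes take the argmax of a (weighted)
Gaussian KDE over ratios with φ×Silverman bandwidth on a 512-point grid;
both get parametric-bootstrap SEs (resampling β̂ᵧ ~ N(β̂ᵧ, σᵧ), 1000 reps,
seeded). Cochran's Q uses ratio weights β̂ₓ²/σᵧ² (IVW form, df k−1) and
Egger-fit residuals (df k−2).

Selection: primary p ≤ 0.05/m within each outcome, gated on Egger intercept
p > 0.05, both Q p > 0.05 (when computable) and Steiger pass; the gates
apply to Bonferroni-significant genes (applying them to all tested genes is
a config switch). Sign agreement among nominally significant secondary
methods is reported as a flag but is not a gate — the emulated protocol's
gating there is ambiguous. pve is the summed per-instrument exposure r².
Cross-phenotype reporting counts per-outcome, pairwise and triple
intersections, verifies the unique count by inclusion–exclusion, and
classifies genes present in all outcomes by polarity (risk: positive on the
binary disease, negative on the continuous traits).

## Pipeline and sizes

`pipeline.run_all` chains all stages with one seed, writes TSVs with
seed/config-hash headers, a per-stage in/out count log and a markdown
report; reruns are byte-identical. The default demo study uses 400 genes,
80 miRNAs, 12 MR-tested genes (4 causal), n_exp = 588, n_out = 20 000 and
completes in a few seconds. The validation studies use 2000 null genes for
calibration (at n_exp = 1000, n_out = 2000 — type-I error is insensitive to
sample size) and 200 replicates at n_exp = 5000, n_out = 50 000 for
coverage/bias; these sizes are the package's chosen desk-scale conditions
and are stated alongside each reported number.

## Known limitations

No proxy-SNP lookup, multi-allelic sites, MR-PRESSO/leave-one-out/
colocalization/multivariable MR; no ortholog mapping; no LD-aware
enrichment; exact symbol matching (no aliases) for druggability. The NB
Wald test is a simplified caller and will not match shrinkage-based tools
feature-for-feature on real data.
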