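"""Two-sample MR estimators, sensitivity cascade and causal-gene selection.

Primary estimation follows the single-vs-multi instrument dispatch: the
Wald ratio for one SNP, fixed-effect inverse-variance weighting for two or
more.  Secondary estimators (MR-Egger, weighted median, simple and weighted
mode) require at least three instruments.  Sensitivity statistics are the
MR-Egger intercept (directional pleiotropy), Cochran's Q in both IVW and
Egger forms (heterogeneity), and the Steiger directionality gate computed
upstream.  Gene selection is Bonferroni on the primary p within each
outcome, with pleiotropy/heterogeneity/directionality gates; effects on a
binary outcome are log-odds and additionally reported as odds ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ivselect import HarmonizedSet, SteigerResult

__all__ = ["MRResult", "SensitivityResult", "CausalGeneTable",
           "wald_ratio", "ivw_fixed", "egger", "weighted_median",
           "mode_estimators", "cochran_q", "run_gene", "select_causal",
           "cross_phenotype", "bonferroni_alpha"]

_Z95 = 1.959963984540054


@dataclass
class MRResult:
    """One estimator's verdict for one gene-outcome pair."""

    gene: str
    outcome: str
    method: str
    nsnp: int
    estimate: float
    se: float
    p: float
    pve: float = float("nan")
    binary: bool = False

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.estimate - _Z95 * self.se, self.estimate + _Z95 * self.se)

    @property
    def odds_ratio(self) -> float | None:
        return math.exp(self.estimate) if self.binary else None

    def to_row(self) -> dict:
        lo, hi = self.ci95
        return {"gene": self.gene, "outcome": self.outcome,
                "method": self.method, "nsnp": self.nsnp,
                "estimate": self.estimate, "se": self.se, "p": self.p,
                "or": self.odds_ratio if self.binary else float("nan"),
                "ci_low": lo, "ci_high": hi, "pve": self.pve}


@dataclass
class SensitivityResult:
    gene: str
    outcome: str
    egger_intercept: float = float("nan")
    egger_intercept_p: float = float("nan")
    q_ivw: float = float("nan")
    q_ivw_df: int = 0
    q_ivw_p: float = float("nan")
    q_egger: float = float("nan")
    q_egger_df: int = 0
    q_egger_p: float = float("nan")
    steiger_p: float = float("nan")
    steiger_direction: bool = False
    steiger_passed: bool = False


@dataclass
class CausalGeneTable:
    """Per-outcome selection: Bonferroni threshold, picks, exclusion reasons."""

    outcome: str
    m_tested: int
    alpha: float
    selected: pd.DataFrame  # gene, estimate, p, sign
    exclusions: dict[str, list[str]] = field(default_factory=dict)


def bonferroni_alpha(m_tested: int, alpha_family: float = 0.05) -> float:
    """Family-wise threshold alpha / m for m tested genes."""
    if m_tested <= 0:
        raise ValueError("m_tested must be positive")
    return alpha_family / m_tested


def _norm_p(z: float) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


def wald_ratio(bx: float, sx: float, by: float, sy: float
               ) -> tuple[float, float, float]:
    """Single-instrument ratio estimate with first-order delta-method SE."""
    if bx == 0:
        raise ZeroDivisionError("Wald ratio undefined for bx = 0")
    est = by / bx
    se = sy / abs(bx)
    return est, se, _norm_p(est / se)


def ivw_fixed(bx, by, sy) -> tuple[float, float, float]:
    """Fixed-effect inverse-variance-weighted estimate.

    Weighted least squares of by on bx through the origin with weights
    1/sy^2 and *no* residual scaling: se = 1/sqrt(sum bx^2/sy^2).  With one
    SNP this reduces exactly to the Wald ratio.
    """
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    sy = np.asarray(sy, dtype=float)
    if (sy <= 0).any():
        raise ValueError("outcome SEs must be positive")
    w = 1.0 / sy ** 2
    denom = float((w * bx ** 2).sum())
    est = float((w * bx * by).sum()) / denom
    se = 1.0 / math.sqrt(denom)
    return est, se, _norm_p(est / se)


def egger(bx, sx, by, sy, se_floor: bool = False
          ) -> tuple[float, float, float, float, float, float]:
    """MR-Egger regression: (slope, slope_se, slope_p, intercept,
    intercept_se, intercept_p).

    Instruments are oriented so every bx >= 0 (negating by alongside), then
    by is regressed on bx with an intercept, weights 1/sy^2.  SEs are scaled
    by s = sqrt(RSS_w / (k-2)) and p-values use the t distribution with k-2
    degrees of freedom (set ``se_floor`` to floor the scale at 1).
    """
    bx = np.asarray(bx, dtype=float).copy()
    by = np.asarray(by, dtype=float).copy()
    sy = np.asarray(sy, dtype=float)
    k = bx.size
    if k < 3:
        raise ValueError("MR-Egger needs >= 3 instruments")
    neg = bx < 0
    bx[neg] *= -1.0
    by[neg] *= -1.0
    w = 1.0 / sy ** 2
    X = np.column_stack([np.ones(k), bx])
    XtWX = X.T @ (w[:, None] * X)
    XtWy = X.T @ (w * by)
    coef = np.linalg.solve(XtWX, XtWy)
    resid = by - X @ coef
    rss_w = float((w * resid ** 2).sum())
    scale = math.sqrt(rss_w / (k - 2))
    if se_floor:
        scale = max(1.0, scale)
    cov = np.linalg.inv(XtWX) * scale ** 2
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, coef / np.where(se > 0, se, 1.0), np.inf)
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=k - 2)
    return (float(coef[1]), float(se[1]), float(pvals[1]),
            float(coef[0]), float(se[0]), float(pvals[0]))


def _ratio_weights(bx, by, sy) -> tuple[np.ndarray, np.ndarray]:
    bx = np.asarray(bx, dtype=float)
    r = np.asarray(by, dtype=float) / bx
    w = bx ** 2 / np.asarray(sy, dtype=float) ** 2
    return r, w / w.sum()


def _weighted_median_point(r: np.ndarray, w: np.ndarray) -> float:
    """Interpolated weighted median of ratios at cumulative midpoint 0.5."""
    order = np.argsort(r)
    r_s, w_s = r[order], w[order]
    cum = np.cumsum(w_s) - w_s / 2.0  # midpoints, already normalised
    if 0.5 <= cum[0]:
        return float(r_s[0])
    if 0.5 >= cum[-1]:
        return float(r_s[-1])
    return float(np.interp(0.5, cum, r_s))


def _bootstrap_se(point_fn, bx, by, sy, n_boot: int,
                  rng: np.random.Generator) -> float:
    """Parametric bootstrap: resample by ~ N(by, sy) with bx fixed."""
    by = np.asarray(by, dtype=float)
    sy = np.asarray(sy, dtype=float)
    ests = np.empty(n_boot)
    for b in range(n_boot):
        ests[b] = point_fn(rng.normal(by, sy))
    return float(ests.std(ddof=1))


def weighted_median(bx, by, sy, n_boot: int = 1000,
                    seed: int | np.random.Generator = 0
                    ) -> tuple[float, float, float]:
    """Weighted-median estimator; valid when <50% of weight is invalid.

    SE by seeded parametric bootstrap of the outcome effects.
    """
    bx = np.asarray(bx, dtype=float)
    if bx.size < 3:
        raise ValueError("weighted median needs >= 3 instruments")
    r, w = _ratio_weights(bx, by, sy)
    est = _weighted_median_point(r, w)
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) \
        else seed
    se = _bootstrap_se(
        lambda byb: _weighted_median_point(byb / bx, w), bx, by, sy,
        n_boot, rng)
    return est, se, _norm_p(est / se)


def _kde_mode(r: np.ndarray, w: np.ndarray, phi: float) -> float:
    """Argmax of a weighted Gaussian KDE over ratios on a 512-point grid.

    Bandwidth is phi times Silverman's rule using the weighted effective
    spread; identical ratios short-circuit to the common value.
    """
    if np.allclose(r, r[0]):
        return float(r[0])
    mean = float((w * r).sum())
    sd = math.sqrt(float((w * (r - mean) ** 2).sum()))
    q75, q25 = np.percentile(r, [75, 25])
    iqr = (q75 - q25) / 1.34
    spread = min(sd, iqr) if iqr > 0 else sd
    h = phi * 0.9 * spread * r.size ** (-1.0 / 5.0)
    if h <= 0:
        return float(r[np.argmax(w)])
    grid = np.linspace(r.min() - 3 * h, r.max() + 3 * h, 512)
    dens = (w[None, :] *
            np.exp(-0.5 * ((grid[:, None] - r[None, :]) / h) ** 2)).sum(axis=1)
    return float(grid[np.argmax(dens)])


def mode_estimators(bx, by, sy, phi: float = 1.0, n_boot: int = 1000,
                    seed: int | np.random.Generator = 0
                    ) -> dict[str, tuple[float, float, float]]:
    """Simple- and weighted-mode estimates with bootstrap SEs."""
    bx = np.asarray(bx, dtype=float)
    if bx.size < 3:
        raise ValueError("mode estimators need >= 3 instruments")
    r, w = _ratio_weights(bx, by, sy)
    uniform = np.full_like(w, 1.0 / w.size)
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) \
        else seed
    out: dict[str, tuple[float, float, float]] = {}
    for name, weights in (("simple_mode", uniform), ("weighted_mode", w)):
        est = _kde_mode(r, weights, phi)
        se = _bootstrap_se(
            lambda byb, wts=weights: _kde_mode(byb / bx, wts, phi),
            bx, by, sy, n_boot, rng)
        if se == 0:
            se = float("nan")
            p = float("nan")
        else:
            p = _norm_p(est / se)
        out[name] = (est, se, p)
    return out


def cochran_q(bx, by, sy, theta: float) -> tuple[float, int, float]:
    """IVW-form heterogeneity: Q = sum w_j (r_j - theta)^2, df = k-1."""
    r, _ = _ratio_weights(bx, by, sy)
    bx = np.asarray(bx, dtype=float)
    w = bx ** 2 / np.asarray(sy, dtype=float) ** 2
    q = float((w * (r - theta) ** 2).sum())
    df = r.size - 1
    p = float(stats.chi2.sf(q, df)) if df > 0 else 1.0
    return q, df, p


def cochran_q_egger(bx, by, sy, slope: float, intercept: float
                    ) -> tuple[float, int, float]:
    """Egger-form heterogeneity from fit residuals, df = k-2."""
    bx = np.asarray(bx, dtype=float).copy()
    by = np.asarray(by, dtype=float).copy()
    neg = bx < 0
    bx[neg] *= -1.0
    by[neg] *= -1.0
    w = 1.0 / np.asarray(sy, dtype=float) ** 2
    q = float((w * (by - intercept - slope * bx) ** 2).sum())
    df = bx.size - 2
    p = float(stats.chi2.sf(q, df)) if df > 0 else 1.0
    return q, df, p


def run_gene(hset: HarmonizedSet, steiger: SteigerResult | None = None,
             binary: bool = False, n_boot: int = 1000, phi: float = 1.0,
             seed: int = 0, se_floor: bool = False
             ) -> tuple[list[MRResult], SensitivityResult]:
    """All applicable estimators plus sensitivity statistics for one gene.

    Primary method is the Wald ratio for a single instrument and fixed-
    effect IVW otherwise; Egger/median/modes join at >= 3 instruments.
    ``pve`` is the summed per-instrument exposure variance explained.
    """
    t = hset.table
    k = len(t)
    if k == 0:
        raise ValueError(f"gene {hset.gene!r} has no usable instruments")
    bx = t["beta_exp"].to_numpy()
    sx = t["se_exp"].to_numpy()
    by = t["beta_out"].to_numpy()
    sy = t["se_out"].to_numpy()
    n_exp = t["n_exp"].to_numpy()
    t2 = (bx / sx) ** 2
    pve = float((t2 / (t2 + n_exp - 2)).sum())

    def _mk(method, est, se, p):
        return MRResult(gene=hset.gene, outcome=hset.outcome, method=method,
                        nsnp=k, estimate=est, se=se, p=p, pve=pve,
                        binary=binary)

    results: list[MRResult] = []
    if k == 1:
        est, se, p = wald_ratio(float(bx[0]), float(sx[0]), float(by[0]),
                                float(sy[0]))
        results.append(_mk("wald_ratio", est, se, p))
        theta = est
    else:
        est, se, p = ivw_fixed(bx, by, sy)
        results.append(_mk("ivw_fe", est, se, p))
        theta = est

    sens = SensitivityResult(gene=hset.gene, outcome=hset.outcome)
    if k >= 2:
        sens.q_ivw, sens.q_ivw_df, sens.q_ivw_p = cochran_q(bx, by, sy, theta)
    if k >= 3:
        slope, slope_se, slope_p, a, a_se, a_p = egger(bx, sx, by, sy,
                                                       se_floor=se_floor)
        results.append(_mk("egger", slope, slope_se, slope_p))
        sens.egger_intercept, sens.egger_intercept_p = a, a_p
        sens.q_egger, sens.q_egger_df, sens.q_egger_p = \
            cochran_q_egger(bx, by, sy, slope, a)
        est, se, p = weighted_median(bx, by, sy, n_boot=n_boot, seed=seed)
        results.append(_mk("weighted_median", est, se, p))
        modes = mode_estimators(bx, by, sy, phi=phi, n_boot=n_boot, seed=seed)
        for name, (est, se, p) in modes.items():
            results.append(_mk(name, est, se, p))
    if steiger is not None:
        sens.steiger_p = steiger.p
        sens.steiger_direction = steiger.direction_ok
        sens.steiger_passed = steiger.passed
    return results, sens


def method_consistency(results: list[MRResult], alpha: float = 0.05) -> bool:
    """Sign agreement of the primary estimate with every secondary method
    that is itself nominally significant (reported, not a selection gate)."""
    primary = next(r for r in results
                   if r.method in ("wald_ratio", "ivw_fe"))
    sign = np.sign(primary.estimate)
    for r in results:
        if r.method in ("wald_ratio", "ivw_fe"):
            continue
        if np.isfinite(r.p) and r.p < alpha and np.sign(r.estimate) != sign:
            return False
    return True


def select_causal(results: list[list[MRResult]],
                  sens: list[SensitivityResult], m_tested: int,
                  outcome: str = "", alpha_family: float = 0.05,
                  sens_alpha: float = 0.05,
                  require_steiger: bool = True) -> CausalGeneTable:
    """Bonferroni selection with sensitivity gates.

    A gene is selected iff its primary p <= alpha_family / m_tested, its
    Egger intercept p > sens_alpha (when computable), both Cochran Q
    p-values > sens_alpha (when computable), and the Steiger gate passed.
    Excluded significant genes carry enumerated reasons.
    """
    alpha = bonferroni_alpha(m_tested, alpha_family)
    sens_by_gene = {s.gene: s for s in sens}
    picked, exclusions = [], {}
    for gene_results in results:
        primary = next(r for r in gene_results
                       if r.method in ("wald_ratio", "ivw_fe"))
        if primary.p > alpha:
            continue
        s = sens_by_gene.get(primary.gene)
        reasons = []
        if s is not None:
            if np.isfinite(s.egger_intercept_p) and \
                    s.egger_intercept_p <= sens_alpha:
                reasons.append("horizontal_pleiotropy")
            if np.isfinite(s.q_ivw_p) and s.q_ivw_p <= sens_alpha:
                reasons.append("heterogeneity_ivw")
            if np.isfinite(s.q_egger_p) and s.q_egger_p <= sens_alpha:
                reasons.append("heterogeneity_egger")
            if require_steiger and not s.steiger_passed:
                reasons.append("steiger_direction")
        if reasons:
            exclusions[primary.gene] = reasons
        else:
            picked.append({
                "gene": primary.gene, "estimate": primary.estimate,
                "se": primary.se, "p": primary.p, "nsnp": primary.nsnp,
                "sign": int(np.sign(primary.estimate)),
                "consistent_methods": method_consistency(gene_results),
            })
    selected = pd.DataFrame(
        picked, columns=["gene", "estimate", "se", "p", "nsnp", "sign",
                         "consistent_methods"])
    if len(selected):
        selected = selected.sort_values("p").reset_index(drop=True)
    return CausalGeneTable(outcome=outcome, m_tested=m_tested, alpha=alpha,
                           selected=selected, exclusions=exclusions)


def cross_phenotype(tables: dict[str, CausalGeneTable],
                    binary_outcomes: set[str] | None = None) -> dict:
    """Shared-gene report across outcomes.

    Counts per-outcome, pairwise and triple intersections, the number of
    unique genes (checkable by inclusion-exclusion: unique = total
    memberships - #exactly-two - 2 * #exactly-three), and classifies genes
    present in every outcome as consistent-risk (positive on the binary
    disease, negative on the continuous traits), consistent-protective
    (the reverse) or inconsistent.
    """
    if len(tables) < 2:
        raise ValueError("need >= 2 outcome tables")
    binary_outcomes = binary_outcomes or set()
    sets = {o: set(t.selected["gene"]) for o, t in tables.items()}
    signs = {o: dict(zip(t.selected["gene"], t.selected["sign"]))
             for o, t in tables.items()}
    all_genes = set().union(*sets.values())
    membership = {g: sum(g in s for s in sets.values()) for g in all_genes}
    n_exactly = {m: sum(1 for c in membership.values() if c == m)
                 for m in (1, 2, 3)}
    total_memberships = sum(len(s) for s in sets.values())
    unique_by_ie = total_memberships - n_exactly.get(2, 0) - \
        2 * n_exactly.get(3, 0)
    assert unique_by_ie == len(all_genes)

    outcomes = list(tables)
    pairwise = {f"{a}&{b}": len(sets[a] & sets[b])
                for i, a in enumerate(outcomes) for b in outcomes[i + 1:]}
    triple = set.intersection(*sets.values()) if sets else set()

    classified = {}
    for g in sorted(triple):
        risk = all((signs[o][g] > 0) == (o in binary_outcomes)
                   for o in outcomes)
        protective = all((signs[o][g] < 0) == (o in binary_outcomes)
                         for o in outcomes)
        classified[g] = ("consistent_risk" if risk else
                         "consistent_protective" if protective else
                         "inconsistent")

    return {
        "per_outcome": {o: len(s) for o, s in sets.items()},
        "pairwise": pairwise,
        "n_triple": len(triple),
        "n_exactly_two": n_exactly.get(2, 0),
        "n_exactly_three": n_exactly.get(3, 0),
        "n_unique": len(all_genes),
        "unique_by_inclusion_exclusion": unique_by_ie,
        "triple_classification": classified,
    }
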