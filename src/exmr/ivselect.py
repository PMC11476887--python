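"""Instrument selection, pruning and harmonisation for two-sample MR.

The cascade is fixed and fully logged: cis filter (TSS +/- 1 Mb) ->
genome-wide significance (p < 5e-8) -> greedy LD clumping (r^2 < 0.05
within a 10 kb window, most significant SNP kept) -> weak-instrument
exclusion (per-SNP F >= 10) -> allele harmonisation against the outcome
records (swaps, strand flips, palindromic drops) -> Steiger directionality
gate.  Every dropped SNP or gene carries a machine-readable reason in the
audit trail.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["HarmonizedSet", "SteigerResult", "cis_filter",
           "significance_filter", "compute_ld", "greedy_clump",
           "f_statistic", "weak_filter", "harmonize", "steiger_filter",
           "select_instruments", "CIS_WINDOW", "IV_P_THRESHOLD",
           "CLUMP_R2", "CLUMP_KB", "F_MIN"]

CIS_WINDOW = 1_000_000
IV_P_THRESHOLD = 5e-8
CLUMP_R2 = 0.05
CLUMP_KB = 10.0
F_MIN = 10.0

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_VALID = set("ACGT")


@dataclass
class HarmonizedSet:
    """Allele-aligned exposure/outcome effect vectors for one gene-outcome pair."""

    gene: str
    outcome: str
    table: pd.DataFrame  # snp, beta_exp, se_exp, beta_out, se_out, eaf_exp,
    #                      eaf_out, n_exp, n_out
    audit: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class SteigerResult:
    direction_ok: bool  # instruments explain more exposure than outcome variance
    p: float
    r2_exp: float
    r2_out: float
    passed: bool = False  # direction_ok and p below the gate's alpha


def _audit(trail: list[dict], snp: str, stage: str, action: str,
           reason: str) -> None:
    trail.append({"snp": snp, "stage": stage, "action": action,
                  "reason": reason})


def cis_filter(stats_df: pd.DataFrame, tss: int,
               window: int = CIS_WINDOW,
               audit: list[dict] | None = None) -> pd.DataFrame:
    """Keep records within ``window`` bp of the 1-based TSS (inclusive)."""
    keep = (stats_df["pos"] - tss).abs() <= window
    if audit is not None:
        for snp in stats_df.loc[~keep, "snp"]:
            _audit(audit, snp, "cis", "drop", f"outside_tss_pm_{window}bp")
    return stats_df[keep].reset_index(drop=True)


def significance_filter(stats_df: pd.DataFrame,
                        p_thresh: float = IV_P_THRESHOLD,
                        audit: list[dict] | None = None) -> pd.DataFrame:
    """Keep records with strictly p < ``p_thresh``."""
    keep = stats_df["p"] < p_thresh
    if audit is not None:
        for snp in stats_df.loc[~keep, "snp"]:
            _audit(audit, snp, "significance", "drop", f"p_ge_{p_thresh:g}")
    return stats_df[keep].reset_index(drop=True)


def compute_ld(panel_dosages: pd.DataFrame, snps=None) -> pd.DataFrame:
    """Squared Pearson correlation of genotype dosages in the reference panel.

    Monomorphic SNPs get r^2 = 0 against everything (with a warning) and 1
    on the diagonal.
    """
    snps = list(panel_dosages.columns) if snps is None else list(snps)
    missing = [s for s in snps if s not in panel_dosages.columns]
    if missing:
        raise KeyError(f"SNPs absent from panel: {missing}")
    mat = panel_dosages[snps].to_numpy(dtype=float)
    sd = mat.std(axis=0)
    mono = sd == 0
    if mono.any():
        warnings.warn(f"{int(mono.sum())} monomorphic SNPs: r^2 set to 0",
                      stacklevel=2)
    safe = np.where(mono, 1.0, sd)
    z = (mat - mat.mean(axis=0)) / safe
    r = z.T @ z / mat.shape[0]
    r2 = r ** 2
    r2[mono, :] = 0.0
    r2[:, mono] = 0.0
    np.fill_diagonal(r2, 1.0)
    return pd.DataFrame(r2, index=snps, columns=snps)


def greedy_clump(stats_df: pd.DataFrame, ld: pd.DataFrame,
                 r2_max: float = CLUMP_R2, window_kb: float = CLUMP_KB,
                 audit: list[dict] | None = None) -> pd.DataFrame:
    """Greedy LD clumping keeping the most significant SNP per clump.

    SNPs are visited by ascending p (ties: position, then id); each kept
    index SNP removes every not-yet-kept SNP with r^2 >= ``r2_max`` *and*
    within ``window_kb`` kb of it.  In the returned set every pair is
    either below the r^2 bound or farther apart than the window, and the
    result is invariant to input row order.
    """
    missing = [s for s in stats_df["snp"] if s not in ld.index]
    if missing:
        raise KeyError(f"SNP missing from LD matrix: {missing[0]}")
    window_bp = window_kb * 1000.0
    order = stats_df.sort_values(["p", "pos", "snp"]).reset_index(drop=True)
    alive = dict(zip(order["snp"], order["pos"]))
    kept: list[str] = []
    for snp, pos in zip(order["snp"], order["pos"]):
        if snp not in alive:
            continue
        kept.append(snp)
        del alive[snp]
        for other, opos in list(alive.items()):
            if abs(opos - pos) <= window_bp and \
                    float(ld.at[snp, other]) >= r2_max:
                del alive[other]
                if audit is not None:
                    _audit(audit, other, "clump", "drop",
                           f"r2_ge_{r2_max:g}_with_{snp}")
    keep_mask = stats_df["snp"].isin(kept)
    return stats_df[keep_mask].reset_index(drop=True)


def f_statistic(beta, se) -> np.ndarray:
    """Per-instrument strength F = (beta / se)^2."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if (se <= 0).any():
        raise ValueError("standard errors must be positive")
    return (beta / se) ** 2


def weak_filter(stats_df: pd.DataFrame, f_min: float = F_MIN,
                audit: list[dict] | None = None) -> pd.DataFrame:
    """Exclude weak instruments: keep F >= ``f_min`` (boundary kept)."""
    F = f_statistic(stats_df["beta"], stats_df["se"])
    keep = F >= f_min
    if audit is not None:
        for snp, f in zip(stats_df.loc[~keep, "snp"], F[~keep]):
            _audit(audit, snp, "weak", "drop", f"F_{f:.2f}_lt_{f_min:g}")
    return stats_df[keep].reset_index(drop=True)


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


def harmonize(exp: pd.DataFrame, out: pd.DataFrame, gene: str = "",
              outcome: str = "", palindrome_eaf_tol: float = 0.08,
              audit: list[dict] | None = None) -> HarmonizedSet:
    """Align outcome records to the exposure's effect alleles.

    Cases: (i) same orientation -> keep; (ii) swapped effect/other ->
    negate beta_out, flip eaf_out; (iii) strand complement -> relabel then
    (i)/(ii); (iv) palindromic (A/T, G/C) -> orient by allele frequency only
    when both eafs are far from 0.5 (|eaf-0.5| > tol) and agree after
    orientation, else drop; (v) incompatible pairs -> drop.
    """
    trail = audit if audit is not None else []
    for name, df in (("exposure", exp), ("outcome", out)):
        if df["snp"].duplicated().any():
            raise ValueError(f"duplicate snp ids in {name} input")

    merged = exp.merge(out, on="snp", suffixes=("_exp", "_out"))
    for snp in set(exp["snp"]) - set(merged["snp"]):
        _audit(trail, snp, "harmonize", "drop", "missing_in_outcome")

    rows = []
    for r in merged.itertuples(index=False):
        e1, e2 = str(r.effect_allele_exp).upper(), str(r.other_allele_exp).upper()
        o1, o2 = str(r.effect_allele_out).upper(), str(r.other_allele_out).upper()
        if not ({e1, e2} <= _VALID and {o1, o2} <= _VALID):
            _audit(trail, r.snp, "harmonize", "drop", "invalid_alleles")
            continue
        beta_out, eaf_out = float(r.beta_out), float(r.eaf_out)
        action = "keep"

        if _is_palindromic(e1, e2):
            # strand unresolvable from alleles; orient by frequency or drop
            if {o1, o2} != {e1, e2}:
                _audit(trail, r.snp, "harmonize", "drop", "incompatible_alleles")
                continue
            de = r.eaf_exp - 0.5
            do_ = eaf_out - 0.5
            if abs(de) <= palindrome_eaf_tol or abs(do_) <= palindrome_eaf_tol:
                _audit(trail, r.snp, "harmonize", "drop",
                       "palindromic_ambiguous_eaf")
                continue
            same_freq_side = (de > 0) == (do_ > 0)
            if o1 == e1:
                if not same_freq_side:
                    _audit(trail, r.snp, "harmonize", "drop",
                           "palindromic_eaf_mismatch")
                    continue
            else:  # reported on the swapped allele
                if same_freq_side:
                    _audit(trail, r.snp, "harmonize", "drop",
                           "palindromic_eaf_mismatch")
                    continue
                beta_out, eaf_out = -beta_out, 1.0 - eaf_out
                action = "swap"
        else:
            if {o1, o2} == {e1, e2}:
                pass
            elif {_COMPLEMENT[o1], _COMPLEMENT[o2]} == {e1, e2}:
                o1, o2 = _COMPLEMENT[o1], _COMPLEMENT[o2]
                action = "strand_flip"
            else:
                _audit(trail, r.snp, "harmonize", "drop", "incompatible_alleles")
                continue
            if o1 == e2:  # swapped effect/other
                beta_out, eaf_out = -beta_out, 1.0 - eaf_out
                action = action + "+swap" if action != "keep" else "swap"

        _audit(trail, r.snp, "harmonize", action, "aligned")
        rows.append((r.snp, float(r.beta_exp), float(r.se_exp), beta_out,
                     float(r.se_out), float(r.eaf_exp), eaf_out,
                     int(r.n_exp), int(r.n_out)))

    table = pd.DataFrame(rows, columns=["snp", "beta_exp", "se_exp",
                                        "beta_out", "se_out", "eaf_exp",
                                        "eaf_out", "n_exp", "n_out"])
    return HarmonizedSet(gene=gene, outcome=outcome, table=table, audit=trail)


def steiger_filter(hset: HarmonizedSet, alpha: float = 0.05) -> SteigerResult:
    """Directionality gate: instruments must explain more variance in the
    exposure than in the outcome.

    Per SNP, r^2 is recovered from the marginal test statistic as
    t^2 / (t^2 + n - 2); gene-level r^2 is the sum over retained
    instruments.  The p-value is the two-independent-samples correlation
    z-test on the Fisher-transformed square roots.
    """
    t_df = hset.table
    if len(t_df) == 0:
        return SteigerResult(False, 1.0, 0.0, 0.0)
    if (t_df["n_exp"] < 4).any() or (t_df["n_out"] < 4).any():
        raise ValueError("Steiger needs n >= 4 per SNP")

    def _r2(beta, se, n):
        t2 = (beta / se) ** 2
        r2 = t2 / (t2 + n - 2)
        return float(r2.sum())

    r2_exp = _r2(t_df["beta_exp"], t_df["se_exp"], t_df["n_exp"])
    r2_out = _r2(t_df["beta_out"], t_df["se_out"], t_df["n_out"])
    clip = 1.0 - 1e-12
    if r2_exp >= 1.0 or r2_out >= 1.0:
        warnings.warn("summed r^2 >= 1; clamped", stacklevel=2)
        r2_exp, r2_out = min(r2_exp, clip), min(r2_out, clip)

    n_exp = float(t_df["n_exp"].median())
    n_out = float(t_df["n_out"].median())
    z = (np.arctanh(np.sqrt(r2_exp)) - np.arctanh(np.sqrt(r2_out))) / \
        np.sqrt(1.0 / (n_exp - 3.0) + 1.0 / (n_out - 3.0))
    p = float(2.0 * stats.norm.sf(abs(z)))
    direction_ok = bool(r2_exp > r2_out)
    return SteigerResult(direction_ok=direction_ok, p=p, r2_exp=r2_exp,
                         r2_out=r2_out, passed=direction_ok and p < alpha)


def select_instruments(exp: pd.DataFrame, out: pd.DataFrame,
                       panel_dosages: pd.DataFrame, tss: int,
                       gene: str = "", outcome: str = "",
                       cis_window: int = CIS_WINDOW,
                       p_thresh: float = IV_P_THRESHOLD,
                       r2_max: float = CLUMP_R2,
                       window_kb: float = CLUMP_KB,
                       f_min: float = F_MIN,
                       palindrome_eaf_tol: float = 0.08,
                       ) -> tuple[HarmonizedSet, dict[str, int]]:
    """Run the full cascade; returns the harmonised set and per-stage counts."""
    audit: list[dict] = []
    counts = {"input": len(exp)}
    stage = cis_filter(exp, tss, cis_window, audit)
    counts["cis"] = len(stage)
    stage = significance_filter(stage, p_thresh, audit)
    counts["significance"] = len(stage)
    if len(stage) > 1:
        ld = compute_ld(panel_dosages, list(stage["snp"]))
        stage = greedy_clump(stage, ld, r2_max, window_kb, audit)
    counts["clump"] = len(stage)
    stage = weak_filter(stage, f_min, audit)
    counts["weak"] = len(stage)
    hset = harmonize(stage, out, gene=gene, outcome=outcome,
                     palindrome_eaf_tol=palindrome_eaf_tol, audit=audit)
    counts["harmonize"] = len(hset)
    return hset, counts
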