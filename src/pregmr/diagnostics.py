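"""Sensitivity diagnostics: heterogeneity, directionality and instrument strength.

Covers Cochran's Q over the per-SNP Wald ratios, leave-one-SNP-out
re-estimation, Steiger directionality filtering (drop instruments that
explain more variance in the outcome than in the exposure), and per-SNP
F-statistics / variance explained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MrEstimate, ivw, wald_ratios
from .summary_data import (EXCL_STEIGER, LINEAR, LOG_ODDS, AssociationTable,
                           HarmonizedSet)

#: residual variance of the standard logistic distribution, used as the
#: latent-scale noise term when converting log-odds betas to variance explained
LOGISTIC_VARIANCE = np.pi**2 / 3.0


@dataclass(frozen=True)
class HeterogeneityStats:
    q: float
    df: int
    pvalue: float


@dataclass(frozen=True)
class StrengthStats:
    per_snp: pd.DataFrame  # rsid, f_stat, r2
    mean_f: float
    total_r2: float


@dataclass(frozen=True)
class TraitMeta:
    """Prevalence and per-SNP sample size of one trait, for Steiger r²."""

    n: float | pd.Series
    prevalence: float | None = None


def cochran_q(h: HarmonizedSet, beta_ref: MrEstimate | float) -> HeterogeneityStats:
    """Cochran's Q of the Wald ratios around a reference estimate.

    Q = sum_j w_j (ratio_j - beta_ref)^2 with w_j the inverse squared
    first-order ratio SEs; p from chi-square with k-1 df.
    """
    beta = beta_ref.beta if isinstance(beta_ref, MrEstimate) else float(beta_ref)
    ratios = wald_ratios(h)
    w = 1.0 / ratios["se"].to_numpy() ** 2
    q = float(np.sum(w * (ratios["ratio"].to_numpy() - beta) ** 2))
    df = len(ratios) - 1
    return HeterogeneityStats(q=q, df=df, pvalue=float(stats.chi2.sf(q, df)))


def leave_one_snp_out(h: HarmonizedSet, variant: str | None = None,
                      ) -> pd.DataFrame:
    """Re-estimate IVW k times, omitting each SNP in turn.

    Returns one row per omitted rsid with the re-estimated beta, se, CI and
    p-value.  Uses the fixed-effect IVW variant unless told otherwise.
    """
    from .estimators import FIXED
    variant = variant or FIXED
    df = h.retained()
    if len(df) < 3:
        raise ValueError("leave-one-SNP-out needs at least 3 retained SNPs")
    rows = []
    for rsid in df["rsid"]:
        est = ivw(h.exclude([rsid], "left-out"), variant=variant)
        rows.append({"omitted_rsid": rsid, **est.to_dict()})
    return pd.DataFrame(rows)


def _r2_binary(beta: np.ndarray, eaf: np.ndarray, scale: str,
               prevalence: float | None, latent: bool = True) -> np.ndarray:
    """Variance in a binary trait explained by one SNP from summary data.

    For log-odds betas the default is the latent logistic scale,
    r² = b²·2f(1-f) / (b²·2f(1-f) + π²/3), which needs no prevalence.  For
    linear (risk-difference) betas, r² = b²·2f(1-f) / (p(1-p)) on the
    observed scale.  ``latent=False`` converts log-odds betas to the observed
    scale via the logistic density at the prevalence before the linear
    formula.
    """
    var_g = 2.0 * eaf * (1.0 - eaf)
    if scale == LOG_ODDS:
        if latent:
            num = beta**2 * var_g
            return num / (num + LOGISTIC_VARIANCE)
        if prevalence is None:
            raise ValueError("observed-scale r² for log-odds betas needs a "
                             "prevalence")
        beta_lin = beta * prevalence * (1.0 - prevalence)
        return beta_lin**2 * var_g / (prevalence * (1.0 - prevalence))
    if scale == LINEAR:
        if prevalence is None:
            raise ValueError("r² for linear-scale betas on a binary trait "
                             "needs the trait prevalence")
        return beta**2 * var_g / (prevalence * (1.0 - prevalence))
    raise ValueError(f"unknown scale {scale!r}")


def steiger_filter(h: HarmonizedSet, exposure_meta: TraitMeta,
                   outcome_meta: TraitMeta, alpha: float = 0.05,
                   latent: bool = True,
                   ) -> tuple[HarmonizedSet, pd.DataFrame]:
    """Directionality filter: drop SNPs explaining more outcome than exposure.

    Per SNP the variance explained in each trait is computed from the
    harmonized betas and EAFs, the implied correlations are compared with a
    Fisher z-test for independent samples,
    z = (atanh r_exp - atanh r_out) / sqrt(1/(n_exp-3) + 1/(n_out-3)),
    and the SNP is removed iff r²_outcome > r²_exposure and the two-sided
    p-value is below ``alpha``.  Returns the filtered set plus an audit table.
    """
    df = h.retained()
    for meta, side in ((exposure_meta, "exposure"), (outcome_meta, "outcome")):
        n = np.asarray(meta.n, dtype=float)
        if np.any(~np.isfinite(n)) or np.any(n <= 3):
            bad = df["rsid"].to_numpy()[~np.isfinite(n) | (n <= 3)] \
                if n.shape else df["rsid"].to_numpy()
            raise ValueError(f"missing/invalid {side} sample size for SNP(s): "
                             f"{list(np.atleast_1d(bad))}")

    r2_exp = _r2_binary(df["beta_exposure"].to_numpy(),
                        df["eaf_exposure"].to_numpy(), h.exposure_scale,
                        exposure_meta.prevalence, latent)
    r2_out = _r2_binary(df["beta_outcome"].to_numpy(),
                        df["eaf_outcome"].to_numpy(), h.outcome_scale,
                        outcome_meta.prevalence, latent)
    n_exp = np.broadcast_to(np.asarray(exposure_meta.n, float), r2_exp.shape)
    n_out = np.broadcast_to(np.asarray(outcome_meta.n, float), r2_out.shape)
    z = (np.arctanh(np.sqrt(r2_exp)) - np.arctanh(np.sqrt(r2_out))) / \
        np.sqrt(1.0 / (n_exp - 3.0) + 1.0 / (n_out - 3.0))
    pvalue = 2.0 * stats.norm.sf(np.abs(z))
    removed = (r2_out > r2_exp) & (pvalue < alpha)
    audit = pd.DataFrame({"rsid": df["rsid"].to_numpy(),
                          "r2_exposure": r2_exp, "r2_outcome": r2_out,
                          "z": z, "pvalue": pvalue, "removed": removed})
    filtered = h.exclude(audit.loc[removed, "rsid"], EXCL_STEIGER)
    return filtered, audit


def instrument_strength(exposure: AssociationTable,
                        exposure_variance: float) -> StrengthStats:
    """Per-SNP F-statistics and variance explained of the exposure.

    F_j = (beta_j / se_j)^2; r²_j = beta_j² · 2 eaf (1-eaf) /
    exposure_variance for linear-scale betas.  Total R² is the sum over SNPs
    (valid for independent instruments) and mean F the simple average.
    """
    df = exposure.to_frame()
    f_stat = (df["beta"] / df["se"]) ** 2
    r2 = df["beta"] ** 2 * 2.0 * df["eaf"] * (1.0 - df["eaf"]) / exposure_variance
    per_snp = pd.DataFrame({"rsid": df["rsid"], "f_stat": f_stat, "r2": r2})
    return StrengthStats(per_snp=per_snp, mean_f=float(f_stat.mean()),
                         total_r2=float(r2.sum()))
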