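"""Two-sample Mendelian randomization estimators.

Given harmonized per-SNP exposure effects gamma_j (with SE) and outcome
effects Gamma_j (with SE), the causal effect of the exposure on the outcome
is estimated by

* **IVW** — regression of Gamma on gamma through the origin, weighted by the
  inverse outcome-effect variances; the workhorse estimator, unbiased when no
  instrument has an unbalanced pleiotropic path to the outcome.
* **MR-Egger** — the same regression with a free intercept; a non-zero
  intercept flags unbalanced horizontal pleiotropy, and the slope remains a
  consistent effect estimate under the InSIDE assumption.
* **Weighted median** — the inverse-variance-weighted median of the per-SNP
  Wald ratios; consistent while valid instruments carry more than half of
  the total weight.

All betas are on the log odds ratio scale of the outcome per one unit of the
exposure; ``exp(beta)`` is exposed as an OR for reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .summary_data import HarmonizedSet

Z95 = 1.96  # normal 95% half-width used for all Wald intervals

FIXED = "fixed"
MULT_RANDOM = "multiplicative-random"


class EstimationError(ValueError):
    """An estimator's preconditions are not met."""


@dataclass(frozen=True)
class MrEstimate:
    """A causal-effect estimate on the log-OR-of-outcome scale."""

    method: str
    beta: float
    se: float
    pvalue: float
    n_snps: int
    model_variant: str = FIXED

    @property
    def ci_low(self) -> float:
        return self.beta - Z95 * self.se

    @property
    def ci_high(self) -> float:
        return self.beta + Z95 * self.se

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    @property
    def or_ci(self) -> tuple[float, float]:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))

    def to_dict(self) -> dict:
        return {"method": self.method, "variant": self.model_variant,
                "n_snps": self.n_snps, "beta": self.beta, "se": self.se,
                "or": self.odds_ratio, "ci_low": self.ci_low,
                "ci_high": self.ci_high, "pvalue": self.pvalue}


@dataclass(frozen=True)
class EggerResult:
    """MR-Egger slope plus its pleiotropy-detecting intercept."""

    slope: MrEstimate
    intercept: float
    intercept_se: float
    intercept_pvalue: float


def _retained(h: HarmonizedSet) -> pd.DataFrame:
    df = h.retained()
    if df.empty:
        raise EstimationError("harmonized set has no retained SNPs")
    return df


def wald_ratios(h: HarmonizedSet, second_order: bool = False) -> pd.DataFrame:
    """Per-SNP causal estimates ratio_j = Gamma_j / gamma_j with delta-method SEs.

    First order propagates only the outcome SE (se_out/|gamma|); the
    second-order variant adds the exposure-SE term
    sqrt(se_out^2/gamma^2 + Gamma^2 se_exp^2 / gamma^4).  SNPs with a zero
    exposure beta cannot form a ratio and are dropped with a warning.
    """
    df = _retained(h)
    zero = df["beta_exposure"] == 0
    if zero.any():
        warnings.warn(f"excluding {int(zero.sum())} SNP(s) with zero exposure "
                      "beta from Wald ratios", stacklevel=2)
        df = df.loc[~zero]
    g, G = df["beta_exposure"].to_numpy(), df["beta_outcome"].to_numpy()
    se_out = df["se_outcome"].to_numpy()
    ratio = G / g
    if second_order:
        se_exp = df["se_exposure"].to_numpy()
        se = np.sqrt(se_out**2 / g**2 + G**2 * se_exp**2 / g**4)
    else:
        se = se_out / np.abs(g)
    return pd.DataFrame({"rsid": df["rsid"].to_numpy(),
                         "ratio": ratio, "se": se})


def _ivw_core(g: np.ndarray, G: np.ndarray, se_out: np.ndarray):
    w = 1.0 / se_out**2
    denom = float(np.sum(w * g**2))
    beta = float(np.sum(w * g * G)) / denom
    se_fixed = denom ** -0.5
    # Cochran's Q of the per-SNP ratios around the IVW estimate
    ratio = G / g
    w_ratio = g**2 / se_out**2
    q = float(np.sum(w_ratio * (ratio - beta) ** 2))
    return beta, se_fixed, q


def ivw(h: HarmonizedSet, variant: str = MULT_RANDOM) -> MrEstimate:
    """Inverse-variance-weighted estimate (regression through the origin).

    ``fixed`` uses the analytic weighted-least-squares SE;
    ``multiplicative-random`` (default) inflates it by
    max(1, sqrt(Q/(k-1))) so that between-SNP heterogeneity widens — never
    narrows — the interval.  P-values are two-sided normal.
    """
    if variant not in (FIXED, MULT_RANDOM):
        raise ValueError(f"unknown IVW variant {variant!r}")
    df = _retained(h)
    if len(df) < 2:
        raise EstimationError(
            "IVW needs at least 2 SNPs; use wald_ratios for a single SNP")
    beta, se, q = _ivw_core(df["beta_exposure"].to_numpy(),
                            df["beta_outcome"].to_numpy(),
                            df["se_outcome"].to_numpy())
    k = len(df)
    if variant == MULT_RANDOM:
        se *= max(1.0, np.sqrt(q / (k - 1)))
    p = 2.0 * stats.norm.sf(abs(beta / se))
    return MrEstimate("ivw", beta, se, float(p), k, model_variant=variant)


def mr_egger(h: HarmonizedSet) -> EggerResult:
    """MR-Egger regression: weighted fit of Gamma on gamma with free intercept.

    Instruments are first oriented to the exposure-increasing allele.  SEs use
    the multiplicative random-effects scaling max(1, sqrt(Q_E/(k-2))) and
    p-values come from t with k-2 degrees of freedom.
    """
    df = _retained(h.oriented())
    k = len(df)
    if k < 3:
        raise EstimationError("MR-Egger needs at least 3 SNPs")
    g = df["beta_exposure"].to_numpy()
    G = df["beta_outcome"].to_numpy()
    w = 1.0 / df["se_outcome"].to_numpy() ** 2
    if np.ptp(g) == 0:
        raise EstimationError("all exposure betas identical: intercept and "
                              "slope are collinear")
    # closed-form weighted least squares on [1, gamma]
    X = np.column_stack([np.ones(k), g])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * G)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = G - X @ coef
    q_e = float(np.sum(w * resid**2))
    scale = max(1.0, np.sqrt(q_e / (k - 2)))
    cov_unscaled = np.linalg.inv(xtwx)
    ses = np.sqrt(np.diag(cov_unscaled)) * scale
    tvals = coef / ses
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=k - 2)
    slope = MrEstimate("egger-slope", float(coef[1]), float(ses[1]),
                       float(pvals[1]), k, model_variant=MULT_RANDOM)
    return EggerResult(slope=slope, intercept=float(coef[0]),
                       intercept_se=float(ses[0]),
                       intercept_pvalue=float(pvals[0]))


def weighted_quantile(values: np.ndarray, weights: np.ndarray,
                      q: float = 0.5) -> float:
    """Interpolated weighted quantile used by the weighted-median estimator.

    Sort values ascending, normalize weights, place each value at the
    midpoint of its cumulative weight band (cumsum(w) - w/2), and linearly
    interpolate the quantile function at ``q``.
    """
    order = np.argsort(values, kind="stable")
    v = np.asarray(values, dtype=float)[order]
    w = np.asarray(weights, dtype=float)[order]
    w = w / w.sum()
    p = np.cumsum(w) - w / 2.0
    return float(np.interp(q, p, v))


def weighted_median(h: HarmonizedSet, n_boot: int = 1000,
                    seed: int | None = None) -> MrEstimate:
    """Weighted-median estimator with a parametric bootstrap SE.

    Point estimate: the inverse-variance-weighted median of the Wald ratios.
    SE: standard deviation of the estimate over ``n_boot`` replicates drawing
    gamma* ~ N(gamma_hat, se_exp^2) and Gamma* ~ N(Gamma_hat, se_out^2).
    A seed is mandatory so results are reproducible; the computation is
    performed in rsid order so it is invariant to input row order.
    """
    if seed is None:
        raise ValueError("weighted_median requires an explicit seed")
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small; bootstrap SE will be noisy",
                      stacklevel=2)
    df = _retained(h).sort_values("rsid", kind="stable").reset_index(drop=True)
    if len(df) < 3:
        raise EstimationError("weighted median needs at least 3 SNPs")
    g = df["beta_exposure"].to_numpy()
    G = df["beta_outcome"].to_numpy()
    se_g = df["se_exposure"].to_numpy()
    se_G = df["se_outcome"].to_numpy()

    def point(gv: np.ndarray, Gv: np.ndarray) -> float:
        ratio = Gv / gv
        se_ratio = se_G / np.abs(gv)
        return weighted_quantile(ratio, 1.0 / se_ratio**2, 0.5)

    beta = point(g, G)
    rng = np.random.default_rng(seed)
    k = len(g)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        boots[b] = point(rng.normal(g, se_g, size=k),
                         rng.normal(G, se_G, size=k))
    se = float(np.std(boots, ddof=1))
    p = 2.0 * stats.norm.sf(abs(beta / se)) if se > 0 else float(beta == 0.0)
    return MrEstimate("weighted-median", float(beta), se, float(p), k)


def estimate_all(h: HarmonizedSet, seed: int, n_boot: int = 1000,
                 ivw_variant: str = MULT_RANDOM) -> pd.DataFrame:
    """Run IVW (both variants), MR-Egger and weighted median; tidy output.

    One row per method with columns method, variant, n_snps, beta, se, or,
    ci_low, ci_high, pvalue (Egger contributes a slope row and an intercept
    row).
    """
    rows = [ivw(h, FIXED).to_dict()]
    if ivw_variant != FIXED:
        rows.append(ivw(h, ivw_variant).to_dict())
    if h.n_retained >= 3:
        egger = mr_egger(h)
        rows.append(egger.slope.to_dict())
        rows.append({"method": "egger-intercept", "variant": MULT_RANDOM,
                     "n_snps": egger.slope.n_snps, "beta": egger.intercept,
                     "se": egger.intercept_se, "or": np.nan,
                     "ci_low": egger.intercept - Z95 * egger.intercept_se,
                     "ci_high": egger.intercept + Z95 * egger.intercept_se,
                     "pvalue": egger.intercept_pvalue})
        rows.append(weighted_median(h, n_boot=n_boot, seed=seed).to_dict())
    return pd.DataFrame(rows)
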