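"""Individual-level cohort stages.

SNP-trait regressions with covariate adjustment, the split cross-over design
(halve one cohort so SNP-exposure and SNP-outcome associations come from
non-overlapping women, estimate in both directions, pool), fetal-genotype
adjustment comparison, the confounder-adjusted multivariable-regression
comparator, and descriptive characteristic tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .estimators import MrEstimate, ivw
from .meta import StudyEstimate, fixed_effects_meta
from .summary_data import (LINEAR, LOG_ODDS, AssociationTable, HarmonizedSet,
                           SnpAssociation, harmonize)

FETAL_PREFIX = "fetal_"

#: logistic-fit contract: IRLS to this relative tolerance, capped iterations
LOGIT_TOL = 1e-8
LOGIT_MAXITER = 100


class CohortError(ValueError):
    pass


@dataclass
class CohortTable:
    """One row per subject: genotype dosages, phenotypes and covariates.

    ``data`` holds everything; ``snps`` names the maternal dosage columns
    (values in [0, 2]).  Fetal dosages, when present, live in columns named
    ``fetal_<rsid>``.  ``pregnancy_col``/``woman_col`` support cohorts where
    a woman contributes several pregnancies.
    """

    data: pd.DataFrame
    snps: list[str]
    alleles: dict[str, tuple[str, str]] = field(default_factory=dict)
    eaf_is_effect: bool = True
    woman_col: str = "woman_id"
    pregnancy_col: str | None = None

    def __post_init__(self) -> None:
        missing = [s for s in self.snps if s not in self.data.columns]
        if missing:
            raise CohortError(f"dosage column(s) missing: {missing}")
        dos = self.data[self.snps]
        if ((dos < 0) | (dos > 2)).any().any():
            raise CohortError("dosages outside [0, 2]")

    def __len__(self) -> int:
        return len(self.data)

    def snp_alleles(self, snp: str) -> tuple[str, str]:
        # synthetic/unspecified cohorts default to an arbitrary non-palindromic pair
        return self.alleles.get(snp, ("A", "G"))

    def has_fetal(self, snp: str) -> bool:
        return FETAL_PREFIX + snp in self.data.columns

    def fetal_subset(self) -> "CohortTable":
        cols = [FETAL_PREFIX + s for s in self.snps if self.has_fetal(s)]
        if not cols:
            raise CohortError("cohort has no fetal genotype columns")
        mask = self.data[cols].notna().all(axis=1)
        return replace(self, data=self.data.loc[mask].reset_index(drop=True))


def select_one_pregnancy(cohort: CohortTable, seed: int) -> CohortTable:
    """Keep exactly one pregnancy per woman, chosen uniformly at random."""
    if cohort.pregnancy_col is None:
        raise CohortError("cohort has no pregnancy index column")
    rng = np.random.default_rng(seed)
    df = cohort.data.sort_values([cohort.woman_col, cohort.pregnancy_col],
                                 kind="stable")
    sizes = df.groupby(cohort.woman_col, sort=True).size()
    starts = np.concatenate([[0], np.cumsum(sizes.to_numpy())[:-1]])
    picks = starts + rng.integers(0, sizes.to_numpy())
    out = df.iloc[np.sort(picks)].reset_index(drop=True)
    return replace(cohort, data=out, pregnancy_col=None)


def _complete_cases(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    return df.dropna(subset=cols)


def fit_snp_trait(cohort: CohortTable, snp: str, trait: str,
                  family: str = "linear",
                  covariates: list[str] | None = None) -> SnpAssociation:
    """Regress one trait on one SNP's dosage (plus covariates).

    ``linear`` fits OLS (risk-difference scale for a binary trait);
    ``logistic`` fits a binomial GLM by IRLS (log-odds scale).  Complete-case
    analysis; a logistic fit that fails to converge is returned flagged
    ``converged=False`` with a warning so callers can exclude it downstream.
    """
    covariates = covariates or []
    cols = [snp, trait, *covariates]
    df = _complete_cases(cohort.data, cols)
    g = df[snp].to_numpy(dtype=float)
    if np.ptp(g) == 0:
        raise CohortError(f"{snp}: zero-variance dosage")
    X = sm.add_constant(df[[snp, *covariates]].astype(float), has_constant="add")
    y = df[trait].to_numpy(dtype=float)
    converged = True
    if family == "linear":
        fit = sm.OLS(y, X).fit()
    elif family == "logistic":
        model = sm.GLM(y, X, family=sm.families.Binomial())
        fit = model.fit(maxiter=LOGIT_MAXITER, tol=LOGIT_TOL)
        converged = bool(fit.converged)
        if not converged:
            warnings.warn(f"{snp} ~ {trait}: logistic fit did not converge",
                          stacklevel=2)
    else:
        raise ValueError(f"unknown family {family!r}")
    ea, oa = cohort.snp_alleles(snp)
    eaf = float(np.mean(g) / 2.0)
    if not cohort.eaf_is_effect:
        eaf = 1.0 - eaf
    return SnpAssociation(
        rsid=snp, effect_allele=ea, other_allele=oa, eaf=eaf,
        beta=float(fit.params[snp]), se=float(fit.bse[snp]),
        pvalue=float(fit.pvalues[snp]), n=float(len(df)),
        scale=LINEAR if family == "linear" else LOG_ODDS,
        trait=trait, converged=converged)


def fit_many_snp_trait(cohort: CohortTable, snps: list[str], trait: str,
                       family: str = "linear",
                       covariates: list[str] | None = None,
                       ) -> AssociationTable:
    """Fit ``fit_snp_trait`` for many SNPs.

    Without covariates and with ``family='linear'`` the per-SNP univariate
    regressions are computed in closed form simultaneously (identical
    estimates to the per-SNP path, orders of magnitude faster on large
    simulated cohorts); every other case loops over :func:`fit_snp_trait`.
    """
    if family == "linear" and not covariates:
        df = _complete_cases(cohort.data, [*snps, trait])
        G = df[snps].to_numpy(dtype=float)
        y = df[trait].to_numpy(dtype=float)
        n = len(df)
        gc = G - G.mean(axis=0)
        yc = y - y.mean()
        sxx = np.einsum("ij,ij->j", gc, gc)
        if np.any(sxx == 0):
            bad = [snps[i] for i in np.flatnonzero(sxx == 0)]
            raise CohortError(f"zero-variance dosage: {bad}")
        beta = gc.T @ yc / sxx
        # residual variance of y on [1, g_j], per SNP
        syy = float(yc @ yc)
        rss = syy - beta**2 * sxx
        sigma2 = rss / (n - 2)
        se = np.sqrt(sigma2 / sxx)
        from scipy import stats
        pvals = 2.0 * stats.t.sf(np.abs(beta / se), df=n - 2)
        eaf = G.mean(axis=0) / 2.0
        records = []
        for j, snp in enumerate(snps):
            ea, oa = cohort.snp_alleles(snp)
            records.append(SnpAssociation(
                rsid=snp, effect_allele=ea, other_allele=oa,
                eaf=float(eaf[j]), beta=float(beta[j]), se=float(se[j]),
                pvalue=float(pvals[j]), n=float(n), scale=LINEAR,
                trait=trait))
        return AssociationTable(records, trait_label=trait)
    records = [fit_snp_trait(cohort, s, trait, family, covariates)
               for s in snps]
    records = [r for r in records if r.converged]
    return AssociationTable(records, trait_label=trait)


@dataclass(frozen=True)
class SplitCrossoverResult:
    a_on_b: MrEstimate
    b_on_a: MrEstimate
    combined: MrEstimate
    seed: int


def split_crossover(cohort: CohortTable, snps: list[str], exposure: str,
                    outcome: str, seed: int,
                    covariates: list[str] | None = None,
                    exposure_family: str = "linear",
                    outcome_family: str = "logistic",
                    ivw_variant: str | None = None,
                    min_cases: int = 10) -> SplitCrossoverResult:
    """Split cross-over two-sample MR inside a single cohort.

    Randomly halve the cohort; estimate SNP-exposure associations in half A
    and SNP-outcome associations in half B (A on B), then the reverse (B on
    A); pool the two IVW estimates by fixed-effects inverse-variance
    meta-analysis.  The split keeps exposure and outcome samples
    non-overlapping, as the two-sample design requires when one cohort
    contributed to the exposure GWAS.
    """
    from .estimators import MULT_RANDOM
    ivw_variant = ivw_variant or MULT_RANDOM
    rng = np.random.default_rng(seed)
    n = len(cohort)
    in_a = np.zeros(n, dtype=bool)
    in_a[rng.permutation(n)[: n // 2]] = True
    halves = {"A": replace(cohort, data=cohort.data.loc[in_a].reset_index(drop=True)),
              "B": replace(cohort, data=cohort.data.loc[~in_a].reset_index(drop=True))}
    for name, half in halves.items():
        cases = int(half.data[outcome].sum())
        if cases < min_cases:
            raise CohortError(
                f"half {name} has only {cases} {outcome} case(s); "
                f"need at least {min_cases} for a stable logistic fit")

    def cross(exp_half: CohortTable, out_half: CohortTable) -> MrEstimate:
        exp_tab = fit_many_snp_trait(exp_half, snps, exposure,
                                     family=exposure_family,
                                     covariates=covariates)
        out_tab = fit_many_snp_trait(out_half, snps, outcome,
                                     family=outcome_family,
                                     covariates=covariates)
        h = harmonize(exp_tab, out_tab)
        return ivw(h, variant=ivw_variant)

    a_on_b = cross(halves["A"], halves["B"])
    b_on_a = cross(halves["B"], halves["A"])
    pooled = fixed_effects_meta([StudyEstimate.from_mr("A-on-B", a_on_b),
                                 StudyEstimate.from_mr("B-on-A", b_on_a)])
    combined = MrEstimate("split-crossover-ivw", pooled.beta, pooled.se,
                          pooled.pvalue, n_snps=a_on_b.n_snps,
                          model_variant=a_on_b.model_variant)
    return SplitCrossoverResult(a_on_b=a_on_b, b_on_a=b_on_a,
                                combined=combined, seed=seed)


def fetal_adjustment_compare(cohort: CohortTable, snps: list[str],
                             outcome: str,
                             covariates: list[str] | None = None,
                             ) -> tuple[AssociationTable, AssociationTable, pd.DataFrame]:
    """Maternal SNP-outcome associations with vs without fetal-genotype adjustment.

    Both logistic fits run on the identical subset of subjects with fetal
    dosages, so any difference reflects the adjustment, not the sample.
    Perfect maternal-fetal collinearity is reported as an error.
    """
    covariates = covariates or []
    sub = cohort.fetal_subset()
    unadj, adj, deltas = [], [], []
    for snp in snps:
        fetal_col = FETAL_PREFIX + snp
        if fetal_col not in sub.data.columns:
            raise CohortError(f"no fetal dosages for {snp}")
        m = sub.data[snp].to_numpy(float)
        f = sub.data[fetal_col].to_numpy(float)
        if np.ptp(m - f) == 0 or abs(np.corrcoef(m, f)[0, 1]) > 0.999:
            raise CohortError(f"{snp}: fetal dosage collinear with maternal "
                              "dosage; adjusted model is not identifiable")
        u = fit_snp_trait(sub, snp, outcome, family="logistic",
                          covariates=covariates)
        a = fit_snp_trait(sub, snp, outcome, family="logistic",
                          covariates=[fetal_col, *covariates])
        unadj.append(u)
        adj.append(a)
        deltas.append({"rsid": snp, "beta_unadjusted": u.beta,
                       "beta_adjusted": a.beta, "delta_beta": a.beta - u.beta})
    return (AssociationTable(unadj, trait_label=outcome),
            AssociationTable(adj, trait_label=outcome + "-fetal-adjusted"),
            pd.DataFrame(deltas))


@dataclass(frozen=True)
class RegressionFit:
    """One fitted regression: per-term estimates plus bookkeeping."""

    terms: pd.DataFrame  # term, beta, se, pvalue
    family: str
    n: int
    converged: bool
    separation_flag: bool = False

    def term(self, name: str) -> pd.Series:
        row = self.terms.set_index("term").loc[name]
        return row

    def odds_ratio(self, name: str) -> tuple[float, float, float]:
        """(OR, ci_low, ci_high) for one term of a logistic fit."""
        row = self.term(name)
        lo = row["beta"] - 1.96 * row["se"]
        hi = row["beta"] + 1.96 * row["se"]
        return float(np.exp(row["beta"])), float(np.exp(lo)), float(np.exp(hi))


def _fit_logistic(df: pd.DataFrame, outcome: str,
                  predictors: list[str]) -> RegressionFit:
    X = sm.add_constant(df[predictors].astype(float), has_constant="add")
    y = df[outcome].to_numpy(dtype=float)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(
            maxiter=LOGIT_MAXITER, tol=LOGIT_TOL)
    separation = any("separat" in str(w.message).lower() for w in caught) \
        or bool(np.any(np.abs(fit.params) > 15))
    terms = pd.DataFrame({"term": fit.params.index,
                          "beta": fit.params.to_numpy(),
                          "se": fit.bse.to_numpy(),
                          "pvalue": fit.pvalues.to_numpy()})
    return RegressionFit(terms=terms, family="logistic", n=len(df),
                         converged=bool(fit.converged),
                         separation_flag=separation)


def multivariable_outcome_regression(cohort: CohortTable, exposure: str,
                                     outcome: str, confounders: list[str],
                                     ) -> tuple[RegressionFit, RegressionFit]:
    """Crude and confounder-adjusted logistic regression of outcome on exposure.

    The observational comparator to MR: both fits are complete-case, so the
    adjusted model's n is at most the crude model's n.
    """
    crude_df = _complete_cases(cohort.data, [exposure, outcome])
    adj_df = _complete_cases(cohort.data, [exposure, outcome, *confounders])
    crude = _fit_logistic(crude_df, outcome, [exposure])
    adjusted = _fit_logistic(adj_df, outcome, [exposure, *confounders])
    return crude, adjusted


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal rounding with ties away from zero (as printed tables round)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def prevalence_pct(cases: float, controls: float, ndigits: int = 1) -> float:
    """Prevalence as a percentage of cases + controls, half-up rounded."""
    total = cases + controls
    if total == 0:
        return 0.0
    return round_half_up(100.0 * cases / total, ndigits)


def percent_of_total(count: float, total: float, ndigits: int = 1) -> float:
    if total == 0:
        return 0.0
    return round_half_up(100.0 * count / total, ndigits)


def crude_odds_ratio(a: float, b: float, c: float, d: float) -> float:
    """Cross-product OR of a 2x2 table: (exposed cases * unexposed controls) /
    (unexposed cases * exposed controls)."""
    return (a * d) / (b * c)


def tabulate_characteristics(cohort: CohortTable,
                             continuous: list[str] | None = None,
                             categorical: list[str] | None = None,
                             outcomes: list[str] | None = None,
                             stratifier: str | None = None) -> pd.DataFrame:
    """Descriptive characteristics table.

    Continuous variables as mean (SD); categorical as N (% of total N);
    binary outcomes as N cases / N controls (prevalence %).  With a
    ``stratifier`` the table gets one column block per stratum.  Percentages
    are rounded to one decimal, half-up, matching how cohort tables print.
    """
    continuous = continuous or []
    categorical = categorical or []
    outcomes = outcomes or []
    if stratifier is None:
        groups = [("all", cohort.data)]
    else:
        levels = sorted(cohort.data[stratifier].dropna().unique())
        groups = [(str(lv), cohort.data[cohort.data[stratifier] == lv])
                  for lv in levels]
    rows = []
    for name, df in groups:
        total = len(df)
        for var in continuous:
            vals = df[var].dropna()
            mean = float(vals.mean()) if len(vals) else 0.0
            sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            rows.append({"stratum": name, "variable": var, "kind": "continuous",
                         "value": f"{round_half_up(mean)} ({round_half_up(sd)})",
                         "n": len(vals)})
        for var in categorical:
            for level, count in df[var].value_counts(dropna=True).sort_index().items():
                pct = percent_of_total(count, total)
                rows.append({"stratum": name, "variable": f"{var}={level}",
                             "kind": "categorical",
                             "value": f"{int(count)} ({pct})", "n": int(count)})
        for var in outcomes:
            vals = df[var].dropna()
            cases = int(vals.sum())
            controls = int(len(vals) - cases)
            prev = prevalence_pct(cases, controls)
            rows.append({"stratum": name, "variable": var, "kind": "outcome",
                         "value": f"{cases}/{controls} ({prev})",
                         "n": cases + controls})
    return pd.DataFrame(rows, columns=["stratum", "variable", "kind",
                                       "value", "n"])
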