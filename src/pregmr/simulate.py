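"""Synthetic cohorts and summary statistics with known causal structure.

The real cohorts behind this analysis (UK Biobank, ALSPAC, BiB, MoBa,
FinnGen) are access-restricted, so every pipeline stage is exercised on
generated data that mimics their structure: ~81 independent biallelic
instruments with small effects on a binary exposure of 20-30% prevalence,
binary outcomes of 0.5-25% prevalence, a configurable causal log-odds
effect, balanced or directional horizontal pleiotropy, shared confounding,
and Mendelian transmission of fetal genotypes.

Two layers are provided:

* :func:`simulate_cohort` — individual-level data through the full liability
  model, for the regression, split cross-over and multivariable stages;
* :func:`simulate_summary_stats` — summary associations drawn directly
  around their true values, a fast layer for estimator calibration studies.

A continuous-exposure/continuous-outcome mode exists alongside the binary
liability mode because odds ratios are non-collapsible: with a binary
exposure the two-sample MR estimand is attenuated relative to the
conditional log-odds effect even with valid instruments, so exact parameter
recovery is only a meaningful benchmark in the linear mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import FETAL_PREFIX, CohortTable
from .summary_data import LINEAR, LOG_ODDS, AssociationTable, SnpAssociation

PLEIOTROPY_KINDS = ("none", "balanced", "directional", "proportion-invalid")


@dataclass(frozen=True)
class PleiotropyConfig:
    """Direct SNP-outcome effects d_j violating the exclusion restriction.

    ``none``: d_j = 0.  ``balanced``: d_j ~ N(0, sigma²) (zero mean, InSIDE
    holds, IVW stays unbiased but heterogeneous).  ``directional``:
    d_j ~ N(mu, sigma²) (IVW biased by mu/mean(a); the Egger intercept
    estimates mu).  ``proportion-invalid``: a fraction ``prop_invalid`` of
    SNPs get d_j ~ N(mu, sigma²), the rest are valid — the weighted-median
    robustness scenario.
    """

    kind: str = "none"
    mu: float = 0.0
    sigma: float = 0.0
    prop_invalid: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in PLEIOTROPY_KINDS:
            raise ValueError(f"unknown pleiotropy kind {self.kind!r}")
        if not 0.0 <= self.prop_invalid <= 1.0:
            raise ValueError("prop_invalid must be in [0, 1]")

    def draw(self, n_snps: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "none":
            return np.zeros(n_snps)
        if self.kind == "balanced":
            return rng.normal(0.0, self.sigma, n_snps)
        if self.kind == "directional":
            return rng.normal(self.mu, self.sigma, n_snps)
        d = np.zeros(n_snps)
        n_invalid = int(round(self.prop_invalid * n_snps))
        idx = rng.choice(n_snps, size=n_invalid, replace=False)
        d[idx] = rng.normal(self.mu, self.sigma, n_invalid)
        return d


@dataclass(frozen=True)
class SimulationConfig:
    """Full generative specification of one synthetic study.

    Defaults mirror the study this package emulates: 81 independent
    instruments, a binary exposure of 28% prevalence whose instruments
    jointly explain 0.42% of its variance, and a rare binary outcome (5%
    prevalence).  ``effect_sizes`` (log-odds per allele in binary mode,
    phenotype units per allele in continuous mode) overrides ``target_r2``
    when given.
    """

    seed: int
    n_subjects: int = 10_000
    n_snps: int = 81
    maf_range: tuple[float, float] = (0.1, 0.5)
    target_r2: float = 0.0042
    effect_sizes: tuple[float, ...] | None = None
    exposure_mode: str = "binary-liability"  # or "continuous"
    outcome_mode: str = "binary"             # or "continuous"
    exposure_prevalence: float = 0.28
    outcome_prevalence: float = 0.05
    causal_effect: float = 0.0
    pleiotropy: PleiotropyConfig = field(default_factory=PleiotropyConfig)
    confounder_exposure: float = 0.0
    confounder_outcome: float = 0.0
    fetal_genotypes: bool = False

    def __post_init__(self) -> None:
        for p, name in ((self.exposure_prevalence, "exposure_prevalence"),
                        (self.outcome_prevalence, "outcome_prevalence")):
            if not 0.0 < p < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.exposure_mode not in ("binary-liability", "continuous"):
            raise ValueError(f"unknown exposure_mode {self.exposure_mode!r}")
        if self.outcome_mode not in ("binary", "continuous"):
            raise ValueError(f"unknown outcome_mode {self.outcome_mode!r}")

    def rsids(self) -> list[str]:
        return [f"rs{j + 1:04d}" for j in range(self.n_snps)]


def _draw_mafs(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = config.maf_range
    return rng.uniform(lo, hi, config.n_snps) if hi > lo \
        else np.full(config.n_snps, lo)


def instrument_effects(config: SimulationConfig, mafs: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    """Per-allele instrument effects a_j.

    Explicit ``effect_sizes`` win; otherwise heterogeneous effects (shape
    multipliers u_j ~ Uniform(0.5, 1.5), as GWAS lead SNPs never share one
    effect size) are scaled so the instruments jointly explain ``target_r2``
    of the exposure variance.  Binary mode calibrates on the observed 0/1
    scale via the logistic linearisation dP/dg ~= p(1-p)·a; continuous mode
    solves sum_j a_j² 2f(1-f) = R²·(sum + c_x² + 1) exactly.
    """
    if config.effect_sizes is not None:
        a = np.asarray(config.effect_sizes, dtype=float)
        if a.shape != (config.n_snps,):
            raise ValueError("effect_sizes length must equal n_snps")
        _ = rng.uniform(0.5, 1.5, config.n_snps)  # keep the stream aligned
        return a
    var_g = 2.0 * mafs * (1.0 - mafs)
    r2 = config.target_r2
    if config.exposure_mode == "continuous":
        resid = config.confounder_exposure**2 + 1.0
        target_sum = r2 * resid / (1.0 - r2)  # sum_j a_j² 2f(1-f)
    else:
        p = config.exposure_prevalence
        # observed-scale r2_j ~= a² p(1-p) 2f(1-f); sum over SNPs = target
        target_sum = r2 / (p * (1.0 - p))
    u = rng.uniform(0.5, 1.5, config.n_snps)
    scale = np.sqrt(target_sum / float(np.sum(u**2 * var_g)))
    return u * scale


def solve_intercept(linear_predictor: np.ndarray, prevalence: float,
                    tol: float = 1e-4, max_iter: int = 200) -> float:
    """Bisection for the intercept giving a target mean of expit(alpha + eta)."""
    lo, hi = -30.0, 30.0
    mean_lo = float(np.mean(expit(lo + linear_predictor)))
    mean_hi = float(np.mean(expit(hi + linear_predictor)))
    if not mean_lo <= prevalence <= mean_hi:
        raise ValueError(
            f"intercept solve failed: prevalence {prevalence} unattainable "
            f"given the linear predictor (range {mean_lo:.3g}..{mean_hi:.3g})")
    for _ in range(max_iter):
        mid = (lo + hi) / 2.0
        mean_mid = float(np.mean(expit(mid + linear_predictor)))
        if abs(mean_mid - prevalence) < tol:
            return mid
        if mean_mid < prevalence:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def _transmit_fetal(maternal: np.ndarray, mafs: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    """Mendelian transmission: one maternal allele + one random paternal allele."""
    from_mother = rng.binomial(1, maternal / 2.0)
    from_father = rng.binomial(1, mafs[None, :],
                               size=maternal.shape)
    return from_mother + from_father


def simulate_cohort(config: SimulationConfig) -> CohortTable:
    """Generate one individual-level cohort under the configured model.

    Genotypes g_j ~ Binomial(2, f_j); confounder U ~ N(0, 1); exposure from
    a logistic liability (binary mode) or a linear model with unit noise
    (continuous mode); outcome from a logistic liability in theta·X plus
    per-SNP pleiotropic paths d_j·g_j and the confounder (binary mode), or
    the analogous linear model (continuous mode).  Intercepts are solved by
    bisection to hit target prevalences within 1e-4.
    """
    rng = np.random.default_rng(config.seed)
    n, k = config.n_subjects, config.n_snps
    mafs = _draw_mafs(config, rng)
    a = instrument_effects(config, mafs, rng)
    # pleiotropy drawn right after mafs so true_effects() sees the same stream
    d = config.pleiotropy.draw(k, rng)
    G = rng.binomial(2, mafs[None, :], size=(n, k)).astype(np.float64)
    U = rng.normal(size=n)
    gsum = G @ a

    if config.exposure_mode == "binary-liability":
        eta_x = gsum + config.confounder_exposure * U
        alpha_x = solve_intercept(eta_x, config.exposure_prevalence)
        X = rng.binomial(1, expit(alpha_x + eta_x)).astype(np.float64)
    else:
        X = gsum + config.confounder_exposure * U + rng.normal(size=n)

    pleio = G @ d
    eta_y = config.causal_effect * X + pleio + config.confounder_outcome * U
    if config.outcome_mode == "binary":
        alpha_y = solve_intercept(eta_y, config.outcome_prevalence)
        Y = rng.binomial(1, expit(alpha_y + eta_y)).astype(np.float64)
    else:
        Y = eta_y + rng.normal(size=n)

    rsids = config.rsids()
    data = pd.DataFrame(G, columns=rsids)
    data.insert(0, "woman_id", np.arange(n))
    data["exposure"] = X
    data["outcome"] = Y
    data["confounder"] = U
    data["age"] = np.round(rng.normal(28.0, 5.0, n), 1)
    if config.fetal_genotypes:
        F = _transmit_fetal(G, mafs, rng).astype(np.float64)
        for j, rsid in enumerate(rsids):
            data[FETAL_PREFIX + rsid] = F[:, j]
    return CohortTable(data=data, snps=rsids)


def true_effects(config: SimulationConfig) -> pd.DataFrame:
    """The generative truths (maf, a_j, d_j) for a config — for oracle tests."""
    rng = np.random.default_rng(config.seed)
    mafs = _draw_mafs(config, rng)
    a = instrument_effects(config, mafs, rng)
    # both generators draw pleiotropy immediately after mafs, so this replays
    # the exact d_j either layer used
    d = config.pleiotropy.draw(config.n_snps, rng)
    return pd.DataFrame({"rsid": config.rsids(), "maf": mafs,
                         "effect_exposure": a, "pleiotropy": d})


def simulate_summary_stats(config: SimulationConfig, se_exposure: float,
                           se_outcome: float,
                           ) -> tuple[AssociationTable, AssociationTable]:
    """Summary-level layer: draw associations directly around their truths.

    gamma_j ~ N(a_j, se_exposure²) and Gamma_j ~ N(theta·a_j + d_j,
    se_outcome²), with EAF and n fields populated consistently with the
    config.  This is the fast oracle layer for estimator calibration; it
    bypasses individual-level sampling entirely.
    """
    rng = np.random.default_rng(config.seed)
    mafs = _draw_mafs(config, rng)
    a = instrument_effects(config, mafs, rng)
    d = config.pleiotropy.draw(config.n_snps, rng)
    gamma = a + rng.normal(0.0, se_exposure, config.n_snps) if se_exposure > 0 \
        else a.copy()
    true_out = config.causal_effect * a + d
    Gamma = true_out + rng.normal(0.0, se_outcome, config.n_snps) \
        if se_outcome > 0 else true_out
    se_g = np.full(config.n_snps, se_exposure if se_exposure > 0 else 1e-12)
    se_G = np.full(config.n_snps, se_outcome if se_outcome > 0 else 1e-12)
    from scipy import stats
    n = float(config.n_subjects)
    # exposure summaries emulate the linear-regression (risk-difference) scale
    exp_scale = LINEAR
    records_exp, records_out = [], []
    for j, rsid in enumerate(config.rsids()):
        p_g = 2.0 * stats.norm.sf(abs(gamma[j] / se_g[j]))
        p_G = 2.0 * stats.norm.sf(abs(Gamma[j] / se_G[j]))
        records_exp.append(SnpAssociation(
            rsid=rsid, effect_allele="A", other_allele="G", eaf=float(mafs[j]),
            beta=float(gamma[j]), se=float(se_g[j]), pvalue=float(p_g), n=n,
            scale=exp_scale, trait="exposure"))
        records_out.append(SnpAssociation(
            rsid=rsid, effect_allele="A", other_allele="G", eaf=float(mafs[j]),
            beta=float(Gamma[j]), se=float(se_G[j]), pvalue=float(p_G), n=n,
            scale=LOG_ODDS, trait="outcome"))
    return (AssociationTable(records_exp, trait_label="exposure"),
            AssociationTable(records_out, trait_label="outcome"))


def child_seeds(seed: int, n: int) -> list[int]:
    """Expand one global seed into reproducible per-stage child seeds (< 2^31)."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]
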