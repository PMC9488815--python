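"""Fixed-effects meta-analysis across studies and leave-one-study-out.

Per-study causal estimates (log-OR scale) are pooled with inverse-variance
weights; between-study heterogeneity is summarised by Cochran's Q across
studies.  Odds ratios are presentation-layer: pooling always happens on the
log scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import Z95, MrEstimate


@dataclass(frozen=True)
class StudyEstimate:
    """One study's contribution to a cross-study meta-analysis."""

    study: str
    beta: float
    se: float

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError(f"{self.study}: se must be > 0")

    @property
    def weight(self) -> float:
        return 1.0 / self.se**2

    @classmethod
    def from_mr(cls, study: str, est: MrEstimate) -> "StudyEstimate":
        return cls(study=study, beta=est.beta, se=est.se)


@dataclass(frozen=True)
class MetaResult:
    beta: float
    se: float
    pvalue: float
    q: float
    q_df: int
    q_pvalue: float
    per_study: pd.DataFrame  # study, beta, se, weight_pct

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

    def as_estimate(self, method: str = "meta") -> MrEstimate:
        return MrEstimate(method, self.beta, self.se, self.pvalue,
                          n_snps=len(self.per_study))


def fixed_effects_meta(estimates: list[StudyEstimate]) -> MetaResult:
    """Inverse-variance-weighted fixed-effects pooling on the log-OR scale."""
    if not estimates:
        raise ValueError("need at least one study estimate")
    betas = np.array([e.beta for e in estimates])
    ses = np.array([e.se for e in estimates])
    w = 1.0 / ses**2
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    p = 2.0 * stats.norm.sf(abs(beta / se))
    q = float(np.sum(w * (betas - beta) ** 2))
    q_df = len(estimates) - 1
    q_p = float(stats.chi2.sf(q, q_df)) if q_df > 0 else float("nan")
    per_study = pd.DataFrame({
        "study": [e.study for e in estimates],
        "beta": betas, "se": ses,
        "weight_pct": 100.0 * w / np.sum(w),
    })
    return MetaResult(beta=beta, se=se, pvalue=float(p), q=q, q_df=q_df,
                      q_pvalue=q_p, per_study=per_study)


def leave_one_study_out(estimates: list[StudyEstimate],
                        restrict: list[str] | None = None,
                        ) -> dict[str, MetaResult]:
    """Re-pool omitting each study in turn, optionally within a named subset."""
    pool = estimates if restrict is None else \
        [e for e in estimates if e.study in set(restrict)]
    if len(pool) < 2:
        raise ValueError("leave-one-study-out needs at least 2 studies")
    out: dict[str, MetaResult] = {}
    for omit in pool:
        rest = [e for e in pool if e.study != omit.study]
        out[omit.study] = fixed_effects_meta(rest)
    return out
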