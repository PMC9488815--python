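"""Summary-statistic data model, I/O and preparation.

GWAS summary statistics arrive as one table per trait per study (rsid,
alleles, effect-allele frequency, beta, SE, p, N).  Before any two-sample
Mendelian randomization estimator can run, the exposure and outcome tables
must be harmonized to a common effect allele, pruned of correlated
instruments, and cleaned of rare variants.  This module owns those steps and
the tagged containers the rest of the package consumes.

Effect sizes carry an explicit scale tag (``linear`` for risk-difference
betas from linear regression on a binary trait, ``log-odds`` for logistic
betas) because the causal estimate inherits the outcome scale and mixing
scales within one instrument set is a silent error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LINEAR = "linear"
LOG_ODDS = "log-odds"
SCALES = (LINEAR, LOG_ODDS)

VALID_BASES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: mandatory columns of the summary-stat TSV dialect
REQUIRED_COLUMNS = ("rsid", "effect_allele", "other_allele", "eaf", "beta",
                    "se", "pvalue", "n")

#: default exposure-EAF window inside which a palindromic (A/T or C/G) SNP
#: cannot be oriented from allele frequencies and is excluded
PALINDROMIC_WINDOW = (0.42, 0.58)

EXCL_PALINDROMIC = "palindromic-ambiguous"
EXCL_ALLELE_MISMATCH = "allele-mismatch"
EXCL_MAF = "maf-filtered"
EXCL_STEIGER = "steiger-removed"


class FormatError(ValueError):
    """A file does not conform to the summary-stat TSV dialect."""


class ValidationError(ValueError):
    """Well-formed input carrying impossible values (se <= 0, eaf > 1, ...)."""


class HarmonizationError(ValueError):
    """Exposure and outcome tables cannot be aligned at all."""


@dataclass(frozen=True)
class SnpAssociation:
    """One SNP's estimated association with one trait in one sample."""

    rsid: str
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pvalue: float
    n: float
    scale: str = LOG_ODDS
    trait: str = ""
    n_cases: float | None = None
    n_controls: float | None = None
    converged: bool = True

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValidationError(f"{self.rsid}: se must be > 0, got {self.se}")
        if not 0.0 <= self.eaf <= 1.0:
            raise ValidationError(f"{self.rsid}: eaf outside [0, 1]: {self.eaf}")
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.rsid}: identical alleles")
        if self.scale not in SCALES:
            raise ValidationError(f"{self.rsid}: unknown scale {self.scale!r}")

    @property
    def maf(self) -> float:
        return min(self.eaf, 1.0 - self.eaf)

    @property
    def is_palindromic(self) -> bool:
        return COMPLEMENT.get(self.effect_allele) == self.other_allele


@dataclass
class AssociationTable:
    """All SNP associations for one trait in one study, keyed by rsid."""

    records: list[SnpAssociation]
    study_label: str = ""
    trait_label: str = ""

    def __post_init__(self) -> None:
        rsids = [r.rsid for r in self.records]
        if len(set(rsids)) != len(rsids):
            dupes = sorted({r for r in rsids if rsids.count(r) > 1})
            raise ValidationError(f"duplicate rsids in table: {dupes}")
        scales = {r.scale for r in self.records}
        if len(scales) > 1:
            raise ValidationError(f"mixed beta scales within one table: {scales}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def scale(self) -> str:
        return self.records[0].scale if self.records else LOG_ODDS

    @property
    def rsids(self) -> list[str]:
        return [r.rsid for r in self.records]

    def get(self, rsid: str) -> SnpAssociation:
        for r in self.records:
            if r.rsid == rsid:
                return r
        raise KeyError(rsid)

    def to_frame(self) -> pd.DataFrame:
        cols = ["rsid", "effect_allele", "other_allele", "eaf", "beta", "se",
                "pvalue", "n"]
        return pd.DataFrame([{c: getattr(r, c) for c in cols}
                             for r in self.records], columns=cols)


@dataclass
class HarmonizedSet:
    """Exposure/outcome association pairs aligned to a common effect allele.

    Rows flagged ``excluded`` stay in the frame for auditability; every
    estimator works on :meth:`retained` only.  ``n_dropped`` counts SNPs that
    were present in only one of the two input tables.
    """

    frame: pd.DataFrame
    exposure_scale: str = LINEAR
    outcome_scale: str = LOG_ODDS
    exposure_label: str = ""
    outcome_label: str = ""
    n_dropped: int = 0

    COLUMNS = ("rsid", "effect_allele", "other_allele",
               "beta_exposure", "se_exposure", "eaf_exposure",
               "n_exposure", "pvalue_exposure",
               "beta_outcome", "se_outcome", "eaf_outcome", "n_outcome",
               "excluded", "exclusion_reason")

    @classmethod
    def from_arrays(cls, beta_exposure, se_exposure, beta_outcome, se_outcome,
                    rsids=None, eaf_exposure=None, eaf_outcome=None,
                    n_exposure=np.nan, n_outcome=np.nan,
                    exposure_scale: str = LINEAR,
                    outcome_scale: str = LOG_ODDS) -> "HarmonizedSet":
        """Build a harmonized set straight from aligned effect arrays.

        For callers that already hold allele-aligned summaries (simulation
        layers, tests); alleles are filled with a placeholder A/G pair.
        """
        beta_exposure = np.asarray(beta_exposure, dtype=float)
        k = len(beta_exposure)
        if rsids is None:
            rsids = [f"rs{j + 1:04d}" for j in range(k)]
        eaf_exposure = np.full(k, 0.3) if eaf_exposure is None else eaf_exposure
        eaf_outcome = eaf_exposure if eaf_outcome is None else eaf_outcome
        frame = pd.DataFrame({
            "rsid": list(rsids),
            "effect_allele": "A", "other_allele": "G",
            "beta_exposure": beta_exposure,
            "se_exposure": np.asarray(se_exposure, dtype=float),
            "eaf_exposure": np.asarray(eaf_exposure, dtype=float),
            "n_exposure": n_exposure, "pvalue_exposure": np.nan,
            "beta_outcome": np.asarray(beta_outcome, dtype=float),
            "se_outcome": np.asarray(se_outcome, dtype=float),
            "eaf_outcome": np.asarray(eaf_outcome, dtype=float),
            "n_outcome": n_outcome,
            "excluded": False, "exclusion_reason": "",
        }, columns=list(cls.COLUMNS))
        return cls(frame=frame, exposure_scale=exposure_scale,
                   outcome_scale=outcome_scale)

    def retained(self) -> pd.DataFrame:
        return self.frame.loc[~self.frame["excluded"]].reset_index(drop=True)

    @property
    def n_retained(self) -> int:
        return int((~self.frame["excluded"]).sum())

    def exclude(self, rsids: Iterable[str], reason: str) -> "HarmonizedSet":
        """Return a copy with the given SNPs flagged excluded."""
        frame = self.frame.copy()
        mask = frame["rsid"].isin(list(rsids)) & ~frame["excluded"]
        frame.loc[mask, "excluded"] = True
        frame.loc[mask, "exclusion_reason"] = reason
        return replace(self, frame=frame)

    def oriented(self) -> "HarmonizedSet":
        """Flip SNP pairs so every retained exposure beta is >= 0.

        MR-Egger is not invariant to the arbitrary choice of effect allele;
        the conventional fix is to orient all instruments to the
        exposure-increasing allele before fitting the intercept.
        """
        frame = self.frame.copy()
        flip = (frame["beta_exposure"] < 0) & ~frame["excluded"]
        for col in ("beta_exposure", "beta_outcome"):
            frame.loc[flip, col] = -frame.loc[flip, col]
        for col in ("eaf_exposure", "eaf_outcome"):
            frame.loc[flip, col] = 1.0 - frame.loc[flip, col]
        ea = frame.loc[flip, "effect_allele"].copy()
        frame.loc[flip, "effect_allele"] = frame.loc[flip, "other_allele"]
        frame.loc[flip, "other_allele"] = ea
        return replace(self, frame=frame)


def _parse_row(row: pd.Series, idx: int, scale: str, trait: str) -> SnpAssociation:
    ea = str(row["effect_allele"]).strip().upper()
    oa = str(row["other_allele"]).strip().upper()
    for allele, name in ((ea, "effect_allele"), (oa, "other_allele")):
        if allele not in VALID_BASES:
            raise ValidationError(
                f"row {idx}: {name} {allele!r} is not a single A/C/G/T base "
                "(indels are out of scope)")
    return SnpAssociation(
        rsid=str(row["rsid"]).strip(),
        effect_allele=ea,
        other_allele=oa,
        eaf=float(row["eaf"]),
        beta=float(row["beta"]),
        se=float(row["se"]),
        pvalue=float(row["pvalue"]),
        n=float(row["n"]),
        scale=scale,
        trait=trait,
    )


def read_association_table(path, scale: str, study_label: str = "",
                           trait_label: str = "") -> AssociationTable:
    """Read a summary-stat TSV and validate every row.

    Raises :class:`FormatError` when a mandatory column is missing and
    :class:`ValidationError` naming the offending row(s) for impossible
    values.  Alleles are normalized to uppercase.
    """
    if scale not in SCALES:
        raise ValueError(f"scale must be one of {SCALES}, got {scale!r}")
    df = pd.read_csv(path, sep="\t", dtype={"rsid": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")
    records, problems = [], []
    for idx, row in df.iterrows():
        try:
            records.append(_parse_row(row, int(idx) + 2, scale, trait_label))
        except (ValidationError, ValueError) as exc:
            # idx+2: 1-based line number counting the header line
            problems.append(f"row {int(idx) + 2}: {exc}")
    if problems:
        raise ValidationError(f"{path}: " + "; ".join(problems))
    return AssociationTable(records, study_label=study_label,
                            trait_label=trait_label)


def write_association_table(table: AssociationTable, path) -> None:
    """Write the table in the same TSV dialect ``read_association_table`` reads."""
    table.to_frame().to_csv(path, sep="\t", index=False)


def read_ld_matrix(path) -> pd.DataFrame:
    """Read an r-squared matrix as TSV with an rsid header row and column."""
    ld = pd.read_csv(path, sep="\t", index_col=0)
    ld.index = ld.index.astype(str)
    return ld


def write_ld_matrix(ld: pd.DataFrame, path) -> None:
    ld.to_csv(path, sep="\t")


def harmonize(exposure: AssociationTable, outcome: AssociationTable,
              palindromic_eaf_window: tuple[float, float] = PALINDROMIC_WINDOW,
              ) -> HarmonizedSet:
    """Align outcome associations to the exposure effect allele.

    For SNPs whose outcome effect allele equals the exposure other allele the
    outcome beta is negated and its EAF complemented.  Palindromic SNPs (A/T
    or C/G) whose exposure EAF falls inside ``palindromic_eaf_window`` are
    excluded as strand-ambiguous; outside the window they are oriented by
    frequency agreement.  SNPs present in only one table are dropped and
    counted in ``n_dropped``.
    """
    lo, hi = palindromic_eaf_window
    out_by_rsid = {r.rsid: r for r in outcome.records}
    common = [r for r in exposure.records if r.rsid in out_by_rsid]
    if not common:
        raise HarmonizationError(
            f"no overlapping rsids between exposure ({len(exposure)} SNPs) "
            f"and outcome ({len(outcome)} SNPs)")
    n_dropped = (len(exposure) - len(common)) + (len(outcome) - len(common))

    rows = []
    for exp in common:
        out = out_by_rsid[exp.rsid]
        beta_out, eaf_out = out.beta, out.eaf
        excluded, reason = False, ""

        same = (out.effect_allele == exp.effect_allele
                and out.other_allele == exp.other_allele)
        swapped = (out.effect_allele == exp.other_allele
                   and out.other_allele == exp.effect_allele)

        if exp.is_palindromic:
            # strand is unresolvable from alleles alone; same/swapped above
            # cannot be distinguished from a strand flip
            if lo < exp.eaf < hi:
                excluded, reason = True, EXCL_PALINDROMIC
            elif not (same or swapped):
                excluded, reason = True, EXCL_ALLELE_MISMATCH
            else:
                # orient by frequency agreement with the exposure EAF
                if (exp.eaf - 0.5) * (eaf_out - 0.5) < 0:
                    beta_out, eaf_out = -beta_out, 1.0 - eaf_out
        elif same:
            pass
        elif swapped:
            beta_out, eaf_out = -beta_out, 1.0 - eaf_out
        else:
            excluded, reason = True, EXCL_ALLELE_MISMATCH

        rows.append({
            "rsid": exp.rsid,
            "effect_allele": exp.effect_allele,
            "other_allele": exp.other_allele,
            "beta_exposure": exp.beta, "se_exposure": exp.se,
            "eaf_exposure": exp.eaf, "n_exposure": exp.n,
            "pvalue_exposure": exp.pvalue,
            "beta_outcome": beta_out, "se_outcome": out.se,
            "eaf_outcome": eaf_out, "n_outcome": out.n,
            "excluded": excluded, "exclusion_reason": reason,
        })
    frame = pd.DataFrame(rows, columns=list(HarmonizedSet.COLUMNS))
    logger.info("harmonize(%s ~ %s): %d aligned, %d excluded, %d dropped",
                exposure.trait_label or "exposure",
                outcome.trait_label or "outcome",
                len(frame), int(frame["excluded"].sum()), n_dropped)
    return HarmonizedSet(frame=frame,
                         exposure_scale=exposure.scale,
                         outcome_scale=outcome.scale,
                         exposure_label=exposure.trait_label,
                         outcome_label=outcome.trait_label,
                         n_dropped=n_dropped)


def prune_ld(snps: AssociationTable, ld: pd.DataFrame,
             r2_threshold: float = 0.01) -> AssociationTable:
    """Greedy LD pruning at an r-squared threshold.

    Repeatedly keep the remaining SNP with the smallest p-value (ties broken
    by rsid, for determinism) and discard everything correlated with it at
    r² >= ``r2_threshold``.  Output is ordered by ascending p-value.
    """
    missing = sorted(set(snps.rsids) - set(map(str, ld.index)))
    if missing:
        raise ValidationError(f"rsids missing from LD matrix: {missing}")
    ld = ld.loc[snps.rsids, snps.rsids]
    if not np.allclose(ld.values, ld.values.T, atol=1e-8):
        raise ValidationError("LD matrix is not symmetric")
    if not np.allclose(np.diag(ld.values), 1.0, atol=1e-6):
        raise ValidationError("LD matrix diagonal is not 1")

    remaining = sorted(snps.records, key=lambda r: (r.pvalue, r.rsid))
    kept: list[SnpAssociation] = []
    while remaining:
        best = remaining.pop(0)
        kept.append(best)
        remaining = [r for r in remaining
                     if float(ld.loc[best.rsid, r.rsid]) < r2_threshold]
    n_removed = len(snps) - len(kept)
    if n_removed:
        logger.info("prune_ld: removed %d of %d SNPs at r2 >= %g",
                    n_removed, len(snps), r2_threshold)
    return AssociationTable(kept, study_label=snps.study_label,
                            trait_label=snps.trait_label)


def filter_maf(table: AssociationTable, min_maf: float = 0.01) -> AssociationTable:
    """Drop records whose minor allele frequency is below ``min_maf``."""
    kept = [r for r in table.records if r.maf >= min_maf]
    n_removed = len(table) - len(kept)
    if n_removed:
        logger.info("filter_maf: removed %d of %d SNPs with MAF < %g",
                    n_removed, len(table), min_maf)
    return AssociationTable(kept, study_label=table.study_label,
                            trait_label=table.trait_label)
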