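"""End-to-end orchestration: per-study MR, diagnostics, and cross-study pooling.

A YAML (or dict) configuration names the exposure summary table, per-study
outcome tables, the outcome list, and the analysis options (LD threshold,
MAF cutoff, Steiger alpha, IVW variant, bootstrap replicates, global seed).
For every outcome the pipeline harmonizes each study against the exposure,
runs IVW / MR-Egger / weighted median with heterogeneity and leave-one-out
diagnostics, re-runs IVW after Steiger filtering, pools studies by
fixed-effects meta-analysis with leave-one-study-out, and writes one tidy
TSV bundle per outcome plus a run log recording every seed and threshold.

A failure in one outcome is recorded in its bundle and the remaining
outcomes still run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import diagnostics, estimators, meta, summary_data
from .simulate import child_seeds

logger = logging.getLogger(__name__)

DEFAULT_OPTIONS = {
    "ld_r2_threshold": 0.01,
    "min_maf": 0.01,
    "steiger_alpha": 0.05,
    "ivw_variant": estimators.MULT_RANDOM,
    "n_boot": 1000,
    "palindromic_window": list(summary_data.PALINDROMIC_WINDOW),
}


@dataclass
class OutcomeBundle:
    """Everything the pipeline produced for one outcome."""

    outcome: str
    results: pd.DataFrame | None = None
    steiger_audit: pd.DataFrame | None = None
    loo_snp: pd.DataFrame | None = None
    loo_study: pd.DataFrame | None = None
    harmonization: pd.DataFrame | None = None
    meta_result: meta.MetaResult | None = None
    error: str | None = None


def load_config(source) -> dict:
    if isinstance(source, dict):
        return source
    with open(source) as fh:
        return yaml.safe_load(fh)


def _load_table(entry: dict, default_scale: str) -> summary_data.AssociationTable:
    if "table_obj" in entry:  # programmatic injection
        return entry["table_obj"]
    return summary_data.read_association_table(
        entry["table"], scale=entry.get("scale", default_scale),
        study_label=entry.get("study", ""), trait_label=entry.get("trait", ""))


def _prepare_exposure(config: dict, options: dict) -> summary_data.AssociationTable:
    exposure = _load_table(config["exposure"], summary_data.LINEAR)
    if config.get("ld_matrix"):
        ld = summary_data.read_ld_matrix(config["ld_matrix"])
        exposure = summary_data.prune_ld(exposure, ld,
                                         options["ld_r2_threshold"])
    return exposure


def _analyse_one_study(exposure, outcome_entry, options, seed, log):
    out_tab = _load_table(outcome_entry, summary_data.LOG_ODDS)
    out_tab = summary_data.filter_maf(out_tab, options["min_maf"])
    h = summary_data.harmonize(
        exposure, out_tab,
        palindromic_eaf_window=tuple(options["palindromic_window"]))
    res = estimators.estimate_all(h, seed=seed, n_boot=options["n_boot"],
                                  ivw_variant=options["ivw_variant"])
    het = diagnostics.cochran_q(h, estimators.ivw(h, estimators.FIXED))
    res["q"] = het.q
    res["q_pvalue"] = het.pvalue

    loo = diagnostics.leave_one_snp_out(h) if h.n_retained >= 3 else None

    audit = None
    filtered_row = None
    exp_meta = outcome_entry.get("exposure_meta") or {}
    out_meta_cfg = {k: outcome_entry.get(k) for k in ("n", "prevalence")}
    if exp_meta and out_meta_cfg.get("n"):
        exp_m = diagnostics.TraitMeta(n=exp_meta["n"],
                                      prevalence=exp_meta.get("prevalence"))
        out_m = diagnostics.TraitMeta(n=out_meta_cfg["n"],
                                      prevalence=out_meta_cfg.get("prevalence"))
        h_filt, audit = diagnostics.steiger_filter(
            h, exp_m, out_m, alpha=options["steiger_alpha"])
        n_removed = int(audit["removed"].sum())
        log.append(f"  steiger: removed {n_removed} SNP(s) at alpha="
                   f"{options['steiger_alpha']}")
        if h_filt.n_retained >= 2:
            est = estimators.ivw(h_filt, variant=options["ivw_variant"])
            filtered_row = {**est.to_dict(), "method": "ivw-steiger-filtered",
                            "q": float("nan"), "q_pvalue": float("nan")}
    if filtered_row is not None:
        res = pd.concat([res, pd.DataFrame([filtered_row])], ignore_index=True)
    return h, res, loo, audit


def run_full_pipeline(config_source, out_dir=None) -> dict[str, OutcomeBundle]:
    """Run the whole analysis described by a config; return per-outcome bundles.

    When ``out_dir`` (or ``config['out_dir']``) is set, each outcome gets a
    directory with results.tsv, steiger_audit.tsv, loo_snp.tsv, loo_study.tsv
    and run.log.
    """
    config = load_config(config_source)
    options = {**DEFAULT_OPTIONS, **(config.get("options") or {})}
    seed = int(config["seed"])
    out_dir = Path(out_dir or config.get("out_dir") or ".")
    outcomes = list(config["outcomes"])
    studies = list(config["studies"])
    # one child seed per (outcome, study) pair, order-independent by keying
    # on sorted labels rather than config order
    study_labels = sorted(s["label"] for s in studies)
    seed_map = {}
    seeds = child_seeds(seed, len(outcomes) * len(study_labels))
    for i, outc in enumerate(sorted(outcomes)):
        for j, lab in enumerate(study_labels):
            seed_map[(outc, lab)] = seeds[i * len(study_labels) + j]

    exposure = _prepare_exposure(config, options)
    bundles: dict[str, OutcomeBundle] = {}
    for outcome in outcomes:
        bundle = OutcomeBundle(outcome=outcome)
        log = [f"outcome: {outcome}", f"global seed: {seed}",
               f"options: {options}"]
        try:
            res_frames, loo_frames, audits, study_ests = [], [], [], []
            harm_frames = []
            for study in sorted(studies, key=lambda s: s["label"]):
                entry = (study.get("outcomes") or {}).get(outcome)
                if entry is None:
                    log.append(f"  {study['label']}: no data for {outcome}")
                    continue
                entry = dict(entry)
                entry.setdefault("exposure_meta", config["exposure"].get("meta"))
                s_seed = seed_map[(outcome, study["label"])]
                log.append(f"  {study['label']}: seed {s_seed}")
                h, res, loo, audit = _analyse_one_study(
                    exposure, entry, options, s_seed, log)
                res.insert(0, "study", study["label"])
                res_frames.append(res)
                harm = h.frame.copy()
                harm.insert(0, "study", study["label"])
                harm_frames.append(harm)
                if loo is not None:
                    loo.insert(0, "study", study["label"])
                    loo_frames.append(loo)
                if audit is not None:
                    audit = audit.copy()
                    audit.insert(0, "study", study["label"])
                    audits.append(audit)
                ivw_row = res[(res["method"] == "ivw")
                              & (res["variant"] == options["ivw_variant"])]
                if ivw_row.empty:
                    ivw_row = res[res["method"] == "ivw"]
                study_ests.append(meta.StudyEstimate(
                    study["label"], float(ivw_row["beta"].iloc[0]),
                    float(ivw_row["se"].iloc[0])))
            if not study_ests:
                raise ValueError(f"no study contributed data for {outcome}")
            study_ests.sort(key=lambda e: e.study)
            pooled = meta.fixed_effects_meta(study_ests)
            bundle.meta_result = pooled
            meta_row = pd.DataFrame([{
                "study": "META", "method": "ivw-meta", "variant": "fixed",
                "n_snps": int(res_frames[0]["n_snps"].iloc[0]),
                "beta": pooled.beta, "se": pooled.se, "or": pooled.odds_ratio,
                "ci_low": pooled.ci_low, "ci_high": pooled.ci_high,
                "pvalue": pooled.pvalue, "q": pooled.q,
                "q_pvalue": pooled.q_pvalue}])
            bundle.results = pd.concat([*res_frames, meta_row],
                                       ignore_index=True)
            bundle.harmonization = pd.concat(harm_frames, ignore_index=True)
            if loo_frames:
                bundle.loo_snp = pd.concat(loo_frames, ignore_index=True)
            if audits:
                bundle.steiger_audit = pd.concat(audits, ignore_index=True)
            if len(study_ests) >= 2:
                loo_study_rows = []
                for omitted, mres in meta.leave_one_study_out(study_ests).items():
                    loo_study_rows.append({
                        "omitted_study": omitted, "beta": mres.beta,
                        "se": mres.se, "or": mres.odds_ratio,
                        "ci_low": mres.ci_low, "ci_high": mres.ci_high,
                        "pvalue": mres.pvalue})
                bundle.loo_study = pd.DataFrame(loo_study_rows)
        except Exception as exc:  # noqa: BLE001 - bundle records and continues
            bundle.error = f"{type(exc).__name__}: {exc}"
            log.append(f"  FAILED: {bundle.error}")
            logger.warning("pipeline failed for %s: %s", outcome, bundle.error)
        bundles[outcome] = bundle
        _write_bundle(bundle, out_dir, log)
    return bundles


def _write_bundle(bundle: OutcomeBundle, out_dir: Path, log: list[str]) -> None:
    if out_dir == Path("."):
        return
    d = out_dir / bundle.outcome
    d.mkdir(parents=True, exist_ok=True)
    for name, frame in (("results", bundle.results),
                        ("steiger_audit", bundle.steiger_audit),
                        ("loo_snp", bundle.loo_snp),
                        ("loo_study", bundle.loo_study),
                        ("harmonization", bundle.harmonization)):
        if frame is not None:
            frame.to_csv(d / f"{name}.tsv", sep="\t", index=False)
    (d / "run.log").write_text("\n".join(log) + "\n")
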