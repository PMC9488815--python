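#!/usr/bin/env python
"""Step 1 — generate the synthetic study cohorts used by the later steps.

Produces one individual-level pregnancy cohort per synthetic "study"
(different sample sizes and outcome prevalences) plus a large exposure-GWAS
cohort at the published-scale instrument strength.  Genotype/phenotype TSVs
go to scratch/ (they are large and regenerable); a small per-cohort summary
goes to results/.
"""

from pathlib import Path

import pandas as pd

from pregmr.simulate import SimulationConfig, child_seeds, simulate_cohort

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "cohorts"
RESULTS = ROOT / "results"

GLOBAL_SEED = 20_240_901
THETA = 0.4  # shared causal log-odds of exposure on every synthetic outcome

COHORT_SPECS = {
    # label: (n_subjects, n_snps, outcome prevalence)
    "synth-ukb": (40_000, 81, 0.20),
    "synth-alspac": (8_000, 81, 0.08),
    "synth-bib": (4_000, 81, 0.10),
}


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
    seeds = child_seeds(GLOBAL_SEED, len(COHORT_SPECS))
    rows = []
    for seed, (label, (n, k, prev)) in zip(seeds, COHORT_SPECS.items()):
        cfg = SimulationConfig(seed=seed, n_subjects=n, n_snps=k,
                               target_r2=0.02, causal_effect=THETA,
                               outcome_prevalence=prev,
                               confounder_exposure=0.3,
                               confounder_outcome=0.3)
        cohort = simulate_cohort(cfg)
        out = SCRATCH / f"{label}.tsv"
        cohort.data.to_csv(out, sep="\t", index=False)
        rows.append({"study": label, "seed": seed, "n": n, "n_snps": k,
                     "exposure_prev": cohort.data["exposure"].mean(),
                     "outcome_prev": cohort.data["outcome"].mean(),
                     "file": str(out.relative_to(ROOT))})
        print(f"{label}: n={n}, outcome prevalence "
              f"{cohort.data['outcome'].mean():.3f}")
    pd.DataFrame(rows).to_csv(RESULTS / "01_cohorts.tsv", sep="\t",
                              index=False)


if __name__ == "__main__":
    main()
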