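#!/usr/bin/env python
"""Vulnerability status and HIV-related risk behaviors.

Fits, for each of the 8 outcomes, a logistic regression with
multidimensional vulnerability as the key exposure, adjusted for
duration in sex work, education, marital status and state.  Prints the
unadjusted percentages by status and the adjusted odds ratios with 95%
Wald intervals, and compares the estimates with the odds ratios the
generator used to draw the outcomes.
"""
import sys
from pathlib import Path

import pandas as pd

from mvindex import (
    IndexDefinition,
    SyntheticConfig,
    associate_all,
    build_matrix,
    deprivation_scores,
    generate_survey,
)
from mvindex.reporting import association_table
from mvindex.simulate import DEFAULT_OUTCOME_MODEL

ROOT = Path(__file__).resolve().parents[1]
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main() -> None:
    definition = IndexDefinition()
    survey = generate_survey(SyntheticConfig(seed=SEED))
    matrix = build_matrix(survey.records, definition)
    clean, _, _ = matrix.complete_case_indicators()
    status = pd.Series(
        deprivation_scores(clean, definition).vulnerable.astype(int), index=clean.index
    )
    results, failures = associate_all(
        matrix.outcomes.loc[clean.index], status, matrix.covariates.loc[clean.index]
    )

    (ROOT / "results").mkdir(exist_ok=True)
    table = association_table(results)
    table["generating_or"] = [
        DEFAULT_OUTCOME_MODEL[name][1] for name in results
    ]
    table["ci_covers_generating_or"] = [
        res.ci_low <= DEFAULT_OUTCOME_MODEL[name][1] <= res.ci_high
        for name, res in results.items()
    ]
    table.to_csv(ROOT / "results" / "associations.csv", index=False)

    print(f"fitted {len(results)} outcomes; {len(failures)} failures")
    for name, msg in failures.items():
        print(f"  FAILED {name}: {msg}")
    print(table.to_string(index=False))
    n_cover = int(table["ci_covers_generating_or"].sum())
    print(f"\n{n_cover}/{len(results)} fitted 95% CIs cover the generating odds ratio")


if __name__ == "__main__":
    main()
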