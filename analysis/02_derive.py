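#!/usr/bin/env python
"""Derive the binary vulnerability indicators and risk outcomes.

Reads the synthetic survey written by 01_simulate.py (regenerating it
if absent), recodes raw fields into the 16 indicators and 8 outcomes,
and reports the raw (uncensored) deprivation headcounts — the share of
all respondents deprived in each indicator, before any identification.
"""
import sys
from pathlib import Path

from mvindex import SyntheticConfig, build_matrix, generate_survey, read_survey_csv
from mvindex.definitions import INDICATOR_LABELS

ROOT = Path(__file__).resolve().parents[1]
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def load_records():
    path = ROOT / "scratch" / "synthetic_survey.csv"
    if path.exists():
        print(f"reading {path}")
        return read_survey_csv(path)
    print("survey CSV not found; regenerating deterministically")
    return generate_survey(SyntheticConfig(seed=SEED)).records


def main() -> None:
    matrix = build_matrix(load_records())
    clean, _, dropped = matrix.complete_case_indicators()
    print(f"derived {matrix.n} rows; {dropped} dropped as incomplete (complete-case)")
    print(f"{matrix.indicators.shape[1]} indicators, {matrix.outcomes.shape[1]} outcomes")
    print("\nraw deprivation headcounts (% of all respondents):")
    for name, share in matrix.indicators.mean().items():
        print(f"  {INDICATOR_LABELS.get(name, name):<36s} {share * 100:5.1f}")
    (ROOT / "scratch").mkdir(exist_ok=True)
    matrix.indicators.to_csv(ROOT / "scratch" / "derived_indicators.csv", index=False)
    print(f"\nindicator matrix -> {ROOT / 'scratch' / 'derived_indicators.csv'}")


if __name__ == "__main__":
    main()
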