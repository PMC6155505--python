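"""End-to-end pipeline: derive → aggregate → decompose → robustness → associate.

``run_pipeline`` executes every stage on either a raw-survey CSV or a
freshly generated synthetic survey and writes the report bundle to the
output directory:

* ``af_measures.csv``        headcount/intensity/MVI/severe by subgroup
* ``contributions.csv``      per-indicator contributions and censored headcounts
* ``mvi_by_threshold.csv``   subgroup × k MVI table
* ``tau_matrix.csv``         pairwise Kendall tau-b between k-specific rankings
* ``vulnerable_share_by_k.csv``  long-format (subgroup, k, % vulnerable) for plotting
* ``associations.csv``       unadjusted percentages and AORs with 95% CI
* ``results.json``           all results, machine-readable, full precision
* ``run_manifest.json``      config hash, seed, package version
* ``run.log``                row counts, exclusions, convergence notes

Reruns with the same seed produce byte-identical ``results.json``.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import af, association, reporting, robustness
from .definitions import IndexDefinition
from .indicators import build_matrix, read_survey_csv
from .simulate import SyntheticConfig, generate_survey

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Pipeline settings; exactly one of input_path / synthetic is set."""

    input_path: str | None = None
    synthetic: SyntheticConfig | None = None
    definition: IndexDefinition = field(default_factory=IndexDefinition)
    k_grid: Sequence[float] = robustness.DEFAULT_K_GRID
    outdir: str = "results"
    seed: int | None = None
    missing_policy: str = "complete_case"
    consistency_threshold: float = 0.9

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.synthetic is None):
            raise ValueError("set exactly one of input_path / synthetic")
        if self.seed is not None and self.synthetic is not None:
            self.synthetic = dataclasses.replace(self.synthetic, seed=self.seed)


def _config_hash(config: RunConfig) -> str:
    payload = {
        "input_path": config.input_path,
        "synthetic": dataclasses.asdict(config.synthetic) if config.synthetic else None,
        "definition": config.definition.to_dict(),
        "k_grid": [float(k) for k in config.k_grid],
        "missing_policy": config.missing_policy,
    }
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()


def _summary_dict(summary: af.AFSummary) -> dict:
    return {
        "n": summary.n,
        "q": summary.q,
        "headcount": summary.headcount,
        "intensity": summary.intensity,
        "mvi": summary.mvi,
        "severe_headcount": summary.severe_headcount,
        "censored_headcount": summary.censored_headcount.to_dict(),
        "contribution": summary.contribution.to_dict(),
        "dimension_contribution": summary.dimension_contribution.to_dict(),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the report bundle; returns the results dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("mvindex")
    root.addHandler(handler)
    try:
        return _run(config, outdir)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, outdir: Path) -> dict:
    definition = config.definition

    # ---- stage: load or simulate -------------------------------------
    if config.synthetic is not None:
        logger.info("simulating survey: n=%d seed=%d", config.synthetic.n, config.synthetic.seed)
        survey = generate_survey(config.synthetic, definition)
        records = survey.records
    else:
        logger.info("reading survey from %s", config.input_path)
        records = read_survey_csv(config.input_path)
    logger.info("records: %d rows", len(records))

    # ---- stage: derive ------------------------------------------------
    matrix = build_matrix(records, definition, missing_policy=config.missing_policy)
    matrix.indicators.to_csv(outdir / "derived_indicators.csv", index=False)

    # ---- stage: aggregate + decompose ---------------------------------
    clean, subgroup, n_dropped = matrix.complete_case_indicators()
    logger.info("AF aggregation on %d rows (%d dropped incomplete)", len(clean), n_dropped)
    result = af.aggregate(clean, definition, subgroup, n_dropped=n_dropped)
    reporting.measures_table(result).to_csv(outdir / "af_measures.csv")
    reporting.contributions_table(result.overall, definition).to_csv(
        outdir / "contributions.csv", index=False
    )

    # ---- stage: robustness --------------------------------------------
    rob = robustness.mvi_by_threshold(
        clean,
        definition,
        subgroup,
        config.k_grid,
        consistency_threshold=config.consistency_threshold,
    )
    reporting.robustness_table(rob).to_csv(outdir / "mvi_by_threshold.csv")
    rob.tau_matrix.to_csv(outdir / "tau_matrix.csv")
    long_rows = [
        {"subgroup": s, "k": k, "pct_vulnerable": reporting.round_pct(v * 100)}
        for k in rob.k_grid
        for s, v in rob.headcount_table[k].items()
        if pd.notna(v)
    ]
    pd.DataFrame(long_rows).to_csv(outdir / "vulnerable_share_by_k.csv", index=False)

    # ---- stage: association -------------------------------------------
    scores = af.deprivation_scores(clean, definition)
    status = pd.Series(scores.vulnerable.astype(int), index=clean.index)
    fits, failures = association.associate_all(
        matrix.outcomes.loc[clean.index], status, matrix.covariates.loc[clean.index]
    )
    for name, msg in failures.items():
        logger.warning("association fit failed: %s: %s", name, msg)
    reporting.association_table(fits).to_csv(outdir / "associations.csv", index=False)

    # ---- machine-readable bundle --------------------------------------
    results = {
        "n_records": len(records),
        "n_used": int(result.overall.n),
        "n_dropped_incomplete": n_dropped,
        "definition": definition.to_dict(),
        "af": {
            "overall": _summary_dict(result.overall),
            "by_subgroup": {s: _summary_dict(v) for s, v in result.by_subgroup.items()},
        },
        "robustness": {
            "k_grid": list(rob.k_grid),
            "mvi_table": {str(s): rob.mvi_table.loc[s].tolist() for s in rob.mvi_table.index},
            "rankings": {str(k): v for k, v in rob.rankings.items()},
            "tau_matrix": [
                [None if pd.isna(v) else float(v) for v in row]
                for row in rob.tau_matrix.to_numpy()
            ],
            "consistent": rob.consistent,
        },
        "association": {
            name: {
                "n_used": fit.n_used,
                "pct_nonvulnerable": fit.pct_nonvulnerable,
                "pct_vulnerable": fit.pct_vulnerable,
                "aor": fit.aor,
                "ci_low": fit.ci_low,
                "ci_high": fit.ci_high,
                "coefficients": {
                    term: {"coef": row["coef"], "se": row["se"]}
                    for term, row in fit.coefficients.iterrows()
                },
            }
            for name, fit in fits.items()
        },
        "association_failures": failures,
    }
    with open(outdir / "results.json", "w", encoding="utf-8") as fh:
        json.dump(results, fh, indent=1, sort_keys=True)
        fh.write("\n")

    from . import __version__

    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.synthetic.seed if config.synthetic else None,
        "version": __version__,
    }
    with open(outdir / "run_manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return results
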