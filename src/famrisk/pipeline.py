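"""End-to-end orchestration: simulate -> ascertain -> match -> analyze.

``run_study`` executes the whole design in memory and is what the tests,
the CLI and the acceptance script all call; ``run_pipeline`` wraps it with
file output and a JSON manifest.  Identical configs produce byte-identical
outputs: every stage seed derives from the simulation seed by a fixed
offset and the manifest records no wall-clock state.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd

from .ascertain import (CodePolicy, CohortResult, diagnosis_flags,
                        estimate_prevalence, identify_cases)
from .config import RunConfig
from .genealogy import Genealogy, write_genealogy, write_records
from .matching import audit_match, match_controls, matches_frame
from .pedigree import pedigree_metrics_all
from .simulate import SimulationParams, simulate_study
from .stats import (build_all_relative_tables, demographics_report,
                    estimates_frame, fit_clustered_logistic,
                    fit_random_intercept_logistic, spousal_analysis,
                    stratified_fdr_analysis)
from .types import MatchSet, RiskEstimate

log = logging.getLogger(__name__)

MATCH_SEED_OFFSET = 1009  # matching seed = simulation seed + this, unless set


@dataclass
class StudyResult:
    """In-memory results of one full pipeline run."""

    genealogy: Genealogy
    affected_truth: Dict[str, bool]
    records: pd.DataFrame
    cohort: CohortResult
    relative_flags: Dict[str, bool]
    matchsets: List[MatchSet]
    unmatched: List[str]
    estimates: Dict[object, List[RiskEstimate]]  # degree / "spouse" -> fits
    skipped: Dict[str, str]
    stratified: List[RiskEstimate] = field(default_factory=list)
    stratified_skipped: Dict[str, str] = field(default_factory=dict)
    table1: Optional[pd.DataFrame] = None
    table1_pvalues: Dict[str, float] = field(default_factory=dict)
    metrics: Optional[dict] = None

    @property
    def controls(self) -> List[str]:
        return [c for ms in self.matchsets for c in ms.control_ids]

    @property
    def matched_cases(self) -> List[str]:
        return [ms.case_id for ms in self.matchsets]


def run_study(config: RunConfig) -> StudyResult:
    """Run every stage in memory; see :class:`StudyResult`."""
    config.validate()
    params = config.simulation
    policy = config.policy
    ref_year = config.resolved_reference_year()

    log.info("simulate: %d founder couples, %d generations, seed %d",
             params.n_founder_couples, params.n_generations, params.seed)
    genealogy, affected, records = simulate_study(params)
    log.info("simulate: %d persons, %d records", len(genealogy), len(records))

    metrics = pedigree_metrics_all(genealogy)
    cohort = identify_cases(records, genealogy, policy, ref_year, metrics=metrics)
    log.info("ascertain: %d cases, %d eligible controls, attrition %s",
             len(cohort.case_ids), len(cohort.control_eligible_ids),
             cohort.excluded_counts)

    match_seed = (config.matching.seed if config.matching.seed is not None
                  else (params.seed + MATCH_SEED_OFFSET) % 2**31)
    matchsets, unmatched = match_controls(
        cohort.case_ids, cohort.control_eligible_ids, genealogy,
        ratio=config.matching.ratio,
        birth_year_window=config.matching.birth_year_window,
        seed=match_seed, metrics=metrics)
    log.info("match: %d matched sets, %d unmatched cases",
             len(matchsets), len(unmatched))

    flags = diagnosis_flags(records, genealogy, policy, ref_year)
    result = StudyResult(
        genealogy=genealogy, affected_truth=affected, records=records,
        cohort=cohort, relative_flags=flags, matchsets=matchsets,
        unmatched=unmatched, estimates={}, skipped={}, metrics=metrics)
    if not matchsets:
        log.info("analyze: no matched sets; analysis tables empty")
        return result

    tables = build_all_relative_tables(
        genealogy, matchsets, flags, include_spouse=config.analysis.spousal)
    fit = (fit_clustered_logistic if config.analysis.estimator == "marginal"
           else _mixed_fit)
    for d in config.analysis.degrees:
        rows = tables[d]
        try:
            result.estimates[d] = fit(rows)
        except Exception as exc:  # degenerate or separated stratum
            result.skipped[f"degree_{d}"] = str(exc)
            log.info("analyze: degree %s skipped: %s", d, exc)
    if config.analysis.spousal:
        ests, skipped = spousal_analysis(genealogy, matchsets, flags,
                                         rows=tables["spouse"])
        result.estimates["spouse"] = ests
        result.skipped.update(skipped)
    if config.analysis.stratified:
        result.stratified, result.stratified_skipped = stratified_fdr_analysis(
            genealogy, matchsets, flags, rows=tables[1])

    cases = result.matched_cases
    controls = result.controls
    if cases and controls:
        result.table1, result.table1_pvalues = demographics_report(
            cases, controls, genealogy, metrics=metrics)
    return result


def _mixed_fit(rows):
    ests, _tau = fit_random_intercept_logistic(rows)
    return ests


def run_pipeline(config: RunConfig) -> dict:
    """Run the study and write genealogy, records, cohort JSON, match CSV,
    analysis TSVs and a manifest under ``config.output_dir``.  Returns the
    manifest (also written as ``manifest.json``)."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = run_study(config)
    g, records = result.genealogy, result.records

    paths = {
        "genealogy": outdir / "genealogy.tsv",
        "records": outdir / "records.csv",
        "truth": outdir / "simulation_truth.csv",
        "cohort": outdir / "cohort.json",
        "matches": outdir / "matches.csv",
        "table2": outdir / "table2.tsv",
        "table1": outdir / "table1.tsv",
        "manifest": outdir / "manifest.json",
    }
    write_genealogy(g, paths["genealogy"])
    write_records(records, paths["records"])
    pd.DataFrame(
        [(pid, int(result.affected_truth[pid])) for pid in g.ids()],
        columns=["person_id", "affected"],
    ).to_csv(paths["truth"], index=False)
    with open(paths["cohort"], "w") as fh:
        json.dump({
            "case_ids": sorted(result.cohort.case_ids),
            "excluded_counts": result.cohort.excluded_counts,
            "n_control_eligible": len(result.cohort.control_eligible_ids),
        }, fh, indent=1, sort_keys=True)
    matches_frame(result.matchsets).to_csv(paths["matches"], index=False)

    all_estimates = []
    for key in (1, 2, 3, "spouse"):
        for e in result.estimates.get(key, []):
            label = {1: "FDR", 2: "SDR", 3: "TDR", "spouse": "spouse"}[key]
            row = e.__class__(**{**e.__dict__})
            row.term = f"{label}:{e.term}"
            all_estimates.append(row)
    all_estimates.extend(result.stratified)
    estimates_frame(all_estimates).to_csv(paths["table2"], sep="\t", index=False)
    if result.table1 is not None:
        t1 = result.table1.copy()
        t1.to_csv(paths["table1"], sep="\t", index=False)

    audit = audit_match(result.matchsets, g, metrics=result.metrics) \
        if result.matchsets else []
    degree_counts = {}
    for key, ests in result.estimates.items():
        if ests:
            degree_counts[str(key)] = {
                "n_case_relatives": ests[0].n_case_relatives,
                "n_control_relatives": ests[0].n_control_relatives,
            }
    manifest = {
        "seeds": {
            "simulation": config.simulation.seed,
            "matching": (config.matching.seed if config.matching.seed is not None
                         else (config.simulation.seed + MATCH_SEED_OFFSET) % 2**31),
        },
        "counts": {
            "persons": len(g),
            "records": int(len(records)),
            "cases": len(result.cohort.case_ids),
            "matched_cases": len(result.matchsets),
            "unmatched_cases": len(result.unmatched),
            "controls": sum(len(ms.control_ids) for ms in result.matchsets),
            "attrition": result.cohort.excluded_counts,
            "relatives_by_degree": degree_counts,
            "match_audit_violations": len(audit),
        },
        "estimates": {
            str(k): [e.__dict__ for e in v] for k, v in result.estimates.items()
        },
        "stratified": [e.__dict__ for e in result.stratified],
        "skipped": {**result.skipped, **result.stratified_skipped},
        "table1_pvalues": result.table1_pvalues,
        "outputs": {k: str(v) for k, v in paths.items()},
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def prevalence_from_result(result: StudyResult, census_year: int,
                           policy: Optional[CodePolicy] = None):
    """Single/confirmed diagnosis prevalence over all simulated persons
    born by the census year."""
    pop = [pid for pid, p in result.genealogy.people.items()
           if p.birth_year <= census_year]
    return estimate_prevalence(result.records, pop, census_year, policy=policy)
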