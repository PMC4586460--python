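"""End-to-end orchestration: simulate -> filter -> batch-correct -> scan
-> SNP-filter -> annotate -> cluster -> report -> recovery."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import annotate as ann
from . import combat, outliers, preprocess, report, simulate
from .config import SimulationConfig

log = logging.getLogger("episcan")


@dataclass
class PipelineResult:
    manifest: pd.DataFrame
    cohort: simulate.SimulatedCohort
    beta_filtered: pd.DataFrame
    filter_report: preprocess.FilterReport
    beta_corrected: pd.DataFrame
    batch_model: combat.BatchModel
    scan_result: outliers.ScanResult
    kept: outliers.ScanResult
    removed: outliers.ScanResult
    calls: pd.DataFrame                  # annotated + clustered kept calls
    burdens: pd.DataFrame
    recovery: report.RecoveryReport
    delta_summary: dict = field(default_factory=dict)
    feature_summary: dict = field(default_factory=dict)


def run_synthetic(config: SimulationConfig,
                  scan_params: outliers.ScanParams | None = None,
                  correct_batch: bool = True) -> PipelineResult:
    """Run the whole analysis on one synthetic cohort draw."""
    manifest = simulate.generate_manifest(config)
    cohort = simulate.generate_cohort(config, manifest)
    log.info("simulated %d probes x %d samples, %d injections",
             len(manifest), len(cohort.sample_sheet), len(cohort.truth))

    beta_f, freport = preprocess.filter_probes(
        cohort.beta, manifest, detection_p=cohort.detection_p)
    log.info("probe filter: %s -> %d retained", freport.removed, freport.n_retained)

    if correct_batch:
        beta_c, model = combat.correct_batches(beta_f, cohort.sample_sheet)
    else:
        beta_c, model = beta_f, None
    mani_retained = manifest[manifest["IlmnID"].isin(beta_c.index)].reset_index(drop=True)

    scan_result = outliers.scan(beta_c, scan_params, manifest=mani_retained)
    kept, removed = outliers.snp_filter(scan_result, mani_retained)
    log.info("scan: %d calls (%d hyper / %d hypo); %d kept after SNP filter",
             len(scan_result.calls), scan_result.n_hyper, scan_result.n_hypo,
             len(kept.calls))

    annotated = ann.annotate_calls(kept, mani_retained)
    clustered = ann.cluster_calls(annotated, mani_retained)
    burdens = report.burden_by_subject(clustered, cohort.sample_sheet)
    recovery = report.score_recovery(clustered, cohort.truth)

    return PipelineResult(
        manifest=manifest, cohort=cohort,
        beta_filtered=beta_f, filter_report=freport,
        beta_corrected=beta_c, batch_model=model,
        scan_result=scan_result, kept=kept, removed=removed,
        calls=clustered, burdens=burdens, recovery=recovery,
        delta_summary=outliers.summarize_deltas(kept),
        feature_summary=ann.feature_summary(clustered),
    )
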