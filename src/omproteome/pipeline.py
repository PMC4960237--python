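"""End-to-end orchestration of the OM-proteome inference pipeline.

Stage order follows the study design: impute missing LFQ values, build
the preliminary OM candidate list per growth condition, confirm OM
localization by the four-criterion consensus, screen the rest of the
genome for OM proteins never detected in the fractions, compare
conditions (>10-fold rule, exclusivity), and scan the proteome for
PEP-CTERM sorting signals.  Every filtering step is recorded in a
count-based audit trail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from . import classify, diffabund, lfq, pepcterm, report
from .config import PipelineConfig
from .table import AbundanceTable
from .types import Compartment, Condition, Fraction

log = logging.getLogger("omproteome")


@dataclass
class PipelineResult:
    """Everything the pipeline computed, ready for report writers."""

    table: AbundanceTable                 # imputed
    calls: list                           # detected-candidate calls
    genome_calls: list                    # genome-only om_confirmed calls
    candidates_by_condition: dict
    om_ids: set                           # om_confirmed among detected
    fold_records: list
    responsive_ids: set
    exclusive_mucin: set
    exclusive_glucose: set
    pepcterm_hits: list
    trail: object = None
    enrichment: dict = field(default_factory=dict)


def run_all(
    records: list,
    profiles: list,
    raw_table: AbundanceTable,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run every stage on one dataset and return the bundled results."""
    config = config or PipelineConfig()
    ccfg = config.classifier

    table = lfq.impute_missing(raw_table, offset=config.impute_offset)

    om_samples_all = table.samples_where(fraction=Fraction.OM_SARKOSYL)
    if not om_samples_all:
        raise ValueError("no sarkosyl OM-fraction samples in the table")

    candidates_by_condition = {}
    for cond in (Condition.MUCIN, Condition.GLUCOSE):
        samples = table.samples_where(
            fraction=Fraction.OM_SARKOSYL, condition=cond
        )
        if samples:
            candidates_by_condition[cond.value] = classify.preliminary_candidates(
                table, profiles, samples, ccfg
            )
    candidates = set().union(*candidates_by_condition.values())

    calls = classify.classify_detected(candidates, profiles, ccfg)
    om_ids = {c.protein_id for c in calls if c.is_om}

    detected_ids = {
        pid
        for pid in table.protein_ids
        if any(table.detected.at[pid, s] for s in om_samples_all)
    }
    genome_calls = classify.genome_screen(profiles, detected_ids, ccfg)

    # condition comparison on the confirmed OM set (mucin = a, glucose = b)
    fold_records = []
    responsive_ids: set = set()
    excl_m: set = set()
    excl_g: set = set()
    om_mucin = table.samples_where(Fraction.OM_SARKOSYL, Condition.MUCIN)
    om_glucose = table.samples_where(Fraction.OM_SARKOSYL, Condition.GLUCOSE)
    if om_mucin and om_glucose:
        fold_records = diffabund.fold_changes(
            table,
            om_mucin[0],
            om_glucose[0],
            ids=om_ids,
            threshold=config.fold_threshold,
        )
        responsive_ids, _ = diffabund.responsive_set(
            fold_records, config.fold_threshold
        )
        excl_m, excl_g = diffabund.exclusive_sets(fold_records)

    hits, _ = pepcterm.scan_proteome(records, config.pepcterm)

    # enrichment of OM-labelled proteins, sarkosyl fraction vs whole proteome
    labels = {p.protein_id: p.cello_label for p in profiles}
    enrichment = {}
    for cond in (Condition.MUCIN, Condition.GLUCOSE):
        om_s = table.samples_where(Fraction.OM_SARKOSYL, cond)
        wp_s = table.samples_where(Fraction.WHOLE_PROTEOME, cond)
        if om_s and wp_s:
            d_om = lfq.compartment_distribution(table, labels, om_s[0])
            d_wp = lfq.compartment_distribution(table, labels, wp_s[0])
            try:
                enrichment[cond.value] = lfq.enrichment_factor(
                    d_om, d_wp, Compartment.OUTER_MEMBRANE
                ).factor
            except (KeyError, ValueError):
                pass

    trail = report.audit(
        [
            ("proteome", len(profiles), "proteins in the predictor table"),
            (
                "detected_om_fraction",
                len(detected_ids),
                "proteins detected in >=1 sarkosyl OM sample",
            ),
            (
                "preliminary_candidates",
                len(candidates),
                "LFQ-threshold or predictor-OM candidates (union of conditions)",
            ),
            ("om_confirmed", len(om_ids), "candidates meeting >=1 OM criterion"),
            (
                "genome_only_om",
                len(genome_calls),
                "undetected proteins meeting the OM criteria",
            ),
            (
                "fold_responsive",
                len(responsive_ids),
                f">{config.fold_threshold:g}-fold between conditions",
            ),
            (
                "condition_exclusive",
                len(excl_m) + len(excl_g),
                "detected in exactly one condition",
            ),
            ("pepcterm_hits", len(hits), "PEP-CTERM sorting signals found"),
        ]
    )

    return PipelineResult(
        table=table,
        calls=calls,
        genome_calls=genome_calls,
        candidates_by_condition=candidates_by_condition,
        om_ids=om_ids,
        fold_records=fold_records,
        responsive_ids=responsive_ids,
        exclusive_mucin=excl_m,
        exclusive_glucose=excl_g,
        pepcterm_hits=hits,
        trail=trail,
        enrichment=enrichment,
    )
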