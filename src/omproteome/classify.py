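"""The localization decision procedure.

Candidates enriched in the sarkosyl OM fraction (log10 LFQ above the 8.5
threshold in any OM sample, or called outer-membrane by either of the two
whole-cell localization predictors) are confirmed as OM proteins when at
least one of four independent criteria fires:

C1  both localization predictors place the protein in the OM;
C2  the lipoprotein predictor calls it a lipoprotein;
C3  the beta-barrel predictor reports a barrel (category >= 1);
C4  no signal peptide, but the non-classical secretion score exceeds
    its cutoff.

Proteins with a signal peptide but no fired criterion fall back to a
periplasmic assignment; everything else keeps its primary localization
label.  The same criteria applied to proteins never detected in the
OM fractions constitute the genome-wide screen.
"""

from __future__ import annotations

import logging

from .config import ClassifierConfig
from .table import AbundanceTable
from .types import (
    C1_DUAL_OM,
    C2_LIPOPROTEIN,
    C3_BETA_BARREL,
    C4_NONCLASSICAL,
    OM_CONFIRMED,
    Compartment,
    LipoproteinClass,
    LocalizationCall,
    PredictorProfile,
)

log = logging.getLogger("omproteome")


def preliminary_candidates(
    table: AbundanceTable,
    profiles: list,
    om_samples: list,
    cfg: ClassifierConfig | None = None,
) -> set:
    """Preliminary OM candidate list from the sarkosyl OM fraction.

    Union of (a) proteins detected above the LFQ threshold in at least
    one OM sample and (b) detected proteins the localization predictors
    place in the OM.  Imputed cells never satisfy the threshold.
    """
    cfg = cfg or ClassifierConfig()
    if not om_samples:
        raise ValueError("om_samples must not be empty")
    for sid in om_samples:
        if sid not in table.sample_ids:
            raise KeyError(f"unknown sample {sid!r}")
    by_id = {p.protein_id: p for p in profiles}
    missing = [pid for pid in table.protein_ids if pid not in by_id]
    if missing:
        raise ValueError(
            f"{len(missing)} table proteins lack predictor profiles "
            f"(e.g. {missing[:3]})"
        )

    candidates: set = set()
    n_lfq = n_pred = 0
    for pid in table.protein_ids:
        detected_any = any(table.detected.at[pid, s] for s in om_samples)
        if not detected_any:
            continue
        above = False
        for sid in om_samples:
            if not table.detected.at[pid, sid]:
                continue
            v = table.log10_lfq.at[pid, sid]
            if (v > cfg.lfq_threshold) or (
                not cfg.strict_threshold and v >= cfg.lfq_threshold
            ):
                above = True
                break
        prof = by_id[pid]
        predictor_om = (
            prof.cello_label is Compartment.OUTER_MEMBRANE
            or prof.psortb_label is Compartment.OUTER_MEMBRANE
        )
        if above:
            n_lfq += 1
        if predictor_om:
            n_pred += 1
        if above or predictor_om:
            candidates.add(pid)
    log.info(
        "preliminary_candidates: %d candidates (%d above LFQ %.2f, "
        "%d predictor-OM; union)",
        len(candidates),
        n_lfq,
        cfg.lfq_threshold,
        n_pred,
    )
    return candidates


def om_criteria(profile: PredictorProfile, cfg: ClassifierConfig | None = None) -> set:
    """Evaluate the four independent OM-confirmation criteria."""
    cfg = cfg or ClassifierConfig()
    fired = set()
    if (
        profile.cello_label is Compartment.OUTER_MEMBRANE
        and profile.psortb_label is Compartment.OUTER_MEMBRANE
    ):
        fired.add(C1_DUAL_OM)
    if profile.lipoprotein_class is LipoproteinClass.LIPOPROTEIN:
        fired.add(C2_LIPOPROTEIN)
    if profile.bomp_category >= cfg.min_bomp_category:
        fired.add(C3_BETA_BARREL)
    if (
        not profile.has_signal_peptide
        and profile.secretomep_score > cfg.secretomep_cutoff
    ):
        fired.add(C4_NONCLASSICAL)
    return fired


def assign_compartment(
    profile: PredictorProfile,
    fired: set,
    in_preliminary_list: bool = False,
    detected_in_proteomics: bool = True,
) -> LocalizationCall:
    """Turn fired criteria into a localization call.

    Any fired criterion confirms the OM; a signal peptide without any
    criterion implies a periplasmic location; otherwise the primary
    localization label (CELLO-style) is retained.
    """
    if fired:
        label = OM_CONFIRMED
    elif profile.has_signal_peptide:
        label = Compartment.PERIPLASMIC.value
    else:
        label = profile.cello_label.value
    return LocalizationCall(
        protein_id=profile.protein_id,
        label=label,
        criterion_fired=frozenset(fired),
        in_preliminary_list=in_preliminary_list,
        detected_in_proteomics=detected_in_proteomics,
    )


def classify_detected(
    candidates: set,
    profiles: list,
    cfg: ClassifierConfig | None = None,
) -> list:
    """Apply the criteria to every preliminary candidate."""
    cfg = cfg or ClassifierConfig()
    by_id = {p.protein_id: p for p in profiles}
    missing = sorted(pid for pid in candidates if pid not in by_id)
    if missing:
        raise ValueError(f"candidates without predictor profiles: {missing}")
    calls = []
    for pid in sorted(candidates):
        prof = by_id[pid]
        fired = om_criteria(prof, cfg)
        calls.append(
            assign_compartment(
                prof, fired, in_preliminary_list=True, detected_in_proteomics=True
            )
        )
    n_om = sum(1 for c in calls if c.is_om)
    log.info(
        "classify_detected: %d candidates -> %d om_confirmed", len(calls), n_om
    )
    return calls


def genome_screen(
    profiles: list,
    detected_ids: set,
    cfg: ClassifierConfig | None = None,
) -> list:
    """Screen proteins absent from the OM fractions for OM criteria.

    Returns om_confirmed calls (only) for undetected proteins, flagged
    ``detected_in_proteomics=False``.
    """
    cfg = cfg or ClassifierConfig()
    calls = []
    for prof in profiles:
        if prof.protein_id in detected_ids:
            continue
        fired = om_criteria(prof, cfg)
        if fired:
            calls.append(
                assign_compartment(
                    prof,
                    fired,
                    in_preliminary_list=False,
                    detected_in_proteomics=False,
                )
            )
    log.info(
        "genome_screen: %d undetected proteins -> %d om_confirmed",
        len(profiles) - len(detected_ids & {p.protein_id for p in profiles}),
        len(calls),
    )
    return calls
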