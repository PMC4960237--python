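"""Condition comparison: fold changes, the >10-fold rule, exclusivity.

Fold changes are linear-scale ratios ``10^(log10_a - log10_b)`` between
one sample per condition (single-replicate design).  A protein is
*responsive* when its fold change exceeds the threshold in either
direction (strict, two-sided), and *condition-exclusive* when the
detection mask shows it in exactly one of the two samples — exclusivity
is a statement about detection, independent of the numeric ratio, which
for exclusive proteins is a ratio against the imputed floor.
"""

from __future__ import annotations

import logging

import numpy as np

from .table import AbundanceTable
from .types import Exclusivity, FoldChangeRecord

log = logging.getLogger("omproteome")


def fold_changes(
    table: AbundanceTable,
    sample_a: str,
    sample_b: str,
    ids: set | None = None,
    threshold: float = 10.0,
    replicates_a: list | None = None,
    replicates_b: list | None = None,
) -> list:
    """Per-protein linear fold change a/b with exclusivity flags.

    ``ids`` restricts the comparison (e.g. to confirmed OM proteins);
    default is every protein in the table.  The table must be imputed so
    that absent proteins contribute their floor value to the ratio.
    Optional replicate lists average log10 values per condition (off by
    default, matching the single-sample design).
    """
    cols_a = replicates_a or [sample_a]
    cols_b = replicates_b or [sample_b]
    for sid in cols_a + cols_b:
        if sid not in table.sample_ids:
            raise KeyError(f"unknown sample {sid!r}")
    if not table.imputed:
        raise ValueError("fold changes require an imputed table")
    if threshold <= 1:
        raise ValueError("threshold must exceed 1")
    if ids is None:
        ids = set(table.protein_ids)
    unknown = sorted(ids - set(table.protein_ids))
    if unknown:
        raise KeyError(f"ids not in table: {unknown[:5]}")

    records = []
    for pid in table.protein_ids:
        if pid not in ids:
            continue
        a = float(np.mean([table.log10_lfq.at[pid, s] for s in cols_a]))
        b = float(np.mean([table.log10_lfq.at[pid, s] for s in cols_b]))
        det_a = any(table.detected.at[pid, s] for s in cols_a)
        det_b = any(table.detected.at[pid, s] for s in cols_b)
        if det_a and not det_b:
            excl = Exclusivity.ONLY_A
        elif det_b and not det_a:
            excl = Exclusivity.ONLY_B
        else:
            excl = Exclusivity.NONE
        fc = 10.0 ** (a - b)
        records.append(
            FoldChangeRecord(
                protein_id=pid,
                log10_a=a,
                log10_b=b,
                fold_change=fc,
                responsive=(fc > threshold or fc < 1.0 / threshold),
                exclusivity=excl,
            )
        )
    n_resp = sum(1 for r in records if r.responsive)
    n_excl = sum(1 for r in records if r.exclusivity is not Exclusivity.NONE)
    log.info(
        "fold_changes: %d proteins, %d responsive (>%g-fold), %d exclusive",
        len(records),
        n_resp,
        threshold,
        n_excl,
    )
    return records


def responsive_set(records: list, threshold: float = 10.0):
    """Ids whose fold change exceeds the threshold in either direction.

    Symmetric in a/b (swapping the samples inverts every ratio but
    leaves membership unchanged).  Returns ``(ids, count)``.
    """
    if threshold <= 1:
        raise ValueError("threshold must exceed 1")
    ids = {
        r.protein_id
        for r in records
        if r.fold_change > threshold or r.fold_change < 1.0 / threshold
    }
    return ids, len(ids)


def exclusive_sets(records: list):
    """Split condition-exclusive proteins by side: ``(only_a, only_b)``."""
    only_a = {r.protein_id for r in records if r.exclusivity is Exclusivity.ONLY_A}
    only_b = {r.protein_id for r in records if r.exclusivity is Exclusivity.ONLY_B}
    return only_a, only_b
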