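"""LFQ intensity processing: imputation, shares, composition, enrichment.

LFQ intensities are treated as a proxy for absolute protein abundance.
Composition analysis works on the *linear* intensity scale: a protein's
share in a sample is its linear intensity divided by the sample total,
and a compartment's share is the sum over proteins predicted there.
Enrichment between fractions is the ratio of compartment shares, so
differing total protein loads between fractions cancel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .table import AbundanceTable
from .types import Compartment, Fraction

log = logging.getLogger("omproteome")


@dataclass(frozen=True)
class CompartmentDistribution:
    """Per-compartment share of total linear-scale intensity in one sample."""

    sample_id: str
    shares: dict

    def __post_init__(self) -> None:
        total = sum(self.shares.values())
        if self.shares and abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"{self.sample_id}: compartment shares sum to {total}, not 1"
            )


@dataclass(frozen=True)
class EnrichmentResult:
    """Fold enrichment of one compartment between two samples."""

    compartment: Compartment
    target_sample: str
    reference_sample: str
    factor: float

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise ValueError("enrichment factor must be positive")


def impute_missing(
    raw: AbundanceTable, offset: float = 0.5, floor: float | None = None
) -> AbundanceTable:
    """Substitute undetected cells with a value below the detected minimum.

    Each undetected cell in a sample becomes
    ``max(min_detected(sample) - offset, floor)``: a value lower than the
    least abundant quantified protein of that sample, bounded below by
    the display floor.  Detected cells and the mask are unchanged.
    """
    if offset <= 0:
        raise ValueError("offset must be positive")
    if floor is None:
        floor = raw.display_floor
    out = raw.copy()
    for sid in out.sample_ids:
        mask = out.detected[sid].to_numpy()
        if not mask.all():
            imputed = max(raw.min_detected(sid) - offset, floor)
            col = out.log10_lfq[sid].to_numpy(copy=True)
            col[~mask] = imputed
            out.log10_lfq[sid] = col
    out.imputed = True
    n_missing = int((~raw.detected.to_numpy()).sum())
    log.info(
        "impute_missing: filled %d undetected cells (offset=%.3g, floor=%.3g)",
        n_missing,
        offset,
        floor,
    )
    return out


def relative_abundance(
    table: AbundanceTable, sample: str, detected_only: bool = True
) -> dict:
    """Per-protein share of total linear intensity in one sample.

    With ``detected_only`` (default) undetected proteins get share 0 and
    the denominator runs over detected proteins only, so imputed floors
    cannot dominate sparse samples.  Shares of included proteins sum to 1.
    """
    if sample not in table.sample_ids:
        raise KeyError(f"unknown sample {sample!r}")
    col = table.log10_lfq[sample]
    mask = table.detected[sample]
    if detected_only:
        include = mask
    else:
        if col.isna().any():
            raise ValueError(
                f"sample {sample!r} has NaN cells; impute first or use "
                "detected_only=True"
            )
        include = col.notna()
    linear = np.where(include, np.power(10.0, col.to_numpy(dtype=float)), 0.0)
    total = linear.sum()
    if total <= 0:
        raise ValueError(f"sample {sample!r} has no usable intensity")
    shares = linear / total
    return dict(zip(table.protein_ids, shares))


def compartment_distribution(
    table: AbundanceTable,
    labels: dict,
    sample: str,
    detected_only: bool = True,
) -> CompartmentDistribution:
    """Sum protein shares per predicted compartment for one sample.

    ``labels`` maps protein id to :class:`Compartment`; proteins missing
    from it count as unknown.  Only compartments present among the
    labels appear in the result.
    """
    shares = relative_abundance(table, sample, detected_only=detected_only)
    acc: dict = {}
    for pid, share in shares.items():
        comp = labels.get(pid, Compartment.UNKNOWN)
        acc[comp] = acc.get(comp, 0.0) + share
    return CompartmentDistribution(sample_id=sample, shares=acc)


def enrichment_factor(
    dist_target: CompartmentDistribution,
    dist_reference: CompartmentDistribution,
    compartment: Compartment,
) -> EnrichmentResult:
    """Ratio of a compartment's share between target and reference samples."""
    for dist in (dist_target, dist_reference):
        if compartment not in dist.shares:
            raise KeyError(
                f"compartment {compartment.value!r} absent from sample "
                f"{dist.sample_id!r}"
            )
    ref = dist_reference.shares[compartment]
    if ref <= 0:
        raise ValueError(
            f"undefined enrichment: reference share of {compartment.value!r} "
            f"in {dist_reference.sample_id!r} is zero"
        )
    return EnrichmentResult(
        compartment=compartment,
        target_sample=dist_target.sample_id,
        reference_sample=dist_reference.sample_id,
        factor=dist_target.shares[compartment] / ref,
    )


def sucrose_gradient_profile(
    table: AbundanceTable,
    labels: dict,
    gradient_samples: list | None = None,
    compartment: Compartment = Compartment.OUTER_MEMBRANE,
    detected_only: bool = True,
):
    """Compartment share along the sucrose gradient, ordered by density index.

    Returns ``(shares, sign)`` where ``shares`` is the per-fraction share
    sequence ordered by gradient index and ``sign`` is the Spearman
    rank-agreement sign (+1 increasing, -1 decreasing, 0 no trend).
    """
    if gradient_samples is None:
        gradient_samples = table.samples_where(fraction=Fraction.SUCROSE_GRADIENT)
    metas = [table.sample_meta(s) for s in gradient_samples]
    for m in metas:
        if m.gradient_index is None:
            raise ValueError(f"sample {m.sample_id!r} lacks a gradient index")
    indices = [m.gradient_index for m in metas]
    if len(set(indices)) != len(indices):
        raise ValueError("duplicate gradient_index among gradient samples")
    order = np.argsort(indices)
    shares = []
    for k in order:
        dist = compartment_distribution(
            table, labels, metas[k].sample_id, detected_only=detected_only
        )
        shares.append(dist.shares.get(compartment, 0.0))
    if len(shares) < 2 or len(set(shares)) == 1:
        return shares, 0
    rho = stats.spearmanr(sorted(indices), shares).statistic
    if np.isnan(rho) or rho == 0:
        return shares, 0
    return shares, int(np.sign(rho))
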