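"""The protein x sample LFQ abundance container.

Intensities are stored on the log10 scale together with a boolean
detection mask.  Cells that were not quantified by the upstream search
engine are ``NaN`` until :func:`omproteome.lfq.impute_missing` replaces
them with a value below the per-sample minimum of detected proteins
(floored at the display floor, 4.0 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import Condition, Fraction, SampleMeta

#: log10 abundance at which undetected proteins are displayed/floored.
DISPLAY_FLOOR = 4.0


@dataclass
class AbundanceTable:
    """log10 LFQ intensities (proteins x samples) with detection mask.

    Attributes
    ----------
    log10_lfq : pandas.DataFrame
        Rows indexed by protein id, columns by sample id.  Undetected
        cells are NaN in a raw table and imputed values afterwards.
    detected : pandas.DataFrame
        Boolean, same shape/labels; True where the protein was quantified.
    samples : list of SampleMeta
        One entry per column, in column order.
    display_floor : float
        Lower bound applied to imputed values (and used for display).
    """

    log10_lfq: pd.DataFrame
    detected: pd.DataFrame
    samples: list
    display_floor: float = DISPLAY_FLOOR
    imputed: bool = field(default=False)

    def __post_init__(self) -> None:
        ids = [m.sample_id for m in self.samples]
        if list(self.log10_lfq.columns) != ids:
            raise ValueError("sample metadata order must match table columns")
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids")
        if self.log10_lfq.shape != self.detected.shape or list(
            self.log10_lfq.index
        ) != list(self.detected.index):
            raise ValueError("log10_lfq and detected must be aligned")
        if self.log10_lfq.index.has_duplicates:
            raise ValueError("duplicate protein ids")

    # -- basic accessors ---------------------------------------------------
    @property
    def protein_ids(self) -> list:
        return list(self.log10_lfq.index)

    @property
    def sample_ids(self) -> list:
        return list(self.log10_lfq.columns)

    def sample_meta(self, sample_id: str) -> SampleMeta:
        for meta in self.samples:
            if meta.sample_id == sample_id:
                return meta
        raise KeyError(f"unknown sample {sample_id!r}")

    def samples_where(
        self,
        fraction: Fraction | None = None,
        condition: Condition | None = None,
    ) -> list:
        """Sample ids matching the given fraction and/or condition."""
        out = []
        for meta in self.samples:
            if fraction is not None and meta.fraction is not fraction:
                continue
            if condition is not None and meta.condition is not condition:
                continue
            out.append(meta.sample_id)
        return out

    def min_detected(self, sample_id: str) -> float:
        """Smallest detected log10 intensity in a sample."""
        mask = self.detected[sample_id]
        if not mask.any():
            raise ValueError(
                f"sample {sample_id!r} has no detected values; cannot define "
                "a detection minimum"
            )
        return float(self.log10_lfq.loc[mask, sample_id].min())

    def copy(self) -> "AbundanceTable":
        return AbundanceTable(
            log10_lfq=self.log10_lfq.copy(),
            detected=self.detected.copy(),
            samples=list(self.samples),
            display_floor=self.display_floor,
            imputed=self.imputed,
        )

    def validate_imputed(self) -> None:
        """Check the post-imputation invariants.

        Every undetected cell must hold a value strictly below the
        sample's detected minimum and at or above the display floor.
        """
        if not self.imputed:
            raise ValueError("table not marked imputed")
        values = self.log10_lfq.to_numpy()
        if np.isnan(values).any():
            raise ValueError("imputed table contains NaN")
        for sid in self.sample_ids:
            mask = self.detected[sid].to_numpy()
            col = self.log10_lfq[sid].to_numpy()
            if (~mask).any():
                mn = col[mask].min() if mask.any() else np.inf
                bad = col[~mask] >= mn
                if bad.any():
                    raise ValueError(
                        f"sample {sid}: imputed values not below the "
                        "detected minimum"
                    )
                if (col[~mask] < self.display_floor - 1e-12).any():
                    raise ValueError(
                        f"sample {sid}: imputed values below display floor"
                    )
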