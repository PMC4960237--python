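"""Shared fixtures: tiny hand-built abundance tables and profile helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from omproteome import (
    AbundanceTable,
    Compartment,
    Condition,
    Fraction,
    LipoproteinClass,
    PredictorProfile,
    SampleMeta,
)


def build_table(data: dict, metas: list, floor: float = 4.0) -> AbundanceTable:
    """Build a raw table from ``{sample_id: {protein_id: log10 | None}}``.

    None means not quantified (NaN, detected=False).
    """
    sample_ids = [m.sample_id for m in metas]
    proteins = list(data[sample_ids[0]])
    values = np.full((len(proteins), len(sample_ids)), np.nan)
    detected = np.zeros_like(values, dtype=bool)
    for j, sid in enumerate(sample_ids):
        for i, pid in enumerate(proteins):
            v = data[sid][pid]
            if v is not None:
                values[i, j] = v
                detected[i, j] = True
    return AbundanceTable(
        log10_lfq=pd.DataFrame(values, index=proteins, columns=sample_ids),
        detected=pd.DataFrame(detected, index=proteins, columns=sample_ids),
        samples=metas,
        display_floor=floor,
    )


def make_profile(pid: str, **overrides) -> PredictorProfile:
    base = dict(
        protein_id=pid,
        has_signal_peptide=False,
        lipoprotein_class=LipoproteinClass.NONE,
        secretomep_score=0.2,
        tm_helix_count=0,
        bomp_category=0,
        cello_label=Compartment.CYTOPLASMIC,
        psortb_label=Compartment.CYTOPLASMIC,
    )
    base.update(overrides)
    return PredictorProfile(**base)


@pytest.fixture
def om_meta():
    return [
        SampleMeta("om_mucin", Fraction.OM_SARKOSYL, Condition.MUCIN),
        SampleMeta("om_glucose", Fraction.OM_SARKOSYL, Condition.GLUCOSE),
    ]


@pytest.fixture
def toy5_table(om_meta):
    """Five proteins, two OM-fraction samples, one undetected cell."""
    data = {
        "om_mucin": {"P1": 9.0, "P2": 8.0, "P3": 7.0, "P4": 6.5, "P5": None},
        "om_glucose": {"P1": 8.8, "P2": 8.1, "P3": None, "P4": 6.4, "P5": 7.2},
    }
    return build_table(data, om_meta)
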