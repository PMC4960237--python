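"""File formats: FASTA, tab-separated tables, and report writers.

All tabular interchange is strict TSV.  Undetected LFQ cells are encoded
on disk as an empty string or ``0`` and written back as empty strings.
Every reader validates against the domain-type invariants and raises a
``FormatError`` naming the offending record.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .table import AbundanceTable
from .types import (
    Compartment,
    Condition,
    Fraction,
    LipoproteinClass,
    LocalizationCall,
    ProteinRecord,
    SampleMeta,
)

log = logging.getLogger("omproteome")


class FormatError(ValueError):
    """An input file violates the expected format or an invariant."""


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list:
    """Read a protein FASTA into :class:`ProteinRecord` objects.

    Sequences are uppercased; duplicate ids and empty sequences are
    rejected.  An empty file yields an empty list.
    """
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: record with empty id")
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate protein id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if not seq:
            raise FormatError(f"{path}: empty sequence for {rec.id!r}")
        try:
            records.append(
                ProteinRecord(
                    id=rec.id, sequence=seq, description=rec.description
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    log.info("read_fasta: %d records from %s", len(records), path)
    return records


def write_fasta(records, path) -> None:
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


def sequence_length_report(records, protein_id: str) -> dict:
    """Look up one protein and report its residue length.

    Used for spot checks of reference proteins (e.g. the type IV pili
    secretin PilQ) once their sequence is supplied in the input FASTA.
    """
    for rec in records:
        if rec.id == protein_id:
            return {
                "protein_id": rec.id,
                "length": len(rec),
                "description": rec.description,
            }
    raise KeyError(f"protein {protein_id!r} not found in the supplied records")


# ---------------------------------------------------------------------------
# Predictor table
# ---------------------------------------------------------------------------

PREDICTOR_COLUMNS = [
    "protein_id",
    "has_signal_peptide",
    "lipoprotein_class",
    "secretomep_score",
    "tm_helix_count",
    "bomp_category",
    "cello_label",
    "psortb_label",
]

_TRUTHY = {"true", "yes", "1", "y"}
_FALSY = {"false", "no", "0", "n"}


def _parse_bool(value, context: str) -> bool:
    text = str(value).strip().lower()
    if text in _TRUTHY:
        return True
    if text in _FALSY:
        return False
    raise FormatError(f"{context}: cannot parse boolean {value!r}")


def _parse_compartment(value, context: str) -> Compartment:
    comp = Compartment.parse(value)
    canonical = str(value).strip().lower().replace(" ", "_").replace("-", "_")
    if comp is Compartment.UNKNOWN and canonical not in ("unknown", ""):
        log.warning("%s: unrecognized compartment %r -> unknown", context, value)
    return comp


def read_predictor_table(path) -> list:
    """Read the external-predictor feature table (strict TSV)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in PREDICTOR_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    profiles = []
    from .types import PredictorProfile  # local to avoid cycle at import time

    for i, row in enumerate(df.itertuples(index=False), start=2):
        pid = getattr(row, "protein_id")
        ctx = f"{path}:{i} ({pid})"
        try:
            score = float(getattr(row, "secretomep_score"))
        except ValueError as exc:
            raise FormatError(f"{ctx}: bad secretomep_score") from exc
        try:
            lipo = LipoproteinClass(getattr(row, "lipoprotein_class").strip())
        except ValueError as exc:
            raise FormatError(
                f"{ctx}: bad lipoprotein_class "
                f"{getattr(row, 'lipoprotein_class')!r}"
            ) from exc
        try:
            profiles.append(
                PredictorProfile(
                    protein_id=pid,
                    has_signal_peptide=_parse_bool(
                        getattr(row, "has_signal_peptide"), ctx
                    ),
                    lipoprotein_class=lipo,
                    secretomep_score=score,
                    tm_helix_count=int(getattr(row, "tm_helix_count")),
                    bomp_category=int(getattr(row, "bomp_category")),
                    cello_label=_parse_compartment(
                        getattr(row, "cello_label"), ctx
                    ),
                    psortb_label=_parse_compartment(
                        getattr(row, "psortb_label"), ctx
                    ),
                )
            )
        except ValueError as exc:
            raise FormatError(f"{ctx}: {exc}") from exc
    log.info("read_predictor_table: %d profiles from %s", len(profiles), path)
    return profiles


def write_predictor_table(profiles, path) -> None:
    rows = [
        {
            "protein_id": p.protein_id,
            "has_signal_peptide": str(p.has_signal_peptide).lower(),
            "lipoprotein_class": p.lipoprotein_class.value,
            "secretomep_score": f"{p.secretomep_score:.6f}",
            "tm_helix_count": p.tm_helix_count,
            "bomp_category": p.bomp_category,
            "cello_label": p.cello_label.value,
            "psortb_label": p.psortb_label.value,
        }
        for p in profiles
    ]
    pd.DataFrame(rows, columns=PREDICTOR_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Sample metadata and LFQ tables
# ---------------------------------------------------------------------------

SAMPLE_COLUMNS = ["sample_id", "fraction", "condition", "gradient_index"]


def read_sample_meta(path) -> list:
    """Read sample metadata (sample_id, fraction, condition, gradient_index)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in SAMPLE_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    metas = []
    for i, row in df.iterrows():
        gi_raw = str(row.get("gradient_index", "")).strip()
        gi = int(gi_raw) if gi_raw else None
        try:
            metas.append(
                SampleMeta(
                    sample_id=row["sample_id"],
                    fraction=Fraction(row["fraction"].strip()),
                    condition=Condition(row["condition"].strip()),
                    gradient_index=gi,
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}:{i + 2}: {exc}") from exc
    return metas


def write_sample_meta(metas, path) -> None:
    rows = [
        {
            "sample_id": m.sample_id,
            "fraction": m.fraction.value,
            "condition": m.condition.value,
            "gradient_index": "" if m.gradient_index is None else m.gradient_index,
        }
        for m in metas
    ]
    pd.DataFrame(rows, columns=SAMPLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_lfq_table(path, meta: list) -> AbundanceTable:
    """Read a protein x sample LFQ TSV as a raw (pre-imputation) table.

    Cells hold linear LFQ intensities; empty strings or ``0`` mean
    not-quantified and become NaN with ``detected=False``.  Values are
    stored as log10.  Every sample column must have metadata.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.columns[0] != "protein_id":
        raise FormatError(f"{path}: first column must be 'protein_id'")
    df = df.set_index("protein_id")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate protein ids {dups}")
    meta_ids = {m.sample_id for m in meta}
    orphans = [c for c in df.columns if c not in meta_ids]
    if orphans:
        raise FormatError(f"{path}: sample columns without metadata: {orphans}")
    meta_by_id = {m.sample_id: m for m in meta}
    ordered_meta = [meta_by_id[c] for c in df.columns]

    values = np.full(df.shape, np.nan)
    detected = np.zeros(df.shape, dtype=bool)
    for j, col in enumerate(df.columns):
        for i, cell in enumerate(df[col]):
            text = str(cell).strip()
            if text in ("", "0", "0.0", "nan", "NA"):
                continue
            try:
                intensity = float(text)
            except ValueError as exc:
                raise FormatError(
                    f"{path}: cell ({df.index[i]}, {col}) = {text!r} is not "
                    "numeric"
                ) from exc
            if intensity < 0:
                raise FormatError(
                    f"{path}: negative intensity {intensity} at "
                    f"({df.index[i]}, {col})"
                )
            values[i, j] = math.log10(intensity)
            detected[i, j] = True

    table = AbundanceTable(
        log10_lfq=pd.DataFrame(values, index=df.index, columns=df.columns),
        detected=pd.DataFrame(detected, index=df.index, columns=df.columns),
        samples=ordered_meta,
    )
    log.info(
        "read_lfq_table: %d proteins x %d samples from %s "
        "(%d detected cells)",
        len(table.protein_ids),
        len(table.sample_ids),
        path,
        int(detected.sum()),
    )
    return table


def write_lfq_table(table: AbundanceTable, path) -> None:
    """Write linear intensities; undetected cells as empty strings."""
    out = pd.DataFrame(index=table.log10_lfq.index, dtype=object)
    for sid in table.sample_ids:
        col = []
        for pid in table.protein_ids:
            if table.detected.at[pid, sid]:
                col.append(f"{10 ** table.log10_lfq.at[pid, sid]:.6e}")
            else:
                col.append("")
        out[sid] = col
    out.index.name = "protein_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Report writers
# ---------------------------------------------------------------------------

def summarize_calls(
    calls: list,
    n_proteome: int,
    descriptions: dict | None = None,
) -> dict:
    """Headline counts and percentages from the localization calls.

    The OM share of the proteome is ``100 * n_om / n_proteome`` rounded to
    one decimal, where ``n_om`` counts om_confirmed calls backed by
    proteomic detection.  Genome-only calls (criteria met but protein
    never detected) are counted separately, with the share of
    uncharacterized proteins among them when descriptions are given.
    """
    if n_proteome < 0:
        raise ValueError("n_proteome must be non-negative")
    om_detected = [c for c in calls if c.is_om and c.detected_in_proteomics]
    om_genome = [c for c in calls if c.is_om and not c.detected_in_proteomics]
    n_om = len(om_detected)
    summary = {
        "n_proteome": n_proteome,
        "n_om": n_om,
        "n_preliminary": sum(1 for c in calls if c.in_preliminary_list),
        "n_genome_only": len(om_genome),
        "om_percent_of_proteome": (
            round(100.0 * n_om / n_proteome, 1) if n_proteome else 0.0
        ),
    }
    if descriptions is not None and om_genome:
        unchar = sum(
            1
            for c in om_genome
            if _is_uncharacterized(descriptions.get(c.protein_id, ""))
        )
        summary["genome_only_uncharacterized_percent"] = round(
            100.0 * unchar / len(om_genome)
        )
        summary["n_genome_only_uncharacterized"] = unchar
    return summary


def _is_uncharacterized(description: str) -> bool:
    text = description.lower()
    return "uncharacterized" in text or "hypothetical" in text


def calls_to_frame(calls: list) -> pd.DataFrame:
    rows = [
        {
            "protein_id": c.protein_id,
            "label": c.label,
            "criteria": ";".join(sorted(c.criterion_fired)),
            "preliminary": str(c.in_preliminary_list).lower(),
            "detected": str(c.detected_in_proteomics).lower(),
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows, columns=["protein_id", "label", "criteria", "preliminary", "detected"]
    )


def fold_changes_to_frame(records: list) -> pd.DataFrame:
    rows = [
        {
            "protein_id": r.protein_id,
            "log10_a": f"{r.log10_a:.6f}",
            "log10_b": f"{r.log10_b:.6f}",
            "fold_change": f"{r.fold_change:.6g}",
            "responsive": str(r.responsive).lower(),
            "exclusivity": r.exclusivity.value,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id",
            "log10_a",
            "log10_b",
            "fold_change",
            "responsive",
            "exclusivity",
        ],
    )


def write_report(
    calls: list,
    diff: list,
    out_dir,
    n_proteome: int | None = None,
    descriptions: dict | None = None,
) -> dict:
    """Write per-protein calls, fold changes, and a JSON summary.

    Returns the summary dict.  ``n_proteome`` defaults to the number of
    calls (the classifier emits one call per proteome protein).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if n_proteome is None:
        n_proteome = len(calls)
    calls_to_frame(calls).to_csv(out / "localization_calls.tsv", sep="\t", index=False)
    fold_changes_to_frame(diff).to_csv(out / "fold_changes.tsv", sep="\t", index=False)
    summary = summarize_calls(calls, n_proteome, descriptions=descriptions)
    summary["n_fold_responsive"] = sum(1 for r in diff if r.responsive)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    log.info("write_report: summary %s", summary)
    return summary
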