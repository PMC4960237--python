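"""Heuristic PEP-CTERM sorting-signal scanner.

The PEP-CTERM domain is a C-terminal protein-sorting signal of
exosortase-encoding Gram-negative bacteria: a Pro-Glu-Pro motif (a
putative recognition/processing site) followed by a transmembrane helix
and a short cluster rich in basic residues.  This module detects the
signal with a transparent three-part heuristic — literal motif match,
Kyte-Doolittle sliding-window TM-segment detection, and a terminal
K/R count — rather than a profile HMM, so the decision is fully
inspectable and has no external model files.  It is a heuristic: counts
on real proteomes will differ from curated domain-model screens.

Coordinates are 0-based half-open internally and 1-based closed in GFF3
output, per that format's convention.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import PepCtermConfig
from .types import HydropathyProfile, PepCtermHit, ProteinRecord

log = logging.getLogger("omproteome")

#: Kyte-Doolittle hydropathy scale; X (unknown residue) scores 0.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0,
}

BASIC_RESIDUES = frozenset("KR")


def hydropathy_profile(
    seq: str,
    protein_id: str = "",
    window: int = 11,
    scale: dict | None = None,
) -> HydropathyProfile:
    """Centered sliding-window mean hydropathy of a sequence.

    ``values[i]`` is the mean scale value over residues ``[i, i+window)``;
    only positions with a full window are reported.
    """
    scale = scale or KYTE_DOOLITTLE
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd positive integer")
    if window > len(seq):
        raise ValueError(
            f"window {window} exceeds sequence length {len(seq)}"
        )
    residue = np.array([scale[aa] for aa in seq.upper()])
    kernel = np.ones(window) / window
    values = np.convolve(residue, kernel, mode="valid")
    return HydropathyProfile(
        protein_id=protein_id,
        window=window,
        values=tuple(float(v) for v in values),
        residue_values=tuple(float(v) for v in residue),
    )


def find_tm_segment(
    profile: HydropathyProfile,
    threshold: float = 1.6,
    min_len: int = 15,
    max_len: int = 25,
    merge_gap: int = 2,
    slack: int = 5,
) -> list:
    """Candidate transmembrane segments as sequence-coordinate intervals.

    Maximal runs of window positions with mean hydropathy >= threshold
    (runs separated by <= ``merge_gap`` sub-threshold positions are
    merged) are mapped to sequence intervals and trimmed of hydrophilic
    flank residues (per-residue hydropathy < 0) that window smoothing
    drags in.  An interval is reported when its residue length lies in
    ``[min_len, max_len + slack]``.
    """
    vals = np.asarray(profile.values)
    above = vals >= threshold
    runs = []
    i = 0
    n = len(above)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j < n and above[j]:
            j += 1
        runs.append([i, j])  # half-open on profile positions
        i = j
    # merge runs separated by short sub-threshold stretches
    merged = []
    for run in runs:
        if merged and run[0] - merged[-1][1] <= merge_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)

    intervals = []
    res = profile.residue_values
    for start, stop in merged:
        s = start
        e = stop - 1 + profile.window  # sequence coords, half-open
        # trim charged/hydrophilic flanks the window smoothing pulled in
        while s < e and res[s] < 0:
            s += 1
        while e > s and res[e - 1] < 0:
            e -= 1
        length = e - s
        if min_len <= length <= max_len + slack:
            intervals.append((s, e))
    return intervals


def scan_pep_cterm(
    record: ProteinRecord, cfg: PepCtermConfig | None = None
) -> PepCtermHit | None:
    """Scan one protein for a C-terminal PEP-CTERM sorting signal.

    A hit requires, within the C-terminal search region: the literal
    motif (default ``PEP``); a TM segment beginning within a small gap
    after the motif; and at least ``min_basic`` basic residues (K/R)
    within ``basic_window`` residues after the TM segment.  The leftmost
    qualifying motif occurrence wins.  Absence of a signal returns None.
    """
    cfg = cfg or PepCtermConfig()
    seq = record.sequence
    if len(seq) < cfg.min_length:
        return None
    profile = hydropathy_profile(seq, record.id, window=cfg.window)
    segments = find_tm_segment(
        profile,
        threshold=cfg.hydropathy_threshold,
        min_len=cfg.tm_min_len,
        max_len=cfg.tm_max_len,
        merge_gap=cfg.merge_gap,
        slack=cfg.tm_len_slack,
    )
    region_start = max(0, len(seq) - cfg.search_region)
    pos = seq.find(cfg.motif, region_start)
    while pos != -1:
        hit = _evaluate_motif(record, seq, pos, segments, cfg)
        if hit is not None:
            return hit
        pos = seq.find(cfg.motif, pos + 1)
    return None


def _evaluate_motif(record, seq, pep_start, segments, cfg):
    pep_end = pep_start + len(cfg.motif)
    res = [KYTE_DOOLITTLE[aa] for aa in seq]
    for ts, te in segments:
        cs = max(ts, pep_end)  # clip TM start to after the motif
        if te <= pep_end:
            continue
        if cs - pep_end > cfg.max_gap_after_motif:
            continue
        if not cfg.tm_min_len <= te - cs <= cfg.tm_max_len + cfg.tm_len_slack:
            continue
        b_end = min(te + cfg.basic_window, len(seq))
        n_basic = sum(1 for aa in seq[te:b_end] if aa in BASIC_RESIDUES)
        if n_basic < cfg.min_basic:
            continue
        return PepCtermHit(
            protein_id=record.id,
            pep_start=pep_start,
            tm_interval=(cs, te),
            basic_cluster_interval=(te, b_end),
            n_basic=n_basic,
            score=float(np.mean(res[cs:te])),
            sequence_length=len(seq),
        )
    return None


def scan_proteome(records: list, cfg: PepCtermConfig | None = None):
    """Scan every record; returns ``(hits, table)``.

    ``hits`` is a list of :class:`PepCtermHit`; ``table`` a tidy
    DataFrame (one row per hit).
    """
    cfg = cfg or PepCtermConfig()
    hits = []
    for rec in records:
        hit = scan_pep_cterm(rec, cfg)
        if hit is not None:
            hits.append(hit)
    log.info("scan_proteome: %d / %d proteins carry the signal", len(hits), len(records))
    return hits, hits_to_frame(hits)


def hits_to_frame(hits: list) -> pd.DataFrame:
    rows = [
        {
            "protein_id": h.protein_id,
            "pep_start": h.pep_start,
            "tm_start": h.tm_interval[0],
            "tm_end": h.tm_interval[1],
            "basic_start": h.basic_cluster_interval[0],
            "basic_end": h.basic_cluster_interval[1],
            "n_basic": h.n_basic,
            "score": round(h.score, 6),
        }
        for h in hits
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id",
            "pep_start",
            "tm_start",
            "tm_end",
            "basic_start",
            "basic_end",
            "n_basic",
            "score",
        ],
    )


def hits_to_gff3(hits: list) -> str:
    """Render hits as GFF3 (1-based, closed intervals)."""
    lines = ["##gff-version 3"]
    for k, h in enumerate(hits, start=1):
        end = h.basic_cluster_interval[1]
        feature_id = f"pepcterm{k:04d}"
        lines.append(
            "\t".join(
                [
                    h.protein_id,
                    "omproteome",
                    "PEP_CTERM_sorting_signal",
                    str(h.pep_start + 1),
                    str(end),
                    f"{h.score:.3f}",
                    ".",
                    ".",
                    f"ID={feature_id}",
                ]
            )
        )
        for sub, (s, e) in (
            ("PEP_motif", (h.pep_start, h.pep_start + 3)),
            ("TM_segment", h.tm_interval),
            ("basic_cluster", h.basic_cluster_interval),
        ):
            lines.append(
                "\t".join(
                    [
                        h.protein_id,
                        "omproteome",
                        sub,
                        str(s + 1),
                        str(e),
                        ".",
                        ".",
                        ".",
                        f"Parent={feature_id}",
                    ]
                )
            )
    return "\n".join(lines) + "\n"
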