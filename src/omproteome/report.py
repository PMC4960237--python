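"""Tabular summaries mirroring the study's figures.

No plotting is required: the deliverables are tidy tables (compartment
stacks per fraction, the paired OM-vs-intracellular abundance table with
the 8.5 candidate threshold and the 4.0 display floor) and the count
audit trail of the filtering chain.  An optional matplotlib scatter is
provided behind a flag for interactive use.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .lfq import compartment_distribution
from .table import AbundanceTable
from .types import AuditTrail


def figure3_table(
    table: AbundanceTable,
    labels: dict,
    sample_om: str,
    sample_ic: str,
    lfq_threshold: float = 8.5,
) -> pd.DataFrame:
    """Paired log10 abundances (OM fraction vs intracellular) per protein.

    Undetected proteins are shown at the display floor (4.0 by default),
    the convention for points under the detection limit.  The
    ``above_threshold`` flag marks proteins exceeding the preliminary
    candidate threshold in the OM-fraction sample.
    """
    for sid in (sample_om, sample_ic):
        if sid not in table.sample_ids:
            raise KeyError(f"unknown sample {sid!r}")
    floor = table.display_floor
    rows = []
    for pid in table.protein_ids:
        vals = {}
        for key, sid in (("log10_om", sample_om), ("log10_ic", sample_ic)):
            if table.detected.at[pid, sid]:
                vals[key] = max(float(table.log10_lfq.at[pid, sid]), floor)
            else:
                vals[key] = floor
        label = labels.get(pid)
        rows.append(
            {
                "protein_id": pid,
                "log10_om": round(vals["log10_om"], 6),
                "log10_ic": round(vals["log10_ic"], 6),
                "compartment": getattr(label, "value", label) or "unknown",
                "above_threshold": vals["log10_om"] > lfq_threshold
                and bool(table.detected.at[pid, sample_om]),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["protein_id", "log10_om", "log10_ic", "compartment", "above_threshold"],
    )


def compartment_stack_table(
    table: AbundanceTable, labels: dict, samples: list | None = None
) -> pd.DataFrame:
    """Tidy (sample, compartment, share) table of per-fraction composition."""
    samples = samples or table.sample_ids
    rows = []
    for sid in samples:
        dist = compartment_distribution(table, labels, sid)
        for comp, share in sorted(dist.shares.items(), key=lambda kv: kv[0].value):
            rows.append(
                {"sample_id": sid, "compartment": comp.value, "share": round(share, 9)}
            )
    return pd.DataFrame(rows, columns=["sample_id", "compartment", "share"])


def audit(stage_counts: list) -> AuditTrail:
    """Build the audit trail from ordered (stage, count, description) triples.

    The filtering chain of the analysis is count-based (identified ->
    preliminary candidates -> confirmed OM -> genome-only -> responsive),
    so every stage logs how many proteins survive it.
    """
    trail = AuditTrail()
    for item in stage_counts:
        name, count = item[0], item[1]
        desc = item[2] if len(item) > 2 else ""
        trail.add(name, count, desc)
    return trail


def write_audit(trail: AuditTrail, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "audit_trail.json", "w") as fh:
        json.dump(trail.to_json_obj(), fh, indent=2)
    (out / "audit_trail.txt").write_text(trail.to_text() + "\n")


def plot_figure3(frame: pd.DataFrame, path, lfq_threshold: float = 8.5) -> None:
    """Optional scatter of the paired abundance table (matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for comp, grp in frame.groupby("compartment"):
        ax.scatter(grp["log10_ic"], grp["log10_om"], s=8, label=comp, alpha=0.6)
    lo = min(frame["log10_ic"].min(), frame["log10_om"].min())
    hi = max(frame["log10_ic"].max(), frame["log10_om"].max())
    ax.plot([lo, hi], [lo, hi], "k--", lw=0.8)
    ax.axhline(lfq_threshold, ls=":", color="gray", lw=0.8)
    ax.set_xlabel("log10 LFQ, intracellular")
    ax.set_ylabel("log10 LFQ, OM fraction")
    ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
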