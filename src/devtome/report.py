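"""Report tables mirroring the published summary layouts.

Pattern-summary percentages are truncated (not rounded) to the stated number
of decimals — the convention under which the published per-class percentages
are exactly reproducible from their counts — while TF-class percentages are
rounded to one decimal.
"""

from __future__ import annotations

import pandas as pd

from ._util import truncate_percent

PATTERN_DISPLAY = {
    "constitutive_high": "Constitutive highly expressed genes",
    "constitutive_low": "Constitutive low",
    "specific_1": "Single stage specific",
    "specific_2": "Two-stage specific",
    "specific_3": "Three-stage specific",
    "specific_4": "Four-stage specific",
    "specific_5": "Five-stage specific",
    "other": "Other",
}


def pattern_table(pattern_counts: pd.DataFrame, total_genes: int,
                  decimals: int = 2) -> pd.DataFrame:
    """Per-pattern counts with percentage of total unigenes (truncated)."""
    table = pattern_counts.copy()
    table["percent_of_total"] = [
        truncate_percent(100.0 * c / total_genes, decimals) if total_genes else 0.0
        for c in table["count"]
    ]
    table["description"] = [PATTERN_DISPLAY.get(lbl, lbl) for lbl in table.index]
    return table


def stage_specific_breakdown(patterns: pd.DataFrame, total_genes: int,
                             decimals: int = 2) -> pd.DataFrame:
    """Single-stage-specific counts per stage, with truncated percentages."""
    single = patterns[patterns["label"] == "specific_1"]
    counts = single["stages"].value_counts().sort_index()
    return pd.DataFrame({
        "count": counts.astype(int),
        "percent_of_total": [truncate_percent(100.0 * c / total_genes, decimals)
                             for c in counts],
    })


def orf_partition_table(gene_classes: dict, transcript_classes: dict) -> pd.DataFrame:
    rows = []
    for cls in ("complete", "partial", "noncoding"):
        rows.append({
            "class": cls,
            "n_genes": sum(1 for v in gene_classes.values() if v == cls),
            "n_transcripts": sum(1 for v in transcript_classes.values() if v == cls),
        })
    return pd.DataFrame(rows).set_index("class")


def preprocess_table(per_library_stats: dict) -> pd.DataFrame:
    """Stage, reads before/after, percent retained (one decimal)."""
    rows = []
    for stage, stats in per_library_stats.items():
        rows.append({"stage": stage, "n_before": stats.n_before,
                     "n_after": stats.n_after_qc,
                     "percent_retained": stats.percent_retained_qc})
    return pd.DataFrame(rows).set_index("stage")
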