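"""Abundance-based transcript filtering and assembly statistics.

Both filters act on expected counts pooled across all libraries:

* the isoform-share filter removes transcripts contributing less than
  ``min_percent`` of their parent gene's pooled expression;
* the TPM filter removes transcripts whose pooled transcripts-per-million
  falls below ``min_tpm``, with TPM_i = 1e6 * (c_i / l_i) / sum_j (c_j / l_j).

Each filter is a per-transcript predicate on pooled values, so the two
commute. Gene identifiers are derived from Trinity-style transcript names
(``comp<g>_c<c>_seq<i>`` -> ``comp<g>_c<c>``) when not supplied.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

_TRINITY_ID = re.compile(r"^(comp\d+_c\d+)_seq\d+$")


class DataIntegrityError(ValueError):
    pass


def gene_of_transcript(transcript_id: str) -> str:
    m = _TRINITY_ID.match(transcript_id)
    if not m:
        raise DataIntegrityError(
            f"cannot derive parent gene from transcript id {transcript_id!r}")
    return m.group(1)


def pooled_counts(counts: pd.DataFrame) -> pd.Series:
    """Sum expected counts across libraries (rows = transcripts)."""
    return counts.sum(axis=1)


def isoform_percent_filter(counts: pd.DataFrame, gene_map: pd.Series,
                           min_percent: float = 1.0) -> pd.Index:
    """Transcripts holding >= min_percent of their gene's pooled expression.

    Genes whose pooled expression is zero retain no isoforms.
    """
    pooled = pooled_counts(counts)
    missing = pooled.index.difference(gene_map.index)
    if len(missing):
        raise DataIntegrityError(
            f"transcripts without a parent gene: {list(missing[:3])}")
    genes = gene_map.reindex(pooled.index)
    gene_totals = pooled.groupby(genes).sum()
    totals = genes.map(gene_totals)
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(totals > 0, 100.0 * pooled / totals, 0.0)
    keep = (share >= min_percent) & (totals > 0)
    return pooled.index[keep]


def tpm(counts: pd.Series, lengths: pd.Series) -> pd.Series:
    """Transcripts-per-million from pooled counts and effective lengths."""
    lengths = lengths.reindex(counts.index)
    if (lengths <= 0).any() or lengths.isna().any():
        raise DataIntegrityError("nonpositive or missing transcript length")
    rate = counts / lengths
    total = rate.sum()
    if total == 0:
        return rate * 0.0
    return 1e6 * rate / total


def tpm_filter(counts: pd.DataFrame, lengths: pd.Series,
               min_tpm: float = 0.5) -> pd.Index:
    values = tpm(pooled_counts(counts), lengths)
    return values.index[values >= min_tpm]


def apply_filters(counts: pd.DataFrame, lengths: pd.Series, gene_map: pd.Series,
                  min_percent: float = 1.0, min_tpm: float = 0.5) -> pd.DataFrame:
    """Both filters with per-transcript reason codes.

    Returns a frame indexed by transcript with columns ``retained`` and
    ``reason`` ({retained, low_isoform_share, low_tpm}); a transcript failing
    both is reported under the isoform-share code.
    """
    share_keep = set(isoform_percent_filter(counts, gene_map, min_percent))
    tpm_keep = set(tpm_filter(counts, lengths, min_tpm))
    reasons = []
    for tid in counts.index:
        if tid not in share_keep:
            reasons.append("low_isoform_share")
        elif tid not in tpm_keep:
            reasons.append("low_tpm")
        else:
            reasons.append("retained")
    return pd.DataFrame({"reason": reasons,
                         "retained": [r == "retained" for r in reasons]},
                        index=counts.index)


@dataclass
class AssemblyStats:
    n_contigs: int
    n50: int
    n_over_1kb: int
    total_sum: int


def assembly_stats(lengths) -> AssemblyStats:
    """Contig count, N50 (sorted cumulative half-sum), >1 kb count, total bases."""
    lengths = np.asarray(list(lengths), dtype=np.int64)
    if lengths.size == 0:
        raise ValueError("assembly_stats requires at least one contig length")
    total = int(lengths.sum())
    ordered = np.sort(lengths)[::-1]
    cumulative = np.cumsum(ordered)
    n50 = int(ordered[np.searchsorted(cumulative, total / 2.0)])
    return AssemblyStats(
        n_contigs=int(lengths.size),
        n50=n50,
        n_over_1kb=int((lengths > 1000).sum()),
        total_sum=total,
    )
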