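"""Between-library normalization, FPKM, ordinal binning and stage patterns.

TMM (trimmed mean of M-values) computes one positive scaling factor per
library by doubly trimming per-gene log-ratios (M) and log-abundances (A)
against a reference library, taking a precision-weighted mean of the
surviving M-values, and mean-centering the factors in log space. FPKM then
uses the effective library size ``N_s * f_s``:

    FPKM_gs = 1e9 * c_gs / (l_g * N_s * f_s)

FPKM values are rounded to the nearest integer (half-up) and binned into the
eight ordinal expression categories used for developmental RNA-seq
("No Expression" through "extremely high"); per-gene patterns over the six
stage libraries are classified from the ordinal codes:

* constitutive high — code >= 5 (moderately high+) in all six libraries;
* k-stage specific, k = 1 — code >= 4 (moderate+) in exactly one library and
  <= 3 (low or less) in the other five;
* k-stage specific, k = 2..5 — code >= 5 in exactly k libraries and <= 2
  (very low or less) in the rest;
* constitutive low — code <= 3 in all six, when nothing above applied;
* other — the remainder.

The single-stage rule intentionally uses different thresholds from the
multi-stage rule; both are implemented verbatim rather than harmonized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import STAGES

BIN_NAMES = {
    1: "No Expression",
    2: "Very Low",
    3: "Low",
    4: "Moderate",
    5: "Moderately High",
    6: "High",
    7: "Very High",
    8: "Extremely High",
}

#: upper edge (inclusive, on integer-rounded FPKM) of codes 1..7; code 8 is open
DEFAULT_BIN_EDGES = (0, 3, 10, 25, 50, 100, 1000)


def _as_matrix(counts) -> pd.DataFrame:
    m = pd.DataFrame(counts).astype(float)
    if (m.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")
    return m


def choose_reference(counts: pd.DataFrame) -> str:
    """Library whose upper quartile (of scaled counts) is closest to the mean."""
    scaled = counts.div(counts.sum(axis=0), axis=1)
    uq = scaled.quantile(0.75, axis=0)
    return (uq - uq.mean()).abs().idxmin()


def _tmm_pair(obs, ref, n_obs, n_ref, trim_m, trim_a):
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep], ref[keep]
    if obs.size == 0:
        return 1.0
    p_obs, p_ref = obs / n_obs, ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # Binomial precision weights on count *proportions* (library sizes treated
    # as equal): proportional to the usual delta-method weights at matched
    # depth, and making the factors a function of relative composition only,
    # so the TMM-FPKM pipeline is exactly invariant to rescaling any library.
    w = (1.0 - p_obs) / p_obs + (1.0 - p_ref) / p_ref
    n = m.size
    lo_m, hi_m = np.floor(n * trim_m) + 1, n + 1 - (np.floor(n * trim_m) + 1)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n + 1 - (np.floor(n * trim_a) + 1)
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any() or w[keep].sum() == 0:
        return 1.0
    return float(2.0 ** (np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])))


def tmm_factors(counts, trim_m: float = 0.30, trim_a: float = 0.05,
                ref: str | None = None) -> pd.Series:
    """TMM scaling factors, mean-centered in log space.

    Genes with zero counts in either the library or the reference are
    excluded from that library's trimmed mean; weights are the usual
    binomial-approximation inverse variances.
    """
    m = _as_matrix(counts)
    if m.shape[1] < 2:
        raise ValueError("TMM needs at least two libraries")
    sizes = m.sum(axis=0)
    if (sizes == 0).any():
        bad = list(sizes.index[sizes == 0])
        raise ValueError(f"libraries with all-zero counts: {bad}")
    if ref is None:
        ref = choose_reference(m)
    ref_col = m[ref].to_numpy()
    factors = {}
    for lib in m.columns:
        if lib == ref:
            factors[lib] = 1.0
        else:
            factors[lib] = _tmm_pair(m[lib].to_numpy(), ref_col,
                                     sizes[lib], sizes[ref], trim_m, trim_a)
    f = pd.Series(factors, index=m.columns)
    return f / np.exp(np.log(f).mean())


def fpkm(counts, factors: pd.Series, lengths: pd.Series) -> pd.DataFrame:
    """FPKM with TMM-adjusted library sizes."""
    m = _as_matrix(counts)
    lengths = lengths.reindex(m.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every feature needs a positive length")
    sizes = m.sum(axis=0) * factors.reindex(m.columns)
    return 1e9 * m.div(lengths, axis=0).div(sizes, axis=1)


def gene_level(counts: pd.DataFrame, lengths: pd.Series, gene_map: pd.Series,
               length_mode: str = "weighted") -> tuple[pd.DataFrame, pd.Series]:
    """Aggregate isoform counts to genes.

    Gene length is the expression-weighted mean of isoform lengths
    (``weighted``, pooled-count weights) or the plain sum (``sum``).
    """
    genes = gene_map.reindex(counts.index)
    gene_counts = counts.groupby(genes).sum()
    # isoform weights from depth-normalized abundances (mean of per-library
    # count proportions), so gene lengths are invariant to library rescaling
    pooled = (counts / counts.sum(axis=0)).mean(axis=1)
    if length_mode == "weighted":
        w = pooled.groupby(genes).transform(lambda s: s / s.sum() if s.sum() else 1.0 / len(s))
        gene_len = (lengths.reindex(counts.index) * w).groupby(genes).sum()
    elif length_mode == "sum":
        gene_len = lengths.reindex(counts.index).groupby(genes).sum()
    else:
        raise ValueError(f"unknown length_mode {length_mode!r}")
    return gene_counts, gene_len


def round_half_up(values):
    return np.floor(np.asarray(values, dtype=float) + 0.5)


def bin_expression(fpkm_matrix, edges=DEFAULT_BIN_EDGES,
                   integerize: str = "round") -> pd.DataFrame:
    """Ordinal category codes 1..8 from FPKM.

    FPKM is integerized (round-half-up by default, ``floor`` available) and
    compared against the inclusive upper edges of codes 1..len(edges).
    """
    m = pd.DataFrame(fpkm_matrix).astype(float)
    if (m.to_numpy() < 0).any():
        raise ValueError("FPKM must be nonnegative")
    edges = np.asarray(edges, dtype=float)
    if not np.all(np.diff(edges) > 0):
        raise ValueError("bin edges must be strictly increasing")
    values = round_half_up(m.to_numpy()) if integerize == "round" else np.floor(m.to_numpy())
    codes = np.searchsorted(edges, values, side="left") + 1
    return pd.DataFrame(codes.astype(int), index=m.index, columns=m.columns)


@dataclass
class StagePattern:
    gene_id: str
    label: str
    stages: tuple = ()


def classify_stage_patterns(categories: pd.DataFrame) -> pd.DataFrame:
    """Per-gene developmental pattern labels from ordinal codes.

    Rules are evaluated in the order documented in the module docstring;
    labels are exhaustive and mutually exclusive. Returns a frame with
    ``label`` and ``stages`` ("+"-joined stage names for specific patterns).
    """
    cats = categories
    stage_names = list(cats.columns)
    codes = cats.to_numpy(int)
    labels, stage_sets = [], []
    for row in codes:
        label, stages = None, ()
        if (row >= 5).all():
            label = "constitutive_high"
        if label is None:
            on = row >= 4
            if on.sum() == 1 and (row[~on] <= 3).all():
                label = "specific_1"
                stages = tuple(np.array(stage_names)[on])
        if label is None:
            on = row >= 5
            k = int(on.sum())
            if 2 <= k <= 5 and (row[~on] <= 2).all():
                label = f"specific_{k}"
                stages = tuple(np.array(stage_names)[on])
        if label is None and (row <= 3).all():
            label = "constitutive_low"
        if label is None:
            label = "other"
        labels.append(label)
        stage_sets.append("+".join(stages))
    return pd.DataFrame({"label": labels, "stages": stage_sets}, index=cats.index)


def pattern_summary(patterns: pd.DataFrame) -> pd.DataFrame:
    """Counts per pattern label (all labels present, zero-filled)."""
    order = (["constitutive_high", "constitutive_low"]
             + [f"specific_{k}" for k in range(1, 6)] + ["other"])
    counts = patterns["label"].value_counts()
    return pd.DataFrame({"count": [int(counts.get(lbl, 0)) for lbl in order]},
                        index=pd.Index(order, name="label"))


def compare_bin_distributions(categories_a: pd.DataFrame,
                              categories_b: pd.DataFrame) -> pd.DataFrame:
    """Per-stage, per-code gene counts for two datasets, side by side."""
    rows = []
    for name, cats in (("A", categories_a), ("B", categories_b)):
        for stage in cats.columns:
            counts = cats[stage].value_counts()
            for code in range(1, 9):
                rows.append({"dataset": name, "stage": stage, "code": code,
                             "bin": BIN_NAMES[code],
                             "n_genes": int(counts.get(code, 0))})
    return pd.DataFrame(rows)


def expression_profile(counts, lengths, gene_map=None, trim_m=0.30, trim_a=0.05,
                       edges=DEFAULT_BIN_EDGES):
    """Counts -> (factors, gene FPKM, categories, patterns) in one call."""
    if gene_map is not None:
        gcounts, glen = gene_level(counts, lengths, gene_map)
    else:
        gcounts, glen = _as_matrix(counts), lengths
    factors = tmm_factors(gcounts, trim_m, trim_a)
    values = fpkm(gcounts, factors, glen)
    categories = bin_expression(values, edges)
    patterns = classify_stage_patterns(categories)
    return factors, values, categories, patterns
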