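"""Reciprocal-best-unique-hit orthology and cross-species expression divergence.

Orthology: gene-level best hits are the subject gene with maximal bitscore
(max over the gene's transcript-level hits). A pair (a, b) is called an
ortholog only when a's best hit is b, b's best hit is a, and both bests are
unique (no second subject ties the maximal bitscore). Mutual pairs failing
uniqueness are reported as ``nonunique_excluded``.

Divergence: per matched developmental stage, ordinary least squares of
log10 expression in species A on species B over ortholog pairs with positive
expression in both; pairs are flagged outside a 95% interval. Two interval
modes are available:

* ``prediction`` (default) — leave-one-out prediction interval, equivalent to
  flagging externally studentized residuals beyond the two-sided t critical
  value, the standard calibrated rule for screening individual observations;
* ``confidence`` — the confidence band of the fitted mean.

Pairs flagged in every fitted stage are the consistently divergent set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

HIT_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
               "qstart", "qend", "sstart", "send", "evalue", "bitscore"]


def read_hit_table(path_or_df) -> pd.DataFrame:
    """Parse a 12-column tabular alignment hit table."""
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
        if list(df.columns) != HIT_COLUMNS:
            df.columns = HIT_COLUMNS
    else:
        df = pd.read_csv(path_or_df, sep="\t", header=None, names=HIT_COLUMNS,
                         comment="#")
    return df


def best_unique_hits(hits: pd.DataFrame,
                     query_gene_map: pd.Series | None = None,
                     subject_gene_map: pd.Series | None = None) -> pd.DataFrame:
    """Per query gene: top-bitscore subject gene and a uniqueness flag.

    Gene-level bitscore is the maximum over transcript-level hits; uniqueness
    fails when two or more subject genes tie that maximum exactly.
    """
    df = hits.copy()
    df["qgene"] = df["qseqid"].map(query_gene_map) if query_gene_map is not None else df["qseqid"]
    df["sgene"] = df["sseqid"].map(subject_gene_map) if subject_gene_map is not None else df["sseqid"]
    if df["qgene"].isna().any() or df["sgene"].isna().any():
        raise ValueError("hit table contains ids absent from the gene maps")
    pair_best = df.groupby(["qgene", "sgene"], sort=False)["bitscore"].max().reset_index()
    out = []
    for qgene, sub in pair_best.groupby("qgene", sort=False):
        top = sub["bitscore"].max()
        winners = tuple(sorted(sub.loc[sub["bitscore"] == top, "sgene"]))
        out.append({"query_gene": qgene, "best_subject": winners[0],
                    "winners": winners, "bitscore": top,
                    "unique": len(winners) == 1})
    return pd.DataFrame(out).set_index("query_gene")


def reciprocal_orthologs(fwd_best: pd.DataFrame, rev_best: pd.DataFrame) -> pd.DataFrame:
    """Reciprocal best-hit pairs with status {ortholog, nonunique_excluded}.

    A pair is mutual when each gene is among the other's top-scoring subjects
    (ties included); mutual pairs are orthologs only when both tops are
    unique, otherwise they are recorded as excluded.
    """
    rows = []
    for gene_a, row in fwd_best.iterrows():
        for gene_b in row["winners"]:
            if gene_b not in rev_best.index:
                continue
            back = rev_best.loc[gene_b]
            if gene_a not in back["winners"]:
                continue
            status = ("ortholog" if (row["unique"] and back["unique"])
                      else "nonunique_excluded")
            rows.append({"gene_a": gene_a, "gene_b": gene_b, "status": status})
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "status"])


def rbh_orthologs(hits_fwd, hits_rev, query_gene_map=None,
                  subject_gene_map=None) -> pd.DataFrame:
    fwd = best_unique_hits(read_hit_table(hits_fwd), query_gene_map, subject_gene_map)
    rev = best_unique_hits(read_hit_table(hits_rev), subject_gene_map, query_gene_map)
    return reciprocal_orthologs(fwd, rev)


@dataclass
class StageRegression:
    stage: str
    slope: float
    intercept: float
    rho: float
    rho_pvalue: float
    n: int
    sigma: float
    flags: pd.DataFrame = field(repr=False)  # per pair: within/outside + residual

    @property
    def outside_fraction(self) -> float:
        return float((self.flags["flag"] == "outside").mean())


def _loo_outside(x, y, alpha):
    """Outside flags from leave-one-out prediction intervals.

    A point is outside its LOO 95% prediction interval iff its externally
    studentized residual exceeds the two-sided t critical value with n-3
    degrees of freedom; computed in closed form from hat values.
    """
    n = x.size
    X = np.column_stack([np.ones(n), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    h = np.sum(X * (X @ np.linalg.inv(X.T @ X)), axis=1)
    sse = float(resid @ resid)
    s = np.sqrt(sse / (n - 2))
    if sse <= 0 or n < 4:  # perfect fit (or too few points to exclude one)
        return beta, resid, s, np.zeros(n, dtype=bool)
    df_loo = n - 3
    # externally studentized residual: s_(i)^2 excludes observation i
    s2_i = np.maximum((sse - resid**2 / (1.0 - h)) / df_loo, 1e-300)
    t_i = resid / np.sqrt(s2_i * (1.0 - h))
    crit = stats.t.ppf(1.0 - alpha / 2.0, df_loo)
    return beta, resid, s, np.abs(t_i) > crit


def _full_fit_outside(x, y, alpha, band):
    n = x.size
    X = np.column_stack([np.ones(n), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    h = np.sum(X * (X @ np.linalg.inv(X.T @ X)), axis=1)
    s = np.sqrt(float(resid @ resid) / (n - 2))
    if s <= 0:
        return beta, resid, s, np.zeros(n, dtype=bool)
    crit = stats.t.ppf(1.0 - alpha / 2.0, n - 2)
    widths = crit * s * (np.sqrt(1.0 + h) if band == "prediction_insample" else np.sqrt(h))
    return beta, resid, s, np.abs(resid) > widths


def fit_stage_regression(pairs: pd.DataFrame, expr_a: pd.DataFrame,
                         expr_b: pd.DataFrame, stage_a: str, stage_b: str,
                         alpha: float = 0.05,
                         band: str = "prediction") -> StageRegression:
    """OLS of log10 expression (A on B) for one stage, with outlier flags.

    Pairs with nonpositive expression in either species are excluded from the
    fit and from flagging (their flag is recorded as ``unfit``). ``band`` is
    ``prediction`` (leave-one-out, default), ``prediction_insample`` or
    ``confidence``.
    """
    orth = pairs[pairs["status"] == "ortholog"]
    a = expr_a.reindex(orth["gene_a"])[stage_a].to_numpy(float)
    b = expr_b.reindex(orth["gene_b"])[stage_b].to_numpy(float)
    usable = np.isfinite(a) & np.isfinite(b) & (a > 0) & (b > 0)
    if usable.sum() < 3:
        raise ValueError(f"stage {stage_a}: fewer than 3 ortholog pairs with "
                         "positive expression in both species")
    y, x = np.log10(a[usable]), np.log10(b[usable])
    if band == "prediction":
        beta, resid, s, outside = _loo_outside(x, y, alpha)
    elif band in ("prediction_insample", "confidence"):
        beta, resid, s, outside = _full_fit_outside(x, y, alpha, band)
    else:
        raise ValueError(f"unknown band mode {band!r}")
    rho, pval = stats.pearsonr(x, y)
    flags = pd.DataFrame({"gene_a": orth["gene_a"].to_numpy(),
                          "gene_b": orth["gene_b"].to_numpy(),
                          "flag": "unfit", "residual": np.nan})
    flags.loc[usable, "flag"] = np.where(outside, "outside", "within")
    flags.loc[usable, "residual"] = resid
    return StageRegression(stage=stage_a, slope=float(beta[1]),
                           intercept=float(beta[0]), rho=float(rho),
                           rho_pvalue=float(pval), n=int(usable.sum()),
                           sigma=float(s), flags=flags.set_index("gene_a"))


def summarize_divergence(regressions: list[StageRegression]) -> pd.DataFrame:
    """Per-pair counts of stages flagged outside, with categories.

    Categories: ``always_within`` (0 outside among fitted stages),
    ``always_outside`` (outside in every fitted stage), ``outside_in_k``
    otherwise. Pairs never fit in any stage are ``unfit``.
    """
    if not regressions:
        raise ValueError("need at least one fitted stage")
    genes = regressions[0].flags.index
    outside = pd.DataFrame(0, index=genes, columns=range(len(regressions)))
    fitted = pd.DataFrame(False, index=genes, columns=range(len(regressions)))
    for j, reg in enumerate(regressions):
        flags = reg.flags["flag"].reindex(genes)
        outside[j] = (flags == "outside").astype(int)
        fitted[j] = flags.isin(["outside", "within"])
    n_outside = outside.sum(axis=1)
    n_fitted = fitted.sum(axis=1)
    category = np.where(n_fitted == 0, "unfit",
                        np.where(n_outside == 0, "always_within",
                                 np.where(n_outside == n_fitted, "always_outside",
                                          "outside_in_k")))
    return pd.DataFrame({"n_stages_fitted": n_fitted, "n_stages_outside": n_outside,
                         "category": category}, index=genes)


def divergence_totals(summary: pd.DataFrame) -> dict:
    fit = summary[summary["category"] != "unfit"]
    n = len(fit)
    always_within = int((fit["category"] == "always_within").sum())
    return {
        "n_pairs": n,
        "always_within": always_within,
        "always_outside": int((fit["category"] == "always_outside").sum()),
        "outside_in_at_least_one": int((fit["n_stages_outside"] > 0).sum()),
        "always_within_percent": int(round(100.0 * always_within / n)) if n else 0,
    }
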