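"""RBH orthology truth recovery and divergence-screen statistics."""

import numpy as np
import pandas as pd
import pytest

from devtome import orthology as orth
from devtome.synthetic import REF_STAGE_MAP


def _hits(rows):
    out = []
    for q, s, bits in rows:
        out.append({"qseqid": q, "sseqid": s, "pident": 90.0, "length": 100,
                    "mismatch": 5, "gapopen": 0, "qstart": 1, "qend": 100,
                    "sstart": 1, "send": 100, "evalue": 1e-50, "bitscore": bits})
    return pd.DataFrame(out, columns=orth.HIT_COLUMNS)


class TestBestUniqueHits:
    def test_single_hit_unique(self):
        best = orth.best_unique_hits(_hits([("a", "x", 100.0)]))
        assert best.loc["a", "best_subject"] == "x" and best.loc["a", "unique"]

    def test_exact_tie_flagged_nonunique(self):
        best = orth.best_unique_hits(_hits([("a", "x", 100.0), ("a", "y", 100.0),
                                            ("a", "z", 60.0)]))
        assert not best.loc["a", "unique"]

    def test_gene_level_max_over_isoforms(self):
        gene_map = pd.Series({"g1_t1": "g1", "g1_t2": "g1"})
        best = orth.best_unique_hits(
            _hits([("g1_t1", "x", 80.0), ("g1_t2", "y", 120.0)]),
            query_gene_map=gene_map)
        assert best.loc["g1", "best_subject"] == "y"
        assert best.loc["g1", "bitscore"] == 120.0

    def test_matches_bruteforce_scan(self, reference_dataset):
        _, _, truth, ref = reference_dataset
        gene_map = truth.transcripts.set_index("transcript_id")["gene_id"]
        subject_map = ref.proteins.set_index("protein_id")["ref_gene_id"]
        best = orth.best_unique_hits(ref.hits_fwd, gene_map, subject_map)
        df = ref.hits_fwd.assign(qgene=ref.hits_fwd["qseqid"].map(gene_map),
                                 sgene=ref.hits_fwd["sseqid"].map(subject_map))
        for qgene, sub in df.groupby("qgene"):
            top = sub["bitscore"].max()
            winners = set(sub.loc[sub["bitscore"] == top, "sgene"])
            assert best.loc[qgene, "unique"] == (len(winners) == 1)
            assert best.loc[qgene, "best_subject"] in winners


class TestReciprocal:
    def test_mutual_tied_pair_excluded(self):
        fwd = _hits([("a", "b", 100.0), ("a", "b2", 100.0)])
        rev = _hits([("b", "a", 100.0)])
        pairs = orth.rbh_orthologs(fwd, rev)
        assert list(pairs["status"]) == ["nonunique_excluded"]

    def test_truth_table_recovery_with_ties(self, reference_dataset):
        _, _, truth, ref = reference_dataset
        gene_map = truth.transcripts.set_index("transcript_id")["gene_id"]
        subject_map = ref.proteins.set_index("protein_id")["ref_gene_id"]
        pairs = orth.rbh_orthologs(ref.hits_fwd, ref.hits_rev, gene_map, subject_map)
        genes = truth.genes.dropna(subset=["ortholog_id"])
        tie = genes["rbh_tie"].astype(bool)
        expected_orth = set(zip(genes.loc[~tie, "gene_id"],
                                genes.loc[~tie, "ortholog_id"]))
        expected_tied = set(zip(genes.loc[tie, "gene_id"],
                                genes.loc[tie, "ortholog_id"]))
        got_orth = set(zip(*pairs.loc[pairs["status"] == "ortholog",
                                      ["gene_a", "gene_b"]].T.values))
        got_tied = set(zip(*pairs.loc[pairs["status"] == "nonunique_excluded",
                                      ["gene_a", "gene_b"]].T.values))
        assert got_orth == expected_orth
        assert got_tied == expected_tied
        assert len(expected_tied) > 0

    def test_symmetric_under_species_swap(self, reference_dataset):
        _, _, truth, ref = reference_dataset
        gene_map = truth.transcripts.set_index("transcript_id")["gene_id"]
        subject_map = ref.proteins.set_index("protein_id")["ref_gene_id"]
        ab = orth.rbh_orthologs(ref.hits_fwd, ref.hits_rev, gene_map, subject_map)
        ba = orth.rbh_orthologs(ref.hits_rev, ref.hits_fwd, subject_map, gene_map)
        pairs_ab = set(map(frozenset, zip(ab["gene_a"], ab["gene_b"])))
        pairs_ba = set(map(frozenset, zip(ba["gene_a"], ba["gene_b"])))
        assert pairs_ab == pairs_ba


def _simulated_pairs(n, seed, offset_sd=0.0, n_divergent=0, rho=0.9):
    rng = np.random.default_rng(seed)
    x = rng.normal(1.0, 0.8, n)
    sigma = 0.8 * np.sqrt(1 / rho**2 - 1)
    y = x + rng.normal(0, sigma, n)
    divergent = np.zeros(n, dtype=bool)
    if n_divergent:
        divergent[:n_divergent] = True
        y[:n_divergent] += offset_sd * sigma * np.where(rng.random(n_divergent) < 0.5, -1, 1)
    genes_a = [f"a{i}" for i in range(n)]
    genes_b = [f"b{i}" for i in range(n)]
    pairs = pd.DataFrame({"gene_a": genes_a, "gene_b": genes_b, "status": "ortholog"})
    expr_a = pd.DataFrame({"stage": 10.0 ** y}, index=genes_a)
    expr_b = pd.DataFrame({"stage": 10.0 ** x}, index=genes_b)
    return pairs, expr_a, expr_b, divergent


class TestStageRegression:
    def test_collinear_points_all_within(self):
        pairs, expr_a, expr_b, _ = _simulated_pairs(50, 0, rho=0.999999)
        expr_a["stage"] = expr_b["stage"].to_numpy() * 2.0  # exact line
        reg = orth.fit_stage_regression(pairs, expr_a, expr_b, "stage", "stage")
        assert reg.rho == pytest.approx(1.0)
        assert (reg.flags["flag"] == "within").all()
        assert reg.sigma == pytest.approx(0.0, abs=1e-12)

    def test_too_few_pairs_error(self):
        pairs, expr_a, expr_b, _ = _simulated_pairs(2, 1)
        with pytest.raises(ValueError):
            orth.fit_stage_regression(pairs, expr_a, expr_b, "stage", "stage")

    def test_zero_expression_pairs_excluded(self):
        pairs, expr_a, expr_b, _ = _simulated_pairs(30, 2)
        expr_a.iloc[0, 0] = 0.0
        reg = orth.fit_stage_regression(pairs, expr_a, expr_b, "stage", "stage")
        assert reg.n == 29
        assert reg.flags["flag"].iloc[0] == "unfit"

    def test_null_outside_rate_near_nominal(self):
        pairs, expr_a, expr_b, _ = _simulated_pairs(500, 3)
        reg = orth.fit_stage_regression(pairs, expr_a, expr_b, "stage", "stage")
        assert abs(reg.outside_fraction - 0.05) < 0.02
        assert reg.rho_pvalue < 0.001

    def test_rho_symmetric_under_axis_exchange(self):
        pairs, expr_a, expr_b, _ = _simulated_pairs(200, 4)
        fwd = orth.fit_stage_regression(pairs, expr_a, expr_b, "stage", "stage")
        swapped = pairs.rename(columns={"gene_a": "gene_b", "gene_b": "gene_a"})
        rev = orth.fit_stage_regression(swapped, expr_b, expr_a, "stage", "stage")
        assert fwd.rho == pytest.approx(rev.rho)

    def test_confidence_band_narrower_than_prediction(self):
        pairs, expr_a, expr_b, _ = _simulated_pairs(300, 5)
        pred = orth.fit_stage_regression(pairs, expr_a, expr_b, "stage", "stage",
                                         band="prediction")
        conf = orth.fit_stage_regression(pairs, expr_a, expr_b, "stage", "stage",
                                         band="confidence")
        assert (conf.flags["flag"] == "outside").sum() \
            > (pred.flags["flag"] == "outside").sum()


class TestDivergenceSummary:
    def _five_stage_screen(self, offset_sd, n_divergent, seed=7):
        regs = []
        for stage_seed in range(5):
            pairs, expr_a, expr_b, divergent = _simulated_pairs(
                480 + n_divergent, seed * 100 + stage_seed,
                offset_sd=offset_sd, n_divergent=n_divergent)
            regs.append(orth.fit_stage_regression(pairs, expr_a, expr_b,
                                                  "stage", "stage"))
        return regs, divergent

    def test_all_within_gives_100_percent(self):
        pairs, expr_a, expr_b, _ = _simulated_pairs(50, 8, rho=0.999999)
        expr_a["stage"] = expr_b["stage"].to_numpy() * 3.0
        reg = orth.fit_stage_regression(pairs, expr_a, expr_b, "stage", "stage")
        summary = orth.summarize_divergence([reg])
        totals = orth.divergence_totals(summary)
        assert totals["always_within_percent"] == 100
        assert totals["always_outside"] == 0

    def test_pair_outside_everywhere_is_always_outside(self):
        regs, _ = self._five_stage_screen(8.0, 5)
        summary = orth.summarize_divergence(regs)
        flagged = summary.loc[[f"a{i}" for i in range(5)], "category"]
        assert (flagged == "always_outside").all()

    def test_planted_divergent_pairs_detected_in_some_stage(self):
        regs, divergent = self._five_stage_screen(3.0, 20)
        summary = orth.summarize_divergence(regs)
        planted = summary.loc[[f"a{i}" for i in range(20)]]
        recall = (planted["n_stages_outside"] > 0).mean()
        assert recall >= 0.9
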