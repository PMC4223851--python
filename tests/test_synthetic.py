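"""Generator correctness: determinism, planted truth, statistical calibration."""

import difflib

import numpy as np
import pandas as pd
import pytest

from devtome import preprocess, synthetic
from devtome.synthetic import ConfigError, STAGES, SyntheticConfig

from conftest import binom_bounds, oracle_orf_scan


def test_invalid_configs_rejected():
    with pytest.raises(ConfigError):
        SyntheticConfig(coding_fraction=1.5)
    with pytest.raises(ConfigError):
        SyntheticConfig(stage_pattern_mix={"constitutive_high": 0.5,
                                           "constitutive_low": 0.4})
    with pytest.raises(ConfigError):
        SyntheticConfig(stage_pattern_mix={"constitutive_high": 1.0,
                                           "no_such_pattern": 0.0})
    with pytest.raises(ConfigError):
        synthetic.config_from_dict({"not_a_field": 1})


def test_all_genes_coding_when_fraction_one():
    cfg = SyntheticConfig(n_genes=5, coding_fraction=1.0, n_background=0, seed=3)
    _, truth = synthetic.generate_transcriptome(cfg)
    assert truth.genes["coding"].all()
    planted = truth.transcripts
    assert (planted["orf_start"] > 0).all()
    assert ((planted["orf_end"] - planted["orf_start"] + 1) % 3 == 0).all()


def test_fixed_seed_byte_identical(tmp_path):
    from devtome.io import write_fasta

    paths = []
    for run in (1, 2):
        cfg = SyntheticConfig(n_genes=15, seed=7)
        tx, truth = synthetic.generate_transcriptome(cfg)
        counts = synthetic.generate_expression(truth, cfg)
        reads, _ = synthetic.generate_reads(tx, truth, cfg)
        ref = synthetic.generate_reference_species(truth, cfg)
        p = tmp_path / f"run{run}"
        p.mkdir()
        write_fasta(tx, p / "t.fasta")
        preprocess.write_pairs(reads, p / "r1.fastq", p / "r2.fastq")
        counts.to_csv(p / "c.tsv", sep="\t")
        ref.hits_fwd.to_csv(p / "h.tsv", sep="\t", index=False)
        ref.expression.to_csv(p / "e.tsv", sep="\t", index=False)
        paths.append(p)
    for name in ("t.fasta", "r1.fastq", "r2.fastq", "c.tsv", "h.tsv", "e.tsv"):
        assert (paths[0] / name).read_bytes() == (paths[1] / name).read_bytes()


def test_planted_coding_count_within_binomial_bounds():
    cfg = SyntheticConfig(n_genes=200, coding_fraction=0.5, n_background=0, seed=11)
    _, truth = synthetic.generate_transcriptome(cfg)
    n_coding = int(truth.genes.loc[~truth.genes["is_background"], "coding"].sum())
    lo, hi = binom_bounds(200, 0.5, 0.99)
    assert lo <= n_coding <= hi


def test_planted_orfs_recoverable_by_bruteforce_scan(small_dataset):
    _, transcripts, truth, _ = small_dataset
    planted = truth.transcripts[truth.transcripts["coding"]]
    for _, row in planted.head(40).iterrows():
        hits = oracle_orf_scan(transcripts[row["transcript_id"]], min_aa=100)
        assert hits, row["transcript_id"]
        strand, frame, n_aa, start, end, completeness = max(hits, key=lambda h: h[2])
        assert strand == row["strand"]
        assert (start, end) == (row["orf_start"], row["orf_end"])
        assert completeness == "complete"


def test_noncoding_transcripts_have_no_long_orf(small_dataset):
    _, transcripts, truth, _ = small_dataset
    noncoding = truth.transcripts[~truth.transcripts["coding"]]
    for tid in noncoding["transcript_id"].head(20):
        assert not oracle_orf_scan(transcripts[tid], min_aa=100)


def test_isoforms_share_sequence(small_dataset):
    _, transcripts, truth, _ = small_dataset
    txs = truth.transcripts
    for gene, sub in list(txs.groupby("gene_id"))[:15]:
        ids = list(sub["transcript_id"])
        if len(ids) < 2:
            continue
        a, b = transcripts[ids[0]], transcripts[ids[1]]
        match = difflib.SequenceMatcher(None, a, b, autojunk=False)\
            .find_longest_match(0, len(a), 0, len(b))
        assert match.size >= 0.6 * min(len(a), len(b))


def test_reads_empty_at_zero_depth(small_dataset):
    cfg, transcripts, truth, _ = small_dataset
    cfg0 = SyntheticConfig(**{**cfg.__dict__, "read_depth": 0.0})
    reads, _ = synthetic.generate_reads(transcripts, truth, cfg0)
    assert reads == []


def test_read_failure_rate_matches_binomial(small_dataset):
    cfg, transcripts, truth, _ = small_dataset
    cfg2 = SyntheticConfig(**{**cfg.__dict__, "fail_fraction": 0.2,
                              "read_depth": 60.0})
    pairs, _ = synthetic.generate_reads(transcripts, truth, cfg2)
    retained, stats = preprocess.quality_filter(pairs)
    n, p = len(pairs), 0.8 * 0.8
    assert n > 2000
    sigma = np.sqrt(p * (1 - p) / n)
    assert abs(stats.n_after_qc / n - p) < 3 * sigma


def test_expression_zero_dispersion_equals_design_means(small_dataset):
    cfg, _, truth, _ = small_dataset
    cfg0 = SyntheticConfig(**{**cfg.__dict__, "dispersion": 0.0})
    counts = synthetic.generate_expression(truth, cfg0)
    genes = truth.genes.set_index("gene_id")
    txs = truth.transcripts.set_index("transcript_id")
    tid = txs.index[0]
    gene = txs.loc[tid, "gene_id"]
    for stage in STAGES:
        expected = (genes.loc[gene, f"fpkm_{stage}"] * genes.loc[gene, "weighted_length"]
                    * cfg.library_size / 1e9 * txs.loc[tid, "isoform_fraction"])
        assert counts.loc[tid, stage] == pytest.approx(expected)


def test_design_levels_respect_pattern_bins(small_dataset):
    """Planted stage means sit inside the intended ordinal bins by construction."""
    _, _, truth, _ = small_dataset
    genes = truth.genes[~truth.genes["is_background"]]
    for _, g in genes.iterrows():
        on = set(g["on_stages"].split("+"))
        for stage in STAGES:
            level = g[f"fpkm_{stage}"]
            if g["pattern"] == "constitutive_high":
                assert level >= 51
            elif g["pattern"] == "constitutive_low":
                assert level <= 10.49
            elif g["pattern"] == "specific_1":
                assert (level >= 11) if stage in on else (level <= 10.49)
            elif g["pattern"].startswith("specific_"):
                assert (level >= 51) if stage in on else (level <= 3.49)


def test_reference_perfect_rbh_recovery():
    from devtome import orthology

    cfg = SyntheticConfig(n_genes=50, coding_fraction=1.0, ortholog_fraction=1.0,
                          tie_fraction=0.0, seed=13)
    _, truth = synthetic.generate_transcriptome(cfg)
    ref = synthetic.generate_reference_species(truth, cfg)
    gene_map = truth.transcripts.set_index("transcript_id")["gene_id"]
    subject_map = ref.proteins.set_index("protein_id")["ref_gene_id"]
    pairs = orthology.rbh_orthologs(ref.hits_fwd, ref.hits_rev, gene_map, subject_map)
    orth = pairs[pairs["status"] == "ortholog"]
    expected = truth.genes.dropna(subset=["ortholog_id"])
    assert len(orth) == len(expected)
    assert dict(zip(orth["gene_a"], orth["gene_b"])) == dict(
        zip(expected["gene_id"], expected["ortholog_id"]))


def test_tie_count_within_binomial_bounds():
    cfg = SyntheticConfig(n_genes=500, coding_fraction=1.0, ortholog_fraction=1.0,
                          tie_fraction=0.1, isoform_rate=1.0, seed=17)
    _, truth = synthetic.generate_transcriptome(cfg)
    synthetic.generate_reference_species(truth, cfg)
    n_tie = int(truth.genes["rbh_tie"].astype(bool).sum())
    lo, hi = binom_bounds(500 + cfg.n_background, 0.1, 0.99)
    assert lo <= n_tie <= hi


def test_log_expression_correlation_converges_to_target():
    cfg = SyntheticConfig(n_genes=2000, coding_fraction=1.0, ortholog_fraction=1.0,
                          tie_fraction=0.0, divergence_fraction=0.0,
                          isoform_rate=1.0, rho_target=0.9, seed=19)
    _, truth = synthetic.generate_transcriptome(cfg)
    ref = synthetic.generate_reference_species(truth, cfg)
    expr = ref.expression.set_index("ref_gene_id")
    genes = truth.genes.dropna(subset=["ortholog_id"])
    for stage, ref_stage in list(synthetic.REF_STAGE_MAP.items())[:2]:
        x = np.log10(genes[f"fpkm_{stage}"].to_numpy(float))
        y = np.log10(expr.loc[genes["ortholog_id"], ref_stage].to_numpy(float))
        rho = np.corrcoef(x, y)[0, 1]
        assert abs(rho - 0.9) < 0.05
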