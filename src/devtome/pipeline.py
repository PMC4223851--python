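"""End-to-end orchestration of the synthetic-data pipeline.

Stages run in a fixed order (synth -> preprocess -> filter -> orfs ->
express -> cluster -> ortho -> mine); each stage reads only the files the
previous stages wrote, so a stage toggled off reuses a prior run's cached
outputs. A manifest records parameter values, per-stage row counts and
output checksums; reruns with the same config and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import clustering, expression, filtering, mining, orf, orthology, preprocess, report
from . import synthetic
from .io import write_fasta, write_tsv
from .synthetic import REF_STAGE_MAP, STAGES, SyntheticConfig

STAGE_ORDER = ("synth", "preprocess", "filter", "orfs", "express", "cluster",
               "ortho", "mine")


@dataclass
class PipelineConfig:
    seed: int = 0
    synthetic: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)      # toggle per stage, default on
    min_isoform_percent: float = 1.0
    min_tpm: float = 0.5
    q_min: int = 20
    min_fraction: float = 0.80
    kmer_size: int = 25
    max_coverage: int = 30
    min_orf_aa: int = 100
    markov_order: int = 5
    n_train: int = 500
    trim_m: float = 0.30
    trim_a: float = 0.05
    cut_fraction: float = 0.45
    band: str = "prediction"
    alpha: float = 0.05
    evalue_max: float = 1e-10

    def enabled(self, stage: str) -> bool:
        return bool(self.stages.get(stage, True))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        return cls(**data)

    def to_yaml(self, path):
        with open(path, "w") as handle:
            yaml.safe_dump(self.to_dict(), handle, sort_keys=True)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage {stage!r}: missing upstream output {path.name} "
            "(enable the producing stage or point at a prior run directory)")
    return path


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute all enabled stages; returns the manifest (also written as JSON)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": {}}

    synth_cfg = synthetic.config_from_dict(
        {**config.synthetic, "seed": config.synthetic.get("seed", config.seed)})

    # --- synth ------------------------------------------------------------
    if config.enabled("synth"):
        transcripts, truth = synthetic.generate_transcriptome(synth_cfg)
        counts = synthetic.generate_expression(truth, synth_cfg)
        reads, _ = synthetic.generate_reads(transcripts, truth, synth_cfg)
        ref = synthetic.generate_reference_species(truth, synth_cfg)
        annotations = synthetic.generate_annotations(truth, synth_cfg)
        sexdet_hits, _, peptide_map = synthetic.generate_sexdet_hits(truth, synth_cfg)

        write_fasta(transcripts, out / "transcripts.fasta")
        preprocess.write_pairs(reads, out / "reads_R1.fastq", out / "reads_R2.fastq")
        counts_tsv = counts.copy()
        counts_tsv.insert(0, "gene_id", truth.transcripts.set_index("transcript_id")
                          ["gene_id"].reindex(counts.index))
        counts_tsv.insert(1, "length", truth.transcripts.set_index("transcript_id")
                          ["length"].reindex(counts.index))
        write_tsv(counts_tsv, out / "counts.tsv")
        write_tsv(truth.genes, out / "truth_genes.tsv", index=False)
        write_tsv(truth.transcripts, out / "truth_transcripts.tsv", index=False)
        write_tsv(ref.expression, out / "ref_expression.tsv", index=False)
        write_tsv(ref.proteins, out / "ref_proteins.tsv", index=False)
        write_tsv(ref.hits_fwd, out / "hits_fwd.tsv", index=False)
        write_tsv(ref.hits_rev, out / "hits_rev.tsv", index=False)
        write_tsv(annotations, out / "annotations.tsv", index=False)
        write_tsv(sexdet_hits, out / "sexdet_hits.tsv", index=False)
        write_tsv(peptide_map, out / "sexdet_panel_peptides.tsv", index=False)
        manifest["stages"]["synth"] = {
            "n_genes": int(len(truth.genes)), "n_transcripts": int(len(truth.transcripts)),
            "n_read_pairs": len(reads)}

    # --- preprocess --------------------------------------------------------
    if config.enabled("preprocess"):
        pairs = preprocess.read_pairs(_require(out / "reads_R1.fastq", "preprocess"),
                                      _require(out / "reads_R2.fastq", "preprocess"))
        after_qc, qc_stats = preprocess.quality_filter(pairs, config.q_min,
                                                       config.min_fraction)
        after_norm, _, n_short = preprocess.kmer_normalize(after_qc, config.kmer_size,
                                                           config.max_coverage)
        stats = preprocess.PreprocessStats(len(pairs), len(after_qc), len(after_norm))
        preprocess.write_pairs(after_norm, out / "reads_filtered_R1.fastq",
                               out / "reads_filtered_R2.fastq")
        write_tsv(pd.DataFrame([{
            "stage": "pooled", "n_before": stats.n_before,
            "n_after_qc": stats.n_after_qc, "n_after_norm": stats.n_after_norm,
            "percent_retained_qc": stats.percent_retained_qc,
            "percent_after_norm": stats.percent_after_norm,
            "n_too_short": n_short,
        }]), out / "preprocess_stats.tsv", index=False)
        manifest["stages"]["preprocess"] = {
            "n_before": stats.n_before, "n_after_qc": stats.n_after_qc,
            "n_after_norm": stats.n_after_norm}

    # --- filter ------------------------------------------------------------
    if config.enabled("filter"):
        counts, lengths, gene_map = _read_counts(_require(out / "counts.tsv", "filter"))
        raw_stats = filtering.assembly_stats(lengths)
        verdicts = filtering.apply_filters(counts, lengths, gene_map,
                                           config.min_isoform_percent, config.min_tpm)
        retained = verdicts.index[verdicts["retained"]]
        write_tsv(verdicts, out / "filter_report.tsv")
        write_tsv(counts.loc[retained].assign(
            gene_id=gene_map.reindex(retained), length=lengths.reindex(retained)),
            out / "counts_filtered.tsv")
        kept_stats = filtering.assembly_stats(lengths.reindex(retained))
        write_tsv(pd.DataFrame([
            {"set": "raw", **dataclasses.asdict(raw_stats)},
            {"set": "abundance_filtered", **dataclasses.asdict(kept_stats)},
        ]), out / "assembly_stats.tsv", index=False)
        manifest["stages"]["filter"] = {
            "n_in": int(len(counts)), "n_retained": int(len(retained))}

    # --- orfs --------------------------------------------------------------
    if config.enabled("orfs"):
        from .io import read_fasta

        counts, lengths, gene_map = _read_counts(_require(out / "counts_filtered.tsv", "orfs"))
        sequences = read_fasta(_require(out / "transcripts.fasta", "orfs"))
        sequences = {tid: sequences[tid] for tid in counts.index if tid in sequences}
        retained, model, _ = orf.predict_orfs(sequences, config.min_orf_aa,
                                              config.markov_order, config.n_train,
                                              seed=config.seed)
        t_class, g_class = orf.partition_transcripts(sequences, retained,
                                                     gene_map.to_dict())
        calls = orf.calls_table(retained, gene_map.to_dict(),
                                {t: len(s) for t, s in sequences.items()})
        write_tsv(calls, out / "orfs.tsv", index=False)
        write_fasta({t: orf.orf_nucleotides(sequences[t], c, include_stop=True)
                     for t, c in sorted(retained.items())}, out / "cds.fasta")
        write_fasta({t: orf.translate_call(sequences[t], c)
                     for t, c in sorted(retained.items())}, out / "peptides.fasta")
        write_tsv(report.orf_partition_table(g_class, t_class), out / "orf_partition.tsv")
        coding_tx = [t for t, cls in t_class.items() if cls != "noncoding"]
        write_tsv(counts.loc[coding_tx].assign(
            gene_id=gene_map.reindex(coding_tx), length=lengths.reindex(coding_tx)),
            out / "counts_coding.tsv")
        manifest["stages"]["orfs"] = {
            "n_in": int(len(sequences)), "n_retained_calls": int(len(retained)),
            "n_coding_transcripts": len(coding_tx),
            "n_genes": {cls: sum(1 for v in g_class.values() if v == cls)
                        for cls in ("complete", "partial", "noncoding")}}

    # --- express -----------------------------------------------------------
    if config.enabled("express"):
        counts, lengths, gene_map = _read_counts(_require(out / "counts_coding.tsv", "express"))
        factors, values, categories, patterns = expression.expression_profile(
            counts, lengths, gene_map, config.trim_m, config.trim_a)
        write_tsv(factors.rename("tmm_factor").to_frame(), out / "tmm_factors.tsv")
        write_tsv(values, out / "fpkm.tsv")
        named = categories.copy()
        write_tsv(named, out / "categories.tsv")
        write_tsv(patterns, out / "patterns.tsv")
        summary = report.pattern_table(expression.pattern_summary(patterns),
                                       total_genes=len(patterns))
        write_tsv(summary, out / "pattern_summary.tsv")
        manifest["stages"]["express"] = {
            "n_genes": int(len(values)),
            "patterns": {k: int(v) for k, v in
                         expression.pattern_summary(patterns)["count"].items()}}

    # --- cluster -----------------------------------------------------------
    if config.enabled("cluster"):
        values = pd.read_csv(_require(out / "fpkm.tsv", "cluster"), sep="\t", index_col=0)
        tree, labels, profiles = clustering.cluster_expression(values, config.cut_fraction)
        write_tsv(labels.to_frame(), out / "clusters.tsv")
        manifest["stages"]["cluster"] = {
            "n_genes": int(len(labels)), "n_subclusters": int(labels.nunique())}

    # --- ortho -------------------------------------------------------------
    if config.enabled("ortho"):
        values = pd.read_csv(_require(out / "fpkm.tsv", "ortho"), sep="\t", index_col=0)
        ref_expr = pd.read_csv(_require(out / "ref_expression.tsv", "ortho"),
                               sep="\t", index_col=0)
        proteins = pd.read_csv(_require(out / "ref_proteins.tsv", "ortho"), sep="\t")
        counts, _, gene_map = _read_counts(out / "counts.tsv")
        subject_map = proteins.set_index("protein_id")["ref_gene_id"]
        pairs = orthology.rbh_orthologs(
            pd.read_csv(out / "hits_fwd.tsv", sep="\t"),
            pd.read_csv(out / "hits_rev.tsv", sep="\t"),
            query_gene_map=gene_map, subject_gene_map=subject_map)
        write_tsv(pairs[pairs["status"] == "ortholog"], out / "orthologs.tsv", index=False)
        write_tsv(pairs[pairs["status"] == "nonunique_excluded"],
                  out / "orthologs_nonunique.tsv", index=False)
        regressions = []
        for stage, ref_stage in REF_STAGE_MAP.items():
            try:
                regressions.append(orthology.fit_stage_regression(
                    pairs, values, ref_expr, stage, ref_stage,
                    alpha=config.alpha, band=config.band))
            except (KeyError, ValueError):
                continue
        if regressions:
            summary = orthology.summarize_divergence(regressions)
            write_tsv(summary, out / "divergence.tsv")
            write_tsv(pd.DataFrame([{
                "stage": r.stage, "slope": r.slope, "intercept": r.intercept,
                "rho": r.rho, "rho_pvalue": r.rho_pvalue, "n": r.n,
                "outside_fraction": r.outside_fraction} for r in regressions]),
                out / "stage_regressions.tsv", index=False)
            manifest["stages"]["ortho"] = {
                "n_orthologs": int((pairs["status"] == "ortholog").sum()),
                "n_nonunique_excluded": int((pairs["status"] == "nonunique_excluded").sum()),
                "divergence": orthology.divergence_totals(summary)}

    # --- mine --------------------------------------------------------------
    if config.enabled("mine"):
        annotations = pd.read_csv(_require(out / "annotations.tsv", "mine"), sep="\t")
        tf_calls, tf_table = mining.classify_tf(annotations)
        detox = mining.classify_detox(annotations)
        sexdet = mining.match_sex_determination(
            pd.read_csv(_require(out / "sexdet_hits.tsv", "mine"), sep="\t"),
            pd.read_csv(_require(out / "sexdet_panel_peptides.tsv", "mine"), sep="\t"),
            config.evalue_max)
        write_tsv(tf_table, out / "tf_table.tsv")
        write_tsv(tf_calls, out / "tf_calls.tsv", index=False)
        write_tsv(mining.detox_summary(detox), out / "detox_table.tsv", index=False)
        write_tsv(sexdet, out / "sexdet_table.tsv", index=False)
        manifest["stages"]["mine"] = {
            "n_tf_transcripts": int(len(tf_calls)),
            "n_p450_genes": int(len(detox.p450)), "n_gst_genes": int(len(detox.gst)),
            "n_ugt_genes": int(len(detox.ugt))}

    checksums = {p.name: _sha256(p) for p in sorted(out.iterdir())
                 if p.is_file() and p.name != "manifest.json"}
    manifest["checksums"] = checksums
    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(checksums, sort_keys=True).encode()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _read_counts(path):
    df = pd.read_csv(path, sep="\t", index_col=0)
    gene_map = df.pop("gene_id")
    lengths = df.pop("length")
    return df[[c for c in df.columns if c in STAGES]], lengths, gene_map


def summary_report(outdir) -> dict:
    """Collect the report tables from a completed run directory."""
    out = Path(outdir)
    result = {}
    summary_path = out / "pattern_summary.tsv"
    if summary_path.exists():
        result["patterns"] = pd.read_csv(summary_path, sep="\t", index_col=0)
    for key, name in (("tf", "tf_table.tsv"), ("detox", "detox_table.tsv"),
                      ("sexdet", "sexdet_table.tsv")):
        path = out / name
        if path.exists():
            result[key] = pd.read_csv(path, sep="\t")
    manifest_path = out / "manifest.json"
    if manifest_path.exists():
        result["manifest"] = json.loads(manifest_path.read_text())
    return result
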