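"""Synthetic data generator for the whole pipeline, with ground truth.

The generator emulates the inputs of a six-stage developmental RNA-seq study
of a holometabolous insect (egg, larvae, pupae, adult male, adult female,
mated adult female):

* multi-isoform gene components with planted coding regions (codon usage drawn
  from a biased table shipped as package data) flanked by uniform-composition
  UTRs, plus non-coding transcripts guaranteed to carry no ORF of predictable
  length;
* paired 101-bp reads with a configurable fraction of quality-failing mates;
* six-library expected-count matrices whose stage means place each planted
  expression pattern (constitutive high/low, k-stage specific) inside the
  intended ordinal FPKM bin;
* a paired reference species with a known 1:1 ortholog map, log-expression
  correlated at a target Pearson rho, planted expression-divergent genes, and
  reciprocal alignment hit tables consistent with the map (including planted
  score ties to exercise the uniqueness rule);
* annotation tables with planted transcription-factor, detoxification and
  sex-determination labels for the rule-based mining stage.

Counts land on an absolute FPKM scale because a small set of "background"
housekeeping genes absorbs the remainder of each library (real libraries are
likewise dominated by a few extremely highly expressed transcripts); without
them an n-gene toy matrix could not place genes in absolute FPKM bins.

Every generator is deterministic for a fixed config seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import orf
from ._util import load_data_table, revcomp

STAGES = ("egg", "larvae", "pupae", "male", "female", "mated_female")

#: reference-species stages matched to STAGES for cross-species comparison;
#: the mated-female library has no counterpart and is excluded.
REF_STAGE_MAP = {
    "egg": "embryo",
    "larvae": "larvae",
    "pupae": "pupae",
    "male": "adult_male",
    "female": "adult_female",
}
REF_STAGES = tuple(REF_STAGE_MAP.values())

CONSTITUTIVE_HIGH = "constitutive_high"
CONSTITUTIVE_LOW = "constitutive_low"

DEFAULT_PATTERN_MIX = {
    CONSTITUTIVE_HIGH: 0.125,
    CONSTITUTIVE_LOW: 0.765,
    "specific_1": 0.029,
    "specific_2": 0.037,
    "specific_3": 0.017,
    "specific_4": 0.014,
    "specific_5": 0.013,
}

# Stage-mean FPKM placed mid-bin for each planted pattern: (on level, off
# level, jitter bands). Bands stay well inside the target ordinal bins.
_PATTERN_LEVELS = {
    CONSTITUTIVE_HIGH: dict(on=75.0, off=75.0, on_band=(60.0, 90.0), off_band=(60.0, 90.0)),
    CONSTITUTIVE_LOW: dict(on=2.0, off=2.0, on_band=(1.2, 3.2), off_band=(1.2, 3.2)),
    "specific_1": dict(on=18.0, off=2.0, on_band=(14.0, 22.0), off_band=(1.2, 3.2)),
    "specific_k": dict(on=75.0, off=1.5, on_band=(60.0, 90.0), off_band=(0.8, 2.4)),
}

HIT_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
               "qstart", "qend", "sstart", "send", "evalue", "bitscore"]

GO_TF_TERMS = ("GO:0003700", "GO:0006355", "GO:0003705")

_TF_CLASS_DOMAINS = [
    ("Zinc finger", "zf-C2H2", 0.261),
    ("Homeobox", "Homeodomain", 0.051),
    ("Helix-loop-helix", "HLH", 0.044),
    ("BTB/POZ", "BTB", 0.035),
    ("Bzip", "bZIP_1", 0.031),
    ("Myb", "Myb_DNA-binding", 0.019),
    ("WD40", "WD40", 0.015),
    ("Basal TFs", "TBP", 0.014),
    ("Fork-head", "Forkhead", 0.014),
    ("Bromodomain", "Bromodomain", 0.012),
    ("Helicase", "Helicase_C", 0.010),
    ("other", "DUF3456", 0.494),
]


class ConfigError(ValueError):
    """Raised when a synthetic configuration is internally inconsistent."""


@dataclass
class SyntheticConfig:
    n_genes: int = 200
    isoform_rate: float = 1.9
    coding_fraction: float = 0.5
    read_depth: float = 20.0
    error_rate: float = 0.001
    read_length: int = 101
    fail_fraction: float = 0.05
    stage_pattern_mix: dict = field(default_factory=lambda: dict(DEFAULT_PATTERN_MIX))
    ortholog_fraction: float = 0.55
    tie_fraction: float = 0.1
    divergence_fraction: float = 0.02
    divergence_offset_sd: float = 3.0
    rho_target: float = 0.9
    ref_extra_fraction: float = 0.2
    dispersion: float = 0.1
    library_size: float = 15_000_000.0
    n_background: int = 10
    background_length: int = 2000
    fpkm_jitter: bool = True
    minus_strand_fraction: float = 0.3
    orf_aa_range: tuple = (150, 500)
    utr_len_range: tuple = (50, 300)
    noncoding_len_range: tuple = (400, 2500)
    low_share_isoform_rate: float = 0.1
    min_orf_aa: int = 100
    tf_fraction: float = 0.06
    detox_fraction: float = 0.03
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self):
        for name in ("coding_fraction", "ortholog_fraction", "tie_fraction",
                     "divergence_fraction", "fail_fraction", "error_rate",
                     "minus_strand_fraction", "low_share_isoform_rate",
                     "tf_fraction", "detox_fraction", "ref_extra_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} is not a proportion in [0, 1]")
        if not -1.0 <= self.rho_target <= 1.0:
            raise ConfigError("rho_target must be a correlation in [-1, 1]")
        mix = self.stage_pattern_mix
        if any(p < 0 for p in mix.values()):
            raise ConfigError("pattern mix proportions must be nonnegative")
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ConfigError(f"pattern mix sums to {sum(mix.values())}, not 1")
        unknown = set(mix) - set(DEFAULT_PATTERN_MIX)
        if unknown:
            raise ConfigError(f"unknown pattern labels in mix: {sorted(unknown)}")
        if self.n_genes < 1:
            raise ConfigError("n_genes must be positive")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be nonnegative")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic stream per generator."""
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class Truth:
    """Ground truth for a synthetic dataset.

    ``genes`` has one row per gene component (pattern, design stage FPKM,
    ortholog/divergence/tie flags, planted annotation class); ``transcripts``
    has one row per isoform (length, isoform expression fraction, planted ORF
    interval on the reported strand).
    """

    genes: pd.DataFrame
    transcripts: pd.DataFrame

    @property
    def design_fpkm(self) -> pd.DataFrame:
        return self.genes.set_index("gene_id")[[f"fpkm_{s}" for s in STAGES]].rename(
            columns={f"fpkm_{s}": s for s in STAGES})


def _load_codon_sampler():
    table = load_data_table("codon_usage.tsv")
    sense = table[table["per_thousand"] > 0]
    codons = sense["codon"].to_numpy()
    probs = sense["per_thousand"].to_numpy(float)
    return codons, probs / probs.sum()


def _random_seq(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))


def _pattern_stage_levels(rng, pattern, config):
    """Design FPKM per stage for a planted pattern; returns (levels, on-set)."""
    if pattern in (CONSTITUTIVE_HIGH, CONSTITUTIVE_LOW):
        spec_ = _PATTERN_LEVELS[pattern]
        on_stages = set(STAGES)
    elif pattern == "specific_1":
        spec_ = _PATTERN_LEVELS["specific_1"]
        on_stages = {STAGES[rng.integers(len(STAGES))]}
    else:
        k = int(pattern.split("_")[1])
        spec_ = _PATTERN_LEVELS["specific_k"]
        on_stages = set(rng.choice(STAGES, size=k, replace=False))
    levels = {}
    for stage in STAGES:
        key = "on" if stage in on_stages else "off"
        if config.fpkm_jitter:
            lo, hi = spec_[f"{key}_band"]
            levels[stage] = float(rng.uniform(lo, hi))
        else:
            levels[stage] = float(spec_[key])
    return levels, on_stages


def _noncoding_sequence(rng, length, min_orf_aa):
    """Uniform-composition sequence with no ORF of >= min_orf_aa codons."""
    for _ in range(200):
        seq = _random_seq(rng, length)
        if not orf.enumerate_orfs(seq, min_aa=min_orf_aa):
            return seq
    raise RuntimeError("could not draw an ORF-free sequence; length too large?")


# Reverse-complement-symmetric guard with stop codons in all six reading
# frames. Placed at the 3' end of 5' UTRs (so planted ORFs are complete, with
# an in-frame stop immediately upstream of the start codon) and of novel
# isoform extensions (so extensions cannot create or extend long open frames).
_STOP_GUARD = "TTAATTAATTAA"


def generate_transcriptome(config: SyntheticConfig):
    """Generate gene components with isoforms and planted coding regions.

    Returns ``(transcripts, truth)`` where ``transcripts`` is an ordered dict
    mapping transcript_id to sequence.
    """
    config.validate()
    rng = config.rng(1)
    codons, codon_p = _load_codon_sampler()
    stop_choices = np.array(["TAA", "TAG", "TGA"])

    patterns = list(config.stage_pattern_mix)
    pattern_p = np.array([config.stage_pattern_mix[p] for p in patterns])

    gene_rows, tx_rows = [], []
    transcripts: dict[str, str] = {}

    n_total = config.n_genes + config.n_background
    for g in range(n_total):
        gene_id = f"comp{g}_c0"
        is_background = g >= config.n_genes
        if is_background:
            coding = True
            pattern = CONSTITUTIVE_HIGH
            levels = {s: np.nan for s in STAGES}  # filled below
            on_stages = set(STAGES)
        else:
            coding = bool(rng.random() < config.coding_fraction)
            pattern = patterns[rng.choice(len(patterns), p=pattern_p)]
            levels, on_stages = _pattern_stage_levels(rng, pattern, config)

        strand = "-" if rng.random() < config.minus_strand_fraction else "+"
        if coding:
            if is_background:
                n_aa = max(config.orf_aa_range[0],
                           (config.background_length - 2 * 60 - 3) // 3)
                utr5 = utr3 = 60
            else:
                n_aa = int(rng.integers(*config.orf_aa_range))
                utr5 = int(rng.integers(*config.utr_len_range))
                utr3 = int(rng.integers(*config.utr_len_range))
            body = "ATG" + "".join(rng.choice(codons, size=n_aa - 1, p=codon_p)) \
                + str(rng.choice(stop_choices))
            utr5 = max(utr5, len(_STOP_GUARD))
            utr5_seq = _random_seq(rng, utr5 - len(_STOP_GUARD)) + _STOP_GUARD
            construct = utr5_seq + body + _random_seq(rng, utr3)
            orf_start, orf_end = utr5 + 1, utr5 + len(body)
        else:
            length = int(rng.integers(*config.noncoding_len_range))
            construct = _noncoding_sequence(rng, length, config.min_orf_aa)
            utr5 = utr3 = 0
            orf_start = orf_end = 0

        n_iso = 1 if is_background else 1 + int(rng.poisson(max(config.isoform_rate - 1, 0)))
        shares = rng.dirichlet(np.full(n_iso, 2.0))
        if n_iso >= 2 and rng.random() < config.low_share_isoform_rate:
            # plant one isoform below a 1%-of-gene share
            j = int(rng.integers(n_iso))
            shares = shares * (1 - 0.004) / (shares.sum() - shares[j] + 1e-12)
            shares[j] = 0.004
            shares = shares / shares.sum()

        isoform_ids = []
        for i in range(n_iso):
            tid = f"{gene_id}_seq{i + 1}"
            isoform_ids.append(tid)
            t5 = t3 = ext = 0
            if i > 0:
                if coding:
                    t5 = int(rng.integers(0, max(utr5 - 10, 1)))
                    t3 = int(rng.integers(0, max(utr3 - 10, 1)))
                else:
                    t5 = int(rng.integers(0, len(construct) // 5))
                    t3 = int(rng.integers(0, len(construct) // 5))
                if rng.random() < 0.3:
                    core = len(construct) - t5 - t3
                    ext = int(rng.integers(20, max(min(150, core // 2), 21)))
            iso_construct = construct[t5:len(construct) - t3 if t3 else len(construct)]
            if ext:
                for _ in range(50):
                    extension = _random_seq(rng, ext) + _STOP_GUARD
                    candidate = extension + iso_construct
                    if coding or not orf.enumerate_orfs(candidate, min_aa=config.min_orf_aa):
                        iso_construct = candidate
                        break
                else:
                    ext = 0
            offset = (ext + len(_STOP_GUARD) if ext else 0) - t5
            seq = revcomp(iso_construct) if strand == "-" else iso_construct
            transcripts[tid] = seq
            tx_rows.append({
                "transcript_id": tid, "gene_id": gene_id, "length": len(seq),
                "isoform_fraction": float(shares[i]),
                "coding": coding, "strand": strand,
                "orf_start": orf_start + offset if coding else 0,
                "orf_end": orf_end + offset if coding else 0,
            })

        row = {
            "gene_id": gene_id, "coding": coding, "pattern": pattern,
            "on_stages": "+".join(s for s in STAGES if s in on_stages),
            "n_isoforms": n_iso, "strand": strand,
            "is_background": is_background,
        }
        row.update({f"fpkm_{s}": levels[s] for s in STAGES})
        gene_rows.append(row)

    genes = pd.DataFrame(gene_rows)
    txs = pd.DataFrame(tx_rows)

    # expression-weighted gene length, then fill background levels so each
    # library's sum of design-FPKM x length is exactly 1e9 (the closed-system
    # identity that puts FPKM on an absolute scale)
    wlen = (txs["length"] * txs["isoform_fraction"]).groupby(txs["gene_id"]).sum()
    genes["weighted_length"] = genes["gene_id"].map(wlen)
    bg = genes["is_background"]
    if bg.any():
        bg_wlen = genes.loc[bg, "weighted_length"].sum()
        for s in STAGES:
            signal_mass = (genes.loc[~bg, f"fpkm_{s}"] * genes.loc[~bg, "weighted_length"]).sum()
            fill = max((1e9 - signal_mass) / bg_wlen, 0.0)
            genes.loc[bg, f"fpkm_{s}"] = fill

    # pooled relative expression drives read simulation
    design = genes.set_index("gene_id")[[f"fpkm_{s}" for s in STAGES]].sum(axis=1)
    txs["rel_expression"] = txs["gene_id"].map(design) * txs["isoform_fraction"]

    return transcripts, Truth(genes=genes, transcripts=txs)


# ---------------------------------------------------------------------------
# reads

def generate_reads(transcripts: dict[str, str], truth: Truth,
                   config: SyntheticConfig):
    """Paired reads drawn proportional to planted expression.

    Returns (pairs, n_skipped): ``pairs`` are ReadPair records with Phred+33
    quality strings. Transcripts shorter than the read length are skipped.
    """
    from .preprocess import ReadPair

    rng = config.rng(2)
    L = config.read_length
    rel = truth.transcripts.set_index("transcript_id")["rel_expression"]
    mean_rel = float(rel.mean()) if len(rel) else 1.0
    records = []
    n_skipped = 0
    for tid, seq in transcripts.items():
        if len(seq) < L:
            n_skipped += 1
            continue
        weight = rel.get(tid, mean_rel) / max(mean_rel, 1e-12)
        n_pairs = int(rng.poisson(config.read_depth * weight))
        for j in range(n_pairs):
            insert = int(np.clip(rng.normal(300, 50), L, len(seq)))
            start = int(rng.integers(0, len(seq) - insert + 1))
            frag = seq[start:start + insert]
            r1 = _with_errors(rng, frag[:L], config.error_rate)
            r2 = _with_errors(rng, revcomp(frag[-L:]), config.error_rate)
            q1 = _qualities(rng, L, rng.random() < config.fail_fraction)
            q2 = _qualities(rng, L, rng.random() < config.fail_fraction)
            records.append(ReadPair(f"{tid}:{j}", r1, q1, r2, q2))
    return records, n_skipped


def _with_errors(rng, seq, rate):
    if rate <= 0:
        return seq
    arr = list(seq)
    for i in np.flatnonzero(rng.random(len(arr)) < rate):
        arr[i] = "ACGT"[rng.integers(4)]
    return "".join(arr)


def _qualities(rng, length, fail: bool):
    q = rng.integers(28, 41, size=length)
    if fail:
        # force >20% of bases below Q20 so the mate fails the quality rule
        n_bad = int(np.ceil(0.25 * length))
        pos = rng.choice(length, size=n_bad, replace=False)
        q[pos] = rng.integers(2, 20, size=n_bad)
    return "".join(chr(int(v) + 33) for v in q)


# ---------------------------------------------------------------------------
# expression

def generate_expression(truth: Truth, config: SyntheticConfig) -> pd.DataFrame:
    """Six-library expected-count matrix (transcripts x stages).

    Counts are negative-binomial around stage means derived from the planted
    design FPKM; with ``dispersion == 0`` counts equal the means exactly
    (expected counts may be fractional, as with EM-based estimators). Isoform
    counts partition gene counts by the per-gene Dirichlet shares.
    """
    rng = config.rng(3)
    txs = truth.transcripts
    genes = truth.genes.set_index("gene_id")
    counts = pd.DataFrame(0.0, index=txs["transcript_id"], columns=list(STAGES))
    wlen = genes["weighted_length"]
    for s in STAGES:
        gene_counts = genes[f"fpkm_{s}"] * wlen * config.library_size / 1e9
        mu = (txs["gene_id"].map(gene_counts) * txs["isoform_fraction"]).to_numpy()
        if config.dispersion > 0:
            n = 1.0 / config.dispersion
            p = n / (n + np.maximum(mu, 1e-12))
            sampled = rng.negative_binomial(n, p).astype(float)
            sampled[mu <= 0] = 0.0
            counts[s] = sampled
        else:
            counts[s] = mu
    return counts


# ---------------------------------------------------------------------------
# reference species

@dataclass
class RefSpecies:
    proteins: pd.DataFrame       # ref_gene_id, protein_id
    expression: pd.DataFrame     # ref genes x REF_STAGES (FPKM)
    hits_fwd: pd.DataFrame       # query transcript -> ref protein
    hits_rev: pd.DataFrame       # ref protein -> query transcript


def _hit_row(q, s, bitscore, evalue, rng):
    alen = int(rng.integers(80, 400))
    return {
        "qseqid": q, "sseqid": s,
        "pident": round(float(rng.uniform(35, 99)), 2), "length": alen,
        "mismatch": int(rng.integers(0, alen // 3 + 1)), "gapopen": int(rng.integers(0, 5)),
        "qstart": 1, "qend": alen, "sstart": 1, "send": alen,
        "evalue": evalue, "bitscore": round(float(bitscore), 1),
    }


def generate_reference_species(truth: Truth, config: SyntheticConfig) -> RefSpecies:
    """Reference-species proteins, stage expression and reciprocal hit tables.

    True ortholog pairs appear as mutual unique top-bitscore hits; a
    ``tie_fraction`` of pairs get an exactly duplicated top bitscore toward a
    decoy subject in the forward direction, so the uniqueness rule excludes
    them. Off-target hits are directed only at genes whose own best hit is
    elsewhere, so no accidental reciprocal pair can arise. Ortholog
    log10-expression tracks the planted design at ``rho_target``; divergent
    genes are displaced by ``divergence_offset_sd`` residual standard
    deviations (constant sign across stages).
    """
    if config.ortholog_fraction <= 0:
        raise ConfigError("ortholog_fraction must be positive to build a reference species")
    rng = config.rng(4)
    genes = truth.genes.copy()
    coding = genes[genes["coding"]].reset_index(drop=True)

    is_orth = rng.random(len(coding)) < config.ortholog_fraction
    ref_ids = [f"FBgn{i:07d}" for i in range(1, int(is_orth.sum()) + 1)]
    coding = coding.assign(ortholog_id=None, divergent=False, rbh_tie=False)
    coding.loc[is_orth, "ortholog_id"] = ref_ids
    orth = coding[is_orth]
    coding.loc[is_orth, "divergent"] = rng.random(len(orth)) < config.divergence_fraction
    coding.loc[is_orth, "rbh_tie"] = rng.random(len(orth)) < config.tie_fraction

    # merge flags back into the truth gene table
    genes["ortholog_id"] = genes["gene_id"].map(coding.set_index("gene_id")["ortholog_id"])
    for col in ("divergent", "rbh_tie"):
        mapped = genes["gene_id"].map(coding.set_index("gene_id")[col])
        genes[col] = mapped.eq(True)
    truth.genes = genes

    orth = coding[is_orth].reset_index(drop=True)
    n_extra = int(round(config.ref_extra_fraction * len(orth)))
    extra_ids = [f"FBgn{i:07d}" for i in range(len(orth) + 1, len(orth) + n_extra + 1)]

    proteins = pd.DataFrame({
        "ref_gene_id": list(orth["ortholog_id"]) + extra_ids,
    })
    proteins["protein_id"] = proteins["ref_gene_id"] + "-PA"

    # --- reference expression -------------------------------------------
    expr = {}
    nondiv = ~orth["divergent"].to_numpy(bool)
    for stage, ref_stage in REF_STAGE_MAP.items():
        x = np.log10(orth[f"fpkm_{stage}"].to_numpy(float))
        sd_x = float(np.std(x[nondiv])) if nondiv.sum() > 1 else 1.0
        rho = min(max(abs(config.rho_target), 1e-6), 0.999999)
        sigma = sd_x * np.sqrt(1.0 / rho**2 - 1.0)
        eps = rng.normal(0.0, sigma, size=len(x))
        y = x + eps
        expr[ref_stage] = y
    signs = np.where(rng.random(len(orth)) < 0.5, -1.0, 1.0)
    for stage, ref_stage in REF_STAGE_MAP.items():
        x = np.log10(orth[f"fpkm_{stage}"].to_numpy(float))
        sd_x = float(np.std(x[nondiv])) if nondiv.sum() > 1 else 1.0
        sigma = sd_x * np.sqrt(1.0 / min(max(abs(config.rho_target), 1e-6), 0.999999)**2 - 1.0)
        y = expr[ref_stage]
        y = y + np.where(orth["divergent"].to_numpy(bool),
                         signs * config.divergence_offset_sd * sigma, 0.0)
        expr[ref_stage] = 10.0 ** y
    expression = pd.DataFrame(expr, index=orth["ortholog_id"])
    if n_extra:
        extra_expr = 10.0 ** rng.normal(0.7, 0.6, size=(n_extra, len(REF_STAGES)))
        expression = pd.concat([
            expression,
            pd.DataFrame(extra_expr, index=extra_ids, columns=list(REF_STAGES)),
        ])
    expression.index.name = "ref_gene_id"

    # --- hit tables ------------------------------------------------------
    txs = truth.transcripts
    iso_of = {g: list(sub["transcript_id"]) for g, sub in txs.groupby("gene_id")}
    fwd_rows, rev_rows = [], []
    orth_pairs = list(zip(orth["gene_id"], orth["ortholog_id"]))
    partnered_ref = list(orth["ortholog_id"])
    partnered_query = list(orth["gene_id"])

    tie_decoys = {}
    for (g, r), tie in zip(orth_pairs, orth["rbh_tie"]):
        best = -np.inf
        best_row = None
        for tid in iso_of[g]:
            score = rng.uniform(190, 210)
            row = _hit_row(tid, r + "-PA", score, 10.0 ** -rng.uniform(30, 120), rng)
            fwd_rows.append(row)
            if row["bitscore"] > best:
                best, best_row = row["bitscore"], row
        if tie and len(orth_pairs) > 1:
            others = [rr for rr in partnered_ref if rr != r]
            decoy = others[int(rng.integers(len(others)))]
            tie_decoys[g] = decoy
            dup = dict(best_row)
            dup["sseqid"] = decoy + "-PA"
            fwd_rows.append(dup)
        # reverse direction: unique top toward g
        for tid in iso_of[g]:
            rev_rows.append(_hit_row(r + "-PA", tid, rng.uniform(190, 210),
                                     10.0 ** -rng.uniform(30, 120), rng))

    # ties that could not be planted (single ortholog pair) are cleared
    planted = truth.genes["gene_id"].isin(tie_decoys)
    truth.genes["rbh_tie"] = truth.genes["rbh_tie"].astype(bool) & planted

    for _, row in coding.iterrows():
        g = row["gene_id"]
        if partnered_ref:
            for _ in range(int(rng.integers(1, 4))):
                target = partnered_ref[int(rng.integers(len(partnered_ref)))]
                if row["ortholog_id"] == target:
                    continue
                tid = iso_of[g][int(rng.integers(len(iso_of[g])))]
                fwd_rows.append(_hit_row(tid, target + "-PA", rng.uniform(50, 150),
                                         10.0 ** -rng.uniform(3, 15), rng))
    for r in extra_ids:
        if partnered_query:
            for _ in range(int(rng.integers(1, 4))):
                g = partnered_query[int(rng.integers(len(partnered_query)))]
                tid = iso_of[g][int(rng.integers(len(iso_of[g])))]
                rev_rows.append(_hit_row(r + "-PA", tid, rng.uniform(50, 150),
                                         10.0 ** -rng.uniform(3, 15), rng))

    return RefSpecies(
        proteins=proteins,
        expression=expression.reset_index(),
        hits_fwd=pd.DataFrame(fwd_rows, columns=HIT_COLUMNS),
        hits_rev=pd.DataFrame(rev_rows, columns=HIT_COLUMNS),
    )


# ---------------------------------------------------------------------------
# annotations and sex-determination hits

def generate_annotations(truth: Truth, config: SyntheticConfig) -> pd.DataFrame:
    """Annotation table with planted TF and detoxification labels.

    Planted classes are recorded in ``truth.genes`` (columns ``tf_class`` and
    ``detox_class``/``detox_detail``) for truth-table tests.
    """
    rng = config.rng(5)
    genes = truth.genes
    tf_class = []
    detox_class = []
    detox_detail = []
    classes, domains, weights = zip(*[(c, d, w) for c, d, w in _TF_CLASS_DOMAINS])
    weights = np.array(weights) / sum(weights)
    families = load_data_table("cyp_families.tsv")["family"].tolist()

    rows = []
    iso_of = {g: list(sub["transcript_id"])
              for g, sub in truth.transcripts.groupby("gene_id")}
    for _, gene in genes.iterrows():
        g = gene["gene_id"]
        tf, detox, detail = None, None, None
        go_terms, pfam, name = ["GO:0008150"], ["DUF1220"], ""
        if gene["coding"] and not gene["is_background"]:
            u = rng.random()
            if u < config.tf_fraction:
                idx = rng.choice(len(classes), p=weights)
                tf = classes[idx]
                go_terms = [GO_TF_TERMS[int(rng.integers(3))]]
                pfam = [domains[idx]]
                name = f"tf-{tf.replace(' ', '').replace('/', '')}"
            elif u < config.tf_fraction + config.detox_fraction:
                v = rng.random()
                if v < 0.55:
                    detox = "P450"
                    fam = families[int(rng.integers(len(families)))]
                    detail = fam
                    name = f"Cyp{fam[3:]}{'abcdeg'[int(rng.integers(6))]}{int(rng.integers(1, 9))}"
                    pfam = ["p450"]
                elif v < 0.80:
                    detox = "GST"
                    w = rng.random()
                    if w < 26 / 34:
                        detail, pfam = "both_domains", ["GST_N", "GST_C"]
                    elif w < 30 / 34:
                        detail, pfam = "N_only", ["GST_N"]
                    else:
                        detail, pfam = "C_only", ["GST_C"]
                    name = f"GstD{int(rng.integers(1, 10))}"
                else:
                    detox = "UGT"
                    detail = "UGT"
                    pfam = ["UDPGT"]
                    name = f"Ugt{int(rng.integers(30, 90))}A{int(rng.integers(1, 5))}"
        tf_class.append(tf)
        detox_class.append(detox)
        detox_detail.append(detail)
        for tid in iso_of[g]:
            rows.append({
                "transcript_id": tid, "gene_id": g,
                "go_terms": ",".join(go_terms),
                "pfam_domains": ",".join(pfam),
                "blast_gene_name": name,
            })
    truth.genes = genes.assign(tf_class=tf_class, detox_class=detox_class,
                               detox_detail=detox_detail)
    return pd.DataFrame(rows)


def generate_sexdet_hits(truth: Truth, config: SyntheticConfig,
                         absent_genes: tuple = ("tra",)):
    """Screening hit table against the shipped sex-determination panel.

    Panel genes in ``absent_genes`` receive only sub-threshold hits, planting
    a known zero-match outcome. Returns (hits, planted) where ``planted`` maps
    panel gene -> set of matched transcript ids.
    """
    rng = config.rng(6)
    panel = load_data_table("sexdet_panel.tsv")
    coding_tx = truth.transcripts[truth.transcripts["coding"]]["transcript_id"].tolist()
    rows, planted = [], {}
    for _, prow in panel.iterrows():
        gene = prow["gene"]
        peptides = [f"{gene}-P{i + 1}" for i in range(int(prow["n_peptides"]))]
        matched = set()
        if gene not in absent_genes and coding_tx:
            n_match = 1 + int(rng.poisson(2))
            chosen = rng.choice(coding_tx, size=min(n_match, len(coding_tx)),
                                replace=False)
            for tid in chosen:
                pep = peptides[int(rng.integers(len(peptides)))]
                rows.append(_hit_row(tid, pep, rng.uniform(150, 400),
                                     10.0 ** -rng.uniform(11, 80), rng))
                matched.add(tid)
        # sub-threshold decoys for every panel gene
        for _ in range(int(rng.integers(1, 4))):
            if not coding_tx:
                break
            tid = coding_tx[int(rng.integers(len(coding_tx)))]
            pep = peptides[int(rng.integers(len(peptides)))]
            rows.append(_hit_row(tid, pep, rng.uniform(40, 80),
                                 10.0 ** -rng.uniform(3, 9), rng))
        planted[gene] = matched
    hits = pd.DataFrame(rows, columns=HIT_COLUMNS)
    peptide_map = pd.DataFrame(
        [(prow["gene"], f"{prow['gene']}-P{i + 1}")
         for _, prow in panel.iterrows() for i in range(int(prow["n_peptides"]))],
        columns=["gene", "peptide_id"])
    return hits, planted, peptide_map


def config_from_dict(d: dict) -> SyntheticConfig:
    known = {f.name for f in dataclasses.fields(SyntheticConfig)}
    unknown = set(d) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    d = dict(d)
    if "stage_pattern_mix" in d and d["stage_pattern_mix"] is not None:
        d["stage_pattern_mix"] = dict(d["stage_pattern_mix"])
    return SyntheticConfig(**d)
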