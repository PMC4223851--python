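"""Paired-read quality filtering and digital (k-mer coverage) normalization.

The quality rule drops a mate when more than ``1 - min_fraction`` of its bases
fall below ``q_min`` (Phred+33); a pair is kept only if both mates pass, so
output files stay synchronized. Digital normalization makes a single pass in
input order: a pair whose k-mers already have a median table count at or above
``max_cov`` is discarded, otherwise it is kept and its canonical k-mers are
counted. Counting is exact (hash table), which is affordable at desk scale
and makes the update rule directly testable.
"""

from __future__ import annotations

import gzip
import statistics
from dataclasses import dataclass

from ._util import revcomp


@dataclass
class ReadPair:
    id: str
    seq1: str
    qual1: str  # Phred+33 encoded
    seq2: str
    qual2: str

    def phred(self, mate: int) -> list[int]:
        qual = self.qual1 if mate == 1 else self.qual2
        return [ord(c) - 33 for c in qual]


@dataclass
class PreprocessStats:
    n_before: int
    n_after_qc: int
    n_after_norm: int

    @property
    def percent_retained_qc(self) -> float:
        return round(100.0 * self.n_after_qc / self.n_before, 1) if self.n_before else 0.0

    @property
    def percent_after_norm(self) -> float:
        return round(100.0 * self.n_after_norm / self.n_before, 1) if self.n_before else 0.0


class FastqParseError(ValueError):
    pass


def _open(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_pairs(r1_path, r2_path) -> list[ReadPair]:
    """Load synchronized paired FASTQ (gzip-transparent, Phred+33)."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    pairs = []
    with _open(r1_path) as h1, _open(r2_path) as h2:
        it1, it2 = FastqGeneralIterator(h1), FastqGeneralIterator(h2)
        for rec1, rec2 in zip(it1, it2, strict=True):
            t1, s1, q1 = rec1
            t2, s2, q2 = rec2
            for title, seq, qual in (rec1, rec2):
                if len(seq) != len(qual):
                    raise FastqParseError(
                        f"record {title.split()[0]!r}: sequence and quality lengths differ")
            pairs.append(ReadPair(t1.split()[0].removesuffix("/1"), s1, q1, s2, q2))
    return pairs


def write_pairs(pairs, r1_path, r2_path):
    with _open(r1_path, "wt") as h1, _open(r2_path, "wt") as h2:
        for p in pairs:
            h1.write(f"@{p.id}/1\n{p.seq1}\n+\n{p.qual1}\n")
            h2.write(f"@{p.id}/2\n{p.seq2}\n+\n{p.qual2}\n")


def mate_passes(qual: str, q_min: int = 20, min_fraction: float = 0.80) -> bool:
    """True iff the fraction of bases at or above q_min is >= min_fraction."""
    if not qual:
        return False
    n_good = sum(1 for c in qual if ord(c) - 33 >= q_min)
    return n_good / len(qual) >= min_fraction


def quality_filter(pairs, q_min: int = 20, min_fraction: float = 0.80):
    """Retain pairs whose two mates both pass the Phred rule.

    Returns (retained pairs, PreprocessStats with n_after_norm == n_after_qc).
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    retained = [p for p in pairs
                if mate_passes(p.qual1, q_min, min_fraction)
                and mate_passes(p.qual2, q_min, min_fraction)]
    stats = PreprocessStats(len(pairs), len(retained), len(retained))
    return retained, stats


def canonical_kmer(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def _pair_kmers(pair: ReadPair, k: int):
    kmers = []
    for seq in (pair.seq1, pair.seq2):
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            kmers.append(canonical_kmer(seq[i:i + k]))
    return kmers


def kmer_normalize(pairs, k: int = 25, max_cov: int = 30):
    """Single-pass digital normalization in input order.

    The median k-mer count is evaluated against the table state *before* the
    current pair's k-mers are added (classic digital-normalization
    semantics). Returns (retained, stats, n_too_short).
    """
    table: dict[str, int] = {}
    retained = []
    n_too_short = 0
    for pair in pairs:
        if len(pair.seq1) < k or len(pair.seq2) < k:
            n_too_short += 1
            continue
        kmers = _pair_kmers(pair, k)
        median = statistics.median(table.get(m, 0) for m in kmers)
        if median >= max_cov:
            continue
        retained.append(pair)
        for m in kmers:
            table[m] = table.get(m, 0) + 1
    stats = PreprocessStats(len(pairs), len(pairs), len(retained))
    return retained, stats, n_too_short


def preprocess(pairs, q_min=20, min_fraction=0.80, k=25, max_cov=30):
    """Quality filter then digital normalization; returns (pairs, stats)."""
    after_qc, _ = quality_filter(pairs, q_min, min_fraction)
    after_norm, _, _ = kmer_normalize(after_qc, k, max_cov)
    return after_norm, PreprocessStats(len(pairs), len(after_qc), len(after_norm))
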