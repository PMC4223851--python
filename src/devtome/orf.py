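"""Coding-region prediction for assembled transcripts.

The predictor mirrors the classic longest-ORF + Markov-model strategy used to
triage de novo transcriptome assemblies:

1. For every transcript, open reading frames are enumerated in all six frames.
   An ORF may be *complete* (start codon through stop codon), truncated at the
   5' end (transcript edge through stop), truncated at the 3' end (start codon
   through transcript edge), or open edge-to-edge. The longest candidate of at
   least ``min_aa`` codons is carried forward.
2. The longest candidates across the transcript set (default: the 500 longest)
   train a phase-aware Markov model of coding sequence; the null model is the
   base composition of the same sequences after per-sequence shuffling, so the
   score is a log-likelihood ratio of "reads like a codon-structured coding
   region" versus "same composition, no structure".
3. A candidate is retained only if the score of its annotated reading frame is
   positive and strictly exceeds the score of the other five frames.

Transcript classes (complete / partial / non-coding) are rolled up to gene
level: a gene is *complete* if any isoform carries a complete retained ORF,
*partial* if any isoform carries a truncated retained ORF, non-coding
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._util import START_CODON, STOP_CODONS, revcomp

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

COMPLETE = "complete"
MISSING_5P = "missing_5p"
MISSING_3P = "missing_3p"
MISSING_BOTH = "missing_both"

_COMPLETENESS_RANK = {COMPLETE: 0, MISSING_5P: 1, MISSING_3P: 2, MISSING_BOTH: 3}


@dataclass
class OrfCall:
    """A candidate or retained coding region on a transcript.

    ``start``/``end`` are 1-based inclusive coordinates on the reported
    strand (i.e. on the reverse complement for minus-strand calls); the stop
    codon, when present, is included in the interval. ``aa_length`` counts
    coding codons (stop excluded).
    """

    transcript_id: str
    strand: str
    frame: int
    start: int
    end: int
    completeness: str
    aa_length: int
    score: float | None = None
    frame_scores: tuple[float, ...] | None = None

    def plus_strand_interval(self, transcript_length: int) -> tuple[int, int]:
        """Project the call onto the plus strand of the input transcript."""
        if self.strand == "+":
            return self.start, self.end
        return transcript_length - self.end + 1, transcript_length - self.start + 1


def _is_stoplike(codon: str) -> bool:
    # N-containing codons break ORFs: treat as stop-equivalent for scanning.
    return codon in STOP_CODONS or any(b not in _BASE_INDEX for b in codon)


def _segment_candidates(transcript_id, strand, frame, codons, seg_start, seg_end,
                        has_stop, at_5_edge):
    """Candidates for one stop-free codon run [seg_start, seg_end] inclusive.

    ``seg_end`` indexes the stop codon itself when ``has_stop``.
    """
    out = []
    coding_end = seg_end - 1 if has_stop else seg_end
    atg = next((i for i in range(seg_start, coding_end + 1)
                if codons[i] == START_CODON), None)

    def _call(first, completeness):
        n_aa = coding_end - first + 1
        start_nt = frame + 3 * first + 1
        end_nt = frame + 3 * seg_end + 3
        return OrfCall(transcript_id, strand, frame, start_nt, end_nt,
                       completeness, n_aa)

    if has_stop:
        if atg is not None:
            out.append(_call(atg, COMPLETE))
        if at_5_edge:
            out.append(_call(seg_start, MISSING_5P))
    else:
        if atg is not None:
            out.append(_call(atg, MISSING_3P))
        if at_5_edge:
            out.append(_call(seg_start, MISSING_BOTH))
    return out


def enumerate_orfs(sequence: str, transcript_id: str = "", min_aa: int = 100) -> list[OrfCall]:
    """Enumerate ORF candidates of >= min_aa codons in all six frames."""
    sequence = sequence.upper()
    candidates: list[OrfCall] = []
    for strand, seq in (("+", sequence), ("-", revcomp(sequence))):
        for frame in range(3):
            codons = [seq[i:i + 3] for i in range(frame, len(seq) - 2, 3)]
            seg_start = 0
            for idx, codon in enumerate(codons):
                if _is_stoplike(codon):
                    if codon in STOP_CODONS:
                        candidates.extend(_segment_candidates(
                            transcript_id, strand, frame, codons, seg_start, idx,
                            True, seg_start == 0))
                    seg_start = idx + 1
            if seg_start < len(codons):
                candidates.extend(_segment_candidates(
                    transcript_id, strand, frame, codons, seg_start,
                    len(codons) - 1, False, seg_start == 0))
    return [c for c in candidates if c.aa_length >= min_aa]


def _candidate_sort_key(call: OrfCall):
    return (-call.aa_length, call.strand != "+", call.frame,
            _COMPLETENESS_RANK[call.completeness], call.start)


def find_longest_orf(sequence: str, transcript_id: str = "", min_aa: int = 100) -> OrfCall | None:
    """The single longest ORF candidate (deterministic tie-break), or None."""
    candidates = enumerate_orfs(sequence, transcript_id, min_aa)
    if not candidates:
        return None
    return min(candidates, key=_candidate_sort_key)


def find_longest_orfs(transcripts: dict[str, str], min_aa: int = 100) -> dict[str, OrfCall]:
    """Longest ORF candidate per transcript; transcripts without one are absent."""
    calls = {}
    for tid, seq in transcripts.items():
        call = find_longest_orf(seq, tid, min_aa)
        if call is not None:
            calls[tid] = call
    return calls


def orf_nucleotides(sequence: str, call: OrfCall, include_stop: bool = False) -> str:
    """Extract the ORF nucleotide sequence on the call's strand."""
    seq = sequence.upper()
    if call.strand == "-":
        seq = revcomp(seq)
    end = call.end
    if not include_stop and call.completeness in (COMPLETE, MISSING_5P):
        end -= 3
    return seq[call.start - 1:end]


def translate_call(sequence: str, call: OrfCall) -> str:
    from Bio.Seq import Seq

    nt = orf_nucleotides(sequence, call)
    return str(Seq(nt).translate())


@dataclass
class MarkovCodingModel:
    """Phase-aware fixed-order Markov model of coding sequence vs a shuffled null.

    ``log_transition`` has shape (3, 4**order, 4): for a base at codon phase p
    with preceding ``order``-mer context c, ``log_transition[p, c, b]`` is the
    log probability of base b. ``log_background`` is the order-0 log
    composition of the shuffled training sequences. Scores are natural-log
    likelihood ratios summed per base; bases whose context window contains an
    ambiguous character contribute zero.
    """

    order: int
    log_transition: np.ndarray
    log_background: np.ndarray
    n_training: int = 0

    def __post_init__(self):
        probs = np.exp(self.log_transition)
        if not np.allclose(probs.sum(axis=2), 1.0, atol=1e-9):
            raise ValueError("transition rows must sum to 1")

    def _encode(self, seq: str) -> np.ndarray:
        return np.array([_BASE_INDEX.get(b, -1) for b in seq], dtype=np.int64)

    def score_sequence(self, seq: str, phase_offset: int = 0) -> float:
        """Log-likelihood ratio of seq read with codon phase ``(i - offset) % 3``."""
        enc = self._encode(seq.upper())
        k = self.order
        if len(enc) <= k:
            return 0.0
        total = 0.0
        ctx = 0
        valid = 0  # number of consecutive valid bases ending at i-1
        pow4 = 4 ** (k - 1)
        mask = 4 ** k
        for i, b in enumerate(enc):
            if i >= k and b >= 0 and valid >= k:
                phase = (i - phase_offset) % 3
                total += self.log_transition[phase, ctx, b] - self.log_background[b]
            if b < 0:
                valid = 0
                ctx = 0
            else:
                valid += 1
                ctx = (ctx * 4 + b) % mask
        return total

    def frame_scores(self, seq: str) -> np.ndarray:
        """Scores of the six readings of ``seq`` (3 shifts x 2 strands).

        Index 0 is the annotated reading (phase 0 on the given strand);
        1 and 2 shift the codon phase; 3-5 read the reverse complement.
        """
        rc = revcomp(seq)
        return np.array(
            [self.score_sequence(seq, s) for s in range(3)]
            + [self.score_sequence(rc, s) for s in range(3)]
        )


def train_markov_model(sequences: list[str], n_train: int = 500, order: int = 5,
                       seed: int = 0) -> MarkovCodingModel:
    """Train the coding model on the ``n_train`` longest candidate ORFs.

    Foreground transition counts are phase-stratified with add-one
    pseudocounts; the null is the order-0 composition of the same sequences
    after independent per-sequence shuffling (seeded), so foreground and null
    share mononucleotide composition by construction.
    """
    sequences = [s.upper() for s in sequences if s]
    if not sequences:
        raise ValueError("cannot train a coding model on zero candidate ORFs")
    training = sorted(sequences, key=len, reverse=True)[:n_train]
    rng = np.random.default_rng(seed)

    k = order
    counts = np.ones((3, 4 ** k, 4))  # add-one pseudocounts
    for seq in training:
        enc = np.array([_BASE_INDEX.get(b, -1) for b in seq], dtype=np.int64)
        ctx, valid = 0, 0
        mask = 4 ** k
        for i, b in enumerate(enc):
            if i >= k and b >= 0 and valid >= k:
                counts[i % 3, ctx, b] += 1
            if b < 0:
                valid, ctx = 0, 0
            else:
                valid += 1
                ctx = (ctx * 4 + b) % mask

    log_transition = np.log(counts / counts.sum(axis=2, keepdims=True))

    bg_counts = np.ones(4)
    for seq in training:
        shuffled = "".join(rng.permutation(list(seq)))
        for b in shuffled:
            idx = _BASE_INDEX.get(b)
            if idx is not None:
                bg_counts[idx] += 1
    log_background = np.log(bg_counts / bg_counts.sum())
    return MarkovCodingModel(order=k, log_transition=log_transition,
                             log_background=log_background,
                             n_training=len(training))


def score_and_retain(model: MarkovCodingModel, sequence: str,
                     call: OrfCall) -> OrfCall | None:
    """Score the call in six frames; retain iff frame 0 is the strict, positive max."""
    nt = orf_nucleotides(sequence, call)
    scores = model.frame_scores(nt)
    call = replace(call, score=float(scores[0]), frame_scores=tuple(scores))
    best_other = max(scores[1:])
    if scores[0] > best_other and scores[0] > 0:
        return call
    return None


def predict_orfs(transcripts: dict[str, str], min_aa: int = 100, order: int = 5,
                 n_train: int = 500, seed: int = 0):
    """End-to-end prediction: scan, train, score, retain.

    Returns (retained calls dict, model, all candidate calls dict).
    """
    candidates = find_longest_orfs(transcripts, min_aa)
    if not candidates:
        raise ValueError("no ORF candidates found; nothing to train on")
    training_seqs = [orf_nucleotides(transcripts[tid], call)
                     for tid, call in candidates.items()]
    model = train_markov_model(training_seqs, n_train=n_train, order=order, seed=seed)
    retained = {}
    for tid, call in candidates.items():
        kept = score_and_retain(model, transcripts[tid], call)
        if kept is not None:
            retained[tid] = kept
    return retained, model, candidates


def partition_transcripts(transcripts: dict[str, str],
                          retained: dict[str, OrfCall],
                          gene_of: dict[str, str]):
    """Partition transcripts and genes into complete / partial / non-coding.

    Returns (transcript_class dict, gene_class dict).
    """
    t_class = {}
    for tid in transcripts:
        call = retained.get(tid)
        if call is None:
            t_class[tid] = "noncoding"
        elif call.completeness == COMPLETE:
            t_class[tid] = "complete"
        else:
            t_class[tid] = "partial"
    g_class: dict[str, str] = {}
    rank = {"complete": 0, "partial": 1, "noncoding": 2}
    for tid, cls in t_class.items():
        gene = gene_of[tid]
        if gene not in g_class or rank[cls] < rank[g_class[gene]]:
            g_class[gene] = cls
    return t_class, g_class


def calls_table(retained: dict[str, OrfCall], gene_of: dict[str, str],
                lengths: dict[str, int]) -> pd.DataFrame:
    rows = []
    for tid, c in sorted(retained.items()):
        p_start, p_end = c.plus_strand_interval(lengths[tid])
        rows.append({
            "transcript_id": tid, "gene_id": gene_of[tid], "strand": c.strand,
            "frame": c.frame, "start": c.start, "end": c.end,
            "plus_start": p_start, "plus_end": p_end,
            "completeness": c.completeness, "aa_length": c.aa_length,
            "score": c.score,
        })
    return pd.DataFrame(rows, columns=[
        "transcript_id", "gene_id", "strand", "frame", "start", "end",
        "plus_start", "plus_end", "completeness", "aa_length", "score"])
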