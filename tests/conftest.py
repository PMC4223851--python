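import numpy as np
import pandas as pd
import pytest

from devtome import synthetic
from devtome.synthetic import SyntheticConfig


@pytest.fixture(scope="session")
def small_dataset():
    """Shared small synthetic dataset with ground truth."""
    cfg = SyntheticConfig(n_genes=60, seed=2)
    transcripts, truth = synthetic.generate_transcriptome(cfg)
    counts = synthetic.generate_expression(truth, cfg)
    return cfg, transcripts, truth, counts


@pytest.fixture(scope="session")
def reference_dataset():
    """Synthetic dataset with a reference species and planted ties."""
    cfg = SyntheticConfig(n_genes=120, seed=5, coding_fraction=1.0,
                          ortholog_fraction=0.7, tie_fraction=0.15,
                          divergence_fraction=0.0, isoform_rate=1.5)
    transcripts, truth = synthetic.generate_transcriptome(cfg)
    ref = synthetic.generate_reference_species(truth, cfg)
    return cfg, transcripts, truth, ref


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive implementations)

_STOPS = {"TAA", "TAG", "TGA"}
_RC = str.maketrans("ACGT", "TGCA")


def oracle_orf_scan(seq, min_aa=100):
    """Brute-force six-frame ORF enumeration.

    Returns a list of (strand, frame, aa_length, start, end, completeness)
    with 1-based inclusive coordinates on the reported strand, stop included.
    """
    seq = seq.upper()
    found = []
    for strand in "+-":
        s = seq if strand == "+" else seq.translate(_RC)[::-1]
        for frame in range(3):
            codons = []
            i = frame
            while i + 3 <= len(s):
                codons.append(s[i:i + 3])
                i += 3
            # split codon indices into stop-free runs
            runs, current = [], []
            for idx, c in enumerate(codons):
                if c in _STOPS:
                    runs.append((current, idx))
                    current = []
                else:
                    current.append(idx)
            runs.append((current, None))
            for run, stop_idx in runs:
                if not run:
                    continue
                at_edge = run[0] == 0
                atgs = [idx for idx in run if codons[idx] == "ATG"]
                options = []
                if stop_idx is not None:
                    if atgs:
                        options.append((atgs[0], "complete"))
                    if at_edge:
                        options.append((run[0], "missing_5p"))
                else:
                    if atgs:
                        options.append((atgs[0], "missing_3p"))
                    if at_edge:
                        options.append((run[0], "missing_both"))
                for first, completeness in options:
                    n_aa = run[-1] - first + 1
                    if n_aa < min_aa:
                        continue
                    last = stop_idx if stop_idx is not None else run[-1]
                    found.append((strand, frame, n_aa,
                                  frame + 3 * first + 1, frame + 3 * last + 3,
                                  completeness))
    return found


def oracle_complete_linkage(dist):
    """O(n^3) complete-linkage agglomeration; returns the cophenetic matrix.

    Ties broken by the smallest (i, j) cluster-index pair.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    clusters = {i: [i] for i in range(n)}
    coph = np.zeros((n, n))
    next_id = n
    while len(clusters) > 1:
        best = None
        keys = sorted(clusters)
        for ai, a in enumerate(keys):
            for b in keys[ai + 1:]:
                d = max(dist[i, j] for i in clusters[a] for j in clusters[b])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = d
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return coph


def oracle_share_filter(counts: pd.DataFrame, gene_map: pd.Series, min_percent):
    pooled = counts.sum(axis=1)
    keep = []
    for tid in counts.index:
        gene = gene_map[tid]
        total = pooled[gene_map[gene_map == gene].index].sum()
        if total > 0 and 100.0 * pooled[tid] / total >= min_percent:
            keep.append(tid)
    return set(keep)


def binom_bounds(n, p, conf=0.99):
    from scipy.stats import binom

    alpha = 1 - conf
    return binom.ppf(alpha / 2, n, p), binom.ppf(1 - alpha / 2, n, p)
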