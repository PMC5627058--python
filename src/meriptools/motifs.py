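"""K-mer enrichment in peak sequences vs matched background.

A count-based consensus-motif scorer: overlapping k-mer occurrences are
counted in peak sequences and in a matched background (same-length windows
drawn from non-peak regions of the same transcripts, which controls for
transcript composition), each k-mer gets a one-sided binomial p-value with
the background frequency as the null rate, and results are BH-adjusted and
ranked.  Methylation is strand-specific, so reverse complements are NOT
collapsed.  With k=5 the expected top hit on methylated RNA is the GGACU
consensus (DNA GGACT).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from .peaks import bh_fdr


@dataclass(frozen=True)
class KmerResult:
    kmer: str
    peak_count: int
    background_count: int
    enrichment: float
    p_value: float
    q_value: float


def _count_kmers(seqs: Sequence[str], k: int) -> tuple[dict, int]:
    counts: dict[str, int] = {}
    total = 0
    for seq in seqs:
        for i in range(len(seq) - k + 1):
            counts[seq[i : i + k]] = counts.get(seq[i : i + k], 0) + 1
        total += max(0, len(seq) - k + 1)
    return counts, total


def kmer_enrichment(
    peak_seqs: Sequence[str],
    background_seqs: Sequence[str],
    k: int = 5,
) -> pd.DataFrame:
    """Ranked k-mer overrepresentation table (peak vs background).

    Enrichment is the pseudocounted frequency ratio; p is the binomial
    upper tail of the peak count at the background rate; rows are sorted
    by q then decreasing enrichment.  Order-invariant in the input
    sequence lists.
    """
    if not background_seqs:
        raise ValueError("background must be non-empty")
    pc, p_total = _count_kmers(peak_seqs, k)
    bc, b_total = _count_kmers(background_seqs, k)
    if p_total == 0 or b_total == 0:
        raise ValueError("k longer than every sequence")
    kmers = sorted(set(pc) | set(bc))
    rows = []
    for kmer in kmers:
        n_p, n_b = pc.get(kmer, 0), bc.get(kmer, 0)
        rate = (n_b + 0.5) / (b_total + 0.5)
        enr = ((n_p + 0.5) / p_total) / ((n_b + 0.5) / b_total)
        p = float(binom.sf(n_p - 1, p_total, rate))
        rows.append((kmer, n_p, n_b, enr, p))
    df = pd.DataFrame(rows, columns=["kmer", "peak_count", "background_count", "enrichment", "p_value"])
    df["q_value"] = bh_fdr(df["p_value"].to_numpy())
    df = df.sort_values(["q_value", "enrichment"], ascending=[True, False], kind="mergesort")
    return df.reset_index(drop=True)


def extract_peak_sequences(
    peaks: Sequence, sequences: Mapping[str, str], flank: int = 0
) -> list[str]:
    """Exact peak subsequences, optionally with symmetric flanks."""
    out = []
    for p in peaks:
        seq = sequences[p.transcript_id]
        s, e = p.start - flank, p.end + flank
        if p.start < 0 or p.end > len(seq):
            raise ValueError("peak outside sequence bounds")
        out.append(seq[max(0, s) : min(len(seq), e)])
    return out


def sample_background(
    peaks: Sequence,
    sequences: Mapping[str, str],
    n: int | None = None,
    length: int | None = None,
    seed: int = 0,
) -> list[str]:
    """Same-length windows from non-peak regions of the peak transcripts.

    Windows never overlap any peak; defaults: one window per peak, of the
    median peak length.
    """
    rng = np.random.default_rng(seed)
    by_tx: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        by_tx.setdefault(p.transcript_id, []).append((p.start, p.end))
    if length is None:
        length = int(np.median([p.end - p.start for p in peaks]))
    if n is None:
        n = len(peaks)
    # free intervals per transcript that can host a window of this length
    slots: list[tuple[str, int, int]] = []
    for tx, ivs in by_tx.items():
        ivs = sorted(ivs)
        cursor = 0
        for s, e in ivs + [(len(sequences[tx]), len(sequences[tx]))]:
            if s - cursor >= length:
                slots.append((tx, cursor, s - length))
            cursor = max(cursor, e)
    if not slots:
        raise ValueError("no peak-free region long enough for the background")
    out = []
    for _ in range(n):
        tx, lo, hi = slots[rng.integers(len(slots))]
        start = int(rng.integers(lo, hi + 1))
        out.append(sequences[tx][start : start + length])
    return out


def shuffle_background(peak_seqs: Sequence[str], seed: int = 0) -> list[str]:
    """Mononucleotide-shuffled copies of the peak sequences (alternative
    background preserving base composition)."""
    rng = np.random.default_rng(seed)
    out = []
    for seq in peak_seqs:
        arr = np.array(list(seq))
        rng.shuffle(arr)
        out.append("".join(arr))
    return out
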