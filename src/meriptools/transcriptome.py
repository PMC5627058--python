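"""Longest-transcript reference and expression quantification.

All downstream peak topology is computed in the coordinate frame of one
transcript per gene — the longest — mirroring the common MeRIP-seq practice
of building a reference transcriptome from the longest isoform.  Expression
is summarized as FPKM (fragments per kilobase of transcript per million
mapped fragments) computed from the input (non-IP) libraries, with genes
above 0.2 FPKM considered stably expressed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

EXPRESSED_FPKM = 0.2


@dataclass(frozen=True)
class TranscriptModel:
    """One gene's representative transcript with UTR/CDS segmentation.

    Coordinates are transcript-space, 0-based half-open.  For coding
    transcripts ``utr5_len + cds_len + utr3_len == length``; lncRNAs carry
    no CDS segmentation (the three fields are ``None``).
    """

    gene_id: str
    transcript_id: str
    biotype: str  # "coding" | "lncRNA"
    length: int
    utr5_len: int | None = None
    cds_len: int | None = None
    utr3_len: int | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("transcript length must be positive")
        if self.biotype == "coding":
            if None in (self.utr5_len, self.cds_len, self.utr3_len):
                raise ValueError("coding transcript requires UTR/CDS lengths")
            if self.utr5_len + self.cds_len + self.utr3_len != self.length:
                raise ValueError("segment lengths must sum to transcript length")
            if self.cds_len < 3:
                raise ValueError("CDS must be at least one codon")
        elif self.biotype == "lncRNA":
            if any(x is not None for x in (self.utr5_len, self.cds_len, self.utr3_len)):
                raise ValueError("lncRNA carries no CDS segmentation")
        else:
            raise ValueError(f"unknown biotype {self.biotype!r}")

    @property
    def cds_start(self) -> int:
        if self.biotype != "coding":
            raise ValueError("lncRNA has no CDS")
        return self.utr5_len

    @property
    def cds_end(self) -> int:
        if self.biotype != "coding":
            raise ValueError("lncRNA has no CDS")
        return self.utr5_len + self.cds_len


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    fragment_count: int
    fpkm: float
    expressed: bool


def select_longest(transcripts: Iterable[TranscriptModel]) -> list[TranscriptModel]:
    """Keep one transcript per gene: the longest, ties by transcript_id.

    Idempotent and independent of input order.
    """
    best: dict[str, TranscriptModel] = {}
    for t in transcripts:
        cur = best.get(t.gene_id)
        if (
            cur is None
            or t.length > cur.length
            or (t.length == cur.length and t.transcript_id < cur.transcript_id)
        ):
            best[t.gene_id] = t
    return sorted(best.values(), key=lambda t: t.gene_id)


def fpkm(count: float, length: int, total: float) -> float:
    """Fragments per kilobase of transcript per million mapped fragments."""
    if length <= 0:
        raise ValueError("transcript length must be positive")
    if total <= 0:
        raise ValueError("total mapped fragments must be positive")
    return count * 1e9 / (length * total)


def count_fragments(
    reads: Sequence[tuple[str, int, int]],
    transcripts: Sequence[TranscriptModel],
) -> dict[str, int]:
    """Assign each read interval to the gene whose selected transcript
    contains its midpoint.

    Reads are transcript-space ``(transcript_id, start, end)`` intervals;
    midpoint assignment avoids double counting at boundaries.
    """
    by_tx = {t.transcript_id: t for t in transcripts}
    counts = {t.gene_id: 0 for t in transcripts}
    for tx_id, start, end in reads:
        t = by_tx.get(tx_id)
        if t is None:
            continue
        mid = (start + end) // 2
        if 0 <= mid < t.length:
            counts[t.gene_id] += 1
    return counts


def expression_table(
    input_reads: Sequence[Sequence[tuple[str, int, int]]],
    transcripts: Sequence[TranscriptModel],
    threshold: float = EXPRESSED_FPKM,
) -> pd.DataFrame:
    """FPKM per gene from pooled input (non-IP) replicate libraries.

    ``expressed`` is strict: FPKM must exceed ``threshold`` (0.2 by
    default); a gene at exactly the threshold is not called expressed.
    """
    pooled: list[tuple[str, int, int]] = []
    for rep in input_reads:
        pooled.extend(rep)
    counts = count_fragments(pooled, transcripts)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no fragments assigned; cannot compute FPKM")
    rows = []
    for t in transcripts:
        c = counts[t.gene_id]
        value = fpkm(c, t.length, total)
        rows.append(
            {
                "gene_id": t.gene_id,
                "fragment_count": c,
                "fpkm": value,
                "expressed": value > threshold,
            }
        )
    return pd.DataFrame(rows)


def gene_map(transcripts: Sequence[TranscriptModel]) -> Mapping[str, str]:
    """transcript_id → gene_id lookup."""
    return {t.transcript_id: t.gene_id for t in transcripts}
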