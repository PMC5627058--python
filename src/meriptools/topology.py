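"""Peak topology along transcripts: metagene profiles and the five-region
classifier.

Metagene: each of 5'UTR, CDS and 3'UTR is rescaled to 100 bins (300 bins
total for mRNA; the whole transcript to 100 bins for lncRNA); a peak
contributes one count to the bin containing its midpoint, and bins are
reported as percentages of all profiled peaks.

Five regions: 5'UTR, start-codon region, CDS, stop-codon region, 3'UTR.
For transcripts with UTRs longer than 100 nt and a CDS longer than 200 nt,
the start/stop-codon regions are the 200-nt windows centred on the codons.
A UTR of 100 nt or less is absorbed into the adjacent codon region
(together with the CDS-side half of the window where the CDS allows).  A
CDS of 200 nt or less is split at its midpoint into start-codon and
stop-codon halves, and the codon windows do not extend into long UTRs.
A peak overlapping several regions takes the highest-priority label:
stop > start > CDS > 3'UTR > 5'UTR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .transcriptome import TranscriptModel

FIVE_UTR = "5'UTR"
START = "start_codon"
CDS = "CDS"
STOP = "stop_codon"
THREE_UTR = "3'UTR"

REGION_ORDER = [FIVE_UTR, START, CDS, STOP, THREE_UTR]
# overlap-resolution priority, highest first
PRIORITY = [STOP, START, CDS, THREE_UTR, FIVE_UTR]

UTR_LONG = 100  # nt; strictly longer activates the centred-window rule
CDS_LONG = 200  # nt; strictly longer activates the centred-window rule
CODON_WINDOW = 200  # nt, centred on the start/stop codon


@dataclass(frozen=True)
class RegionSegmentation:
    """Disjoint cover of [0, length) in 5'→3' label order."""

    transcript_id: str
    length: int
    intervals: tuple  # ((label, start, end), ...) — empty intervals omitted

    def region(self, label: str) -> tuple[int, int] | None:
        for lab, s, e in self.intervals:
            if lab == label:
                return s, e
        return None


def segment(t: TranscriptModel) -> RegionSegmentation:
    """Five-region segmentation of a coding transcript."""
    if t.biotype != "coding":
        raise ValueError("only coding transcripts are segmented")
    u, c, w = t.utr5_len, t.cds_len, t.utr3_len
    L = t.length
    half = CODON_WINDOW // 2
    if c > CDS_LONG:
        if u > UTR_LONG:
            start_iv = (u - half, u + half)
            utr5_iv = (0, u - half)
        else:
            # short 5'UTR absorbed into the start-codon region, keeping the
            # CDS-side half of the window
            start_iv = (0, u + min(half, c // 2))
            utr5_iv = None
        if w > UTR_LONG:
            stop_iv = (u + c - half, u + c + half)
            utr3_iv = (u + c + half, L)
        else:
            stop_iv = (u + c - min(half, c // 2), L)
            utr3_iv = None
        cds_iv = (start_iv[1], stop_iv[0])
    else:
        # short CDS: split at the midpoint; no extension into long UTRs
        mid = u + c // 2
        start_iv = (u, mid)
        stop_iv = (mid, u + c)
        utr5_iv = (0, u)
        utr3_iv = (u + c, L)
        if u <= UTR_LONG:
            start_iv = (0, mid)
            utr5_iv = None
        if w <= UTR_LONG:
            stop_iv = (mid, L)
            utr3_iv = None
        cds_iv = None
    labelled = [
        (FIVE_UTR, utr5_iv),
        (START, start_iv),
        (CDS, cds_iv),
        (STOP, stop_iv),
        (THREE_UTR, utr3_iv),
    ]
    intervals = tuple(
        (lab, iv[0], iv[1]) for lab, iv in labelled if iv is not None and iv[1] > iv[0]
    )
    return RegionSegmentation(t.transcript_id, L, intervals)


def assign_region(peak, segmentation: RegionSegmentation) -> str:
    """Highest-priority region the peak overlaps by at least 1 nt."""
    if peak.start < 0 or peak.end > segmentation.length or peak.end <= peak.start:
        raise ValueError("peak outside the segmented transcript")
    overlapping = {
        lab
        for lab, s, e in segmentation.intervals
        if min(peak.end, e) > max(peak.start, s)
    }
    for lab in PRIORITY:
        if lab in overlapping:
            return lab
    raise AssertionError("segmentation does not cover the peak")  # unreachable


@dataclass(frozen=True)
class MetageneProfile:
    """Per-bin percentage occupancy of peak midpoints (300 bins mRNA /
    100 bins lncRNA); percentages sum to 100 when any peak is profiled."""

    bins: np.ndarray
    n_peaks: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin": np.arange(len(self.bins)), "percent": self.bins})


def _fraction_bin(offset_nt: int, seg_len: int, n_bins: int = 100) -> int:
    """Bin of a position within a segment.

    Bins are right-closed at exact boundaries: a midpoint sitting exactly
    at fraction k/n belongs to bin k-1 (so the segment's exact halfway
    point falls in bin n/2 - 1), clamped to [0, n-1].
    """
    if offset_nt <= 0:
        return 0
    num = offset_nt * n_bins
    return min(n_bins - 1, (num + seg_len - 1) // seg_len - 1)


def _segment_bin(mid: int, u: int, c: int, length: int) -> int:
    """Global 0-299 bin of a midpoint on a coding transcript."""
    bounds = [(0, u, 0), (u, u + c, 100), (u + c, length, 200)]
    for s, e, offset in bounds:
        if s <= mid < e:
            return offset + _fraction_bin(mid - s, e - s)
    # only reachable for mid == length on a zero-length 3'UTR
    return 299


def metagene(
    peaks: Iterable, transcripts: Sequence[TranscriptModel], biotype: str = "coding"
) -> MetageneProfile:
    """Metagene occupancy profile of peak midpoints.

    ``peaks`` need transcript_id/start/end; only peaks on transcripts of
    the requested biotype are profiled.
    """
    by_tx = {t.transcript_id: t for t in transcripts if t.biotype == biotype}
    n_bins = 300 if biotype == "coding" else 100
    counts = np.zeros(n_bins)
    n = 0
    for p in peaks:
        t = by_tx.get(p.transcript_id)
        if t is None:
            continue
        mid = (p.start + p.end) // 2
        if biotype == "coding":
            b = _segment_bin(mid, t.utr5_len, t.cds_len, t.length)
        else:
            b = _fraction_bin(mid, t.length, n_bins)
        counts[b] += 1
        n += 1
    percents = counts * 100.0 / n if n else counts
    return MetageneProfile(percents, n)


def region_counts(
    assignments: pd.DataFrame, group_col: str = "group"
) -> pd.DataFrame:
    """5-region × group contingency of peak counts and within-group
    percentages.  ``assignments`` needs columns 'region' and ``group_col``."""
    if assignments.empty:
        zeros = pd.DataFrame(0, index=REGION_ORDER, columns=["count"])
        zeros["percent"] = 0.0
        return zeros
    table = (
        assignments.groupby([group_col, "region"], observed=True).size().rename("count").reset_index()
    )
    full = []
    for group, sub in table.groupby(group_col, observed=True):
        total = sub["count"].sum()
        for region in REGION_ORDER:
            cnt = int(sub.loc[sub["region"] == region, "count"].sum())
            full.append(
                {
                    group_col: group,
                    "region": region,
                    "count": cnt,
                    "percent": 100.0 * cnt / total if total else 0.0,
                }
            )
    return pd.DataFrame(full)


def utr5_filter(
    gene_ids: Iterable[str],
    transcripts: Sequence[TranscriptModel],
    threshold: int = 100,
) -> float:
    """Fraction of genes whose 5'UTR is strictly longer than ``threshold``.

    Used to argue that start-codon-region peaks are genuine internal
    methylation rather than cap-adjacent m6Am, which can only confound
    short-5'UTR transcripts.
    """
    by_gene = {t.gene_id: t for t in transcripts if t.biotype == "coding"}
    lens = [by_gene[g].utr5_len for g in gene_ids if g in by_gene]
    if not lens:
        raise ValueError("empty gene set")
    return float(np.mean([x > threshold for x in lens]))
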