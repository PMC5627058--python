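"""Read preprocessing: adapter removal, 3' quality trimming, retention filters.

The pipeline applies, in fixed order: (1) adapter removal — the read is cut
at the leftmost position where a full-length adapter window matches with at
most ``max_mismatch`` mismatches; (2) 3'-end quality trimming of the
trailing run of bases below ``trim_qual``; (3) retention — keep reads
strictly longer than ``keep_min_len`` nt with strictly more than
``frac_min`` of bases at Phred strictly above ``frac_qual``; (4) the
mappability length filter — strictly longer than ``map_min_len`` nt.  All
inequalities are strict; boundary reads (length exactly 20 or 50, quality
fraction exactly 0.70) are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence


@dataclass(frozen=True)
class Read:
    id: str
    bases: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError("bases and qualities must have equal length")
        if any(q < 0 for q in self.quals):
            raise ValueError("Phred scores must be non-negative")

    def __len__(self) -> int:
        return len(self.bases)

    def prefix(self, n: int) -> "Read":
        return Read(self.id, self.bases[:n], self.quals[:n])


@dataclass(frozen=True)
class QcParams:
    adapter: str = "GATCGGAAGA"
    max_mismatch: int = 2
    trim_qual: int = 20
    keep_min_len: int = 20
    frac_qual: int = 25
    frac_min: float = 0.70
    map_min_len: int = 50

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_min <= 1.0:
            raise ValueError("frac_min must lie in [0, 1]")
        if min(self.max_mismatch, self.trim_qual, self.keep_min_len,
               self.frac_qual, self.map_min_len) < 0:
            raise ValueError("thresholds must be non-negative")


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def find_adapter(bases: str, adapter: str, max_mismatch: int) -> int | None:
    """Leftmost start of a full-length adapter window within the mismatch
    budget, or None.  Partial 3'-terminal adapter prefixes are not matched."""
    k = len(adapter)
    for i in range(len(bases) - k + 1):
        if _hamming(bases[i : i + k], adapter) <= max_mismatch:
            return i
    return None


def trim_adapter(read: Read, params: QcParams = QcParams()) -> Read:
    """Cut the read at the leftmost adapter occurrence (adapter and
    everything 3' of it removed); unchanged if no window qualifies."""
    pos = find_adapter(read.bases, params.adapter, params.max_mismatch)
    return read if pos is None else read.prefix(pos)


def trim_low_quality_3prime(read: Read, params: QcParams = QcParams()) -> Read:
    """Remove the maximal trailing run of bases below ``trim_qual``.

    Internal low-quality bases are retained.
    """
    n = len(read)
    while n > 0 and read.quals[n - 1] < params.trim_qual:
        n -= 1
    return read if n == len(read) else read.prefix(n)


def retain(read: Read, params: QcParams = QcParams()) -> bool:
    """Keep iff length > keep_min_len and the high-quality base fraction
    (Phred strictly above ``frac_qual``) strictly exceeds ``frac_min``."""
    n = len(read)
    if n == 0 or n <= params.keep_min_len:
        return False
    good = sum(q > params.frac_qual for q in read.quals)
    return good / n > params.frac_min


def mappable(read: Read, params: QcParams = QcParams()) -> bool:
    """Keep for mapping iff strictly longer than ``map_min_len`` nt."""
    return len(read) > params.map_min_len


@dataclass
class QcReport:
    """Per-rule accounting of the preprocessing pipeline."""

    n_input: int = 0
    n_adapter_trimmed: int = 0
    n_quality_trimmed: int = 0
    n_dropped_retain: int = 0
    n_dropped_length: int = 0
    n_kept: int = 0
    counts: dict = field(default_factory=dict)

    def to_tsv(self, path: str) -> None:
        import pandas as pd

        rows = [
            ("input_reads", self.n_input),
            ("adapter_trimmed", self.n_adapter_trimmed),
            ("quality_trimmed", self.n_quality_trimmed),
            ("dropped_retention_filter", self.n_dropped_retain),
            ("dropped_mapping_length_filter", self.n_dropped_length),
            ("kept", self.n_kept),
        ]
        pd.DataFrame(rows, columns=["rule", "count"]).to_csv(path, sep="\t", index=False)


def run_qc(
    reads: Iterable[Read], params: QcParams = QcParams()
) -> tuple[list[Read], QcReport]:
    """Full preprocessing: trim_adapter → trim_low_quality_3prime → retain
    → mappable.  Returns the surviving reads and a per-rule report."""
    report = QcReport()
    kept: list[Read] = []
    for read in reads:
        report.n_input += 1
        trimmed = trim_adapter(read, params)
        if len(trimmed) < len(read):
            report.n_adapter_trimmed += 1
        qtrimmed = trim_low_quality_3prime(trimmed, params)
        if len(qtrimmed) < len(trimmed):
            report.n_quality_trimmed += 1
        if not retain(qtrimmed, params):
            report.n_dropped_retain += 1
            continue
        if not mappable(qtrimmed, params):
            report.n_dropped_length += 1
            continue
        report.n_kept += 1
        kept.append(qtrimmed)
    return kept, report
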