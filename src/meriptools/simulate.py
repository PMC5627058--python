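"""Synthetic MeRIP-seq data with known ground truth.

The generator emulates the data-generating structure the comparative
analysis assumes: two tissues (A, B) sharing most methylation peaks
("common") plus tissue-private peaks; two biological replicates per tissue;
IP coverage enriched over input inside true peaks; the GGACU consensus
(DNA GGACT) embedded at true sites; mRNAs with realistic 5'UTR/CDS/3'UTR
length spreads including short UTRs (<100 nt) and short CDSs (<200 nt) so
the downstream edge rules are exercised; and a minority class of
single-exon lncRNAs.

Counts per 100-nt window are negative binomial (mean ``base_depth``,
overdispersion ``dispersion``; Poisson is recovered as dispersion → ∞);
inside a truth peak active in a tissue the IP mean is multiplied by
``enrichment_fold``.  Replicates are independent draws.  Everything is
deterministic under a fixed seed.

Reads are emitted directly in transcript space as BED intervals; genome
alignment is out of scope, so no genome-space mode exists.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import io as mio
from .qc import Read, find_adapter
from .transcriptome import TranscriptModel

logger = logging.getLogger(__name__)

ADAPTER = "GATCGGAAGA"
_BASES = np.array(list("ACGT"))


class PlacementError(ValueError):
    """Annotation too small to place the requested truth peaks."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults encode the simulated study conditions: 300 genes (10%
    lncRNA), 200 truth peaks of which 75% are common to both tissues
    (matching the common-peak share the analysis expects to see), 8-fold
    IP enrichment over a mean input depth of 50 reads per 100-nt window,
    and the GGACT consensus planted in 80% of peaks.
    """

    n_genes: int = 300
    utr5_len_range: tuple[int, int] = (50, 300)
    cds_len_range: tuple[int, int] = (150, 1800)
    utr3_len_range: tuple[int, int] = (50, 400)
    lncrna_len_range: tuple[int, int] = (300, 2000)
    frac_lncrna: float = 0.10
    n_common_peaks: int = 150
    n_specA_peaks: int = 25
    n_specB_peaks: int = 25
    peak_width: int = 200
    enrichment_fold: float = 8.0
    base_depth: float = 50.0
    dispersion: float = 100.0
    motif: str = "GGACT"
    motif_plant_rate: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_common_peaks", "n_specA_peaks", "n_specB_peaks"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.enrichment_fold < 1:
            raise ValueError("enrichment_fold must be >= 1")
        for name in ("frac_lncrna", "motif_plant_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("utr5_len_range", "cds_len_range", "utr3_len_range", "lncrna_len_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ValueError(f"{name} must be a non-degenerate positive range")
        # downstream short-UTR / short-CDS edge rules must be reachable
        if self.cds_len_range[0] >= 200:
            raise ValueError("cds_len_range must include values < 200")
        if self.utr5_len_range[0] >= 100 or self.utr3_len_range[0] >= 100:
            raise ValueError("UTR length ranges must include values < 100")
        if self.base_depth <= 0 or self.dispersion <= 0:
            raise ValueError("base_depth and dispersion must be positive")
        if self.peak_width <= 0:
            raise ValueError("peak_width must be positive")


@dataclass(frozen=True)
class TruthPeak:
    """A planted methylation site: ground truth for recovery tests."""

    gene_id: str
    transcript_id: str
    transcript_start: int
    transcript_end: int
    tissues: frozenset
    planted_fold: float

    def __post_init__(self) -> None:
        if not 0 <= self.transcript_start < self.transcript_end:
            raise ValueError("invalid truth-peak interval")
        if not self.tissues:
            raise ValueError("tissues must be non-empty")


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    # independent, order-insensitive stream per generation stage
    return np.random.default_rng([config.seed, stage])


def make_annotation(config: SimConfig) -> tuple[list[TranscriptModel], dict[str, str]]:
    """One single-exon transcript per gene plus a uniform-random sequence.

    Coding CDS lengths are rounded down to a codon multiple; lncRNAs carry
    no CDS.  Deterministic under a fixed seed.
    """
    rng = _rng(config, 0)
    transcripts: list[TranscriptModel] = []
    sequences: dict[str, str] = {}
    n_lnc = int(round(config.n_genes * config.frac_lncrna))
    is_lnc = np.zeros(config.n_genes, dtype=bool)
    if n_lnc:
        is_lnc[rng.choice(config.n_genes, size=n_lnc, replace=False)] = True
    for i in range(config.n_genes):
        gene_id = f"gene{i + 1:05d}"
        tx_id = f"{gene_id}.t1"
        if is_lnc[i]:
            length = int(rng.integers(config.lncrna_len_range[0], config.lncrna_len_range[1] + 1))
            t = TranscriptModel(gene_id, tx_id, "lncRNA", length)
        else:
            u = int(rng.integers(config.utr5_len_range[0], config.utr5_len_range[1] + 1))
            c = int(rng.integers(config.cds_len_range[0], config.cds_len_range[1] + 1))
            c = max(3, (c // 3) * 3)
            w = int(rng.integers(config.utr3_len_range[0], config.utr3_len_range[1] + 1))
            t = TranscriptModel(gene_id, tx_id, "coding", u + c + w, u, c, w)
        transcripts.append(t)
        sequences[tx_id] = "".join(rng.choice(_BASES, size=t.length))
    return transcripts, sequences


def plant_truth(
    config: SimConfig,
    annotation: list[TranscriptModel],
    sequences: dict[str, str],
) -> tuple[list[TruthPeak], dict[str, str]]:
    """Place non-overlapping truth peaks and embed the consensus motif.

    Exactly ``n_common + n_specA + n_specB`` peaks are planted; with
    probability ``motif_plant_rate`` the motif is written into the
    sequence centred on the peak.  Returns the truth set and the (copied)
    sequences with motifs embedded.
    """
    rng = _rng(config, 1)
    width = config.peak_width
    total = config.n_common_peaks + config.n_specA_peaks + config.n_specB_peaks
    eligible = [t for t in annotation if t.length >= width]
    if not eligible and total > 0:
        raise PlacementError("no transcript long enough for the requested peak width")
    tissue_labels = (
        [frozenset("AB")] * config.n_common_peaks
        + [frozenset("A")] * config.n_specA_peaks
        + [frozenset("B")] * config.n_specB_peaks
    )
    order = rng.permutation(len(tissue_labels))
    seqs = {k: list(v) for k, v in sequences.items()}
    occupied: dict[str, list[tuple[int, int]]] = {t.transcript_id: [] for t in eligible}
    peaks: list[TruthPeak] = []
    tx_order = list(rng.permutation(len(eligible)))
    cursor = 0
    for idx in order:
        tissues = tissue_labels[idx]
        placed = False
        for _ in range(len(eligible)):
            t = eligible[tx_order[cursor % len(eligible)]]
            cursor += 1
            for _try in range(30):
                start = int(rng.integers(0, t.length - width + 1))
                end = start + width
                if all(end <= s or start >= e for s, e in occupied[t.transcript_id]):
                    occupied[t.transcript_id].append((start, end))
                    peaks.append(
                        TruthPeak(t.gene_id, t.transcript_id, start, end, tissues, config.enrichment_fold)
                    )
                    if rng.random() < config.motif_plant_rate:
                        k = len(config.motif)
                        centre = start + width // 2
                        pos = min(max(centre - k // 2, 0), t.length - k)
                        seqs[t.transcript_id][pos : pos + k] = list(config.motif)
                    placed = True
                    break
            if placed:
                break
        if not placed:
            raise PlacementError("annotation too small to place requested truth peaks")
    peaks.sort(key=lambda p: (p.transcript_id, p.transcript_start))
    return peaks, {k: "".join(v) for k, v in seqs.items()}


def _tile_means(t: TranscriptModel, active: list[tuple[int, int]], config: SimConfig) -> np.ndarray:
    """Per-100nt-tile IP mean multipliers times base depth."""
    n_tiles = (t.length + 99) // 100
    starts = np.arange(n_tiles) * 100
    ends = np.minimum(starts + 100, t.length)
    mu = config.base_depth * (ends - starts) / 100.0
    mids = (starts + ends) // 2
    enriched = np.zeros(n_tiles, dtype=bool)
    for s, e in active:
        enriched |= (mids >= s) & (mids < e)
    return mu, enriched


def simulate_reads(
    config: SimConfig,
    annotation: list[TranscriptModel],
    truth: list[TruthPeak],
) -> dict[tuple[str, int, str], list[tuple[str, int, int]]]:
    """Simulate read intervals for tissue × replicate × {IP, input}.

    Returns a dict keyed by ``(tissue, replicate, assay)`` with tissue in
    {"A","B"}, replicate in {1,2}, assay in {"IP","input"}; values are
    lists of transcript-space ``(transcript_id, start, end)`` intervals.
    """
    by_tx: dict[str, list[TruthPeak]] = {}
    for p in truth:
        by_tx.setdefault(p.transcript_id, []).append(p)
    out: dict[tuple[str, int, str], list[tuple[str, int, int]]] = {}
    stage = 2
    for tissue in ("A", "B"):
        for rep in (1, 2):
            for assay in ("IP", "input"):
                rng = _rng(config, stage)
                stage += 1
                reads: list[tuple[str, int, int]] = []
                for t in annotation:
                    active = [
                        (p.transcript_start, p.transcript_end)
                        for p in by_tx.get(t.transcript_id, [])
                        if tissue in p.tissues
                    ] if assay == "IP" else []
                    mu, enriched = _tile_means(t, active, config)
                    if assay == "IP":
                        mu = np.where(enriched, mu * config.enrichment_fold, mu)
                    r = config.dispersion
                    counts = rng.negative_binomial(r, r / (r + mu))
                    n_tiles = len(counts)
                    starts = np.arange(n_tiles) * 100
                    ends = np.minimum(starts + 100, t.length)
                    for w in np.nonzero(counts)[0]:
                        mids = rng.integers(starts[w], ends[w], size=counts[w])
                        for m in mids:
                            reads.append(
                                (t.transcript_id, int(max(0, m - 50)), int(min(t.length, m + 50)))
                            )
                out[(tissue, rep, assay)] = reads
    return out


# ---------------------------------------------------------------------------
# FASTQ simulation for the QC stage

def simulate_fastq(
    n_reads: int,
    read_len: int = 100,
    adapter_fraction: float = 0.0,
    adapter_mismatches: int = 0,
    low_quality_fraction: float = 0.1,
    adapter: str = ADAPTER,
    clean_mismatch: int = 2,
    seed: int = 0,
) -> list[Read]:
    """Adapter-bearing FASTQ reads with known contamination fraction.

    Exactly ``round(adapter_fraction * n_reads)`` reads carry the adapter
    (with ``adapter_mismatches`` random substitutions, 0-2) inserted at a
    random internal position and followed by random fill.  Reads are
    rejection-sampled so that no *unplanted* window lies within
    ``clean_mismatch`` Hamming distance of the adapter: the planted
    fraction is exact ground truth for the trimmer.  A
    ``low_quality_fraction`` of reads get a trailing low-quality run to
    exercise the 3' trimming and retention filters.
    """
    rng = np.random.default_rng(seed)
    k = len(adapter)
    n_adapter = int(round(adapter_fraction * n_reads))
    with_adapter = np.zeros(n_reads, dtype=bool)
    if n_adapter:
        with_adapter[rng.choice(n_reads, size=n_adapter, replace=False)] = True
    low_q = rng.random(n_reads) < low_quality_fraction
    reads: list[Read] = []
    for i in range(n_reads):
        while True:
            bases = "".join(rng.choice(_BASES, size=read_len))
            if find_adapter(bases, adapter, clean_mismatch) is None:
                break
        if with_adapter[i]:
            insert_at = int(rng.integers(k + 10, read_len - k + 1))
            ad = list(adapter)
            if adapter_mismatches:
                pos = rng.choice(k, size=adapter_mismatches, replace=False)
                for p in pos:
                    ad[p] = rng.choice([b for b in "ACGT" if b != ad[p]])
            bases = bases[:insert_at] + "".join(ad) + bases[insert_at + k :]
        quals = rng.integers(28, 41, size=read_len)
        if low_q[i]:
            run = int(rng.integers(5, 31))
            quals[-run:] = rng.integers(2, 16, size=run)
        reads.append(Read(f"read{i + 1:06d}", bases, tuple(int(q) for q in quals)))
    return reads


# ---------------------------------------------------------------------------
# On-disk round trips

def write_truth_bed(truth: list[TruthPeak], path: str) -> None:
    rows = [
        (p.transcript_id, p.transcript_start, p.transcript_end,
         f"{p.gene_id}:{''.join(sorted(p.tissues))}", p.planted_fold, "+")
        for p in truth
    ]
    mio.write_bed(rows, path)
    logger.info("wrote %d truth peaks to %s", len(truth), path)


def read_truth_bed(path: str) -> list[TruthPeak]:
    df = mio.read_bed(path)
    out = []
    for row in df.itertuples(index=False):
        gene_id, tissues = row.name.split(":")
        out.append(
            TruthPeak(gene_id, row.chrom, int(row.start), int(row.end),
                      frozenset(tissues), float(row.score))
        )
    return out


def write_reads_bed(reads: list[tuple[str, int, int]], path: str) -> None:
    rows = [(tx, s, e, f"r{i + 1}", 0, "+") for i, (tx, s, e) in enumerate(reads)]
    mio.write_bed(rows, path)


def read_reads_bed(path: str) -> list[tuple[str, int, int]]:
    df = mio.read_bed(path)
    return [(r.chrom, int(r.start), int(r.end)) for r in df.itertuples(index=False)]


def save_config(config: SimConfig, path: str) -> None:
    d = dataclasses.asdict(config)
    d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def load_config(path: str) -> SimConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    for key in ("utr5_len_range", "cds_len_range", "utr3_len_range", "lncrna_len_range"):
        if key in d:
            d[key] = tuple(d[key])
    return SimConfig(**d)


def generate_dataset(config: SimConfig, outdir: str | None = None):
    """Full generation: annotation, sequences (with motifs), truth, reads.

    If ``outdir`` is given, writes GTF/FASTA/BED/YAML there and logs paths.
    """
    annotation, sequences = make_annotation(config)
    truth, sequences = plant_truth(config, annotation, sequences)
    reads = simulate_reads(config, annotation, truth)
    if outdir is not None:
        import os

        os.makedirs(outdir, exist_ok=True)
        logger.info("seed=%d outdir=%s", config.seed, outdir)
        save_config(config, os.path.join(outdir, "sim_config.yaml"))
        mio.write_gtf(annotation, os.path.join(outdir, "annotation.gtf"))
        mio.write_fasta(sequences, os.path.join(outdir, "transcripts.fa"))
        write_truth_bed(truth, os.path.join(outdir, "truth_peaks.bed"))
        for (tissue, rep, assay), rr in reads.items():
            write_reads_bed(rr, os.path.join(outdir, f"{tissue}_rep{rep}_{assay}.bed"))
    return annotation, sequences, truth, reads
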