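"""File formats: GTF, FASTA, BED, FASTQ, YAML config.

Conventions: GTF is 1-based closed (converted internally to 0-based
half-open); BED is 0-based half-open; FASTQ qualities are Phred+33.
Transcripts are emitted in transcript space — each transcript is its own
sequence — so every feature sits on a seqname equal to its transcript_id.
"""

from __future__ import annotations

import io as _io
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .transcriptome import TranscriptModel

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


# ---------------------------------------------------------------------------
# GTF

def write_gtf(transcripts: Sequence[TranscriptModel], path: str) -> None:
    """Write exon (and CDS for coding genes) features, 1-based closed."""
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; biotype "{t.biotype}";'
            fh.write(
                "\t".join(
                    [t.transcript_id, "meriptools", "exon", "1", str(t.length),
                     ".", "+", ".", attrs]
                )
                + "\n"
            )
            if t.biotype == "coding":
                fh.write(
                    "\t".join(
                        [t.transcript_id, "meriptools", "CDS",
                         str(t.cds_start + 1), str(t.cds_end), ".", "+", ".", attrs]
                    )
                    + "\n"
                )


def read_gtf(path: str) -> list[TranscriptModel]:
    """Rebuild transcript models from a GTF written by :func:`write_gtf`."""
    db = gffutils.create_db(
        path, ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    exons: dict[str, dict] = {}
    cds: dict[str, tuple[int, int]] = {}
    for feat in db.all_features():
        tx = feat.attributes["transcript_id"][0]
        if feat.featuretype == "exon":
            exons[tx] = {
                "gene_id": feat.attributes["gene_id"][0],
                "biotype": feat.attributes.get("biotype", ["coding"])[0],
                "length": feat.end - feat.start + 1,
            }
        elif feat.featuretype == "CDS":
            cds[tx] = (feat.start - 1, feat.end)  # to 0-based half-open
    out = []
    for tx, rec in sorted(exons.items()):
        if rec["biotype"] == "coding":
            c0, c1 = cds[tx]
            out.append(
                TranscriptModel(
                    gene_id=rec["gene_id"], transcript_id=tx, biotype="coding",
                    length=rec["length"], utr5_len=c0, cds_len=c1 - c0,
                    utr3_len=rec["length"] - c1,
                )
            )
        else:
            out.append(
                TranscriptModel(
                    gene_id=rec["gene_id"], transcript_id=tx,
                    biotype="lncRNA", length=rec["length"],
                )
            )
    return out


# ---------------------------------------------------------------------------
# FASTA

def write_fasta(sequences: Mapping[str, str], path: str) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


# ---------------------------------------------------------------------------
# BED

def write_bed(intervals: Iterable[tuple], path: str, extra_columns: Sequence[str] = ()) -> None:
    """Write BED6(+N) rows: (chrom, start, end, name, score, strand, *extra)."""
    df = pd.DataFrame(list(intervals), columns=BED6_COLUMNS + list(extra_columns))
    df.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str, extra_columns: Sequence[str] = ()) -> pd.DataFrame:
    names = BED6_COLUMNS + list(extra_columns)
    return pd.read_csv(path, sep="\t", header=None, names=names)


# ---------------------------------------------------------------------------
# FASTQ

def write_fastq(reads: Iterable, path: str) -> None:
    """Write qc.Read-like objects (id, bases, quals) as Phred+33 FASTQ."""
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.bases), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = list(r.quals)
        records.append(rec)
    SeqIO.write(records, path, "fastq")


def read_fastq(path: str):
    """Yield (id, bases, quals) tuples from a Phred+33 FASTQ."""
    for rec in SeqIO.parse(path, "fastq"):
        yield rec.id, str(rec.seq), rec.letter_annotations["phred_quality"]


def fastq_str(reads: Iterable) -> str:
    """FASTQ text for byte-identity checks."""
    buf = _io.StringIO()
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.bases), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = list(r.quals)
        records.append(rec)
    SeqIO.write(records, buf, "fastq")
    return buf.getvalue()
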