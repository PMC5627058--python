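"""Replicate concordance and common/region-specific methylation.

Two biological replicates per tissue are reconciled first: peaks
overlapping by more than 50% of the shorter peak's length are concordant,
and only concordant peaks enter the tissue comparison.  A concordant peak
is *common* when it overlaps (>= 1 nt) a concordant peak of the other
tissue; *specific* when it overlaps no peak of either raw replicate of the
other tissue; anything in between (present in exactly one replicate of the
other tissue) is *ambiguous* and excluded from the common/specific
analyses.  Genes inherit labels from their peaks: a gene with any common
peak is a commonly methylated RNA (CMR); a gene with specific peaks of one
tissue only is a specifically methylated RNA (SMR) of that tissue.

Methylation level is proxied by log2 fold enrichment; set comparisons use
the two-sided Wilcoxon rank-sum test throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, spearmanr

from .peaks import Peak
from .transcriptome import TranscriptModel

COMMON = "common"
SPECIFIC_A = "specific_A"
SPECIFIC_B = "specific_B"
AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class ConcordantPeak:
    """Union interval of two overlapping replicate peaks within one tissue."""

    transcript_id: str
    start: int
    end: int
    rep_q: tuple[float, float]
    log2_fe: float  # mean of the two replicate log2 fold enrichments
    tissue: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PeakClassification:
    peak: ConcordantPeak
    label: str  # common | specific_A | specific_B | ambiguous


@dataclass(frozen=True)
class GeneMethylation:
    gene_id: str
    n_peaks: int
    gene_log2_fe: float  # mean of the gene's peak log2 fold enrichments
    label: str  # CMR | SMR_A | SMR_B | mixed | unmethylated


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def concordant(
    peaks_rep1: Sequence[Peak],
    peaks_rep2: Sequence[Peak],
    tissue: str = "",
    min_frac: float = 0.5,
) -> list[ConcordantPeak]:
    """Match replicate peaks requiring overlap > min_frac of the shorter.

    Each peak is used at most once; candidate pairs are consumed in
    decreasing overlap order (best-overlap matching).  The emitted
    interval is the union of the pair; symmetric in replicate order.
    """
    pairs = []
    for i, p1 in enumerate(peaks_rep1):
        for j, p2 in enumerate(peaks_rep2):
            if p1.transcript_id != p2.transcript_id:
                continue
            ov = _overlap(p1.start, p1.end, p2.start, p2.end)
            if ov > min_frac * min(p1.length, p2.length):
                pairs.append((ov, i, j))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used1: set[int] = set()
    used2: set[int] = set()
    out: list[ConcordantPeak] = []
    for ov, i, j in pairs:
        if i in used1 or j in used2:
            continue
        used1.add(i)
        used2.add(j)
        p1, p2 = peaks_rep1[i], peaks_rep2[j]
        out.append(
            ConcordantPeak(
                p1.transcript_id,
                min(p1.start, p2.start),
                max(p1.end, p2.end),
                (p1.q_value, p2.q_value),
                float((p1.log2_fe + p2.log2_fe) / 2.0),
                tissue,
            )
        )
    out.sort(key=lambda c: (c.transcript_id, c.start))
    return out


def _overlaps_any(peak, others: Iterable) -> bool:
    return any(
        peak.transcript_id == o.transcript_id
        and _overlap(peak.start, peak.end, o.start, o.end) > 0
        for o in others
    )


def classify_peaks(
    concordant_a: Sequence[ConcordantPeak],
    concordant_b: Sequence[ConcordantPeak],
    raw_reps_a: Sequence[Sequence[Peak]],
    raw_reps_b: Sequence[Sequence[Peak]],
) -> list[PeakClassification]:
    """Label every concordant peak of both tissues.

    common: concordant in its own tissue and overlapping a concordant peak
    of the other tissue.  specific: overlapping no FDR-significant peak of
    either raw replicate of the other tissue.  ambiguous: everything else
    (e.g. present in exactly one replicate of the other tissue) —
    mutually exclusive and exhaustive.
    """
    out: list[PeakClassification] = []
    for peak in concordant_a:
        if _overlaps_any(peak, concordant_b):
            label = COMMON
        elif not any(_overlaps_any(peak, rep) for rep in raw_reps_b):
            label = SPECIFIC_A
        else:
            label = AMBIGUOUS
        out.append(PeakClassification(peak, label))
    for peak in concordant_b:
        if _overlaps_any(peak, concordant_a):
            label = COMMON
        elif not any(_overlaps_any(peak, rep) for rep in raw_reps_a):
            label = SPECIFIC_B
        else:
            label = AMBIGUOUS
        out.append(PeakClassification(peak, label))
    return out


def assign_peak_gene(
    peak, transcripts: Sequence[TranscriptModel]
) -> str | None:
    """Gene whose selected transcript overlaps the peak most (nt), ties by
    gene_id.  In transcript space this is the transcript's own gene."""
    best = None
    for t in transcripts:
        if t.transcript_id != peak.transcript_id:
            continue
        ov = _overlap(peak.start, peak.end, 0, t.length)
        if ov > 0 and (best is None or ov > best[0] or (ov == best[0] and t.gene_id < best[1])):
            best = (ov, t.gene_id)
    return best[1] if best else None


def classify_genes(
    classifications: Sequence[PeakClassification],
    transcripts: Sequence[TranscriptModel],
    gene_universe: Iterable[str] | None = None,
) -> list[GeneMethylation]:
    """Gene-level labels from peak labels (ambiguous peaks excluded).

    CMR takes precedence: any common peak makes the gene a CMR; specific
    peaks of exactly one tissue make it an SMR of that tissue; specific
    peaks of both tissues (and no common) → mixed.  Genes from
    ``gene_universe`` with no classified peak are emitted as unmethylated.
    """
    tx2gene = {t.transcript_id: t.gene_id for t in transcripts}
    per_gene: dict[str, list[PeakClassification]] = {}
    for pc in classifications:
        if pc.label == AMBIGUOUS:
            continue
        gene = tx2gene.get(pc.peak.transcript_id)
        if gene is None:
            continue
        per_gene.setdefault(gene, []).append(pc)
    out = []
    for gene, pcs in sorted(per_gene.items()):
        labels = {pc.label for pc in pcs}
        if COMMON in labels:
            label = "CMR"
        elif labels == {SPECIFIC_A}:
            label = "SMR_A"
        elif labels == {SPECIFIC_B}:
            label = "SMR_B"
        else:
            label = "mixed"
        fe = float(np.mean([pc.peak.log2_fe for pc in pcs]))
        out.append(GeneMethylation(gene, len(pcs), fe, label))
    if gene_universe is not None:
        seen = {g.gene_id for g in out}
        for gene in sorted(set(gene_universe) - seen):
            out.append(GeneMethylation(gene, 0, float("nan"), "unmethylated"))
    return out


def methylated_genes(
    concordant_peaks: Sequence[ConcordantPeak],
    transcripts: Sequence[TranscriptModel],
) -> set[str]:
    """Genes with at least one concordant peak in the queried tissue."""
    tx2gene = {t.transcript_id: t.gene_id for t in transcripts}
    return {
        tx2gene[c.transcript_id] for c in concordant_peaks if c.transcript_id in tx2gene
    }


def compare_levels(
    values1: Sequence[float], values2: Sequence[float]
) -> tuple[float, float, float]:
    """Medians of the two samples and two-sided Wilcoxon rank-sum p.

    Exact p for small tie-free samples (scipy's exact Mann-Whitney path).
    """
    v1 = np.asarray(values1, dtype=float)
    v2 = np.asarray(values2, dtype=float)
    if v1.size == 0 or v2.size == 0:
        raise ValueError("both sets must be non-empty")
    res = mannwhitneyu(v1, v2, alternative="two-sided", method="auto")
    return float(np.median(v1)), float(np.median(v2)), float(res.pvalue)


def subsample_control(
    cmr_values: Sequence[float],
    smr_values: Sequence[float],
    draws: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Size-matched resampling control for the CMR-vs-SMR comparison.

    Each draw samples ``len(smr_values)`` CMR values without replacement
    and reruns the rank-sum comparison; seed-deterministic.
    """
    cmr = np.asarray(cmr_values, dtype=float)
    smr = np.asarray(smr_values, dtype=float)
    if cmr.size < smr.size:
        raise ValueError("CMR set must be at least as large as the SMR set")
    rng = np.random.default_rng(seed)
    rows = []
    for d in range(draws):
        sample = rng.choice(cmr, size=smr.size, replace=False)
        m1, m2, p = compare_levels(sample, smr)
        rows.append(
            {
                "draw": d + 1,
                "n_sample": int(sample.size),
                "median_cmr_sample": m1,
                "median_smr": m2,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)


def expression_vs_methylation(
    expression: pd.DataFrame,
    gene_methylation: Sequence[GeneMethylation],
) -> dict:
    """Relate expression (FPKM) to methylation status and level.

    Returns the median FPKM of methylated vs unmethylated genes, the
    rank-sum p between them, and Spearman's rho between FPKM and
    gene-level log2 fold enrichment among methylated genes.
    """
    fe = {g.gene_id: g.gene_log2_fe for g in gene_methylation if g.n_peaks > 0}
    expr = expression.set_index("gene_id")["fpkm"]
    meth_fpkm = expr[expr.index.isin(fe)].to_numpy()
    unmeth_fpkm = expr[~expr.index.isin(fe)].to_numpy()
    if meth_fpkm.size < 3:
        raise ValueError("need at least 3 methylated genes for the correlation")
    med_m, med_u, p = compare_levels(meth_fpkm, unmeth_fpkm)
    genes = [g for g in expr.index if g in fe]
    rho = spearmanr(expr[genes].to_numpy(), np.array([fe[g] for g in genes])).statistic
    return {
        "median_fpkm_methylated": med_m,
        "median_fpkm_unmethylated": med_u,
        "wilcoxon_p": p,
        "spearman_rho": float(rho),
    }


def classification_table(classifications: Sequence[PeakClassification]) -> pd.DataFrame:
    rows = [
        {
            "transcript_id": pc.peak.transcript_id,
            "start": pc.peak.start,
            "end": pc.peak.end,
            "tissue": pc.peak.tissue,
            "log2_fe": pc.peak.log2_fe,
            "label": pc.label,
        }
        for pc in classifications
    ]
    return pd.DataFrame(rows)


def gene_table(genes: Sequence[GeneMethylation]) -> pd.DataFrame:
    return pd.DataFrame([dataclass_dict(g) for g in genes])


def dataclass_dict(g) -> Mapping:
    from dataclasses import asdict

    return asdict(g)
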