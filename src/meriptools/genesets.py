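"""External gene-list overlays on methylation results.

Joins curated gene lists (FMRP targets, synaptic proteome, cell-type
enriched genes) to the methylation calls: what fraction of the list is
methylated in a tissue, how many peaks its genes carry, where those peaks
sit along the transcript, and how the list's methylation levels compare
with all methylated genes (empirical CDFs and rank-sum tests).  Gene-ID
matching is exact and case-sensitive; unmatched ids are reported, never
silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .compare import compare_levels
from .topology import REGION_ORDER


@dataclass(frozen=True)
class GeneList:
    name: str
    gene_ids: frozenset

    def __len__(self) -> int:
        return len(self.gene_ids)


def load_gene_list(path: str, name: str | None = None) -> GeneList:
    """One id per line, or first column of a 2-column TSV; deduplicated."""
    ids = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                ids.add(line.split("\t")[0])
    return GeneList(name or path, frozenset(ids))


@dataclass
class OverlayResult:
    list_name: str
    n_list: int
    n_methylated: int
    pct_methylated: float
    mean_peaks_per_gene: float
    region_distribution: dict = field(default_factory=dict)  # region → percent
    fe_values: np.ndarray = field(default_factory=lambda: np.array([]))
    unmatched: int = 0


def overlay(
    gene_list: GeneList,
    gene_peaks: pd.DataFrame,
    known_genes: set | None = None,
) -> OverlayResult:
    """Join a gene list to per-gene peak records.

    ``gene_peaks`` has one row per (gene, peak) with columns gene_id,
    log2_fe and (optionally) region; a gene is methylated iff it appears
    there.  ``known_genes`` (e.g. all annotated genes) lets unmatched ids
    be counted instead of silently conflated with unmethylated ones.
    """
    if len(gene_list) == 0:
        raise ValueError("empty gene list")
    ids = gene_list.gene_ids
    sub = gene_peaks[gene_peaks["gene_id"].isin(ids)]
    methylated = set(sub["gene_id"])
    n_meth = len(methylated)
    pct = 100.0 * n_meth / len(ids)
    mean_peaks = len(sub) / n_meth if n_meth else 0.0
    region_dist: dict[str, float] = {}
    if "region" in sub.columns and len(sub):
        counts = sub["region"].value_counts()
        region_dist = {
            r: 100.0 * counts.get(r, 0) / len(sub) for r in REGION_ORDER
        }
    unmatched = len(ids - known_genes) if known_genes is not None else 0
    return OverlayResult(
        list_name=gene_list.name,
        n_list=len(ids),
        n_methylated=n_meth,
        pct_methylated=pct,
        mean_peaks_per_gene=mean_peaks,
        region_distribution=region_dist,
        fe_values=sub["log2_fe"].to_numpy() if len(sub) else np.array([]),
        unmatched=unmatched,
    )


def ecdf(values: Sequence[float], grid: Sequence[float]) -> np.ndarray:
    """Right-continuous empirical CDF evaluated on a grid."""
    v = np.sort(np.asarray(values, dtype=float))
    return np.searchsorted(v, grid, side="right") / v.size


def compare_fe_cdf(fe_by_list: Mapping[str, Sequence[float]]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-list ECDFs of log2 fold enrichment on the pooled support, plus
    pairwise two-sided rank-sum p-values."""
    for name, v in fe_by_list.items():
        if len(v) == 0:
            raise ValueError(f"empty list {name!r}")
    grid = np.unique(np.concatenate([np.asarray(v, float) for v in fe_by_list.values()]))
    cdf = pd.DataFrame({"log2_fe": grid})
    for name, v in fe_by_list.items():
        cdf[name] = ecdf(v, grid)
    names = list(fe_by_list)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            _, _, p = compare_levels(fe_by_list[a], fe_by_list[b])
            rows.append({"list_a": a, "list_b": b, "wilcoxon_p": p})
    return cdf, pd.DataFrame(rows)


def median_fe_compare(
    list_fe: Sequence[float], all_fe: Sequence[float]
) -> tuple[float, float, float]:
    """Median log2 FE of the list vs all methylated genes, with rank-sum p."""
    return compare_levels(list_fe, all_fe)
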