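"""Anatomic-niche expression analysis (CT vs PPN/PNZ).

Selects genes differentially expressed between the cellular tumor (CT)
and a peri-necrotic niche (PPN or PNZ) of a region-annotated expression
table, then correlates the OATP/SLCO genes with the selected gene set.
The differential statistic is deliberately simple and fully specified -
log2 ratio of region means (with a +1 offset), a two-sided Mann-Whitney
test across samples, and Benjamini-Hochberg adjustment across genes -
so the stage is self-contained and verifiable on synthetic tables; it is
not a negative-binomial RNAseq model and makes no claim to reproduce DEG
lists fitted with one.

Default selection cutoffs are conjunctive: BH-adjusted p < 0.01 (the FDR
cutoff) and raw p < 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average as _average_linkage
from scipy.cluster.hierarchy import leaves_list as _leaves_list
from scipy.spatial.distance import squareform as _squareform

from . import stats as _stats
from .simgen import ExpressionTable
from .stats import CorrelationMatrix

__all__ = [
    "DEGResult",
    "RegionOverlap",
    "differential_expression",
    "oatp_gene_correlation",
    "region_overlap",
]

DEFAULT_CUTOFFS = {"fdr": 0.01, "p": 0.1}


@dataclass
class DEGResult:
    gene: str
    region: str
    log2_fold_change: float  # region vs CT
    p: float
    p_bh: float
    selected: bool


def differential_expression(
    table: ExpressionTable,
    region: str,
    cutoffs: dict[str, float] | None = None,
) -> list[DEGResult]:
    """Per-gene differential expression of ``region`` versus CT.

    log2FC = log2(mean(region)+1) - log2(mean(CT)+1); p from a two-sided
    Mann-Whitney U across samples; BH across genes; selected when
    p_bh < cutoffs["fdr"] and p < cutoffs["p"].
    """
    cutoffs = dict(DEFAULT_CUTOFFS if cutoffs is None else cutoffs)
    if region == "CT":
        raise ValueError("region must differ from the CT reference")
    ref_samples = table.samples_in("CT")
    reg_samples = table.samples_in(region)
    if len(ref_samples) < 2 or len(reg_samples) < 2:
        raise ValueError("need at least 2 samples in each compared region")
    ref = table.values[ref_samples].to_numpy()
    reg = table.values[reg_samples].to_numpy()
    lfc = np.log2(reg.mean(axis=1) + 1.0) - np.log2(ref.mean(axis=1) + 1.0)
    ps = np.array(
        [
            _stats.mann_whitney_u(reg[i], ref[i]).p_two_sided
            for i in range(len(table.genes))
        ]
    )
    p_bh = _stats.bh_adjust(ps)
    out = []
    for gene, l, p, q in zip(table.genes, lfc, ps, p_bh):
        selected = bool(q < cutoffs["fdr"] and p < cutoffs["p"])
        out.append(DEGResult(gene=gene, region=region, log2_fold_change=float(l), p=float(p), p_bh=float(q), selected=selected))
    return out


def top_genes(degs: list[DEGResult], n: int = 40) -> list[str]:
    """The n selected genes with smallest BH-adjusted p (ties by raw p,
    then gene name)."""
    selected = [d for d in degs if d.selected]
    selected.sort(key=lambda d: (d.p_bh, d.p, d.gene))
    return [d.gene for d in selected[:n]]


def _cluster_order(rho: pd.DataFrame) -> list[str]:
    """Average-linkage leaf order on 1-rho distance, deterministic given
    the matrix (genes pre-sorted by name for tie-breaking)."""
    genes = sorted(rho.index)
    if len(genes) <= 2:
        return genes
    r = rho.loc[genes, genes].to_numpy(copy=True)
    r = np.clip(np.nan_to_num(r, nan=0.0), -1.0, 1.0)
    dist = 1.0 - r
    np.fill_diagonal(dist, 0.0)
    dist = 0.5 * (dist + dist.T)
    link = _average_linkage(_squareform(dist, checks=False))
    return [genes[i] for i in _leaves_list(link)]


def oatp_gene_correlation(
    table: ExpressionTable,
    oatp_genes: list[str],
    gene_set: list[str],
    cluster: bool = True,
) -> CorrelationMatrix:
    """Spearman correlation matrix over samples for OATP genes + gene set.

    Rows/columns are ordered by average-linkage clustering on 1-rho for
    reporting; correlations are computed across all samples of the table.
    """
    wanted = list(dict.fromkeys(list(oatp_genes) + list(gene_set)))
    missing = [g for g in wanted if g not in table.values.index]
    if missing:
        raise KeyError(f"genes not in expression table: {missing}")
    sub = table.values.loc[wanted].T  # samples x genes
    mat = _stats.correlation_matrix(sub, wanted)
    if cluster and len(wanted) > 2:
        order = _cluster_order(mat.rho)
        mat = CorrelationMatrix(
            variables=order,
            rho=mat.rho.loc[order, order],
            p=mat.p.loc[order, order],
            p_adjusted=mat.p_adjusted.loc[order, order],
            n=mat.n.loc[order, order],
        )
    return mat


@dataclass
class RegionOverlap:
    """Shared and region-unique DEGs, split by the sign of log2FC."""

    shared_up: set[str]
    shared_down: set[str]
    unique_up: dict[str, set[str]]
    unique_down: dict[str, set[str]]
    fraction_shared_up: float
    fraction_shared_down: float
    fraction_shared: float

    def to_dict(self) -> dict:
        return {
            "shared_up": sorted(self.shared_up),
            "shared_down": sorted(self.shared_down),
            "unique_up": {k: sorted(v) for k, v in self.unique_up.items()},
            "unique_down": {k: sorted(v) for k, v in self.unique_down.items()},
            "fraction_shared_up": self.fraction_shared_up,
            "fraction_shared_down": self.fraction_shared_down,
            "fraction_shared": self.fraction_shared,
        }


def region_overlap(deg_a: list[DEGResult], deg_b: list[DEGResult]) -> RegionOverlap:
    """Set overlap of two selected-DEG lists by gene and log2FC sign.

    Fractions are of the union of selected genes with that sign (e.g.
    10 shared up-genes out of 20 distinct up-genes -> 0.5).
    """

    def split(degs):
        up = {d.gene for d in degs if d.selected and d.log2_fold_change > 0}
        down = {d.gene for d in degs if d.selected and d.log2_fold_change < 0}
        return up, down

    up_a, down_a = split(deg_a)
    up_b, down_b = split(deg_b)
    name_a = deg_a[0].region if deg_a else "a"
    name_b = deg_b[0].region if deg_b else "b"

    def frac(shared, union):
        return len(shared) / len(union) if union else 0.0

    shared_up = up_a & up_b
    shared_down = down_a & down_b
    all_a = up_a | down_a
    all_b = up_b | down_b
    return RegionOverlap(
        shared_up=shared_up,
        shared_down=shared_down,
        unique_up={name_a: up_a - up_b, name_b: up_b - up_a},
        unique_down={name_a: down_a - down_b, name_b: down_b - down_a},
        fraction_shared_up=frac(shared_up, up_a | up_b),
        fraction_shared_down=frac(shared_down, down_a | down_b),
        fraction_shared=frac(all_a & all_b, all_a | all_b),
    )
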