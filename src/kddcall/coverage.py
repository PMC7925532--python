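"""Coverage-based KDD caller.

The caller mirrors how intragenic duplications are found in targeted-panel
copy-number data: per-exon tumor depth is compared against an unmatched
normal to produce a log2 fold-change profile over the gene, the profile is
split into two clusters by exact 1-D 2-means, and the sample is called
KDD-positive when the elevated cluster involves at least 70% of the
kinase domain (or encompasses it) with a cluster-median fold-change
difference of at least 0.4.

A heterozygous single-extra-copy tandem duplication in a pure, fully
clonal tumor raises the affected exons from 2 to 3 copies, i.e. a depth
ratio of 1.5 and log2 fold change of log2(1.5) ~ 0.585 — comfortably above
the 0.4 threshold; purity and subclonality attenuate the signal toward it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .calls import KDDCall
from .gene_models import GeneModel, kd_overlap_fraction


class CoverageError(ValueError):
    pass


@dataclass
class ExonCoverageTable:
    """Mean sequencing depth per exon of one gene in one sample."""

    sample_id: str
    gene_id: str
    depths: pd.Series  # indexed by exon ordinal
    intervals: dict[int, tuple[str, int, int]] | None = None

    def __post_init__(self) -> None:
        self.depths = pd.Series(self.depths, dtype=float)
        if self.depths.index.has_duplicates:
            raise CoverageError(f"{self.sample_id}: duplicate exon ordinals")
        if (self.depths < 0).any():
            raise CoverageError(f"{self.sample_id}: negative depths")

    @classmethod
    def from_gene(
        cls,
        sample_id: str,
        gene: GeneModel,
        depths: Sequence[float],
    ) -> "ExonCoverageTable":
        ords = [e.ordinal for e in gene.exons]
        if len(depths) != len(ords):
            raise CoverageError(
                f"{sample_id}/{gene.gene_id}: {len(depths)} depths for "
                f"{len(ords)} exons"
            )
        return cls(
            sample_id=sample_id,
            gene_id=gene.gene_id,
            depths=pd.Series(list(depths), index=sorted(ords)),
            intervals={
                e.ordinal: (e.chrom, e.start, e.end) for e in gene.exons
            },
        )


@dataclass
class FoldChangeProfile:
    """Per-exon log2 fold change of median-normalized tumor vs normal depth."""

    sample_id: str
    gene_id: str
    fold_change: pd.Series  # indexed by exon ordinal
    tumor_norm_factor: float
    normal_norm_factor: float


@dataclass
class ClusterResult:
    """Exact 1-D 2-means split of a fold-change profile."""

    assignment: pd.Series  # "low"/"high" per exon ordinal
    median_low: float
    median_high: float
    sse: float
    degenerate: bool

    @property
    def median_diff(self) -> float:
        return self.median_high - self.median_low

    def ordinals(self, label: str) -> list[int]:
        return list(self.assignment.index[self.assignment == label])


@dataclass
class CoverageCallerConfig:
    min_kd_overlap: float = 0.70
    min_median_diff: float = 0.4
    fc_scale: str = "log2"
    pseudo_depth: float = 1.0
    exclude_whole_gene: bool = True
    degenerate_tol: float = 0.05
    kd_overlap_mode: str = "exonic"

    def __post_init__(self) -> None:
        if not (0 < self.min_kd_overlap <= 1):
            raise CoverageError("min_kd_overlap must be in (0, 1]")
        if self.min_median_diff <= 0:
            raise CoverageError("min_median_diff must be positive")
        if self.fc_scale not in {"log2", "linear"}:
            raise CoverageError("fc_scale must be 'log2' or 'linear'")


def compute_fold_change(
    tumor: ExonCoverageTable,
    normal: ExonCoverageTable,
    cfg: CoverageCallerConfig | None = None,
) -> FoldChangeProfile:
    """Per-exon fold change of tumor over unmatched normal.

    Each sample's depths are first divided by that sample's median exon
    depth, removing library-size differences; zero depths are replaced by
    ``pseudo_depth`` reads beforehand so the ratio stays finite.  On the
    default log2 scale fc = log2(tumor_norm / normal_norm).
    """
    cfg = cfg or CoverageCallerConfig()
    if tumor.gene_id != normal.gene_id:
        raise CoverageError(
            f"gene mismatch: {tumor.gene_id} vs {normal.gene_id}"
        )
    if not tumor.depths.index.equals(normal.depths.index):
        raise CoverageError(
            f"{tumor.sample_id}: tumor and normal cover different exon sets"
        )
    if (normal.depths == 0).all():
        raise CoverageError(f"{normal.sample_id}: all-zero normal coverage")
    t = tumor.depths.where(tumor.depths > 0, cfg.pseudo_depth)
    n = normal.depths.where(normal.depths > 0, cfg.pseudo_depth)
    t_med, n_med = float(t.median()), float(n.median())
    t_norm, n_norm = t / t_med, n / n_med
    ratio = t_norm / n_norm
    fc = np.log2(ratio) if cfg.fc_scale == "log2" else ratio - 1.0
    return FoldChangeProfile(
        sample_id=tumor.sample_id,
        gene_id=tumor.gene_id,
        fold_change=pd.Series(fc, index=tumor.depths.index),
        tumor_norm_factor=t_med,
        normal_norm_factor=n_med,
    )


def two_means_1d(
    values: Sequence[float] | pd.Series,
    degenerate_tol: float = 0.05,
) -> ClusterResult:
    """Exact 2-means clustering of 1-D values.

    Optimal 1-D k-means clusters are contiguous in sorted order, so the
    global optimum is found by scanning every split point of the sorted
    values — no iterative refinement, no seed sensitivity.  SSE ties keep
    the smallest low cluster; equal values straddling the split are
    assigned by stable sort order.  When the value range is below
    ``degenerate_tol`` the profile is declared flat (degenerate): all
    points in one cluster, median difference zero.
    """
    s = pd.Series(values, dtype=float)
    if len(s) < 2:
        raise CoverageError("two_means_1d needs at least 2 values")
    raw = s.to_numpy()
    order = np.argsort(raw, kind="stable")
    v = raw[order]
    n = len(v)
    if v[-1] - v[0] < degenerate_tol:
        med = float(np.median(v))
        return ClusterResult(
            assignment=pd.Series("low", index=s.index),
            median_low=med,
            median_high=med,
            sse=float(np.sum((v - v.mean()) ** 2)),
            degenerate=True,
        )
    csum = np.cumsum(v)
    csq = np.cumsum(v**2)
    best_k, best_sse = None, math.inf
    for k in range(1, n):  # low cluster = v[:k], high = v[k:]
        s1, q1 = csum[k - 1], csq[k - 1]
        s2, q2 = csum[-1] - s1, csq[-1] - q1
        sse = (q1 - s1**2 / k) + (q2 - s2**2 / (n - k))
        if sse < best_sse - 1e-12:
            best_k, best_sse = k, sse
    low_vals, high_vals = v[:best_k], v[best_k:]
    labels = np.empty(n, dtype=object)
    labels[order[:best_k]] = "low"
    labels[order[best_k:]] = "high"
    return ClusterResult(
        assignment=pd.Series(labels, index=s.index),
        median_low=float(np.median(low_vals)),
        median_high=float(np.median(high_vals)),
        sse=float(max(best_sse, 0.0)),
        degenerate=False,
    )


def call_kdd_from_coverage(
    profile: FoldChangeProfile,
    gene: GeneModel,
    cfg: CoverageCallerConfig | None = None,
) -> KDDCall:
    """Classify one fold-change profile as KDD-positive or negative.

    Positive requires all of:

    1. non-degenerate 2-means clustering of the profile;
    2. cluster-median fold-change difference >= ``min_median_diff``;
    3. the high cluster's exons either cover >= ``min_kd_overlap`` of the
       kinase domain or encompass it (every kinase-domain exon is in the
       high cluster);
    4. if ``exclude_whole_gene``, at least one exon sits in the low
       cluster — a uniformly elevated gene is amplification, not an
       intragenic duplication.

    Both thresholds are inclusive ("at least").
    """
    cfg = cfg or CoverageCallerConfig()
    expected = {e.ordinal for e in gene.exons}
    got = set(profile.fold_change.index)
    if got != expected:
        raise CoverageError(
            f"{profile.sample_id}/{gene.gene_id}: profile exons {sorted(got)} "
            f"do not match gene exons"
        )
    clusters = two_means_1d(profile.fold_change, cfg.degenerate_tol)
    high_ords = clusters.ordinals("high")
    high_ivs = [gene.exon(o).interval for o in high_ords]
    overlap = (
        kd_overlap_fraction(gene, high_ivs, mode=cfg.kd_overlap_mode)
        if high_ivs
        else 0.0
    )
    encompasses = gene.kd_exon_ordinals <= set(high_ords)
    has_low = len(clusters.ordinals("low")) > 0
    positive = (
        not clusters.degenerate
        and clusters.median_diff >= cfg.min_median_diff
        and (overlap >= cfg.min_kd_overlap or encompasses)
        and (has_low or not cfg.exclude_whole_gene)
    )
    return KDDCall(
        sample_id=profile.sample_id,
        gene_id=profile.gene_id,
        method="coverage",
        positive=positive,
        tier="candidate" if positive else "negative",
        metrics={
            "kd_overlap_fraction": overlap,
            "median_diff": clusters.median_diff,
            "median_low": clusters.median_low,
            "median_high": clusters.median_high,
            "degenerate": clusters.degenerate,
            "encompasses_kd": encompasses,
            "duplicated_exons": sorted(high_ords),
        },
    )
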