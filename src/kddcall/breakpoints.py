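"""Discordant-read-pair KDD caller.

Chimeric (both-mates-anchored) pairs inside a gene of interest are
clustered by single linkage on both anchor coordinates; each cluster's
per-side median anchor midpoint gives consensus duplication breakpoints.
Semi-mapped pairs (one confidently mapped mate) contribute one-sided
support to an existing cluster but never seed one.  A cluster with the
everted orientation signature becomes a duplication call, and the call is
KDD-positive when the breakpoints flank — without disrupting — the
kinase-domain interval while staying within the gene span.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .calls import KDDCall
from .gene_models import GeneModel


class BreakpointError(ValueError):
    pass


class OrientationError(BreakpointError):
    """Cluster orientation inconsistent with a tandem duplication."""

    def __init__(self, reason: str):
        self.reason = reason
        super().__init__(f"not a duplication signature: {reason}")


@dataclass
class BreakpointCluster:
    consensus_left: int
    consensus_right: int
    support_chimeric: int
    support_semi_mapped: int
    members: list[str]
    strand_left: str  # majority strand of left anchors among chimeric members
    strand_right: str

    def __post_init__(self) -> None:
        if self.consensus_left >= self.consensus_right:
            raise BreakpointError("consensus_left must be < consensus_right")

    @property
    def total_support(self) -> int:
        return self.support_chimeric + self.support_semi_mapped


@dataclass
class DuplicationCall:
    gene_id: str
    sample_id: str
    bp_left: int
    bp_right: int
    total_support: int
    sv_type: str = "DUP"

    def __post_init__(self) -> None:
        if self.bp_left >= self.bp_right:
            raise BreakpointError("bp_left must be < bp_right")


def _midpoints(df: pd.DataFrame, side: int) -> np.ndarray:
    s = df[f"start{side}"].to_numpy()
    e = df[f"end{side}"].to_numpy()
    return s + (e - s) // 2


def cluster_discordant_pairs(
    pairs: pd.DataFrame,
    gene: GeneModel,
    window: int = 300,
    min_support: int = 2,
    flank: int = 5000,
) -> list[BreakpointCluster]:
    """Single-linkage clustering of discordant pairs within a gene.

    Two chimeric pairs join when both their left-anchor and right-anchor
    midpoints lie within `window` bases of each other.  Clustering is
    independent of input order.  Clusters below `min_support` total
    support (either evidence class counts) are suppressed.
    """
    if window <= 0:
        raise BreakpointError("window must be > 0")
    if min_support < 1:
        raise BreakpointError("min_support must be >= 1")
    if pairs.empty:
        return []
    span = (gene.span[0] - flank, gene.span[1] + flank)
    disc = pairs[pairs["pair_class"] != "concordant"].copy()
    if disc.empty:
        return []
    chim = disc[disc["pair_class"] == "chimeric"]
    chim = chim[
        (chim["chrom1"] == gene.chrom)
        & (chim["chrom2"] == gene.chrom)
        & (_midpoints(chim, 1) >= span[0])
        & (_midpoints(chim, 1) < span[1])
        & (_midpoints(chim, 2) >= span[0])
        & (_midpoints(chim, 2) < span[1])
    ]
    semi = disc[disc["pair_class"] == "semi_mapped"]
    semi = semi[
        (semi["chrom1"] == gene.chrom)
        & (_midpoints(semi, 1) >= span[0])
        & (_midpoints(semi, 1) < span[1])
    ]
    if chim.empty:
        return []
    lmid = _midpoints(chim, 1)
    rmid = _midpoints(chim, 2)
    n = len(chim)
    # union-find single linkage; per-gene pair counts are small
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if abs(lmid[i] - lmid[j]) <= window and abs(rmid[i] - rmid[j]) <= window:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    names = chim["name"].to_numpy()
    clusters: list[BreakpointCluster] = []
    semi_mid = _midpoints(semi, 1) if not semi.empty else np.array([], dtype=int)
    semi_used = np.zeros(len(semi), dtype=bool)
    for idxs in groups.values():
        cl = int(round(float(np.median(lmid[idxs]))))
        cr = int(round(float(np.median(rmid[idxs]))))
        if cl >= cr:
            continue
        sl = "-" if (chim["strand1"].iloc[idxs] == "-").mean() >= 0.5 else "+"
        sr = "+" if (chim["strand2"].iloc[idxs] == "+").mean() >= 0.5 else "-"
        # semi-mapped reinforcement: anchored midpoint near either consensus
        n_semi = 0
        for k in range(len(semi)):
            if semi_used[k]:
                continue
            if abs(semi_mid[k] - cl) <= window or abs(semi_mid[k] - cr) <= window:
                semi_used[k] = True
                n_semi += 1
        clusters.append(
            BreakpointCluster(
                consensus_left=cl,
                consensus_right=cr,
                support_chimeric=len(idxs),
                support_semi_mapped=n_semi,
                members=sorted(names[idxs]),
                strand_left=sl,
                strand_right=sr,
            )
        )
    clusters = [c for c in clusters if c.total_support >= min_support]
    clusters.sort(key=lambda c: (c.consensus_left, c.consensus_right))
    return clusters


def derive_duplication(
    cluster: BreakpointCluster,
    gene: GeneModel,
    sample_id: str = "S1",
) -> DuplicationCall:
    """Interpret an everted cluster as a tandem-duplication call.

    The everted signature — left anchors on the reverse strand, right
    anchors forward — marks read pairs spanning a junction that joins the
    duplicated segment's end back to its start.  Any other orientation is
    rejected: forward/reverse is a deletion signature, matching strands
    suggest an inversion.
    """
    if (cluster.strand_left, cluster.strand_right) != ("-", "+"):
        if (cluster.strand_left, cluster.strand_right) == ("+", "-"):
            raise OrientationError("deletion_signature")
        raise OrientationError("inversion_or_mixed_signature")
    return DuplicationCall(
        gene_id=gene.gene_id,
        sample_id=sample_id,
        bp_left=cluster.consensus_left,
        bp_right=cluster.consensus_right,
        total_support=cluster.total_support,
    )


def classify_kdd_breakpoints(
    dup: DuplicationCall,
    gene: GeneModel,
    flank: int = 5000,
) -> KDDCall:
    """KDD-positive iff breakpoints strictly flank the kinase domain.

    Requires bp_left < kd_start and bp_right > kd_end (a breakpoint on or
    inside the kinase-domain interval disrupts it) and both breakpoints
    within the gene span plus `flank` — a duplication extending far beyond
    the gene is amplification-like, not an intragenic event.
    """
    if dup.gene_id != gene.gene_id:
        raise BreakpointError(
            f"duplication is for {dup.gene_id}, gene is {gene.gene_id}"
        )
    kd_start, kd_end = gene.kinase_domain
    span = (gene.span[0] - flank, gene.span[1] + flank)
    flanks_kd = dup.bp_left < kd_start and dup.bp_right > kd_end
    intragenic = dup.bp_left >= span[0] and dup.bp_right < span[1]
    positive = flanks_kd and intragenic
    dup_iv = (dup.bp_left, dup.bp_right)
    dup_exons = sorted(
        e.ordinal
        for e in gene.exons
        if min(e.end, dup_iv[1]) - max(e.start, dup_iv[0]) > 0
    )
    return KDDCall(
        sample_id=dup.sample_id,
        gene_id=dup.gene_id,
        method="breakpoint",
        positive=positive,
        tier="candidate" if positive else "negative",
        metrics={
            "support_reads": dup.total_support,
            "flanks_kd": flanks_kd,
            "intragenic": intragenic,
            "duplicated_exons": dup_exons,
            "duplicated_kd_exons": sorted(
                set(dup_exons) & gene.kd_exon_ordinals
            ),
        },
        breakpoints=(dup.bp_left, dup.bp_right),
    )


def call_kdd_from_pairs(
    pairs: pd.DataFrame,
    gene: GeneModel,
    sample_id: str = "S1",
    window: int = 300,
    min_support: int = 2,
    flank: int = 5000,
) -> Optional[KDDCall]:
    """End-to-end breakpoint calling for one sample.

    Returns the best (highest-support) positive call, else the
    best-supported negative call, else None when no everted cluster exists.
    """
    clusters = cluster_discordant_pairs(pairs, gene, window, min_support, flank)
    calls: list[KDDCall] = []
    for cl in clusters:
        try:
            dup = derive_duplication(cl, gene, sample_id=sample_id)
        except OrientationError:
            continue
        calls.append(classify_kdd_breakpoints(dup, gene, flank=flank))
    if not calls:
        return None
    calls.sort(
        key=lambda c: (c.positive, c.metrics["support_reads"]), reverse=True
    )
    return calls[0]
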