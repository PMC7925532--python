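"""Shared KDD call record and the two-method consensus policy.

A sample can be interrogated by two independent lines of evidence: the
exon-coverage fold-change caller and the discordant-read-pair breakpoint
caller.  Agreement of both methods yields a *confident* call; a single
method firing yields a *candidate*; neither yields a negative.  This
consensus tier stands in for case-by-case manual review.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional

TIER_ORDER = {"negative": 0, "candidate": 1, "confident": 2}


class CallError(ValueError):
    pass


@dataclass
class KDDCall:
    """Per-sample, per-gene kinase-domain-duplication call."""

    sample_id: str
    gene_id: str
    method: str  # {"coverage", "breakpoint", "consensus"}
    positive: bool
    tier: str  # {"confident", "candidate", "negative"}
    metrics: dict[str, Any] = field(default_factory=dict)
    breakpoints: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.method not in {"coverage", "breakpoint", "consensus"}:
            raise CallError(f"unknown method {self.method!r}")
        if self.tier not in TIER_ORDER:
            raise CallError(f"unknown tier {self.tier!r}")
        if self.positive != (self.tier != "negative"):
            raise CallError("positive flag must agree with tier")


#: consensus tier by (coverage positive, breakpoint positive)
CONSENSUS_POLICY: dict[tuple[bool, bool], str] = {
    (True, True): "confident",
    (True, False): "candidate",
    (False, True): "candidate",
    (False, False): "negative",
}


def combine_calls(
    cov: KDDCall,
    bp: Optional[KDDCall],
    policy: dict[tuple[bool, bool], str] = CONSENSUS_POLICY,
) -> KDDCall:
    """Merge a coverage call and an optional breakpoint call into a consensus.

    The breakpoint caller may simply have no discordant evidence for a
    sample; ``bp=None`` is treated as breakpoint-negative.
    """
    if bp is not None and (cov.sample_id != bp.sample_id or cov.gene_id != bp.gene_id):
        raise CallError(
            f"cannot combine calls for different sample/gene: "
            f"({cov.sample_id},{cov.gene_id}) vs ({bp.sample_id},{bp.gene_id})"
        )
    bp_pos = bool(bp is not None and bp.positive)
    tier = policy[(cov.positive, bp_pos)]
    metrics = {f"coverage_{k}": v for k, v in cov.metrics.items()}
    if bp is not None:
        metrics.update({f"breakpoint_{k}": v for k, v in bp.metrics.items()})
    return KDDCall(
        sample_id=cov.sample_id,
        gene_id=cov.gene_id,
        method="consensus",
        positive=tier != "negative",
        tier=tier,
        metrics=metrics,
        breakpoints=bp.breakpoints if bp is not None else None,
    )
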