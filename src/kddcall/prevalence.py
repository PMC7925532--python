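"""Cohort prevalence tables and Fisher-exact enrichment.

Aggregates per-sample KDD calls into tumor-type x gene count tables with
per-tumor-type denominators, computes prevalence percentages with
half-away-from-zero rounding at a caller-chosen precision, and tests
enrichment of a gene's KDD burden in one tumor type against the rest of
the cohort with Fisher's exact test (two-sided, point-probability
convention; sample odds ratio ad/bc with explicit 0/inf at zero cells).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import math

import pandas as pd
from scipy import stats

from .calls import TIER_ORDER, KDDCall


class PrevalenceError(ValueError):
    pass


SUMMARY_COLUMNS = ["tumor_type", "gene_id", "kdd_positive_count", "total_samples"]


@dataclass
class CohortSummary:
    """Tumor-type x gene KDD counts with per-tumor-type denominators."""

    table: pd.DataFrame  # SUMMARY_COLUMNS; total_samples repeats per gene row

    def __post_init__(self) -> None:
        missing = set(SUMMARY_COLUMNS) - set(self.table.columns)
        if missing:
            raise PrevalenceError(f"summary table missing columns {sorted(missing)}")
        t = self.table
        if (t["kdd_positive_count"] < 0).any() or (
            t["kdd_positive_count"] > t["total_samples"]
        ).any():
            raise PrevalenceError("counts must satisfy 0 <= positives <= total")
        per_type = t.groupby("tumor_type")["total_samples"].nunique()
        if (per_type > 1).any():
            bad = per_type[per_type > 1].index.tolist()
            raise PrevalenceError(
                f"inconsistent total_samples within tumor type(s) {bad}"
            )

    # -- denominators -----------------------------------------------------
    def total_samples(self, tumor_type: Optional[str | Sequence[str]] = None) -> int:
        t = self._filter(tumor_type=tumor_type)
        return int(t.drop_duplicates("tumor_type")["total_samples"].sum())

    def positives(
        self,
        gene_id: Optional[str | Sequence[str]] = None,
        tumor_type: Optional[str | Sequence[str]] = None,
    ) -> int:
        return int(self._filter(gene_id, tumor_type)["kdd_positive_count"].sum())

    def _filter(
        self,
        gene_id: Optional[str | Sequence[str]] = None,
        tumor_type: Optional[str | Sequence[str]] = None,
    ) -> pd.DataFrame:
        t = self.table
        if gene_id is not None:
            genes = [gene_id] if isinstance(gene_id, str) else list(gene_id)
            t = t[t["gene_id"].isin(genes)]
        if tumor_type is not None:
            types = [tumor_type] if isinstance(tumor_type, str) else list(tumor_type)
            t = t[t["tumor_type"].isin(types)]
        return t

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def read_tsv(cls, path: str | Path) -> "CohortSummary":
        return cls(pd.read_csv(path, sep="\t", comment="#"))

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def merged_with(self, other: "CohortSummary") -> "CohortSummary":
        """Combine two summaries over disjoint tumor types."""
        shared = set(self.table["tumor_type"]) & set(other.table["tumor_type"])
        if shared:
            raise PrevalenceError(f"tumor types present in both: {sorted(shared)}")
        return CohortSummary(
            pd.concat([self.table, other.table], ignore_index=True)
        )


def summarize_cohort(
    calls: Iterable[KDDCall],
    sample_metadata: Mapping[str, str],
    totals: Optional[Mapping[str, int]] = None,
    tier_threshold: str = "candidate",
) -> CohortSummary:
    """Count per-sample calls into a tumor-type x gene summary.

    `sample_metadata` maps every sequenced sample -> tumor type; the
    per-tumor-type denominators are its value counts unless `totals`
    overrides them (e.g. when metadata only covers interrogated samples).
    A sample x gene combination counts at most once, at tier >=
    `tier_threshold`.
    """
    if tier_threshold not in TIER_ORDER:
        raise PrevalenceError(f"unknown tier {tier_threshold!r}")
    thr = TIER_ORDER[tier_threshold]
    if totals is None:
        tally: dict[str, int] = {}
        for tt in sample_metadata.values():
            tally[tt] = tally.get(tt, 0) + 1
        totals = tally
    calls = list(calls)
    unknown = sorted({c.sample_id for c in calls} - set(sample_metadata))
    if unknown:
        raise PrevalenceError(f"samples missing from metadata: {unknown}")
    seen: set[tuple[str, str]] = set()
    counts: dict[tuple[str, str], int] = {}
    genes: set[str] = set()
    for c in calls:
        genes.add(c.gene_id)
        key = (c.sample_id, c.gene_id)
        if key in seen:
            continue
        seen.add(key)
        if TIER_ORDER[c.tier] >= thr and c.positive:
            tt = sample_metadata[c.sample_id]
            counts[(tt, c.gene_id)] = counts.get((tt, c.gene_id), 0) + 1
    rows = [
        (tt, g, counts.get((tt, g), 0), int(n))
        for tt, n in sorted(totals.items())
        for g in sorted(genes) or ["NA"]
    ]
    return CohortSummary(pd.DataFrame(rows, columns=SUMMARY_COLUMNS))


def round_half_away(value: float, decimals: int) -> float:
    """Round half away from zero at `decimals` (0.25 -> 0.3 at 1 decimal)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def frequency(
    summary: CohortSummary,
    gene_id: Optional[str | Sequence[str]] = None,
    tumor_type: Optional[str | Sequence[str]] = None,
    decimals: int = 1,
) -> tuple[float, float]:
    """KDD prevalence as a percentage: (rounded, raw).

    Numerator: positive calls matching the filters.  Denominator: samples
    of the matching tumor types (each counted once regardless of how many
    genes were interrogated).
    """
    denom = summary.total_samples(tumor_type)
    if denom == 0:
        raise PrevalenceError("zero denominator after filtering")
    raw = 100.0 * summary.positives(gene_id, tumor_type) / denom
    return round_half_away(raw, decimals), raw


def kdd_share(
    summary: CohortSummary,
    gene_id: str | Sequence[str],
    decimals: int = 1,
) -> tuple[float, float]:
    """One gene's share of all KDD events, as a percentage: (rounded, raw)."""
    total = summary.positives()
    if total == 0:
        raise PrevalenceError("no KDD events in summary")
    raw = 100.0 * summary.positives(gene_id) / total
    return round_half_away(raw, decimals), raw


# ---------------------------------------------------------------------------
# Fisher's exact test


@dataclass(frozen=True)
class Contingency2x2:
    """Counts [[a, b], [c, d]]; rows = groups, columns = outcome."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise PrevalenceError("contingency counts must be >= 0")
        if self.a + self.b + self.c + self.d == 0:
            raise PrevalenceError("empty contingency table")

    @property
    def margins(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


def fisher_exact(table: Contingency2x2) -> tuple[float, float]:
    """Two-sided Fisher's exact test: (odds_ratio, p).

    The odds ratio is the sample estimate a*d / (b*c), reported as inf
    when b*c == 0 and 0.0 when only a*d == 0.  The two-sided p sums the
    hypergeometric probabilities of all tables (at fixed margins) no more
    likely than the observed one (point-probability convention).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if 0 in table.margins:
        raise PrevalenceError("degenerate margin: a row or column sums to zero")
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    if a * d == 0 and b * c > 0:
        odds = 0.0
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return odds, float(p)


def enrichment(
    summary: CohortSummary,
    gene_id: str,
    tumor_type: str,
) -> tuple[Contingency2x2, float, float]:
    """Enrichment of one gene's KDD in one tumor type vs the rest.

    Returns the 2x2 table [[pos_in, neg_in], [pos_out, neg_out]] with the
    odds ratio and two-sided Fisher p.
    """
    pos_in = summary.positives(gene_id, tumor_type)
    n_in = summary.total_samples(tumor_type)
    other = [t for t in summary.table["tumor_type"].unique() if t != tumor_type]
    pos_out = summary.positives(gene_id, other)
    n_out = summary.total_samples(other)
    t = Contingency2x2(pos_in, n_in - pos_in, pos_out, n_out - pos_out)
    odds, p = fisher_exact(t)
    return t, odds, p


def enrichment_table(summary: CohortSummary) -> pd.DataFrame:
    """Fisher enrichment for every (gene, tumor type) combination."""
    rows = []
    for g in sorted(summary.table["gene_id"].unique()):
        for tt in sorted(summary.table["tumor_type"].unique()):
            try:
                t, odds, p = enrichment(summary, g, tt)
            except PrevalenceError:
                continue
            rows.append((g, tt, t.a, t.a + t.b, odds, p))
    return pd.DataFrame(
        rows,
        columns=["gene_id", "tumor_type", "positives", "samples",
                 "odds_ratio", "p_value"],
    )


# ---------------------------------------------------------------------------
# packaged cohort-count fixtures


def load_packaged_summary(which: str = "fmi") -> CohortSummary:
    """Packaged pan-cancer ERBB-KDD count tables.

    ``"fmi"``: counts from a 237,701-sample comprehensive-genomic-profiling
    database (four ERBB genes, nine named tumor types plus an aggregate
    remainder row). ``"msk"``: counts from a 40,165-sample prospective
    panel cohort (EGFR/ERBB2, five tumor types).
    """
    name = {"fmi": "fmi_cohort_counts.tsv", "msk": "msk_cohort_counts.tsv"}[which]
    path = Path(resources.files("kddcall").joinpath("data", name))
    return CohortSummary.read_tsv(path)
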