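"""Seeded synthetic targeted-panel data generator.

Emulates the two evidence streams the callers consume, at the level the
callers see them (no base-level reads):

* per-exon mean coverage for a tumor and an unmatched normal, with
  overdispersed (negative-binomial) count noise, tumor purity and
  subclonality attenuating the duplication signal;
* discordant read pairs in everted orientation scattering around the
  tandem-duplication junction, split into chimeric (both mates anchored)
  and semi-mapped (one mate anchored) classes, on top of concordant
  background pairs.

An expected tumor/normal depth ratio on duplicated exons of
(2 + purity * clonal_fraction * extra_copies) / 2 follows from diploid
copy-number arithmetic: a fraction purity*clonal_fraction of cells carry
extra_copies additional copies of the duplicated segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .coverage import ExonCoverageTable
from .gene_models import GeneModel
from .intervals import overlap_length


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class DuplicationTruth:
    """Ground-truth tandem duplication used to spike simulated samples."""

    gene_id: str
    bp_left: int
    bp_right: int
    extra_copies: int = 1
    clonal_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.bp_left >= self.bp_right:
            raise SimulationError("bp_left must be < bp_right")
        if self.extra_copies < 1:
            raise SimulationError("extra_copies must be >= 1")
        if not (0 < self.clonal_fraction <= 1):
            raise SimulationError("clonal_fraction must be in (0, 1]")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.bp_left, self.bp_right)


@dataclass(frozen=True)
class CoverageSimConfig:
    """Noise model for exon depths.

    Depth is negative-binomial with mean mu and variance mu + dispersion *
    mu**2; dispersion 0 degenerates to the deterministic mean, so the
    squared coefficient of variation at depth mu is 1/mu + dispersion.
    """

    baseline_depth: float = 500.0
    dispersion: float = 0.0
    purity: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_depth <= 0:
            raise SimulationError("baseline_depth must be > 0")
        if self.dispersion < 0:
            raise SimulationError("dispersion must be >= 0")
        if not (0 < self.purity <= 1):
            raise SimulationError("purity must be in (0, 1]")


def dispersion_for_cv(cv: float, depth: float) -> float:
    """Dispersion giving total depth CV `cv` at mean depth `depth`."""
    return max(0.0, cv**2 - 1.0 / depth)


def expected_depth_ratio(truth: DuplicationTruth, purity: float) -> float:
    """Expected tumor/normal ratio on fully duplicated exons."""
    return (2.0 + purity * truth.clonal_fraction * truth.extra_copies) / 2.0


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion == 0:
        return mean.astype(float)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p).astype(float)


def simulate_exon_coverage(
    gene: GeneModel,
    cfg: CoverageSimConfig,
    truth: Optional[DuplicationTruth] = None,
    sample_id: str = "S1",
) -> tuple[ExonCoverageTable, ExonCoverageTable]:
    """Simulate (tumor, unmatched normal) exon coverage for one sample.

    Exons partially overlapped by the duplication get a ratio prorated by
    the fraction of their bases inside it.  Deterministic given the seed.
    """
    if truth is not None and truth.gene_id != gene.gene_id:
        raise SimulationError(
            f"truth is for {truth.gene_id}, gene is {gene.gene_id}"
        )
    rng = np.random.default_rng(cfg.seed)
    ords = sorted(e.ordinal for e in gene.exons)
    base = np.full(len(ords), cfg.baseline_depth)
    tumor_mean = base.copy()
    if truth is not None:
        r = expected_depth_ratio(truth, cfg.purity)
        for i, o in enumerate(ords):
            e = gene.exon(o)
            frac = overlap_length(e.interval, truth.interval) / len(e)
            tumor_mean[i] = cfg.baseline_depth * (1.0 + frac * (r - 1.0))
    tumor_depths = _nb_draw(rng, tumor_mean, cfg.dispersion)
    normal_depths = _nb_draw(rng, base, cfg.dispersion)
    tumor = ExonCoverageTable.from_gene(f"{sample_id}_T", gene, tumor_depths)
    normal = ExonCoverageTable.from_gene(f"{sample_id}_N", gene, normal_depths)
    return tumor, normal


# ---------------------------------------------------------------------------
# discordant read pairs


@dataclass(frozen=True)
class ReadPairSimConfig:
    """Junction-spanning read-pair generator settings."""

    n_support: int = 10
    jitter_sd: float = 30.0
    read_length: int = 100
    chimeric_fraction: float = 0.8  # remainder emitted as semi-mapped
    n_background: int = 50
    insert_size: int = 350
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_support < 0 or self.n_background < 0:
            raise SimulationError("pair counts must be >= 0")
        if not (0 <= self.chimeric_fraction <= 1):
            raise SimulationError("chimeric_fraction must be in [0, 1]")


BEDPE_COLUMNS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2",
    "name", "score", "strand1", "strand2", "pair_class",
]


def _anchor(mid: int, read_length: int) -> tuple[int, int]:
    # interval whose midpoint (start + len//2) is `mid`
    return (mid - read_length // 2, mid - read_length // 2 + read_length)


def simulate_read_pairs(
    gene: GeneModel,
    truth: Optional[DuplicationTruth],
    cfg: ReadPairSimConfig,
    sample_id: str = "S1",
    background_only: bool = False,
) -> pd.DataFrame:
    """Emit a BEDPE-shaped table of read pairs for one sample.

    Junction-supporting pairs are everted (left anchor on the reverse
    strand, right anchor forward — the tandem-duplication signature);
    their anchor midpoints scatter as round(Normal(breakpoint, jitter_sd)).
    Semi-mapped pairs keep only the anchored side; mate fields are ".'/-1.
    Concordant background pairs are uniform over the gene span.
    """
    if truth is None and not background_only:
        raise SimulationError(
            "truth required unless background_only is set"
        )
    if truth is not None and truth.gene_id != gene.gene_id:
        raise SimulationError(
            f"truth is for {truth.gene_id}, gene is {gene.gene_id}"
        )
    rng = np.random.default_rng(cfg.seed)
    rows: list[tuple] = []
    pair_no = 0

    def name() -> str:
        nonlocal pair_no
        pair_no += 1
        return f"{sample_id}|p{pair_no}"

    if truth is not None and not background_only:
        n_chim = int(round(cfg.n_support * cfg.chimeric_fraction))
        for i in range(cfg.n_support):
            lmid = int(round(truth.bp_left + rng.normal(0, cfg.jitter_sd))) if cfg.jitter_sd > 0 else truth.bp_left
            rmid = int(round(truth.bp_right + rng.normal(0, cfg.jitter_sd))) if cfg.jitter_sd > 0 else truth.bp_right
            ls, le = _anchor(lmid, cfg.read_length)
            rs, re_ = _anchor(rmid, cfg.read_length)
            if i < n_chim:
                rows.append((gene.chrom, ls, le, gene.chrom, rs, re_,
                             name(), 60, "-", "+", "chimeric"))
            else:
                # one-end-anchored evidence; anchored side picked at random
                if rng.random() < 0.5:
                    rows.append((gene.chrom, ls, le, ".", -1, -1,
                                 name(), 60, "-", ".", "semi_mapped"))
                else:
                    rows.append((gene.chrom, rs, re_, ".", -1, -1,
                                 name(), 60, "+", ".", "semi_mapped"))
    span = gene.span
    for _ in range(cfg.n_background):
        s = int(rng.integers(span[0], max(span[0] + 1, span[1] - cfg.insert_size)))
        ls, le = s, s + cfg.read_length
        rs = s + cfg.insert_size - cfg.read_length
        rows.append((gene.chrom, ls, le, gene.chrom, rs, rs + cfg.read_length,
                     name(), 60, "+", "-", "concordant"))
    return pd.DataFrame(rows, columns=BEDPE_COLUMNS)


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class CohortRow:
    tumor_type: str
    gene_id: str
    n_samples: int
    kdd_prevalence: float

    def __post_init__(self) -> None:
        if self.n_samples < 0:
            raise SimulationError("n_samples must be >= 0")
        if not (0 <= self.kdd_prevalence <= 1):
            raise SimulationError("kdd_prevalence must be in [0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    rows: tuple[CohortRow, ...]
    seed: int = 0
    expected_count_mode: bool = False

    @classmethod
    def from_records(cls, records: Sequence[tuple], seed: int = 0,
                     expected_count_mode: bool = False) -> "CohortSpec":
        return cls(tuple(CohortRow(*r) for r in records), seed,
                   expected_count_mode)


@dataclass
class CohortSample:
    sample_id: str
    tumor_type: str
    gene_id: str
    truth: Optional[DuplicationTruth]
    tumor: ExonCoverageTable
    normal: ExonCoverageTable
    read_pairs: pd.DataFrame


@dataclass
class CohortBundle:
    samples: list[CohortSample]
    truth_table: pd.DataFrame  # sample_id, tumor_type, gene_id, kdd_positive, bp_left, bp_right


def kd_spanning_truth(gene: GeneModel, margin: int = 200,
                      extra_copies: int = 1,
                      clonal_fraction: float = 1.0) -> DuplicationTruth:
    """Truth duplication spanning the gene's kinase-domain exons.

    Breakpoints sit `margin` bases outside the outermost kinase-domain
    exons, so the event flanks the kinase domain without disrupting it.
    """
    kd_exons = [gene.exon(o) for o in sorted(gene.kd_exon_ordinals)]
    left = min(e.start for e in kd_exons) - margin
    right = max(e.end for e in kd_exons) + margin
    span = gene.span
    return DuplicationTruth(
        gene_id=gene.gene_id,
        bp_left=max(left, span[0]),
        bp_right=min(right, span[1]),
        extra_copies=extra_copies,
        clonal_fraction=clonal_fraction,
    )


def simulate_cohort(
    spec: CohortSpec,
    gene_models: dict[str, GeneModel],
    cov_cfg: CoverageSimConfig | None = None,
    rp_cfg: ReadPairSimConfig | None = None,
    truth_margin: int = 200,
) -> CohortBundle:
    """Simulate every sample of a cohort spec with truth labels.

    Each sample is KDD-positive with its row's prevalence (independent
    Bernoulli draws, or exactly round(n * p) positives in expected-count
    mode); positives carry a duplication spanning the gene's kinase-domain
    exons.  Fully reproducible given the spec seed.
    """
    cov_cfg = cov_cfg or CoverageSimConfig()
    rp_cfg = rp_cfg or ReadPairSimConfig()
    rng = np.random.default_rng(spec.seed)
    samples: list[CohortSample] = []
    truth_rows: list[tuple] = []
    for row in spec.rows:
        if row.gene_id not in gene_models:
            raise SimulationError(f"unknown gene {row.gene_id!r}")
        gene = gene_models[row.gene_id]
        if spec.expected_count_mode:
            n_pos = int(round(row.n_samples * row.kdd_prevalence))
            labels = np.zeros(row.n_samples, dtype=bool)
            labels[:n_pos] = True
        else:
            labels = rng.random(row.n_samples) < row.kdd_prevalence
        for i, pos in enumerate(labels):
            sid = f"{row.tumor_type}_{row.gene_id}_{i:05d}"
            truth = kd_spanning_truth(gene, margin=truth_margin) if pos else None
            sub_cov = replace(cov_cfg, seed=int(rng.integers(0, 2**31 - 1)))
            sub_rp = replace(rp_cfg, seed=int(rng.integers(0, 2**31 - 1)))
            tumor, normal = simulate_exon_coverage(gene, sub_cov, truth, sample_id=sid)
            pairs = simulate_read_pairs(
                gene, truth, sub_rp, sample_id=sid, background_only=truth is None
            )
            samples.append(CohortSample(sid, row.tumor_type, row.gene_id,
                                        truth, tumor, normal, pairs))
            truth_rows.append((
                sid, row.tumor_type, row.gene_id, bool(pos),
                truth.bp_left if truth else -1,
                truth.bp_right if truth else -1,
            ))
    truth_table = pd.DataFrame(
        truth_rows,
        columns=["sample_id", "tumor_type", "gene_id", "kdd_positive",
                 "bp_left", "bp_right"],
    )
    return CohortBundle(samples=samples, truth_table=truth_table)
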