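"""Readers and writers for the pipeline's on-disk formats.

Coverage and truth tables are TSV, read pairs are BEDPE (ten standard
columns plus a ``pair_class`` column; semi-mapped pairs carry "." / -1 in
the mate fields), duplication calls go out as VCF 4.2 (SVTYPE=DUP) via
pysam, and per-sample KDD calls round-trip as TSV or JSON.  Every
writer/reader pair is lossless on valid data; internal coordinates are
0-based half-open and become 1-based only in VCF POS.
"""

from __future__ import annotations

import datetime as _dt
import json
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import pysam

from .breakpoints import DuplicationCall
from .calls import KDDCall
from .coverage import ExonCoverageTable
from .gene_models import GeneModel
from .simulate import BEDPE_COLUMNS, CohortBundle


class FormatError(ValueError):
    pass


COVERAGE_COLUMNS = [
    "sample_id", "gene_id", "exon_ordinal", "chrom", "start", "end", "mean_depth",
]


# ---------------------------------------------------------------------------
# coverage TSV


def coverage_frame(tables: Iterable[ExonCoverageTable]) -> pd.DataFrame:
    rows = []
    for t in tables:
        for ordinal, depth in t.depths.items():
            chrom, start, end = (t.intervals or {}).get(
                ordinal, (".", -1, -1)
            )
            rows.append(
                (t.sample_id, t.gene_id, int(ordinal), chrom, start, end, depth)
            )
    return pd.DataFrame(rows, columns=COVERAGE_COLUMNS)


def write_coverage_tsv(tables: Iterable[ExonCoverageTable], path: str | Path) -> None:
    coverage_frame(tables).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def read_coverage_tsv(path: str | Path) -> dict[tuple[str, str], ExonCoverageTable]:
    """Read coverage TSV into tables keyed by (sample_id, gene_id)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(COVERAGE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    out: dict[tuple[str, str], ExonCoverageTable] = {}
    for (sid, gid), grp in df.groupby(["sample_id", "gene_id"], sort=True):
        grp = grp.sort_values("exon_ordinal")
        out[(sid, gid)] = ExonCoverageTable(
            sample_id=str(sid),
            gene_id=str(gid),
            depths=pd.Series(
                grp["mean_depth"].to_numpy(),
                index=grp["exon_ordinal"].astype(int).to_numpy(),
            ),
            intervals={
                int(r.exon_ordinal): (str(r.chrom), int(r.start), int(r.end))
                for r in grp.itertuples()
            },
        )
    return out


# ---------------------------------------------------------------------------
# BEDPE


def write_bedpe(pairs: pd.DataFrame, path: str | Path) -> None:
    missing = set(BEDPE_COLUMNS) - set(pairs.columns)
    if missing:
        raise FormatError(f"BEDPE frame missing columns {sorted(missing)}")
    pairs[BEDPE_COLUMNS].to_csv(path, sep="\t", index=False, header=False)


def read_bedpe(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", names=BEDPE_COLUMNS, comment="#", header=None,
        dtype={"chrom1": str, "chrom2": str},
    )
    if df.empty:
        return pd.DataFrame(columns=BEDPE_COLUMNS)
    bad = ~df["pair_class"].isin({"chimeric", "semi_mapped", "concordant"})
    if bad.any():
        raise FormatError(
            f"{path}: invalid pair_class values "
            f"{sorted(df.loc[bad, 'pair_class'].unique())}"
        )
    return df


def split_bedpe_by_sample(pairs: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Group a BEDPE frame by the sample prefix of its name column."""
    sids = pairs["name"].str.split("|").str[0]
    return {str(s): g for s, g in pairs.groupby(sids)}


# ---------------------------------------------------------------------------
# KDD call TSV / JSON

CALL_COLUMNS = [
    "sample_id", "gene_id", "method", "positive", "tier",
    "bp_left", "bp_right", "metrics_json",
]


def calls_frame(calls: Iterable[KDDCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        bp = c.breakpoints or (-1, -1)
        rows.append((
            c.sample_id, c.gene_id, c.method, c.positive, c.tier,
            bp[0], bp[1], json.dumps(c.metrics, sort_keys=True),
        ))
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def write_calls_tsv(calls: Iterable[KDDCall], path: str | Path) -> None:
    calls_frame(calls).to_csv(path, sep="\t", index=False)


def write_calls_json(calls: Iterable[KDDCall], path: str | Path) -> None:
    recs = [
        {
            "sample_id": c.sample_id,
            "gene_id": c.gene_id,
            "method": c.method,
            "positive": c.positive,
            "tier": c.tier,
            "breakpoints": list(c.breakpoints) if c.breakpoints else None,
            "metrics": c.metrics,
        }
        for c in calls
    ]
    Path(path).write_text(json.dumps(recs, indent=2, sort_keys=True) + "\n")


def read_calls_tsv(path: str | Path) -> list[KDDCall]:
    df = pd.read_csv(path, sep="\t")
    calls = []
    for r in df.itertuples():
        bp = None if r.bp_left < 0 else (int(r.bp_left), int(r.bp_right))
        calls.append(KDDCall(
            sample_id=str(r.sample_id),
            gene_id=str(r.gene_id),
            method=str(r.method),
            positive=bool(r.positive),
            tier=str(r.tier),
            metrics=json.loads(r.metrics_json),
            breakpoints=bp,
        ))
    return calls


# ---------------------------------------------------------------------------
# VCF


def _vcf_header(
    genes: Sequence[GeneModel],
    fixed_clock: bool = False,
    contig_margin: int = 100_000,
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    date = "20000101" if fixed_clock else _dt.date.today().strftime("%Y%m%d")
    header.add_line(f"##fileDate={date}")
    header.add_line("##source=kddcall")
    contigs: dict[str, int] = {}
    for g in genes:
        contigs[g.chrom] = max(contigs.get(g.chrom, 0), g.span[1] + contig_margin)
    for chrom in sorted(contigs):
        header.contigs.add(chrom, length=contigs[chrom])
    header.add_line(
        '##ALT=<ID=DUP,Description="Tandem duplication">'
    )
    header.add_line(
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Structural variant type">'
    )
    header.add_line(
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End of the duplicated segment">'
    )
    header.add_line(
        '##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Supporting discordant read pairs">'
    )
    header.add_line(
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">'
    )
    header.add_line(
        '##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Sample identifier">'
    )
    header.add_line(
        '##INFO=<ID=KDD_TIER,Number=1,Type=String,Description="KDD confidence tier">'
    )
    return header


def write_dup_vcf(
    calls: Iterable[DuplicationCall],
    genes: Mapping[str, GeneModel],
    path: str | Path,
    tiers: Optional[Mapping[tuple[str, str], str]] = None,
    fixed_clock: bool = False,
) -> None:
    """Write duplication calls as VCF 4.2 (SVTYPE=DUP, 1-based POS).

    Internal 0-based bp_left maps to POS = bp_left + 1; INFO END carries
    bp_right, which equals the 1-based inclusive end of the duplicated
    segment.  `tiers` optionally maps (sample_id, gene_id) to the KDD
    consensus tier.
    """
    calls = list(calls)
    for c in calls:
        if c.gene_id not in genes:
            raise FormatError(f"no gene model for {c.gene_id!r}")
    header = _vcf_header(
        [genes[c.gene_id] for c in calls] or list(genes.values()),
        fixed_clock=fixed_clock,
    )
    order = {c: i for i, c in enumerate(header.contigs)}
    calls.sort(key=lambda c: (order[genes[c.gene_id].chrom], c.bp_left, c.sample_id))
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for i, c in enumerate(calls, 1):
            rec = vf.new_record(
                contig=genes[c.gene_id].chrom,
                start=c.bp_left,
                stop=c.bp_right,
                alleles=("N", "<DUP>"),
                id=f"KDD{i}",
            )
            rec.info["SVTYPE"] = "DUP"
            rec.info["SUPPORT"] = c.total_support
            rec.info["GENE"] = c.gene_id
            rec.info["SAMPLE"] = c.sample_id
            if tiers and (c.sample_id, c.gene_id) in tiers:
                rec.info["KDD_TIER"] = tiers[(c.sample_id, c.gene_id)]
            vf.write(rec)


def read_dup_vcf(path: str | Path) -> list[DuplicationCall]:
    """Read a duplication VCF back into 0-based DuplicationCall records."""
    calls = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            if rec.info.get("SVTYPE") != "DUP":
                continue
            calls.append(DuplicationCall(
                gene_id=str(rec.info["GENE"]),
                sample_id=str(rec.info["SAMPLE"]),
                bp_left=rec.start,          # pysam start is 0-based
                bp_right=rec.stop,          # INFO END
                total_support=int(rec.info["SUPPORT"]),
            ))
    return calls


# ---------------------------------------------------------------------------
# cohort bundle


def write_cohort_bundle(bundle: CohortBundle, outdir: str | Path) -> dict[str, Path]:
    """Write a simulated cohort as coverage.tsv, pairs.bedpe, truth.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "coverage": outdir / "coverage.tsv",
        "pairs": outdir / "pairs.bedpe",
        "truth": outdir / "truth.tsv",
    }
    tables: list[ExonCoverageTable] = []
    for s in bundle.samples:
        tables.extend([s.tumor, s.normal])
    write_coverage_tsv(tables, paths["coverage"])
    pairs = (
        pd.concat([s.read_pairs for s in bundle.samples], ignore_index=True)
        if bundle.samples
        else pd.DataFrame(columns=BEDPE_COLUMNS)
    )
    write_bedpe(pairs, paths["pairs"])
    bundle.truth_table.to_csv(paths["truth"], sep="\t", index=False)
    return paths
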