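"""Gene models: exon structure and kinase-domain annotation.

A :class:`GeneModel` carries the ordered exon intervals of one canonical
transcript of an ERBB-family gene plus the genomic interval encoding its
tyrosine kinase domain (TKD).  For EGFR the TKD is encoded by exons 18-25,
so a single-extra-copy tandem duplication whose breakpoints flank those
exons duplicates the whole kinase domain in frame.

Exon ordinals are assigned in transcript order: on a minus-strand gene
ordinal 1 is the genomically last exon.  Coordinates are 0-based half-open
throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .intervals import covered_bases, merge_intervals, overlap_length


class GeneModelError(ValueError):
    """Malformed annotation input or inconsistent gene/kinase-domain geometry."""


@dataclass(frozen=True)
class ExonInterval:
    """One exon, 0-based half-open, with its 1-based transcript-order ordinal."""

    chrom: str
    start: int
    end: int
    ordinal: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise GeneModelError(
                f"exon {self.ordinal}: start {self.start} must be < end {self.end}"
            )
        if self.ordinal < 1:
            raise GeneModelError(f"exon ordinal must be >= 1, got {self.ordinal}")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """Canonical transcript of one gene with its kinase-domain interval."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[ExonInterval, ...]
    kinase_domain: tuple[int, int]

    kd_exon_ordinals: frozenset[int] = field(init=False)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise GeneModelError(f"{self.gene_id}: strand must be '+' or '-'")
        by_coord = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(by_coord, by_coord[1:]):
            if a.end > b.start:
                raise GeneModelError(
                    f"{self.gene_id}: exons {a.ordinal} and {b.ordinal} overlap"
                )
        ordinals = sorted(e.ordinal for e in self.exons)
        if ordinals != list(range(1, len(self.exons) + 1)):
            raise GeneModelError(
                f"{self.gene_id}: exon ordinals must be consecutive from 1, got {ordinals}"
            )
        kd_start, kd_end = self.kinase_domain
        if kd_start >= kd_end:
            raise GeneModelError(f"{self.gene_id}: empty kinase domain")
        if kd_start < self.span[0] or kd_end > self.span[1]:
            raise GeneModelError(
                f"{self.gene_id}: kinase domain {self.kinase_domain} outside "
                f"gene span {self.span}"
            )
        object.__setattr__(
            self,
            "kd_exon_ordinals",
            frozenset(
                e.ordinal
                for e in self.exons
                if overlap_length(e.interval, self.kinase_domain) > 0
            ),
        )
        if not self.kd_exon_ordinals:
            raise GeneModelError(
                f"{self.gene_id}: kinase domain intersects no exon"
            )

    @property
    def span(self) -> tuple[int, int]:
        """Genomic interval from first exon start to last exon end."""
        return (min(e.start for e in self.exons), max(e.end for e in self.exons))

    @property
    def exons_by_ordinal(self) -> dict[int, ExonInterval]:
        return {e.ordinal: e for e in self.exons}

    def exon(self, ordinal: int) -> ExonInterval:
        return self.exons_by_ordinal[ordinal]

    def kd_exonic_length(self) -> int:
        """Kinase-domain bases that fall inside exons."""
        return sum(
            overlap_length(e.interval, self.kinase_domain) for e in self.exons
        )


def kd_overlap_fraction(
    gene: GeneModel,
    intervals: Iterable[tuple[int, int] | ExonInterval],
    mode: str = "exonic",
) -> float:
    """Fraction of the kinase domain covered by the union of `intervals`.

    With ``mode="exonic"`` (default) both numerator and denominator are
    restricted to exonic bases of the gene: targeted panels only observe
    coverage over exons, so intronic kinase-domain bases carry no signal.
    ``mode="genomic"`` counts every base of the kinase-domain interval.
    """
    ivs = [iv.interval if isinstance(iv, ExonInterval) else tuple(iv) for iv in intervals]
    kd = gene.kinase_domain
    if mode == "genomic":
        denom = kd[1] - kd[0]
        num = covered_bases(ivs, kd)
    elif mode == "exonic":
        denom = gene.kd_exonic_length()
        if denom == 0:
            raise GeneModelError(
                f"{gene.gene_id}: kinase domain has no exonic bases"
            )
        merged = merge_intervals(ivs)
        num = 0
        for e in gene.exons:
            kd_in_exon = (max(e.start, kd[0]), min(e.end, kd[1]))
            if kd_in_exon[0] >= kd_in_exon[1]:
                continue
            num += covered_bases(merged, kd_in_exon)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if denom == 0:
        raise GeneModelError(f"{gene.gene_id}: empty kinase domain")
    return num / denom


# ---------------------------------------------------------------------------
# annotation I/O


def read_kd_annotations(path: str | Path) -> dict[str, tuple[int, int]]:
    """Read a kinase-domain table: columns gene_id, chrom, kd_start, kd_end."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene_id", "kd_start", "kd_end"}
    if not required.issubset(df.columns):
        raise GeneModelError(
            f"kinase-domain table must have columns {sorted(required)}"
        )
    return {
        str(r.gene_id): (int(r.kd_start), int(r.kd_end)) for r in df.itertuples()
    }


_GFF3_ATTR = re.compile(r"(\w+)=([^;]+)")


def _parse_gff3_attrs(s: str) -> dict[str, str]:
    return {m.group(1): m.group(2) for m in _GFF3_ATTR.finditer(s)}


def _load_gff3(path: str | Path) -> dict[str, dict]:
    """Collect exon rows per gene from a GFF3 file (one transcript per gene)."""
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GeneModelError(
                    f"{path}:{lineno}: expected 9 tab-separated fields"
                )
            chrom, _source, ftype, start, end, _score, strand, _phase, attrs = fields
            try:
                start_i, end_i = int(start) - 1, int(end)  # GFF3 is 1-based closed
            except ValueError as exc:
                raise GeneModelError(f"{path}:{lineno}: bad coordinates") from exc
            if ftype != "exon":
                continue
            a = _parse_gff3_attrs(attrs)
            gene_id = a.get("gene_id") or a.get("gene_name")
            if gene_id is None:
                raise GeneModelError(
                    f"{path}:{lineno}: exon record lacks gene_id attribute"
                )
            rec = genes.setdefault(
                gene_id,
                {
                    "chrom": chrom,
                    "strand": strand,
                    "transcript_id": a.get("transcript_id", f"{gene_id}.t1"),
                    "exons": [],
                },
            )
            if rec["chrom"] != chrom or rec["strand"] != strand:
                raise GeneModelError(
                    f"{path}:{lineno}: inconsistent chrom/strand for {gene_id}"
                )
            rec["exons"].append((start_i, end_i))
    return genes


def _load_bed12(path: str | Path) -> dict[str, dict]:
    """Collect exon rows per gene from a BED12 file (blocks = exons)."""
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise GeneModelError(f"{path}:{lineno}: BED12 needs 12 fields")
            try:
                chrom, chrom_start = f[0], int(f[1])
                name, strand = f[3], f[5]
                n_blocks = int(f[9])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                starts = [int(x) for x in f[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise GeneModelError(f"{path}:{lineno}: malformed BED12 record") from exc
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise GeneModelError(
                    f"{path}:{lineno}: blockCount disagrees with block lists"
                )
            genes[name] = {
                "chrom": chrom,
                "strand": strand,
                "transcript_id": f"{name}.t1",
                "exons": [
                    (chrom_start + off, chrom_start + off + size)
                    for off, size in zip(starts, sizes)
                ],
            }
    return genes


def load_gene_models(
    path: str | Path,
    kd_annotations: str | Path | Mapping[str, tuple[int, int]],
) -> dict[str, GeneModel]:
    """Load gene models from GFF3 or BED12 plus a kinase-domain table.

    Every gene named in `kd_annotations` must appear in the annotation file;
    genes without a kinase-domain entry are skipped.  Ordinals are assigned
    in transcript (strand-aware) order.
    """
    path = Path(path)
    if not isinstance(kd_annotations, Mapping):
        kd_annotations = read_kd_annotations(kd_annotations)
    if path.suffix.lower() in {".bed", ".bed12"}:
        raw = _load_bed12(path)
    else:
        raw = _load_gff3(path)
    missing = sorted(set(kd_annotations) - set(raw))
    if missing:
        raise GeneModelError(f"genes absent from {path}: {missing}")
    models: dict[str, GeneModel] = {}
    for gene_id, kd in kd_annotations.items():
        rec = raw[gene_id]
        exon_ivs = sorted(rec["exons"])
        if rec["strand"] == "-":
            ordered = list(reversed(exon_ivs))
        else:
            ordered = exon_ivs
        exons = tuple(
            ExonInterval(rec["chrom"], s, e, i)
            for i, (s, e) in enumerate(ordered, start=1)
        )
        models[gene_id] = GeneModel(
            gene_id=gene_id,
            transcript_id=rec["transcript_id"],
            chrom=rec["chrom"],
            strand=rec["strand"],
            exons=exons,
            kinase_domain=tuple(kd),
        )
    return models


def write_gene_models_gff3(models: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (gene + exon records, 1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(models, key=lambda m: (m.chrom, m.span[0])):
            s, e = g.span
            fh.write(
                f"{g.chrom}\tkddcall\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id};gene_id={g.gene_id}\n"
            )
            for ex in g.exons:
                fh.write(
                    f"{g.chrom}\tkddcall\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{g.strand}\t.\tParent={g.gene_id};gene_id={g.gene_id};"
                    f"transcript_id={g.transcript_id};exon_number={ex.ordinal}\n"
                )


def write_kd_annotations(
    models: Iterable[GeneModel] | Mapping[str, tuple[int, int]],
    path: str | Path,
    chroms: Mapping[str, str] | None = None,
) -> None:
    rows = []
    if isinstance(models, Mapping):
        for gid, (s, e) in models.items():
            rows.append((gid, (chroms or {}).get(gid, "."), s, e))
    else:
        for g in models:
            rows.append((g.gene_id, g.chrom, *g.kinase_domain))
    pd.DataFrame(rows, columns=["gene_id", "chrom", "kd_start", "kd_end"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# packaged reference annotation


def packaged_path(name: str) -> Path:
    """Path of a packaged data file."""
    return Path(resources.files("kddcall").joinpath("data", name))


def load_packaged_gene_models() -> dict[str, GeneModel]:
    """ERBB-family (EGFR/ERBB2/ERBB3/ERBB4) reference models, hg19-like.

    Coordinates are synthetic but respect the canonical exon counts and the
    fact that the EGFR kinase domain is encoded by exons 18-25.
    """
    return load_gene_models(
        packaged_path("erbb_gene_models.gff3"),
        packaged_path("erbb_kinase_domains.tsv"),
    )
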