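"""Genomic data model and file readers/writers.

Internal coordinates are 1-based inclusive (GTF convention). BED input is
converted at the boundary; writers invert the conversion so round-trips are
lossless. Readers are order-preserving and count every rejected record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "GenomicFeature",
    "DEResult",
    "CpGSite",
    "FilterConfig",
    "ReadStats",
    "RecordList",
    "GTFParseError",
    "SchemaError",
    "read_gtf",
    "write_gtf",
    "read_locus_bed",
    "write_locus_bed",
    "read_de_table",
    "write_de_table",
    "read_methylation_table",
]


class GTFParseError(ValueError):
    """A malformed annotation line; the message names the line number."""


class SchemaError(ValueError):
    """A tabular input is missing mandatory columns."""


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass(frozen=True)
class GenomicFeature:
    """A located, stranded interval: a gene or a retroelement locus.

    Coordinates are 1-based inclusive; ``tss`` is the strand-aware
    transcription start (start on "+", end on "-").
    """

    feature_id: str
    kind: str  # "gene" | "locus"
    chrom: str
    start: int
    end: int
    strand: str  # "+" | "-"
    biotype: Optional[str] = None
    tss: Optional[int] = None

    def __post_init__(self):
        if self.start < 1:
            raise ValueError(f"{self.feature_id}: start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"{self.feature_id}: end {self.end} < start {self.start}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.feature_id}: strand must be + or -, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicFeature") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )


@dataclass(frozen=True)
class DEResult:
    """One feature's differential expression from one tool for one subtype.

    ``pvalue``/``padj`` may be None (missing); missing significance always
    propagates as "not significant" downstream, never imputed.
    """

    feature_id: str
    log2fc: float
    pvalue: Optional[float] = None
    padj: Optional[float] = None
    tool: str = "generic"
    subtype: str = ""

    def __post_init__(self):
        for name in ("pvalue", "padj"):
            v = getattr(self, name)
            if v is not None and not _is_missing(v) and not (0.0 <= v <= 1.0):
                raise ValueError(f"{self.feature_id}: {name}={v} outside [0, 1]")


@dataclass(frozen=True)
class CpGSite:
    """One methylation probe with differential-methylation statistics.

    ``promoter_of`` is TSS200 membership from the array manifest;
    ``strand`` is the manifest probe strand, defaulting to "+" when the
    manifest does not provide one.
    """

    cpg_id: str
    chrom: str
    position: int
    meth_log2fc: float
    pvalue: Optional[float] = None
    padj: Optional[float] = None
    beta_tumor: Optional[float] = None
    beta_normal: Optional[float] = None
    promoter_of: frozenset = field(default_factory=frozenset)
    strand: str = "+"

    def __post_init__(self):
        for name in ("beta_tumor", "beta_normal"):
            v = getattr(self, name)
            if v is not None and not _is_missing(v) and not (0.0 <= v <= 1.0):
                raise ValueError(f"beta-value of site {self.cpg_id} outside [0, 1]: {v}")


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for methylation/expression pair filtering.

    All fold-change comparisons downstream are strict ("> min"); the
    significance comparisons are strict ("< alpha"). ``use_adjusted_*``
    select BH-adjusted vs raw p-values.
    """

    meth_lfc_min: float = 0.1
    meth_alpha: float = 0.05
    expr_lfc_min: float = 1.0
    expr_alpha: float = 0.05
    use_adjusted_meth_p: bool = True
    use_adjusted_expr_p: bool = True

    def __post_init__(self):
        if self.meth_lfc_min <= 0 or self.expr_lfc_min <= 0:
            raise ValueError("fold-change thresholds must be positive")
        for a in (self.meth_alpha, self.expr_alpha):
            if not (0.0 < a < 1.0):
                raise ValueError(f"alpha must be in (0, 1), got {a}")


@dataclass
class ReadStats:
    """Bookkeeping for one reader call: input rows == kept + rejected."""

    n_input: int = 0
    n_kept: int = 0
    n_rejected: int = 0
    warnings: list = field(default_factory=list)


class RecordList(list):
    """A list of records carrying the reader's :class:`ReadStats`."""

    def __init__(self, records: Iterable = (), stats: Optional[ReadStats] = None):
        super().__init__(records)
        self.stats = stats if stats is not None else ReadStats()


# ---------------------------------------------------------------------------
# GTF

_GTF_COLS = 9


def read_gtf(path, feature_kinds: Sequence[str] = ("gene",)) -> RecordList:
    """Read gene-level features from a GTF file.

    Captures gene_id, gene_name and gene_biotype attributes; the TSS is
    derived from the strand (start on "+", end on "-"). Records whose
    annotation type is not in ``feature_kinds`` are skipped silently;
    records with an unknown strand symbol are rejected and counted.
    """
    wanted = set(feature_kinds)
    stats = ReadStats()
    out = RecordList(stats=stats)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != _GTF_COLS:
                raise GTFParseError(
                    f"{path}: line {lineno}: expected {_GTF_COLS} tab-separated "
                    f"columns, found {len(parts)}"
                )
            chrom, _src, ftype, start_s, end_s, _score, strand, _frame, attrs = parts
            if ftype not in wanted:
                continue
            stats.n_input += 1
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise GTFParseError(
                    f"{path}: line {lineno}: non-integer coordinates "
                    f"{start_s!r}/{end_s!r}"
                ) from None
            if strand not in ("+", "-"):
                stats.n_rejected += 1
                stats.warnings.append(
                    f"line {lineno}: unknown strand {strand!r}, record rejected"
                )
                continue
            attr = _parse_gtf_attributes(attrs)
            fid = attr.get("gene_id")
            if fid is None:
                stats.n_rejected += 1
                stats.warnings.append(f"line {lineno}: missing gene_id, record rejected")
                continue
            try:
                feat = GenomicFeature(
                    feature_id=fid,
                    kind="gene",
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    biotype=attr.get("gene_biotype"),
                    tss=start if strand == "+" else end,
                )
            except ValueError as exc:
                stats.n_rejected += 1
                stats.warnings.append(f"line {lineno}: {exc}")
                continue
            stats.n_kept += 1
            out.append(feat)
    return out


def _parse_gtf_attributes(s: str) -> dict:
    attrs = {}
    for chunk in s.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " not in chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def write_gtf(features: Iterable[GenomicFeature], path) -> None:
    """Write features as GTF gene records (inverse of :func:`read_gtf`)."""
    with open(path, "w") as fh:
        for f in features:
            attrs = f'gene_id "{f.feature_id}";'
            if f.biotype is not None:
                attrs += f' gene_biotype "{f.biotype}";'
            fh.write(
                f"{f.chrom}\tretromethyl\tgene\t{f.start}\t{f.end}\t.\t"
                f"{f.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# BED


def read_locus_bed(path, kind: str = "locus") -> RecordList:
    """Read retroelement locus coordinates from a BED3+ file.

    BED is 0-based half-open; records are converted to the internal 1-based
    inclusive convention (start+1, end). A missing strand column defaults to
    "+" with a warning; zero-length intervals are rejected and counted.
    """
    stats = ReadStats()
    out = RecordList(stats=stats)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise GTFParseError(
                    f"{path}: line {lineno}: BED requires at least 3 columns"
                )
            stats.n_input += 1
            chrom = parts[0]
            try:
                bed_start, bed_end = int(parts[1]), int(parts[2])
            except ValueError:
                raise GTFParseError(
                    f"{path}: line {lineno}: non-integer BED coordinates"
                ) from None
            name = parts[3] if len(parts) > 3 else f"locus_{lineno}"
            if len(parts) > 5 and parts[5] in ("+", "-"):
                strand = parts[5]
            else:
                strand = "+"
                stats.warnings.append(
                    f"line {lineno}: missing strand, defaulting to '+'"
                )
            start, end = bed_start + 1, bed_end
            if start > end:
                stats.n_rejected += 1
                stats.warnings.append(
                    f"line {lineno}: zero-length or inverted interval rejected"
                )
                continue
            out.append(
                GenomicFeature(
                    feature_id=name, kind=kind, chrom=chrom,
                    start=start, end=end, strand=strand,
                )
            )
            stats.n_kept += 1
    return out


def write_locus_bed(features: Iterable[GenomicFeature], path) -> None:
    """Write features as BED6 (inverse of :func:`read_locus_bed`)."""
    with open(path, "w") as fh:
        for f in features:
            fh.write(
                f"{f.chrom}\t{f.start - 1}\t{f.end}\t{f.feature_id}\t0\t{f.strand}\n"
            )


# ---------------------------------------------------------------------------
# DE tables

DEFAULT_DE_COLUMNS = {
    "feature_id": "feature_id",
    "log2fc": "log2FoldChange",
    "pvalue": "pvalue",
    "padj": "padj",
}


def read_de_table(path, tool: str = "generic", subtype: str = "",
                  columns: Optional[dict] = None) -> RecordList:
    """Read a per-tool differential-expression table (TSV with header).

    ``columns`` maps the internal field names (feature_id, log2fc, pvalue,
    padj) to the column names in the file; defaults match common DESeq2
    exports. "NA"/empty cells become missing values, which downstream
    filters treat as not significant.
    """
    colmap = dict(DEFAULT_DE_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, sep="\t", dtype={colmap["feature_id"]: str})
    missing = [c for c in colmap.values() if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing mandatory column(s) {missing}; "
            f"found columns {list(df.columns)}"
        )
    stats = ReadStats(n_input=len(df), n_kept=len(df))
    out = RecordList(stats=stats)
    for row in df.itertuples(index=False):
        d = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        out.append(
            DEResult(
                feature_id=str(d[colmap["feature_id"]]),
                log2fc=float(d[colmap["log2fc"]]),
                pvalue=_none_if_nan(d[colmap["pvalue"]]),
                padj=_none_if_nan(d[colmap["padj"]]),
                tool=tool,
                subtype=subtype,
            )
        )
    return out


def write_de_table(results: Iterable[DEResult], path) -> None:
    df = pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in results],
            "log2FoldChange": [r.log2fc for r in results],
            "pvalue": [r.pvalue for r in results],
            "padj": [r.padj for r in results],
        }
    )
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def _none_if_nan(x) -> Optional[float]:
    if x is None:
        return None
    x = float(x)
    return None if math.isnan(x) else x


# ---------------------------------------------------------------------------
# Methylation + manifest

DEFAULT_METH_COLUMNS = {
    "cpg_id": "cpg_id",
    "log2fc": "log2FoldChange",
    "pvalue": "pvalue",
    "padj": "padj",
}


def read_methylation_table(path, manifest_path,
                           columns: Optional[dict] = None) -> RecordList:
    """Read a differential-methylation table and join it to a probe manifest.

    The manifest (TSV) maps cpg_id to chromosome, position, optional probe
    strand and semicolon-separated TSS200 gene ids. Sites absent from the
    manifest are kept only when the methylation table itself carries
    ``chrom``/``position`` columns; otherwise they are dropped and counted.
    Duplicate cpg_ids in the manifest raise an error.
    """
    colmap = dict(DEFAULT_METH_COLUMNS)
    if columns:
        colmap.update(columns)
    meth = pd.read_csv(path, sep="\t", dtype={colmap["cpg_id"]: str})
    missing = [c for c in colmap.values() if c not in meth.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing mandatory column(s) {missing}; "
            f"found columns {list(meth.columns)}"
        )
    man = pd.read_csv(manifest_path, sep="\t", dtype={"cpg_id": str})
    for c in ("cpg_id", "chrom", "position"):
        if c not in man.columns:
            raise SchemaError(f"{manifest_path}: manifest missing column {c!r}")
    if man["cpg_id"].duplicated().any():
        dupes = man.loc[man["cpg_id"].duplicated(), "cpg_id"].tolist()[:5]
        raise ValueError(f"{manifest_path}: duplicate cpg_id(s) in manifest: {dupes}")
    man = man.set_index("cpg_id")

    has_own_coords = "chrom" in meth.columns and "position" in meth.columns
    stats = ReadStats(n_input=len(meth))
    out = RecordList(stats=stats)
    for row in meth.itertuples(index=False):
        d = dict(zip(meth.columns, row))
        cid = str(d[colmap["cpg_id"]])
        promoter_of = frozenset()
        strand = "+"
        if cid in man.index:
            m = man.loc[cid]
            chrom, position = str(m["chrom"]), int(m["position"])
            tss200 = m.get("TSS200")
            if isinstance(tss200, str) and tss200:
                promoter_of = frozenset(g for g in tss200.split(";") if g)
            s = m.get("strand")
            if isinstance(s, str) and s in ("+", "-"):
                strand = s
        elif has_own_coords and not _is_missing(d.get("position")):
            chrom, position = str(d["chrom"]), int(d["position"])
        else:
            stats.n_rejected += 1
            stats.warnings.append(f"site {cid} absent from manifest, dropped")
            continue
        out.append(
            CpGSite(
                cpg_id=cid,
                chrom=chrom,
                position=position,
                meth_log2fc=float(d[colmap["log2fc"]]),
                pvalue=_none_if_nan(d[colmap["pvalue"]]),
                padj=_none_if_nan(d[colmap["padj"]]),
                beta_tumor=_none_if_nan(d.get("beta_tumor")),
                beta_normal=_none_if_nan(d.get("beta_normal")),
                promoter_of=promoter_of,
                strand=strand,
            )
        )
        stats.n_kept += 1
    return out
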