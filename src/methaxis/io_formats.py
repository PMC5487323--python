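"""Readers and writers for the per-cytosine count and interval formats.

The pipeline starts from per-cytosine methylated/unmethylated read
counts as emitted by bisulfite aligners (Bismark-style "coverage" and
"cytosine report" dialects), a CGI interval track (BED) and a minimal
gene model (gene + exon GTF lines, or BED12).

Coordinate conventions: per-cytosine inputs are 1-based; BED/GTF-derived
intervals are normalised to 0-based half-open internally. A site's
1-based position ``pos`` corresponds to the 0-based base ``pos - 1``.

Strand-specific counting is used throughout: the two cytosines of a CpG
dyad are separate sites and counts are never merged across strands.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._intervals import merge as _merge_intervals

CPG = "CpG"
CPH = "CpH"

#: canonical column order of a single-library site table
SITE_COLUMNS = ["chrom", "pos", "strand", "context", "m", "u"]

_CONTEXT_MAP = {
    "CpG": CPG,
    "CG": CPG,
    "CHG": CPH,
    "CHH": CPH,
    "CpH": CPH,
}


class ParseError(ValueError):
    """A malformed row in an input file; carries the 1-based line number."""


@dataclass(frozen=True)
class Interval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    label: str = ""

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(
                f"empty interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GeneModel:
    """One gene with ordered exons; TSS/TES are strand-normalised.

    ``start``/``end`` bound the gene body in genomic 0-based half-open
    coordinates. For a ``+`` gene the TSS is ``start`` and the TES is
    ``end``; for a ``-`` gene the 5' end (TSS) is at ``end`` and the TES
    at ``start``, so "upstream" always means 5' of the TSS.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        self.exons = [tuple(map(int, e)) for e in sorted(self.exons)]
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"gene {self.gene_id}: empty exon {s}-{e}")
            if s < self.start or e > self.end:
                raise ValueError(
                    f"gene {self.gene_id}: exon {s}-{e} outside gene span"
                )
        merged = _merge_intervals(self.exons) if self.exons else []
        if len(merged) != len(self.exons):
            raise ValueError(f"gene {self.gene_id}: overlapping exons")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start


def _validate_counts(df: pd.DataFrame, path) -> None:
    if (df["m"] < 0).any() or (df["u"] < 0).any():
        bad = df.index[(df["m"] < 0) | (df["u"] < 0)][0]
        raise ParseError(f"{path}: negative count at line {bad + 1}")
    if (df["pos"] < 1).any():
        bad = df.index[df["pos"] < 1][0]
        raise ParseError(f"{path}: position < 1 at line {bad + 1}")


def read_bismark_coverage(path) -> pd.DataFrame:
    """Read a Bismark ``.cov``-style file for one library.

    Columns: chrom, start, end, methylation percentage, count
    methylated, count unmethylated; positions 1-based. The percentage
    column is discarded and recomputed downstream from the counts. The
    dialect carries no strand or context, so strand is recorded as
    ``.`` and context as CpG (the contexts Bismark emits in this file).
    """
    try:
        df = pd.read_csv(
            path,
            sep=r"\s+",
            header=None,
            comment="#",
            names=["chrom", "pos", "end", "pct", "m", "u"],
            dtype={"chrom": str},
        )
    except (pd.errors.ParserError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if df.empty:
        return pd.DataFrame(columns=SITE_COLUMNS)
    for col in ("pos", "m", "u"):
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
            raise ParseError(f"{path}: malformed row at line {bad + 1}")
    _validate_counts(df, path)
    out = df[["chrom", "pos", "m", "u"]].copy()
    out["strand"] = "."
    out["context"] = CPG
    out["pos"] = out["pos"].astype(np.int64)
    return out[SITE_COLUMNS]


def read_cytosine_report(path) -> pd.DataFrame:
    """Read a Bismark per-cytosine report for one library.

    Columns: chrom, pos (1-based), strand, count methylated, count
    unmethylated, context (CpG/CHG/CHH), trinucleotide. CHG and CHH are
    both mapped to the CpH context; counts stay strand-specific (one
    site per (chrom, pos, strand)).
    """
    try:
        df = pd.read_csv(
            path,
            sep=r"\s+",
            header=None,
            comment="#",
            names=["chrom", "pos", "strand", "m", "u", "context", "tri"],
            dtype={"chrom": str, "strand": str, "context": str},
        )
    except (pd.errors.ParserError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if df.empty:
        return pd.DataFrame(columns=SITE_COLUMNS)
    unknown = ~df["context"].isin(_CONTEXT_MAP)
    if unknown.any():
        bad = df.loc[unknown, "context"].iloc[0]
        raise ParseError(f"{path}: unknown cytosine context {bad!r}")
    _validate_counts(df, path)
    out = df[["chrom", "pos", "strand", "m", "u"]].copy()
    out["context"] = df["context"].map(_CONTEXT_MAP)
    out["pos"] = out["pos"].astype(np.int64)
    return out[SITE_COLUMNS]


def combine_libraries(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Merge single-library tables into one wide multi-library table.

    Returns a frame keyed by (chrom, pos, strand, context) with columns
    ``m_<label>``/``u_<label>`` per library. A site absent from a
    library gets zero counts there (coverage 0, so it is removed by any
    positive coverage filter).
    """
    frames = []
    for label, df in tables.items():
        f = df.set_index(["chrom", "pos", "strand", "context"])[["m", "u"]]
        f.columns = [f"m_{label}", f"u_{label}"]
        frames.append(f)
    wide = pd.concat(frames, axis=1, join="outer").fillna(0)
    wide = wide.astype(np.int64).reset_index()
    return wide.sort_values(["chrom", "pos", "strand"]).reset_index(drop=True)


def library_labels(wide: pd.DataFrame) -> list[str]:
    """Library labels present in a wide multi-library site table."""
    return [c[2:] for c in wide.columns if c.startswith("m_")]


def read_bed(path, warn_overlaps: bool = True) -> list[Interval]:
    """Read BED3+ into sorted Intervals (0-based half-open).

    Overlapping input intervals are preserved; their number is reported
    through a warning so callers can decide whether to merge.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: fewer than 3 fields")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ParseError(
                    f"{path}: line {lineno}: start >= end ({start} >= {end})"
                )
            name = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 else "."
            out.append(Interval(chrom, start, end, strand, name))
    out.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    if warn_overlaps:
        n_overlap = sum(
            1
            for a, b in zip(out, out[1:])
            if a.chrom == b.chrom and b.start < a.end
        )
        if n_overlap:
            warnings.warn(
                f"{path}: {n_overlap} overlapping interval pair(s) preserved",
                stacklevel=2,
            )
    return out


_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def read_gene_models(path) -> list[GeneModel]:
    """Read gene models from minimal GTF (gene/exon lines) or BED12.

    GTF coordinates are 1-based inclusive and converted to 0-based
    half-open. Genes lacking an explicit ``gene`` line take their span
    from the union of their exons.
    """
    with open(path) as fh:
        first = ""
        for line in fh:
            if line.strip() and not line.startswith("#"):
                first = line
                break
    n_fields = len(first.rstrip("\n").split("\t"))
    if n_fields == 12:
        return _read_bed12(path)
    return _read_gtf(path)


def _read_gtf(path) -> list[GeneModel]:
    spans: dict[str, tuple[str, str, int, int]] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ParseError(f"{path}: line {lineno}: fewer than 9 fields")
            chrom, _, feat, start, end, _, strand = f[0], f[1], f[2], f[3], f[4], f[5], f[6]
            attrs = dict(_GTF_ATTR.findall(f[8]))
            gid = attrs.get("gene_id")
            if gid is None:
                raise ParseError(f"{path}: line {lineno}: no gene_id attribute")
            s, e = int(start) - 1, int(end)  # GTF is 1-based inclusive
            if feat == "gene":
                spans[gid] = (chrom, strand, s, e)
            elif feat == "exon":
                exons.setdefault(gid, []).append((s, e))
    genes = []
    for gid in spans.keys() | exons.keys():
        ex = sorted(exons.get(gid, []))
        if gid in spans:
            chrom, strand, s, e = spans[gid]
        else:
            # infer from exons; strand comes from any exon line (re-scan not
            # needed because minimal dialect repeats strand on every line)
            raise ParseError(f"gene {gid}: exon lines without a gene line")
        for xs, xe in ex:
            if xs < s or xe > e:
                raise ParseError(
                    f"gene {gid}: exon {xs}-{xe} outside gene span {s}-{e}"
                )
        if not ex:
            ex = [(s, e)]
        genes.append(GeneModel(gid, chrom, strand, s, e, ex))
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


def _read_bed12(path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ParseError(f"{path}: line {lineno}: not BED12")
            chrom, start, name, strand = f[0], int(f[1]), f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            ex = [(start + o, start + o + sz) for o, sz in zip(offsets, sizes)]
            genes.append(GeneModel(name, chrom, strand, start, int(f[2]), ex))
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


def write_site_table(wide: pd.DataFrame, path) -> None:
    """Write a multi-library site table as sorted TSV (round-trippable)."""
    out = wide.sort_values(["chrom", "pos", "strand"]).reset_index(drop=True)
    out.to_csv(path, sep="\t", index=False)


def read_site_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str})
    df["pos"] = df["pos"].astype(np.int64)
    return df


def write_bed(intervals, path, scores=None) -> None:
    """Write Intervals as BED; optional parallel score column (BED5)."""
    rows = list(intervals)
    paired = list(zip(rows, scores)) if scores is not None else [(iv, None) for iv in rows]
    paired.sort(key=lambda p: (p[0].chrom, p[0].start, p[0].end))
    with open(path, "w") as fh:
        for iv, score in paired:
            fields = [iv.chrom, str(iv.start), str(iv.end), iv.label or "."]
            if score is not None:
                fields.append(f"{score:.6g}")
            fh.write("\t".join(fields) + "\n")
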