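"""Binned meta-profiles along genes and CGIs, and 1-Mb window tracks.

Gene profiles use 20 + 40 + 20 bins for the 5-kb upstream flank, the
gene body and the 5-kb downstream flank; CGI profiles use 20 + 20 + 20
bins for the 2-kb flanks and the island core. Flank bins have fixed
width (250 bp for genes, 100 bp for CGIs); body bins scale with element
length. Gene bins run 5' to 3', so profiles of minus-strand genes are
mirrored before averaging.

Per-bin methylation is the mean tissue-level beta over all
(element, site) assignments in the bin; per-bin density is assigned
sites per element per base pair, making flank and body bins comparable
despite unequal widths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CPG, GeneModel, Interval

GENE_BINS = (20, 40, 20)
GENE_FLANK = 5000
CGI_BINS = (20, 20, 20)
CGI_FLANK = 2000


@dataclass
class MetaProfile:
    """Per-bin methylation and site density along scaled elements."""

    table: pd.DataFrame  # bin, segment, segment_bin, methylation, density, n_pairs
    mode: str  # "gene" or "cgi"
    context: str
    tissue: str
    n_elements: int
    stratum: str | None = None

    @property
    def n_bins(self) -> int:
        return len(self.table)

    def bins(self, segment: str, lo: int, hi: int) -> pd.DataFrame:
        """Rows of ``segment`` with 1-based segment-local bin in [lo, hi]."""
        t = self.table
        return t[(t["segment"] == segment) & t["segment_bin"].between(lo, hi)]


def _gene_bin(pos0: int, gene: GeneModel, n_up: int, n_body: int, n_down: int, flank: int):
    """Global bin index (0-based) of a site within one gene's span, or None."""
    w = flank // n_up
    length = gene.length
    if gene.strand == "+":
        if gene.start - flank <= pos0 < gene.start:  # upstream, far -> TSS
            d = gene.start - pos0
            return n_up - 1 - (d - 1) // w
        if gene.start <= pos0 < gene.end:  # body, 5' -> 3'
            rel = pos0 - gene.start
            return n_up + min(rel * n_body // length, n_body - 1)
        if gene.end <= pos0 < gene.end + flank:  # downstream
            d = pos0 - gene.end + 1
            return n_up + n_body + (d - 1) // w
    else:
        if gene.end <= pos0 < gene.end + flank:  # upstream of a minus gene
            d = pos0 - gene.end + 1
            return n_up - 1 - (d - 1) // w
        if gene.start <= pos0 < gene.end:
            rel = gene.end - 1 - pos0
            return n_up + min(rel * n_body // length, n_body - 1)
        if gene.start - flank <= pos0 < gene.start:
            d = gene.start - pos0
            return n_up + n_body + (d - 1) // w
    return None


def _cgi_bin(pos0: int, cgi: Interval, n_flank: int, n_core: int, flank: int):
    w = flank // n_flank
    if cgi.start - flank <= pos0 < cgi.start:
        d = cgi.start - pos0
        return n_flank - 1 - (d - 1) // w
    if cgi.start <= pos0 < cgi.end:
        rel = pos0 - cgi.start
        return n_flank + min(rel * n_core // cgi.length, n_core - 1)
    if cgi.end <= pos0 < cgi.end + flank:
        d = pos0 - cgi.end + 1
        return n_flank + n_core + (d - 1) // w
    return None


def _segment_labels(mode: str):
    if mode == "gene":
        n_up, n_body, n_down = GENE_BINS
        segs = ["up"] * n_up + ["body"] * n_body + ["down"] * n_down
    else:
        n_up, n_body, n_down = CGI_BINS
        segs = ["up"] * n_up + ["cgi"] * n_body + ["down"] * n_down
    seg_bin, counter = [], {}
    for s in segs:
        counter[s] = counter.get(s, 0) + 1
        seg_bin.append(counter[s])
    return segs, seg_bin


def build_meta_profile(
    elements,
    levels: pd.DataFrame,
    mode: str,
    tissue: str,
    context: str = CPG,
    stratum: str | None = None,
) -> MetaProfile:
    """Aggregate per-site tissue betas into a binned meta-profile.

    Each site falling inside an element's span (body plus flanks) is
    assigned to exactly one bin of that element; sites spanning two
    overlapping elements contribute to both. Bins with no assignments
    report methylation NaN (undefined, not zero) and density 0.
    """
    if mode not in ("gene", "cgi"):
        raise ValueError("mode must be 'gene' or 'cgi'")
    n_up, n_body, n_down = GENE_BINS if mode == "gene" else CGI_BINS
    flank = GENE_FLANK if mode == "gene" else CGI_FLANK
    total_bins = n_up + n_body + n_down

    sub = levels[levels["context"] == context]
    beta_col = f"beta_{tissue}"
    by_chrom = {}
    for chrom, grp in sub.groupby("chrom", sort=False):
        pos0 = grp["pos"].to_numpy() - 1
        order = np.argsort(pos0, kind="stable")
        by_chrom[chrom] = (pos0[order], grp[beta_col].to_numpy()[order])
    sums = np.zeros(total_bins)
    counts = np.zeros(total_bins, dtype=np.int64)
    body_widths = []
    n_elements = 0
    for el in elements:
        n_elements += 1
        chrom = el.chrom
        body_widths.append(el.length / n_body)
        if chrom not in by_chrom:
            continue
        pos0, beta = by_chrom[chrom]
        span_lo, span_hi = el.start - flank, el.end + flank
        lo = np.searchsorted(pos0, span_lo, side="left")
        hi = np.searchsorted(pos0, span_hi, side="left")
        for p, b in zip(pos0[lo:hi], beta[lo:hi]):
            if not np.isfinite(b):
                continue
            idx = (
                _gene_bin(int(p), el, n_up, n_body, n_down, flank)
                if mode == "gene"
                else _cgi_bin(int(p), el, n_up, n_body, flank)
            )
            if idx is not None:
                sums[idx] += b
                counts[idx] += 1

    with np.errstate(invalid="ignore"):
        meth = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    flank_w = flank / n_up
    mean_body_w = float(np.mean(body_widths)) if body_widths else np.nan
    widths = np.array([flank_w] * n_up + [mean_body_w] * n_body + [flank_w] * n_down)
    density = counts / max(n_elements, 1) / widths
    segs, seg_bin = _segment_labels(mode)
    table = pd.DataFrame(
        {
            "bin": np.arange(1, total_bins + 1),
            "segment": segs,
            "segment_bin": seg_bin,
            "methylation": meth,
            "density": density,
            "n_pairs": counts,
        }
    )
    return MetaProfile(table, mode, context, tissue, n_elements, stratum)


def _correlation_rows(profile: MetaProfile, which: str) -> pd.DataFrame:
    t = profile.table
    if which == "whole":
        return t
    if which == "cgi":
        if profile.mode != "cgi":
            raise ValueError("'cgi' range needs a CGI-mode profile")
        return t
    if profile.mode != "gene":
        raise ValueError(f"range {which!r} needs a gene-mode profile")
    if which == "tss":  # 10 upstream bins nearest the TSS + first 10 body bins
        return pd.concat([profile.bins("up", 11, 20), profile.bins("body", 1, 10)])
    if which == "tes":  # last 10 body bins + 10 downstream bins nearest the TES
        return pd.concat([profile.bins("body", 31, 40), profile.bins("down", 1, 10)])
    raise ValueError(f"unknown range {which!r}")


def profile_correlation(profile: MetaProfile, which: str = "whole"):
    """Pearson r of per-bin methylation vs density over a bin range.

    ``which``: "whole" (all bins), "tss"/"tes" (ten bins either side of
    the TSS/TES of a gene profile) or "cgi" (all bins of a CGI
    profile). Bins with undefined methylation are excluded pairwise.
    """
    rows = _correlation_rows(profile, which)
    ok = np.isfinite(rows["methylation"].to_numpy()) & np.isfinite(
        rows["density"].to_numpy()
    )
    x = rows.loc[ok, "methylation"].to_numpy()
    y = rows.loc[ok, "density"].to_numpy()
    if len(x) < 3:
        raise ValueError("fewer than 3 defined bins in range")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), int(len(x))


def stratified_profiles(
    strata: dict[str, list],
    levels: pd.DataFrame,
    mode: str,
    tissue: str,
    context: str = CPG,
) -> dict[str, MetaProfile]:
    """One meta-profile per stratum (e.g. CGI class or gene-CGI class).

    Empty strata are omitted. Strata that partition the element set
    recombine: the pair-weighted mean of strata bins equals the
    unstratified profile.
    """
    out = {}
    for name, elements in strata.items():
        if not elements:
            continue
        out[name] = build_meta_profile(elements, levels, mode, tissue, context, name)
    return out


def window_track(
    levels: pd.DataFrame,
    genes: list[GeneModel],
    chrom_sizes: dict[str, int],
    tissues: list[str],
    context: str = CPG,
    window: int = 1_000_000,
    gene_count_by: str = "start",
) -> pd.DataFrame:
    """Tile chromosomes with non-overlapping windows; mean beta + gene count.

    Window methylation is the mean tissue-level beta of covered sites
    in the window (NaN when no site); gene counts place each gene in
    the window containing its ``start`` (or its TSS with
    ``gene_count_by="tss"``). The last window of a chromosome may be
    shorter than ``window``.
    """
    rows = []
    sub = levels[levels["context"] == context]
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        grp = sub[sub["chrom"] == chrom]
        pos0 = grp["pos"].to_numpy() - 1
        edges = np.arange(0, size + window, window)
        edges[-1] = min(edges[-1], size)
        if edges[-1] == edges[-2]:
            edges = edges[:-1]
        widx = np.minimum(pos0 // window, len(edges) - 2) if len(pos0) else pos0
        anchor = {"start": lambda g: g.start, "tss": lambda g: g.tss}[gene_count_by]
        gpos = [anchor(g) for g in genes if g.chrom == chrom]
        for i, (s, e) in enumerate(zip(edges[:-1], edges[1:])):
            row = {"chrom": chrom, "start": int(s), "end": int(e)}
            in_win = widx == i
            for tissue in tissues:
                vals = grp[f"beta_{tissue}"].to_numpy()[in_win]
                vals = vals[np.isfinite(vals)]
                row[f"meth_{tissue}"] = float(np.mean(vals)) if len(vals) else np.nan
                row[f"n_sites_{tissue}"] = int(len(vals))
            row["gene_count"] = int(sum(s <= p < e for p in gpos))
            rows.append(row)
    return pd.DataFrame(rows)


def window_correlation(track: pd.DataFrame, col_a: str, col_b: str):
    """Pearson r between two window columns, NaN windows excluded pairwise."""
    x = track[col_a].to_numpy(dtype=float)
    y = track[col_b].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 jointly defined windows")
    r, p = stats.pearsonr(x[ok], y[ok])
    return float(r), float(p), int(ok.sum())
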