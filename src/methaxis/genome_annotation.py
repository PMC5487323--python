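"""Genic partition, CGI shores/shelves and CGI-to-feature localization.

The genome is partitioned into five genic features — upstream (5 kb 5'
of the TSS), exon, intron, downstream (5 kb 3' of the TES) and
intergenic — with every base carrying exactly one label. Where features
of different genes overlap, the fixed priority exon > intron > upstream
> downstream decides; intergenic is the complement.

CGI shores are the 2 kb flanks outside CGIs and shelves the next 2 kb
outside shores, trimmed with priority CGI > shore > shelf so the three
tracks are mutually disjoint.

A CGI is localized to the genic feature covering strictly more than
half of its length ("upstream CGI", "exonic CGI", ...); genes owning
that feature become the corresponding CGI-Upstream / CGI-Exon /
CGI-Intron / CGI-Downstream genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _intervals as iv
from .io_formats import GeneModel, Interval

GENIC_FEATURES = ["upstream", "exon", "intron", "downstream", "intergenic"]
CGI_FEATURES = ["cgi", "shore", "shelf"]


@dataclass
class FeatureMap:
    """Priority-resolved five-way genic partition of the genome.

    ``features[label][chrom]`` is a sorted, disjoint ``(N, 2)`` array;
    per chromosome the five labels tile ``[0, chrom_size)`` exactly.
    ``provenance[label][chrom]`` keeps the raw per-gene intervals
    (before priority resolution) so CGIs can be tied back to genes.
    """

    chrom_sizes: dict[str, int]
    features: dict[str, dict[str, np.ndarray]]
    provenance: dict[str, dict[str, list[Interval]]]
    flank: int = 5000

    def label_of(self, chrom: str, pos0: int) -> str:
        """Feature label of one 0-based position."""
        for label in GENIC_FEATURES:
            arr = self.features[label].get(chrom)
            if arr is not None and iv.positions_in(np.array([pos0]), arr)[0]:
                return label
        raise KeyError(f"{chrom}:{pos0} outside all features (unknown chrom?)")

    def intervals(self, label: str) -> list[Interval]:
        out = []
        for chrom in sorted(self.features[label]):
            for s, e in self.features[label][chrom]:
                out.append(Interval(chrom, int(s), int(e), ".", label))
        return out


@dataclass
class CGIFeatureSet:
    """CGIs with their shores (±2 kb) and shelves (next ±2 kb)."""

    cgis: dict[str, np.ndarray]
    shores: dict[str, np.ndarray]
    shelves: dict[str, np.ndarray]
    flank: int = 2000

    def intervals(self, label: str) -> list[Interval]:
        track = {"cgi": self.cgis, "shore": self.shores, "shelf": self.shelves}[label]
        return [
            Interval(chrom, int(s), int(e), ".", label)
            for chrom in sorted(track)
            for s, e in track[chrom]
        ]


@dataclass(frozen=True)
class CGIClass:
    """A CGI's assigned genic feature and per-feature overlap fractions."""

    cgi: Interval
    feature: str  # one of GENIC_FEATURES or "unassigned"
    fraction: float
    fractions: dict[str, float] = field(default_factory=dict, compare=False)


def _gene_feature_intervals(gene: GeneModel, flank: int):
    """Raw (pre-priority) feature intervals of one gene, unclipped."""
    exons = iv.merge(gene.exons)
    introns = iv.subtract([(gene.start, gene.end)], exons)
    if gene.strand == "+":
        upstream = [(gene.start - flank, gene.start)]
        downstream = [(gene.end, gene.end + flank)]
    else:
        upstream = [(gene.end, gene.end + flank)]
        downstream = [(gene.start - flank, gene.start)]
    return {
        "exon": exons,
        "intron": introns,
        "upstream": iv.as_array(upstream),
        "downstream": iv.as_array(downstream),
    }


def build_genic_features(
    genes: list[GeneModel],
    chrom_sizes: dict[str, int],
    flank: int = 5000,
) -> FeatureMap:
    """Partition each chromosome into the five genic features.

    Overlaps between different genes' features are resolved with the
    fixed priority exon > intron > upstream > downstream; the result is
    independent of gene input order. Intervals extending past the
    chromosome ends are clipped (with a warning for gene bodies).
    """
    raw: dict[str, dict[str, list]] = {
        lab: {c: [] for c in chrom_sizes} for lab in GENIC_FEATURES[:4]
    }
    prov: dict[str, dict[str, list[Interval]]] = {
        lab: {c: [] for c in chrom_sizes} for lab in GENIC_FEATURES[:4]
    }
    for gene in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
        size = chrom_sizes.get(gene.chrom)
        if size is None:
            raise KeyError(f"gene {gene.gene_id}: unknown chromosome {gene.chrom}")
        if gene.end > size:
            warnings.warn(
                f"gene {gene.gene_id} extends past end of {gene.chrom}; clipped",
                stacklevel=2,
            )
        for lab, arr in _gene_feature_intervals(gene, flank).items():
            arr = iv.clip(arr, size)
            for s, e in arr:
                raw[lab][gene.chrom].append((int(s), int(e)))
                prov[lab][gene.chrom].append(
                    Interval(gene.chrom, int(s), int(e), gene.strand, gene.gene_id)
                )

    features: dict[str, dict[str, np.ndarray]] = {lab: {} for lab in GENIC_FEATURES}
    for chrom, size in chrom_sizes.items():
        exon = iv.merge(raw["exon"][chrom])
        intron = iv.subtract(iv.merge(raw["intron"][chrom]), exon)
        genic = iv.merge(np.vstack([exon, intron]) if len(exon) + len(intron) else [])
        upstream = iv.subtract(iv.merge(raw["upstream"][chrom]), genic)
        taken = iv.merge(np.vstack([genic, upstream]) if len(genic) + len(upstream) else [])
        downstream = iv.subtract(iv.merge(raw["downstream"][chrom]), taken)
        all_taken = iv.merge(
            np.vstack([taken, downstream]) if len(taken) + len(downstream) else []
        )
        features["exon"][chrom] = exon
        features["intron"][chrom] = intron
        features["upstream"][chrom] = upstream
        features["downstream"][chrom] = downstream
        features["intergenic"][chrom] = iv.complement(all_taken, size)
    return FeatureMap(dict(chrom_sizes), features, prov, flank)


def build_cgi_features(
    cgis: list[Interval],
    chrom_sizes: dict[str, int] | None = None,
    flank: int = 2000,
) -> CGIFeatureSet:
    """Shores (±``flank`` outside CGIs) and shelves (next ±``flank``).

    Flanks of nearby CGIs are merged, then trimmed with priority
    CGI > shore > shelf, so the three tracks are pairwise disjoint.
    Everything is clipped at 0 and, when sizes are given, at the
    chromosome end.
    """
    by_chrom: dict[str, list] = {}
    for c in cgis:
        by_chrom.setdefault(c.chrom, []).append((c.start, c.end))
    cgi_t, shore_t, shelf_t = {}, {}, {}
    for chrom, arr in by_chrom.items():
        size = None if chrom_sizes is None else chrom_sizes.get(chrom)
        core = iv.merge(arr)
        ext1 = iv.merge([(s - flank, e + flank) for s, e in core])
        ext2 = iv.merge([(s - 2 * flank, e + 2 * flank) for s, e in core])
        shores = iv.subtract(ext1, core)
        shelves = iv.subtract(iv.subtract(ext2, ext1), core)
        if size is not None:
            core, shores, shelves = (
                iv.clip(core, size),
                iv.clip(shores, size),
                iv.clip(shelves, size),
            )
        else:
            core, shores, shelves = (
                iv.clip(core, 2**62),
                iv.clip(shores, 2**62),
                iv.clip(shelves, 2**62),
            )
        cgi_t[chrom], shore_t[chrom], shelf_t[chrom] = core, shores, shelves
    return CGIFeatureSet(cgi_t, shore_t, shelf_t, flank)


def classify_cgi(cgi: Interval, feature_map: FeatureMap) -> CGIClass:
    """Assign one CGI to the genic feature covering > 50% of its length.

    Fractions are computed against the priority-resolved partition, so
    they sum to exactly 1 for CGIs inside known chromosomes. An exact
    half-overlap (or an unknown chromosome) leaves the CGI unassigned.
    """
    if cgi.chrom not in feature_map.chrom_sizes:
        warnings.warn(f"CGI on unknown chromosome {cgi.chrom}", stacklevel=2)
        return CGIClass(cgi, "unassigned", 0.0, {})
    query = (cgi.start, cgi.end)
    fractions = {}
    for label in GENIC_FEATURES:
        arr = feature_map.features[label].get(cgi.chrom)
        ovl = iv.overlap_length(query, arr) if arr is not None else 0
        fractions[label] = ovl / cgi.length
    best = max(GENIC_FEATURES, key=lambda lab: fractions[lab])
    if fractions[best] > 0.5:
        return CGIClass(cgi, best, fractions[best], fractions)
    return CGIClass(cgi, "unassigned", fractions[best], fractions)


def classify_cgis(cgis: list[Interval], feature_map: FeatureMap) -> list[CGIClass]:
    return [classify_cgi(c, feature_map) for c in cgis]


def classify_genes_by_cgi(
    cgi_classes: list[CGIClass], feature_map: FeatureMap
) -> dict[str, set[str]]:
    """Gene sets keyed ``CGI-Upstream``/``CGI-Exon``/``CGI-Intron``/``CGI-Downstream``.

    Gene g joins ``CGI-F`` iff some CGI assigned to feature F overlaps
    one of g's raw F intervals. Sets are not mutually exclusive and
    intergenic/unassigned CGIs contribute to none.
    """
    out = {f"CGI-{lab.capitalize()}": set() for lab in GENIC_FEATURES[:4]}
    for cls in cgi_classes:
        if cls.feature not in ("upstream", "exon", "intron", "downstream"):
            continue
        key = f"CGI-{cls.feature.capitalize()}"
        for raw in feature_map.provenance[cls.feature].get(cls.cgi.chrom, []):
            if raw.start < cls.cgi.end and cls.cgi.start < raw.end:
                out[key].add(raw.label)
    return out


def is_cgi(seq: str, min_length: int = 200, min_gc: float = 0.5, min_oe: float = 0.6):
    """CpG-island predicate on a nucleotide string.

    True iff length > ``min_length``, GC fraction > ``min_gc`` and
    observed/expected CpG ratio > ``min_oe``, with the expected CpG
    count taken as ((C+G)/2)^2 / length (Gardiner-Garden & Frommer).
    Non-ACGT characters are excluded from the counts with a warning.
    Returns ``(verdict, diagnostics)``.
    """
    seq = seq.upper()
    clean = [b for b in seq if b in "ACGT"]
    if len(clean) != len(seq):
        warnings.warn(
            f"{len(seq) - len(clean)} non-ACGT characters ignored", stacklevel=2
        )
    n = len(clean)
    s = "".join(clean)
    c, g = s.count("C"), s.count("G")
    obs_cpg = s.count("CG")
    gc = (c + g) / n if n else 0.0
    expected = ((c + g) / 2) ** 2 / n if n else 0.0
    oe = obs_cpg / expected if expected > 0 else 0.0
    verdict = n > min_length and gc > min_gc and oe > min_oe
    return verdict, {
        "length": n,
        "gc": gc,
        "observed_cpg": obs_cpg,
        "expected_cpg": expected,
        "obs_exp_ratio": oe,
    }
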