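"""Synthetic multi-tissue RRBS data with known truth.

The generator emulates the structure of a reduced-representation
bisulfite experiment on a three-tissue, three-replicate design
(hypothalamus / pituitary / ovary): CpG sites come in clusters — dense
runs inside CpG islands and shorter MspI-fragment-like clusters in the
background — and per-site counts are beta-binomially distributed
around feature-dependent means (CGIs and upstream regions
hypomethylated, gene bodies and intergenic space hypermethylated, CpH
near zero). Coverage is negative-binomial. Tissue-specific
differential regions are planted as a mean shift over a run of
consecutive CpGs and recorded in a truth table, so DMC/DMR callers can
be scored against ground truth.

Fragment clustering approximates the site spacing RRBS produces; it
does not cut a real genome sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_annotation import build_cgi_features, build_genic_features
from .io_formats import CPG, CPH, GeneModel, Interval
from .methylation_core import Design
from . import _intervals as iv

DEFAULT_FEATURE_MEANS = {
    "cgi": 0.10,
    "upstream": 0.10,
    "exon": 0.65,
    "intron": 0.75,
    "downstream": 0.75,
    "intergenic": 0.75,
    "shore": 0.45,
    "shelf": 0.65,
}

# global-mean offsets mirroring the published tissue ordering:
# hypothalamus ~2 percentage points above pituitary, ovary just below it
DEFAULT_TISSUE_SHIFTS = {"hypothalamus": 0.02, "pituitary": 0.0, "ovary": -0.002}


@dataclass
class SimConfig:
    """All knobs of the generator; the seed fully determines the output."""

    seed: int = 0
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 2_000_000, "chr2": 1_500_000}
    )
    genes_per_mb: float = 30.0
    cgi_gene_fraction: float = 0.6  # genes given a promoter CGI
    cgi_other_per_mb: float = 12.0  # exonic/intronic/intergenic CGIs
    feature_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FEATURE_MEANS)
    )
    cph_mean: float = 0.006
    phi: float = 0.01  # beta-binomial dispersion
    coverage_mean: float = 30.0
    coverage_size: float = 5.0  # negative-binomial size parameter
    tissue_shifts: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TISSUE_SHIFTS)
    )
    n_replicates: int = 3
    n_planted_dmrs: int = 60
    planted_delta: float = 0.4
    cluster_gap_mean: float = 3000.0  # background fragment spacing
    cph_per_cluster: float = 2.0

    def design(self) -> Design:
        return Design.default(tuple(self.tissue_shifts), self.n_replicates)


@dataclass
class PlantedDMR:
    chrom: str
    start: int  # 1-based first affected CpG
    end: int  # 1-based last affected CpG
    tissue: str
    delta: float
    n_sites: int


@dataclass
class SimResult:
    config: SimConfig
    genes: list[GeneModel]
    cgis: list[Interval]
    sites: pd.DataFrame  # wide multi-library count table
    truth: pd.DataFrame
    planted: list[PlantedDMR]

    def design(self) -> Design:
        return self.config.design()

    def write(self, outdir) -> dict[str, Path]:
        """Emit GTF, CGI BED, per-library count files and the truth TSV.

        Per library both dialects are written: a Bismark-style coverage
        file (CpG sites) and a cytosine report (all sites, with strand
        and context).
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        gtf = outdir / "genes.gtf"
        with open(gtf, "w") as fh:
            for g in self.genes:
                attrs = f'gene_id "{g.gene_id}";'
                fh.write(
                    f"{g.chrom}\tsim\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
                )
                for s, e in g.exons:
                    fh.write(
                        f"{g.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                    )
        paths["genes"] = gtf
        bed = outdir / "cgis.bed"
        with open(bed, "w") as fh:
            for i, c in enumerate(self.cgis):
                fh.write(f"{c.chrom}\t{c.start}\t{c.end}\tCGI_{i + 1}\n")
        paths["cgis"] = bed

        df = self.sites
        for lib in self.design().libraries:
            m = df[f"m_{lib}"].to_numpy()
            u = df[f"u_{lib}"].to_numpy()
            n = m + u
            cov = outdir / f"{lib}.cov"
            cpg = (df["context"] == CPG).to_numpy() & (n > 0)
            with open(cov, "w") as fh:
                for chrom, pos, mi, ui in zip(
                    df.loc[cpg, "chrom"], df.loc[cpg, "pos"], m[cpg], u[cpg]
                ):
                    pct = 100.0 * mi / (mi + ui)
                    fh.write(f"{chrom}\t{pos}\t{pos}\t{pct:.6g}\t{mi}\t{ui}\n")
            rep = outdir / f"{lib}.cytosine_report.txt"
            with open(rep, "w") as fh:
                for chrom, pos, strand, ctx, mi, ui in zip(
                    df["chrom"], df["pos"], df["strand"], df["context"], m, u
                ):
                    bismark_ctx = "CpG" if ctx == CPG else "CHH"
                    tri = "CGG" if ctx == CPG else "CTA"
                    fh.write(
                        f"{chrom}\t{pos}\t{strand}\t{mi}\t{ui}\t{bismark_ctx}\t{tri}\n"
                    )
            paths[lib] = cov
        truth_path = outdir / "truth.tsv"
        self.truth.to_csv(truth_path, sep="\t", index=False)
        paths["truth"] = truth_path
        return paths


def _make_genes(rng: np.random.Generator, config: SimConfig) -> list[GeneModel]:
    genes = []
    gid = 0
    for chrom, size in config.chrom_sizes.items():
        n_target = int(config.genes_per_mb * size / 1e6)
        cursor = 12_000
        while len([g for g in genes if g.chrom == chrom]) < n_target:
            gap = int(rng.exponential(1.2e6 / max(config.genes_per_mb * 40, 1))) + 9_000
            start = cursor + gap
            n_exons = int(rng.integers(2, 7))
            exon_lens = rng.integers(200, 1_200, n_exons)
            intron_lens = rng.integers(600, 4_000, n_exons - 1)
            exons, pos = [], start
            for i, el in enumerate(exon_lens):
                exons.append((pos, pos + int(el)))
                pos += int(el)
                if i < n_exons - 1:
                    pos += int(intron_lens[i])
            end = pos
            if end + 12_000 > size:
                break
            gid += 1
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(f"G{gid:04d}", chrom, strand, start, end, exons))
            cursor = end
    return genes


def _make_cgis(rng, config, genes) -> list[Interval]:
    cgis = []
    for g in genes:
        if rng.random() < config.cgi_gene_fraction:
            length = int(rng.integers(500, 1_400))
            # promoter island straddling the TSS, mostly upstream of it
            if g.strand == "+":
                s = g.tss - int(0.8 * length)
            else:
                s = g.tss - int(0.2 * length)
            cgis.append(Interval(g.chrom, max(s, 0), max(s, 0) + length, ".", "cgi"))
    for chrom, size in config.chrom_sizes.items():
        n_other = int(config.cgi_other_per_mb * size / 1e6)
        chrom_genes = [g for g in genes if g.chrom == chrom]
        for _ in range(n_other):
            kind = rng.choice(["exon", "intron", "intergenic"], p=[0.3, 0.3, 0.4])
            length = int(rng.integers(400, 1_000))
            placed = None
            if kind == "exon" and chrom_genes:
                g = chrom_genes[rng.integers(len(chrom_genes))]
                big = [e for e in g.exons if e[1] - e[0] > length + 20]
                if big:
                    s, e = big[rng.integers(len(big))]
                    placed = int(rng.integers(s, e - length))
            elif kind == "intron" and chrom_genes:
                g = chrom_genes[rng.integers(len(chrom_genes))]
                introns = [
                    (a[1], b[0])
                    for a, b in zip(g.exons, g.exons[1:])
                    if b[0] - a[1] > length + 20
                ]
                if introns:
                    s, e = introns[rng.integers(len(introns))]
                    placed = int(rng.integers(s, e - length))
            else:
                placed = int(rng.integers(10_000, size - 10_000 - length))
            if placed is not None:
                cgis.append(Interval(chrom, placed, placed + length, ".", "cgi"))
    cgis.sort(key=lambda c: (c.chrom, c.start))
    return cgis


def _site_positions(rng, config, cgis):
    """CpG/CpH 0-based positions per chromosome, clustered."""
    out = {}
    for chrom, size in config.chrom_sizes.items():
        cpg, cph, cluster_id = [], [], []
        cid = 0
        # dense CpGs inside each island
        for c in (x for x in cgis if x.chrom == chrom):
            cid += 1
            p = c.start + int(rng.integers(2, 10))
            while p < c.end:
                cpg.append(p)
                cluster_id.append(cid)
                p += int(rng.integers(6, 25))
        # background MspI-fragment-like clusters
        p = 1_000
        while p < size - 1_000:
            p += int(rng.exponential(config.cluster_gap_mean)) + 120
            if p >= size - 1_000:
                break
            cid += 1
            n_sites = int(rng.integers(3, 11))
            q = p
            for _ in range(n_sites):
                cpg.append(q)
                cluster_id.append(cid)
                q += int(rng.integers(8, 40))
            n_cph = rng.poisson(config.cph_per_cluster)
            for _ in range(n_cph):
                cph.append(p + int(rng.integers(0, max(q - p, 1))))
        out[chrom] = (np.array(sorted(set(cpg))), np.array(sorted(set(cph))), cluster_id)
    return out


def _beta_binomial(rng, n, mu, phi):
    """m ~ BetaBinomial(n, mu, phi); phi=0 degenerates to binomial."""
    mu = np.clip(mu, 1e-4, 1 - 1e-4)
    if phi <= 0:
        return rng.binomial(n, mu)
    conc = 1.0 / phi - 1.0
    p = rng.beta(mu * conc, (1.0 - mu) * conc)
    return rng.binomial(n, p)


def simulate(config: SimConfig | None = None) -> SimResult:
    """Generate gene models, CGIs, nine count libraries and the truth.

    Deterministic in ``config.seed``; rerunning with the same config
    reproduces the result (and :meth:`SimResult.write` output)
    byte-for-byte.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    genes = _make_genes(rng, config)
    cgis = _make_cgis(rng, config, genes)
    fmap = build_genic_features(genes, config.chrom_sizes)
    cgi_set = build_cgi_features(cgis, config.chrom_sizes)

    positions = _site_positions(rng, config, cgis)

    chrom_col, pos_col, strand_col, ctx_col, feat_col = [], [], [], [], []
    for chrom in sorted(config.chrom_sizes):
        cpg, cph, _ = positions[chrom]
        lookup_tracks = [
            ("cgi", cgi_set.cgis.get(chrom)),
            ("shore", cgi_set.shores.get(chrom)),
            ("shelf", cgi_set.shelves.get(chrom)),
            ("upstream", fmap.features["upstream"].get(chrom)),
            ("exon", fmap.features["exon"].get(chrom)),
            ("intron", fmap.features["intron"].get(chrom)),
            ("downstream", fmap.features["downstream"].get(chrom)),
        ]

        def feature_of(parr):
            lab = np.full(len(parr), "intergenic", dtype=object)
            undecided = np.ones(len(parr), dtype=bool)
            for name, arr in lookup_tracks:
                if arr is None or len(arr) == 0:
                    continue
                hit = iv.positions_in(parr, arr) & undecided
                lab[hit] = name
                undecided &= ~hit
            return lab

        for parr, ctx in ((cpg, CPG), (cph, CPH)):
            chrom_col.extend([chrom] * len(parr))
            pos_col.extend((parr + 1).tolist())  # 1-based
            strand_col.extend(
                rng.choice(["+", "-"], size=len(parr)).tolist()
                if ctx == CPH
                else ["+"] * len(parr)
            )
            ctx_col.extend([ctx] * len(parr))
            feat_col.extend(feature_of(parr).tolist())

    sites = pd.DataFrame(
        {
            "chrom": chrom_col,
            "pos": np.array(pos_col, dtype=np.int64),
            "strand": strand_col,
            "context": ctx_col,
            "feature": feat_col,
        }
    ).sort_values(["chrom", "pos", "strand"]).reset_index(drop=True)

    tissues = list(config.tissue_shifts)
    base_mu = np.where(
        sites["context"].to_numpy() == CPH,
        config.cph_mean,
        pd.Series(sites["feature"]).map(config.feature_means).to_numpy(dtype=float),
    )
    mu = {}
    for t in tissues:
        shift = np.where(sites["context"].to_numpy() == CPG, config.tissue_shifts[t], 0.0)
        mu[t] = np.clip(base_mu + shift, 0.002, 0.998)

    planted = _plant_dmrs(rng, config, sites, mu, tissues)

    design = config.design()
    n_sites = len(sites)
    for tissue in tissues:
        for r in range(config.n_replicates):
            lib = f"{tissue}_{r + 1}"
            n = rng.negative_binomial(
                config.coverage_size,
                config.coverage_size / (config.coverage_size + config.coverage_mean),
                n_sites,
            )
            m = _beta_binomial(rng, n, mu[tissue], config.phi)
            sites[f"m_{lib}"] = m.astype(np.int64)
            sites[f"u_{lib}"] = (n - m).astype(np.int64)

    truth = sites[["chrom", "pos", "strand", "context", "feature"]].copy()
    for t in tissues:
        truth[f"mu_{t}"] = mu[t]
    dmr_id = np.zeros(n_sites, dtype=np.int64)
    for k, d in enumerate(planted, 1):
        sel = (
            (truth["chrom"] == d.chrom)
            & (truth["pos"] >= d.start)
            & (truth["pos"] <= d.end)
            & (truth["context"] == CPG)
        )
        dmr_id[sel.to_numpy()] = k
    truth["planted_dmr"] = dmr_id
    for a_i in range(len(tissues)):
        for b_i in range(a_i + 1, len(tissues)):
            a, b = tissues[a_i], tissues[b_i]
            truth[f"true_dmc_{a}_vs_{b}"] = np.abs(mu[a] - mu[b]) > 0.2

    site_cols = ["chrom", "pos", "strand", "context"] + [
        c for c in sites.columns if c.startswith(("m_", "u_"))
    ]
    return SimResult(config, genes, cgis, sites[site_cols].copy(), truth, planted)


def _plant_dmrs(rng, config, sites, mu, tissues) -> list[PlantedDMR]:
    """Shift one tissue's mean by +-delta over runs of consecutive CpGs.

    Runs are picked from background (non-island) clusters with at least
    five CpGs spanning more than 50 bp — islands are left untouched,
    mirroring their observed protection from methylation dynamics — so
    each planted region is callable under the >=3-DMC / >50-bp rule;
    infeasible configs (no such cluster left) raise before any counts
    are drawn.
    """
    cpg_mask = (sites["context"] == CPG).to_numpy()
    feature = sites["feature"].to_numpy()
    planted: list[PlantedDMR] = []
    if config.n_planted_dmrs == 0:
        return planted
    idx_all = np.flatnonzero(cpg_mask)
    pos = sites["pos"].to_numpy()
    chrom = sites["chrom"].to_numpy()
    # candidate runs: consecutive CpG sites within 100 bp of each other
    runs = []
    start = 0
    for i in range(1, len(idx_all) + 1):
        end_of_run = (
            i == len(idx_all)
            or chrom[idx_all[i]] != chrom[idx_all[i - 1]]
            or pos[idx_all[i]] - pos[idx_all[i - 1]] > 100
        )
        if end_of_run:
            seg = idx_all[start:i]
            if (
                len(seg) >= 5
                and pos[seg[-1]] - pos[seg[0]] + 1 > 50
                and not (feature[seg] == "cgi").any()
            ):
                runs.append(seg)
            start = i
    rng.shuffle(runs)
    usable = runs
    if len(usable) < config.n_planted_dmrs:
        raise ValueError(
            f"only {len(usable)} plantable clusters for "
            f"{config.n_planted_dmrs} requested DMRs"
        )
    for k in range(config.n_planted_dmrs):
        seg = usable[k]
        tissue = tissues[k % len(tissues)]
        base = float(np.mean(mu[tissue][seg]))
        sign = -1.0 if base > 0.5 else 1.0
        delta = sign * config.planted_delta
        mu[tissue][seg] = np.clip(mu[tissue][seg] + delta, 0.02, 0.98)
        planted.append(
            PlantedDMR(
                chrom[seg[0]],
                int(pos[seg[0]]),
                int(pos[seg[-1]]),
                tissue,
                delta,
                len(seg),
            )
        )
    return planted


def evaluate_calls(
    truth: pd.DataFrame,
    dmc_records: pd.DataFrame,
    dmrs,
    pair: tuple[str, str],
    planted: list[PlantedDMR] | None = None,
) -> dict:
    """Score called DMCs/DMRs against the generator truth.

    Site-level precision/recall compares the caller's ``is_dmc`` flag
    with the true-mean difference rule for the tissue pair; DMR recall
    is the fraction of planted regions relevant to the pair overlapped
    (>= 1 bp) by at least one called DMR. Precision of an empty call
    set is undefined (NaN).
    """
    a, b = pair
    col = (
        f"true_dmc_{a}_vs_{b}"
        if f"true_dmc_{a}_vs_{b}" in truth.columns
        else f"true_dmc_{b}_vs_{a}"
    )
    key = ["chrom", "pos", "strand", "context"]
    merged = dmc_records.merge(
        truth[key + [col]], on=key, how="left", validate="one_to_one"
    )
    called = merged["is_dmc"].to_numpy(dtype=bool)
    true = merged[col].to_numpy(dtype=bool)
    tp = int((called & true).sum())
    precision = tp / called.sum() if called.sum() else float("nan")
    recall = tp / true.sum() if true.sum() else float("nan")
    out = {
        "n_called": int(called.sum()),
        "n_true": int(true.sum()),
        "dmc_precision": float(precision),
        "dmc_recall": float(recall),
    }
    if planted is not None:
        relevant = [d for d in planted if d.tissue in pair]
        hit = 0
        for d in relevant:
            for r in dmrs:
                if r.chrom == d.chrom and r.start <= d.end and d.start <= r.end:
                    hit += 1
                    break
        out["n_planted_dmrs"] = len(relevant)
        out["dmr_recall"] = hit / len(relevant) if relevant else float("nan")
    return out
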