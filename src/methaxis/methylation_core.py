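"""Per-site and per-region methylation levels, filtering and QC.

A cytosine's methylation level in one library is beta = m / (m + u),
methylated reads over total covered reads. A tissue's level at a site
is the arithmetic mean of its replicates' beta values (not pooled
counts). A region's level in a tissue is the unweighted mean of the
tissue-level betas of the covered sites inside it.

Sites enter the analysis only if covered by at least ``min_coverage``
reads in every library, so tissue means are always full-replicate
means ("covered by at least five reads and co-present everywhere").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CPG, CPH, Interval, library_labels

#: default library design: 3 tissues x 3 replicates
DEFAULT_TISSUES = ("hypothalamus", "pituitary", "ovary")


@dataclass(frozen=True)
class Design:
    """Mapping from tissue name to its replicate library labels."""

    tissues: dict[str, tuple[str, ...]]

    @classmethod
    def default(cls, tissues=DEFAULT_TISSUES, n_replicates: int = 3) -> "Design":
        return cls({t: tuple(f"{t}_{i + 1}" for i in range(n_replicates)) for t in tissues})

    @property
    def libraries(self) -> list[str]:
        return [lib for libs in self.tissues.values() for lib in libs]


def filter_sites(
    wide: pd.DataFrame, min_coverage: int = 5, libraries: list[str] | None = None
) -> pd.DataFrame:
    """Keep sites with coverage >= ``min_coverage`` in every library."""
    libs = libraries if libraries is not None else library_labels(wide)
    if not libs:
        raise ValueError("no libraries in site table")
    mask = np.ones(len(wide), dtype=bool)
    for lib in libs:
        mask &= (wide[f"m_{lib}"].to_numpy() + wide[f"u_{lib}"].to_numpy()) >= min_coverage
    return wide.loc[mask].reset_index(drop=True)


def retained_counts(wide: pd.DataFrame) -> dict[str, int]:
    """Site tally per context (CpG / CpH)."""
    return wide["context"].value_counts().to_dict()


def add_levels(wide: pd.DataFrame, design: Design) -> pd.DataFrame:
    """Append per-library ``beta_<lib>`` and per-tissue ``beta_<tissue>``.

    Per-library level is m/(m+u); tissue level is the mean of replicate
    levels. Libraries with zero coverage yield NaN (never the case
    after :func:`filter_sites`).
    """
    out = wide.copy()
    for tissue, libs in design.tissues.items():
        reps = []
        for lib in libs:
            m = out[f"m_{lib}"].to_numpy(dtype=float)
            n = m + out[f"u_{lib}"].to_numpy(dtype=float)
            with np.errstate(invalid="ignore", divide="ignore"):
                beta = np.where(n > 0, m / n, np.nan)
            out[f"beta_{lib}"] = beta
            reps.append(beta)
        out[f"beta_{tissue}"] = np.mean(np.vstack(reps), axis=0)
    return out


def region_level(
    region: Interval, levels: pd.DataFrame, tissue: str, context: str = CPG
) -> tuple[float, int]:
    """Unweighted mean tissue-level beta over covered sites in a region.

    Returns ``(level, n_sites)``; an empty region gives ``(nan, 0)`` and
    is excluded from downstream means.
    """
    pos0 = levels["pos"].to_numpy() - 1
    mask = (
        (levels["chrom"] == region.chrom).to_numpy()
        & (pos0 >= region.start)
        & (pos0 < region.end)
        & (levels["context"] == context).to_numpy()
    )
    vals = levels.loc[mask, f"beta_{tissue}"].to_numpy()
    if len(vals) == 0:
        return float("nan"), 0
    return float(np.mean(vals)), int(len(vals))


def region_levels(
    regions: list[Interval], levels: pd.DataFrame, tissue: str, context: str = CPG
) -> pd.DataFrame:
    """Vectorised :func:`region_level` over many regions (one tissue)."""
    rows = []
    for r in regions:
        lv, n = region_level(r, levels, tissue, context)
        rows.append((r.chrom, r.start, r.end, r.label, lv, n))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "label", "level", "n_sites"]
    )


def conversion_rate(wide: pd.DataFrame, library: str) -> dict[str, float]:
    """Bisulfite conversion QC from CpH sites of one library.

    Non-conversion = sum(m) / sum(m + u) over covered CpH cytosines
    (CpHs are assumed unmethylated, so methylated calls there are
    conversion failures); efficiency = 100 * (1 - non-conversion).
    """
    cph = wide[wide["context"] == CPH]
    m = cph[f"m_{library}"].to_numpy(dtype=float)
    n = m + cph[f"u_{library}"].to_numpy(dtype=float)
    covered = n > 0
    if not covered.any():
        warnings.warn(f"{library}: no covered CpH sites", stacklevel=2)
        return {"non_conversion": float("nan"), "efficiency_pct": float("nan")}
    nc = m[covered].sum() / n[covered].sum()
    return {"non_conversion": float(nc), "efficiency_pct": float(100 * (1 - nc))}


DEFAULT_BANDS = (0.0, 0.2, 0.6, 0.9, 1.0)


def level_histogram(betas, bands=DEFAULT_BANDS) -> pd.Series:
    """Fraction of sites per methylation band.

    Bands are left-closed ([0, 20%), [20, 60%), [60, 90%)) with the last
    band closed at 100%. Fractions sum to exactly 1 over finite inputs.
    """
    vals = np.asarray(betas, dtype=float)
    vals = vals[np.isfinite(vals)]
    edges = np.asarray(bands, dtype=float)
    counts, _ = np.histogram(vals, bins=edges)
    labels = [
        f"[{100 * a:g},{100 * b:g})" if i < len(edges) - 2 else f"[{100 * a:g},{100 * b:g}]"
        for i, (a, b) in enumerate(zip(edges, edges[1:]))
    ]
    frac = counts / counts.sum() if counts.sum() else counts.astype(float)
    return pd.Series(frac, index=labels, name="fraction")


@dataclass(frozen=True)
class TwoSampleTest:
    statistic: float
    pvalue: float
    welch_statistic: float
    welch_pvalue: float
    n_a: int
    n_b: int
    significant_05: bool = field(init=False)
    significant_01: bool = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "significant_05", self.welch_pvalue < 0.05)
        object.__setattr__(self, "significant_01", self.welch_pvalue < 0.01)


def compare_feature_levels(levels_a, levels_b) -> TwoSampleTest:
    """Two-sided two-sample t-test between region-level methylation sets.

    The Welch (unequal-variance) form drives the significance flags;
    the classical equal-variance statistic is reported alongside.
    NaN region levels (empty regions) are dropped.
    """
    a = np.asarray(levels_a, dtype=float)
    b = np.asarray(levels_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two regions per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        # identical constant samples: no evidence of difference
        return TwoSampleTest(0.0, 1.0, 0.0, 1.0, len(a), len(b))
    student = stats.ttest_ind(a, b, equal_var=True)
    welch = stats.ttest_ind(a, b, equal_var=False)
    return TwoSampleTest(
        float(student.statistic),
        float(student.pvalue),
        float(welch.statistic),
        float(welch.pvalue),
        len(a),
        len(b),
    )


def global_summary(levels: pd.DataFrame, design: Design) -> pd.DataFrame:
    """Mean tissue-level methylation (%) per context and tissue."""
    rows = []
    for context in (CPG, CPH):
        sub = levels[levels["context"] == context]
        for tissue in design.tissues:
            vals = sub[f"beta_{tissue}"].to_numpy()
            rows.append(
                {
                    "context": context,
                    "tissue": tissue,
                    "mean_pct": float(100 * np.nanmean(vals)) if len(vals) else float("nan"),
                    "n_sites": int(len(vals)),
                }
            )
    return pd.DataFrame(rows)
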