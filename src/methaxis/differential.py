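"""Differential methylation: constitutive classes, Wald test, DMCs,
DMR merging and genomic-feature enrichment.

The two-group test is a beta-binomial Wald test. Group means are
pooled-count proportions p_g = sum(m)/sum(n); a common dispersion phi
is estimated per site by method of moments across replicates (pooled
over the two groups, floored at 0), giving

    Var(p_g) = sum_i n_i p_g (1 - p_g) [1 + (n_i - 1) phi] / (sum_i n_i)^2
    Z = (p_1 - p_2) / sqrt(V_1 + V_2)

with a two-sided normal p-value. A site is a DMC when the methylation
difference exceeds 20 percentage points (strict) and P <= 0.01
(inclusive). DMRs are maximal runs of at least three consecutive
tested CpGs that are all DMCs of the same sign and span more than
50 bp. Feature enrichment is a two-tailed Fisher's exact test on the
2x2 table of DMC membership inside vs outside the feature among all
tested sites; both the sample odds ratio ad/bc and the conditional
maximum-likelihood odds ratio are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _cmle_odds_ratio

from . import _intervals as iv
from .io_formats import CPG, Interval


# ---------------------------------------------------------------------------
# constitutive hypo/hyper classification
# ---------------------------------------------------------------------------

def classify_constitutive(
    levels: pd.DataFrame,
    tissues: list[str],
    hypo: float = 0.20,
    hyper: float = 0.80,
) -> pd.Series:
    """Label each site HypoC / HyperC / neither across tissues.

    HypoC: tissue-level methylation <= ``hypo`` in every tissue;
    HyperC: >= ``hyper`` in every tissue (both bounds inclusive).
    Sites with a missing tissue level are excluded (label NaN).
    """
    betas = np.vstack([levels[f"beta_{t}"].to_numpy(dtype=float) for t in tissues])
    out = np.full(betas.shape[1], "neither", dtype=object)
    valid = np.isfinite(betas).all(axis=0)
    out[valid & (betas <= hypo).all(axis=0)] = "HypoC"
    out[valid & (betas >= hyper).all(axis=0)] = "HyperC"
    out[~valid] = None
    return pd.Series(out, index=levels.index, name="constitutive")


# ---------------------------------------------------------------------------
# beta-binomial Wald test
# ---------------------------------------------------------------------------

def _group_arrays(wide: pd.DataFrame, libs: list[str]):
    m = np.column_stack([wide[f"m_{l}"].to_numpy(dtype=float) for l in libs])
    n = m + np.column_stack([wide[f"u_{l}"].to_numpy(dtype=float) for l in libs])
    return m, n


def _moment_dispersion_parts(m, n, p):
    """Per-site numerator/denominator of the moment dispersion estimator.

    Within one group, with replicate proportions p_i = m_i/n_i and the
    pooled mean p = sum(m)/sum(n), the weighted residual sum
    S = sum_i n_i (p_i - p)^2 has expectation

        p q [ (k - 1) + phi (N - k - sum(n_i^2)/N + 1) ]

    so phi is estimated as a ratio of (S/pq - (k-1)) over the bracket
    scale. Returning the two parts lets callers pool the ratio over
    groups (and, for the common estimate, over sites).
    """
    k = m.shape[1]
    N = n.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(n > 0, m / np.maximum(n, 1), 0.0)
    S = (n * (pi - p[:, None]) ** 2).sum(axis=1)
    pq = p * (1.0 - p)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = np.where(pq > 0, S / np.where(pq > 0, pq, 1.0) - (k - 1), 0.0)
    den = np.where(pq > 0, N - k - (n**2).sum(axis=1) / N + 1, 0.0)
    return num, den


def wald_test(
    wide: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    dispersion: str = "common",
) -> pd.DataFrame:
    """Vectorised per-site beta-binomial Wald test between two groups.

    Returns one row per input site: pooled group means ``p1``/``p2``,
    difference ``delta`` = p1 - p2, the moment dispersion ``phi``, the
    Wald statistic ``z`` and the two-sided ``p``.

    ``dispersion="common"`` (default) estimates a single shared phi by
    pooling the moment estimator over both groups and all sites —
    with few replicates the per-site moments are far too noisy and
    make the test anti-conservative. ``dispersion="per-site"`` keeps
    each site's own (group-pooled) estimate.

    Degenerate sites (both groups all-0 or all-1) give z = 0, p = 1;
    all-or-nothing sites with unequal means fall back to 0.5
    pseudo-counts on each group's pooled totals and are marked in
    ``pseudo``.
    """
    if dispersion not in ("common", "per-site"):
        raise ValueError("dispersion must be 'common' or 'per-site'")
    m1, n1 = _group_arrays(wide, group_a)
    m2, n2 = _group_arrays(wide, group_b)
    N1, N2 = n1.sum(axis=1), n2.sum(axis=1)
    if (N1 == 0).any() or (N2 == 0).any():
        raise ValueError("zero total coverage in a group; filter sites first")
    p1, p2 = m1.sum(axis=1) / N1, m2.sum(axis=1) / N2

    num_a, den_a = _moment_dispersion_parts(m1, n1, p1)
    num_b, den_b = _moment_dispersion_parts(m2, n2, p2)
    num, den = num_a + num_b, den_a + den_b
    if dispersion == "common":
        total_den = den.sum()
        common = num.sum() / total_den if total_den > 0 else 0.0
        phi = np.full(len(wide), np.clip(common, 0.0, 1.0))
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            phi = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        phi = np.clip(phi, 0.0, 1.0)

    def group_var(n, p, phi):
        q = 1.0 - p
        return ((n * (p * q)[:, None] * (1.0 + (n - 1.0) * phi[:, None])).sum(axis=1)) / (
            n.sum(axis=1) ** 2
        )

    v1, v2 = group_var(n1, p1, phi), group_var(n2, p2, phi)
    var = v1 + v2
    delta = p1 - p2

    pseudo = (var == 0) & (delta != 0)
    if pseudo.any():
        # all-or-nothing counts: soften pooled totals by half a read each way
        p1s = (m1.sum(axis=1) + 0.5) / (N1 + 1.0)
        p2s = (m2.sum(axis=1) + 0.5) / (N2 + 1.0)
        v1s = p1s * (1 - p1s) / (N1 + 1.0)
        v2s = p2s * (1 - p2s) / (N2 + 1.0)
        var = np.where(pseudo, v1s + v2s, var)

    z = np.zeros(len(wide))
    nz = var > 0
    z[nz] = delta[nz] / np.sqrt(var[nz])
    p = np.where(nz, 2.0 * stats.norm.sf(np.abs(z)), 1.0)

    out = wide[["chrom", "pos", "strand", "context"]].copy()
    out["p1"], out["p2"], out["delta"] = p1, p2, delta
    out["phi"], out["z"], out["p"] = phi, z, p
    out["pseudo"] = pseudo
    return out


def call_dmcs(
    records: pd.DataFrame, delta: float = 0.20, alpha: float = 0.01
) -> pd.DataFrame:
    """Flag DMCs: |difference| strictly above ``delta`` and p <= ``alpha``."""
    out = records.copy()
    out["is_dmc"] = (np.abs(out["delta"].to_numpy()) > delta) & (
        out["p"].to_numpy() <= alpha
    )
    return out


@dataclass(frozen=True)
class DMRRecord:
    chrom: str
    start: int  # 1-based position of the first member DMC
    end: int  # 1-based position of the last member DMC
    n_dmcs: int
    mean_delta: float
    direction: int  # +1 hyper in group A, -1 hypo in group A

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    def as_interval(self) -> Interval:
        # BED-style 0-based half-open covering both member positions
        return Interval(self.chrom, self.start - 1, self.end, ".", "DMR")


def call_dmrs(
    records: pd.DataFrame,
    min_dmcs: int = 3,
    min_span: int = 51,
    same_direction: bool = True,
) -> list[DMRRecord]:
    """Merge DMCs into DMRs.

    A DMR is a maximal run of consecutive *tested* sites that are all
    DMCs (of the same sign when ``same_direction``), containing at
    least ``min_dmcs`` members and spanning at least ``min_span`` bp
    (last - first + 1, i.e. strictly more than 50 bp by default). A
    tested non-DMC between two DMCs breaks a run; an untested cytosine
    does not, because it is absent from the record sequence.
    """
    recs = records.sort_values(["chrom", "pos"]).reset_index(drop=True)
    out: list[DMRRecord] = []
    for chrom, grp in recs.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy()
        flag = grp["is_dmc"].to_numpy()
        sign = np.sign(grp["delta"].to_numpy())
        dlt = grp["delta"].to_numpy()
        i, n = 0, len(grp)
        while i < n:
            if not flag[i]:
                i += 1
                continue
            j = i + 1
            while j < n and flag[j] and (not same_direction or sign[j] == sign[i]):
                j += 1
            run = slice(i, j)
            if (j - i) >= min_dmcs and (pos[j - 1] - pos[i] + 1) >= min_span:
                out.append(
                    DMRRecord(
                        chrom,
                        int(pos[i]),
                        int(pos[j - 1]),
                        j - i,
                        float(np.mean(dlt[run])),
                        int(sign[i]) if sign[i] != 0 else 0,
                    )
                )
            i = j
    return out


# ---------------------------------------------------------------------------
# Fisher's exact enrichment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnrichmentResult:
    feature: str
    a: int  # DMCs in feature
    b: int  # DMCs outside
    c: int  # tested non-DMCs in feature
    d: int  # tested non-DMCs outside
    sample_or: float  # ad / bc
    cmle_or: float  # conditional MLE of the noncentral hypergeometric OR
    pvalue: float  # two-tailed Fisher

    @property
    def table(self):
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


def enrichment_from_counts(
    feature: str,
    dmcs_in_feature: int,
    total_dmcs: int,
    detected_in_feature: int,
    total_detected: int,
) -> EnrichmentResult:
    """Enrichment from marginal counts (e.g. a published summary table).

    Builds the 2x2 table a = DMCs in the feature, b = DMCs outside,
    c = non-DMC tested sites in the feature, d = non-DMC outside, and
    tests it with a two-tailed Fisher's exact test.
    """
    a = int(dmcs_in_feature)
    b = int(total_dmcs) - a
    c = int(detected_in_feature) - a
    d = int(total_detected) - int(detected_in_feature) - b
    if min(a, b, c, d) < 0:
        raise ValueError(f"{feature}: inconsistent marginals")
    table = [[a, b], [c, d]]
    if (a + b == 0) or (a + c == 0) or (b + d == 0) or (c + d == 0):
        return EnrichmentResult(feature, a, b, c, d, float("nan"), float("nan"), 1.0)
    _, p = stats.fisher_exact(table, alternative="two-sided")
    sample = (a * d) / (b * c) if b * c > 0 else float("inf")
    cmle = float(_cmle_odds_ratio(table, kind="conditional").statistic)
    return EnrichmentResult(feature, a, b, c, d, float(sample), cmle, float(p))


def enrichment(
    records: pd.DataFrame,
    feature_tracks: dict[str, dict[str, np.ndarray]],
    context: str = CPG,
) -> list[EnrichmentResult]:
    """DMC enrichment per genomic feature among all tested sites.

    ``feature_tracks`` maps a feature label to per-chromosome interval
    arrays (0-based half-open); features may overlap each other (CGI
    and genic tracks are tested independently). Membership of a site is
    by its 0-based position.
    """
    recs = records[records["context"] == context].reset_index(drop=True)
    total = len(recs)
    total_dmcs = int(recs["is_dmc"].sum())
    dmc = recs["is_dmc"].to_numpy()
    pos0 = recs["pos"].to_numpy() - 1
    chroms = recs["chrom"].to_numpy()
    out = []
    for label, track in feature_tracks.items():
        in_feat = np.zeros(total, dtype=bool)
        for chrom in pd.unique(chroms):
            arr = track.get(chrom)
            if arr is None or len(arr) == 0:
                continue
            sel = chroms == chrom
            in_feat[sel] = iv.positions_in(pos0[sel], arr)
        a = int((in_feat & dmc).sum())
        n_in = int(in_feat.sum())
        out.append(enrichment_from_counts(label, a, total_dmcs, n_in, total))
    return out


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature": [r.feature for r in results],
            "detected": [r.a + r.c for r in results],
            "dmcs": [r.a for r in results],
            "sample_or": [r.sample_or for r in results],
            "cmle_or": [r.cmle_or for r in results],
            "pvalue": [r.pvalue for r in results],
        }
    )
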