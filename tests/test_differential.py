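from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import brentq

import methaxis as mx
from methaxis.differential import (
    call_dmcs,
    call_dmrs,
    classify_constitutive,
    enrichment,
    enrichment_from_counts,
    wald_test,
)
from methaxis.io_formats import CPG
from conftest import make_two_group_table


class TestConstitutive:
    def frame(self, rows):
        return pd.DataFrame(
            {f"beta_{t}": col for t, col in zip(("h", "p", "o"), zip(*rows))}
        )

    def test_inclusive_hypo_boundary(self):
        lv = self.frame([(0.20, 0.10, 0.00)])
        assert classify_constitutive(lv, ["h", "p", "o"]).iloc[0] == "HypoC"

    def test_mixed_levels_neither(self):
        lv = self.frame([(0.20, 0.85, 0.85)])
        assert classify_constitutive(lv, ["h", "p", "o"]).iloc[0] == "neither"

    def test_inclusive_hyper_boundary(self):
        lv = self.frame([(0.80, 0.9, 1.0)])
        assert classify_constitutive(lv, ["h", "p", "o"]).iloc[0] == "HyperC"

    def test_tallies_match_brute_force(self):
        rng = np.random.default_rng(0)
        b = rng.uniform(0, 1, size=(10_000, 3))
        lv = self.frame(b)
        out = classify_constitutive(lv, ["h", "p", "o"])
        hypo = sum(1 for row in b if all(x <= 0.20 for x in row))
        hyper = sum(1 for row in b if all(x >= 0.80 for x in row))
        assert (out == "HypoC").sum() == hypo
        assert (out == "HyperC").sum() == hyper


class TestWaldTest:
    def test_identical_groups_null(self):
        t = make_two_group_table([10, 12, 9], [20, 22, 19], [10, 12, 9], [20, 22, 19])
        rec = wald_test(t, ["A0", "A1", "A2"], ["B0", "B1", "B2"])
        assert rec["delta"].iloc[0] == 0.0
        assert rec["p"].iloc[0] == 1.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        m = rng.integers(0, 20, size=(50, 6))
        n = m + rng.integers(1, 20, size=(50, 6))
        t = make_two_group_table(m[:, :3], n[:, :3], m[:, 3:], n[:, 3:])
        ab = wald_test(t, ["A0", "A1", "A2"], ["B0", "B1", "B2"])
        ba = wald_test(t, ["B0", "B1", "B2"], ["A0", "A1", "A2"])
        np.testing.assert_allclose(ab["z"], -ba["z"])
        np.testing.assert_allclose(ab["p"], ba["p"])

    def test_strong_separation_is_dmc_and_agrees_with_oracles(self):
        # A: 40/50, 38/50, 42/50 vs B: 5/50, 6/50, 4/50
        t = make_two_group_table([40, 38, 42], [50] * 3, [5, 6, 4], [50] * 3)
        rec = call_dmcs(wald_test(t, ["A0", "A1", "A2"], ["B0", "B1", "B2"]))
        assert rec["delta"].iloc[0] == pytest.approx(0.7)
        assert rec["p"].iloc[0] < 1e-6 and bool(rec["is_dmc"].iloc[0])

        # oracle 1: binomial likelihood-ratio test on pooled counts
        m = np.array([40, 38, 42, 5, 6, 4])
        n = np.full(6, 50)
        grp = np.array([0, 0, 0, 1, 1, 1])

        def ll(m, n, p):
            p = np.clip(p, 1e-12, 1 - 1e-12)
            return (m * np.log(p) + (n - m) * np.log(1 - p)).sum()

        p_pool = m.sum() / n.sum()
        p_a = m[grp == 0].sum() / n[grp == 0].sum()
        p_b = m[grp == 1].sum() / n[grp == 1].sum()
        lrt = 2 * (
            ll(m[grp == 0], n[grp == 0], p_a)
            + ll(m[grp == 1], n[grp == 1], p_b)
            - ll(m, n, p_pool)
        )
        p_lrt = stats.chi2.sf(lrt, 1)
        assert p_lrt < 1e-6  # same call

        # oracle 2: the observed labelling maximises |delta| over all
        # replicate-label reassignments (permutation rank 1 of 20)
        deltas = []
        for a_idx in combinations(range(6), 3):
            b_idx = [i for i in range(6) if i not in a_idx]
            da = m[list(a_idx)].sum() / n[list(a_idx)].sum()
            db = m[b_idx].sum() / n[b_idx].sum()
            deltas.append(abs(da - db))
        assert max(deltas) == pytest.approx(0.7)
        assert sum(d >= 0.7 - 1e-12 for d in deltas) == 2  # the split and its mirror

    def test_all_or_nothing_pseudocount_fallback(self):
        t = make_two_group_table([10, 10, 10], [10] * 3, [0, 0, 0], [10] * 3)
        rec = wald_test(t, ["A0", "A1", "A2"], ["B0", "B1", "B2"])
        assert bool(rec["pseudo"].iloc[0])
        assert 0 < rec["p"].iloc[0] < 0.01

    def test_null_type_one_error_within_band(self):
        # beta-binomial null: equal means, phi=0.05, NegBin coverage, 3v3
        rng = np.random.default_rng(11)
        n_sites = 10_000
        mu = rng.uniform(0.1, 0.9, n_sites)
        conc = 1 / 0.05 - 1

        def group():
            n = np.maximum(rng.negative_binomial(5, 5 / 35, (n_sites, 3)), 5)
            p = rng.beta(
                mu[:, None] * conc, (1 - mu[:, None]) * conc, (n_sites, 3)
            )
            return rng.binomial(n, p), n

        (ma, na), (mb, nb) = group(), group()
        t = make_two_group_table(ma, na, mb, nb, pos=np.arange(1, n_sites + 1) * 10)
        rec = wald_test(t, ["A0", "A1", "A2"], ["B0", "B1", "B2"])
        rate = (rec["p"] <= 0.01).mean()
        assert 0.005 <= rate <= 0.02

    def test_planted_effect_recall(self):
        # true delta 0.4 at coverage ~30: nearly always called
        rng = np.random.default_rng(4)
        n_sites = 2_000
        conc = 1 / 0.01 - 1

        def group(mu):
            n = np.maximum(rng.negative_binomial(5, 5 / 35, (n_sites, 3)), 5)
            p = rng.beta(mu * conc, (1 - mu) * conc, (n_sites, 3))
            return rng.binomial(n, p), n

        (ma, na), (mb, nb) = group(0.3), group(0.7)
        t = make_two_group_table(ma, na, mb, nb, pos=np.arange(1, n_sites + 1) * 10)
        rec = call_dmcs(wald_test(t, ["A0", "A1", "A2"], ["B0", "B1", "B2"]))
        assert rec["is_dmc"].mean() > 0.9


class TestCallDMCs:
    def frame(self, delta, p):
        return pd.DataFrame(
            {
                "chrom": ["chr1"] * len(delta),
                "pos": np.arange(1, len(delta) + 1),
                "strand": ["+"] * len(delta),
                "context": [CPG] * len(delta),
                "delta": delta,
                "p": p,
            }
        )

    def test_delta_threshold_strict(self):
        rec = call_dmcs(self.frame([0.20], [1e-9]))
        assert not rec["is_dmc"].iloc[0]

    def test_alpha_threshold_inclusive(self):
        rec = call_dmcs(self.frame([0.5], [0.01]))
        assert bool(rec["is_dmc"].iloc[0])


def oracle_dmrs(pos, flag, sign, min_dmcs=3, min_span=51):
    """Independent maximal-run scan over the tested-site sequence."""
    out = []
    runs, cur = [], []
    for i in range(len(pos)):
        if flag[i] and (not cur or sign[i] == sign[cur[-1]]):
            cur.append(i)
        else:
            if cur:
                runs.append(cur)
            cur = [i] if flag[i] else []
    if cur:
        runs.append(cur)
    for r in runs:
        if len(r) >= min_dmcs and pos[r[-1]] - pos[r[0]] + 1 >= min_span:
            out.append((pos[r[0]], pos[r[-1]], len(r)))
    return out


class TestCallDMRs:
    def frame(self, pos, flag, delta=None):
        delta = delta if delta is not None else [0.5 if f else 0.0 for f in flag]
        return pd.DataFrame(
            {
                "chrom": ["chr1"] * len(pos),
                "pos": pos,
                "strand": ["+"] * len(pos),
                "context": [CPG] * len(pos),
                "delta": delta,
                "p": [0.001 if f else 0.9 for f in flag],
                "is_dmc": flag,
            }
        )

    def test_basic_triple(self):
        recs = self.frame([100, 130, 160], [True] * 3)
        (d,) = call_dmrs(recs)
        assert (d.start, d.end, d.n_dmcs, d.span) == (100, 160, 3, 61)

    def test_tested_non_dmc_breaks_run(self):
        recs = self.frame(
            [100, 130, 160, 190, 220, 250],
            [True, True, False, True, True, True],
        )
        (d,) = call_dmrs(recs)
        assert (d.start, d.end) == (190, 250)

    def test_short_span_rejected(self):
        recs = self.frame([100, 120, 139], [True] * 3)  # span 40
        assert call_dmrs(recs) == []

    def test_opposite_sign_breaks_run(self):
        recs = self.frame(
            [100, 130, 160, 190, 220, 250],
            [True] * 6,
            delta=[0.5, 0.5, 0.5, -0.5, -0.5, -0.5],
        )
        dmrs = call_dmrs(recs)
        assert [(d.start, d.end) for d in dmrs] == [(100, 160), (190, 250)]

    def test_matches_exhaustive_oracle_on_random_patterns(self):
        rng = np.random.default_rng(7)
        n = 1000
        pos = np.cumsum(rng.integers(5, 60, n)) + 100
        flag = rng.random(n) < 0.35
        sign = rng.choice([-1.0, 1.0], n)
        delta = sign * rng.uniform(0.21, 0.6, n)
        recs = self.frame(pos.tolist(), flag.tolist(), delta=delta.tolist())
        got = [(d.start, d.end, d.n_dmcs) for d in call_dmrs(recs)]
        assert got == oracle_dmrs(pos, flag, np.sign(delta))

    def test_output_never_overlaps_itself(self, cpg_filtered, design):
        rec = call_dmcs(
            wald_test(
                cpg_filtered,
                list(design.tissues["hypothalamus"]),
                list(design.tissues["ovary"]),
            )
        )
        dmrs = sorted(call_dmrs(rec), key=lambda d: (d.chrom, d.start))
        for a, b in zip(dmrs, dmrs[1:]):
            assert a.chrom != b.chrom or a.end < b.start


def oracle_fisher(a, b, c, d):
    """Exact two-tailed Fisher p by rational enumeration of the support."""
    r1, r2, c1 = a + b, c + d, a + c
    N = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    denom = comb(N, c1)
    probs = {x: Fraction(comb(r1, x) * comb(r2, c1 - x), denom) for x in range(lo, hi + 1)}
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))


def oracle_cmle(a, b, c, d):
    """Conditional-MLE odds ratio by root-finding on the conditional mean."""
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    if a == lo:
        return 0.0
    if a == hi:
        return np.inf
    xs = np.arange(lo, hi + 1)
    w = np.array([comb(r1, int(x)) * comb(r2, int(c1 - x)) for x in xs], dtype=float)

    def cond_mean_minus_a(log_psi):
        lw = np.log(w) + xs * log_psi
        lw -= lw.max()
        pw = np.exp(lw)
        return (xs * pw).sum() / pw.sum() - a

    return float(np.exp(brentq(cond_mean_minus_a, -50, 50)))


class TestEnrichment:
    def test_equal_proportions_or_one(self):
        r = enrichment_from_counts("f", 10, 30, 100, 300)
        assert r.sample_or == pytest.approx(1.0)
        assert r.pvalue == pytest.approx(1.0)

    def test_small_table_matches_enumeration(self):
        r = enrichment_from_counts("f", 3, 10, 8, 20)
        a, b, c, d = r.a, r.b, r.c, r.d
        assert (a, b, c, d) == (3, 7, 5, 5)
        assert r.pvalue == pytest.approx(oracle_fisher(a, b, c, d), rel=1e-9)
        assert r.cmle_or == pytest.approx(oracle_cmle(a, b, c, d), rel=1e-6)

    def test_complement_feature_inverts_sample_or(self):
        r = enrichment_from_counts("f", 400, 1000, 5_000, 20_000)
        rc = enrichment_from_counts("not-f", 600, 1000, 15_000, 20_000)
        assert rc.sample_or == pytest.approx(1.0 / r.sample_or)
        assert rc.pvalue == pytest.approx(r.pvalue, rel=1e-9)

    def test_partition_counts_sum_to_total(self, sim_default, cpg_filtered, design):
        fm = mx.build_genic_features(sim_default.genes, sim_default.config.chrom_sizes)
        rec = call_dmcs(
            wald_test(
                cpg_filtered,
                list(design.tissues["hypothalamus"]),
                list(design.tissues["pituitary"]),
            )
        )
        results = enrichment(rec, fm.features)
        total_dmcs = int(rec["is_dmc"].sum())
        assert sum(r.a for r in results) == total_dmcs
        assert sum(r.a + r.c for r in results) == len(rec)
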