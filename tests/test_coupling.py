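"""Pairing geometry, filters, Spearman coupling and interaction OLS."""

import math

import numpy as np
import pytest
from scipy import stats

from retromethyl.coupling import (
    PairRecord,
    aggregate_promoter_beta,
    filter_pairs,
    fit_gene_model,
    fit_locus_model,
    pair_cpg_gene,
    pair_cpg_locus,
    spearman_coupling,
)
from retromethyl.features import CpGSite, FilterConfig
from retromethyl.simulate import SimulationConfig, simulate_pairs

from .conftest import make_de, make_feature


def site(cpg_id, position, lfc=0.5, padj=0.01, strand="+", promoter_of=(),
         chrom="chr1", **kw):
    return CpGSite(cpg_id=cpg_id, chrom=chrom, position=position,
                   meth_log2fc=lfc, pvalue=padj, padj=padj, strand=strand,
                   promoter_of=frozenset(promoter_of), **kw)


def make_pair(x1, y=None, x2=1, x3=None, kind="cpg_locus", cpg="cg1", partner="P1"):
    return PairRecord(pair_kind=kind, cpg_id=cpg, partner_id=partner,
                      X1=x1, X2=x2, X3=x3, Y=y)


class TestPromoterBeta:
    def test_mean_and_identity(self):
        sites = [
            site("cg1", 100, beta_tumor=0.2, promoter_of=["G1"]),
            site("cg2", 150, beta_tumor=0.4, promoter_of=["G1"]),
            site("cg3", 900, beta_tumor=0.7, promoter_of=["G2"]),
            site("cg4", 999, beta_tumor=0.5),  # no promoter membership
        ]
        agg = aggregate_promoter_beta(sites)
        assert agg == {"G1": pytest.approx(0.3), "G2": pytest.approx(0.7)}

    def test_matches_groupby_mean_oracle(self, rng):
        sites, expected = [], {}
        for i in range(200):
            gid = f"G{int(rng.integers(0, 20))}"
            b = float(rng.random())
            sites.append(site(f"cg{i}", i, beta_tumor=b, promoter_of=[gid]))
            expected.setdefault(gid, []).append(b)
        agg = aggregate_promoter_beta(sites)
        for gid, vals in expected.items():
            assert agg[gid] == pytest.approx(sum(vals) / len(vals))


class TestPairing:
    def test_gene_window_boundaries(self):
        gene = make_feature("G1", 1000, 2000, "+", kind="gene")
        inside = site("cg1", 900)
        out = site("cg2", 5001)
        at_edge = site("cg3", 5000)
        pairs = pair_cpg_gene([inside, out, at_edge], [gene], window=3000)
        got = {(p.cpg_id, p.distance_bp) for p in pairs}
        assert got == {("cg1", 100), ("cg3", 3000)}

    def test_locus_window_and_inside_distance_zero(self):
        locus = make_feature("L1", 1000, 2000, "+")
        inside = site("cg1", 1500)
        far = site("cg2", 12001)
        pairs = pair_cpg_locus([inside, far], [locus], window=10_000)
        assert [(p.cpg_id, p.distance_bp) for p in pairs] == [("cg1", 0)]

    def test_promoter_flag_from_manifest_and_strand_dichotomy(self):
        gene = make_feature("G1", 1000, 2000, "-", kind="gene")
        s1 = site("cg1", 1500, strand="-", promoter_of=["G1"])
        s2 = site("cg2", 1500, strand="+", promoter_of=["OTHER"])
        p1, p2 = pair_cpg_gene([s1, s2], [gene])
        assert (p1.X3, p1.X2) == (1, 1)
        assert (p2.X3, p2.X2) == (0, 0)

    def test_locus_pairs_have_no_x3(self):
        locus = make_feature("L1", 1000, 2000)
        (p,) = pair_cpg_locus([site("cg1", 1500)], [locus])
        assert p.X3 is None

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        genes = [make_feature(f"G{i}", int(rng.integers(1, 200_000)),
                              0, kind="gene") for i in range(0)]
        # random genes with valid ends
        genes = []
        for i in range(100):
            start = int(rng.integers(1, 200_000))
            genes.append(make_feature(f"G{i}", start,
                                      start + int(rng.integers(100, 5000)),
                                      kind="gene"))
        sites = [site(f"cg{i}", int(rng.integers(1, 210_000)))
                 for i in range(300)]
        window = 3000
        got = {(p.cpg_id, p.partner_id, p.distance_bp)
               for p in pair_cpg_gene(sites, genes, window=window)}
        oracle = set()
        for s in sites:
            for g in genes:
                d = max(0, g.start - s.position, s.position - g.end)
                if d <= window:
                    oracle.add((s.cpg_id, g.feature_id, d))
        assert got == oracle


class TestFilterPairs:
    def _setup(self):
        sites = [site("cg1", 100, lfc=-0.5, padj=0.01),
                 site("cg2", 200, lfc=0.1, padj=0.001),   # |X1| == threshold
                 site("cg3", 300, lfc=0.8, padj=0.2)]     # not significant
        de = [make_de("P1", 2.0, padj=0.001, pvalue=0.001)]
        pairs = [make_pair(-0.5, cpg="cg1"),
                 make_pair(0.1, cpg="cg2"),
                 make_pair(0.8, cpg="cg3")]
        return pairs, sites, de

    def test_strict_inequality_at_methylation_threshold(self):
        pairs, sites, de = self._setup()
        kept = filter_pairs(pairs, sites, de)
        assert [p.cpg_id for p in kept] == ["cg1"]
        assert kept[0].Y == 2.0

    def test_expression_threshold_strict(self):
        sites = [site("cg1", 100, lfc=-0.5, padj=0.01)]
        de_at = [make_de("P1", 1.0, padj=0.001)]
        de_over = [make_de("P1", 1.01, padj=0.001)]
        assert filter_pairs([make_pair(-0.5)], sites, de_at) == []
        assert len(filter_pairs([make_pair(-0.5)], sites, de_over)) == 1

    def test_partner_without_de_record_dropped_and_counted(self):
        from retromethyl.coupling import PairFilterReport
        sites = [site("cg1", 100, lfc=-0.5, padj=0.01)]
        rep = PairFilterReport()
        out = filter_pairs([make_pair(-0.5, partner="UNKNOWN")], sites, [],
                           report=rep)
        assert out == [] and rep.n_no_de_record == 1

    def test_consensus_restriction(self):
        sites = [site("cg1", 100, lfc=-0.5, padj=0.01)]
        de = [make_de("P1", 2.0, padj=0.001)]
        assert filter_pairs([make_pair(-0.5)], sites, de, consensus={"P1"})
        assert not filter_pairs([make_pair(-0.5)], sites, de, consensus={"P9"})

    def test_raw_p_toggle_changes_pair_set(self):
        sites = [CpGSite(cpg_id="cg1", chrom="chr1", position=1,
                         meth_log2fc=0.5, pvalue=0.01, padj=0.2)]
        de = [make_de("P1", 2.0, padj=0.001, pvalue=0.001)]
        pair = [make_pair(0.5)]
        assert filter_pairs(pair, sites, de, FilterConfig()) == []
        kept = filter_pairs(pair, sites, de,
                            FilterConfig(use_adjusted_meth_p=False))
        assert len(kept) == 1

    def test_idempotent(self, rng):
        sites = [site(f"cg{i}", i, lfc=float(rng.normal(0, 0.5)),
                      padj=float(rng.random() * 0.1)) for i in range(50)]
        de = [make_de(f"P{i}", float(rng.normal(0, 2)),
                      padj=float(rng.random() * 0.1)) for i in range(50)]
        pairs = [make_pair(sites[i].meth_log2fc, cpg=f"cg{i}", partner=f"P{i}")
                 for i in range(50)]
        once = filter_pairs(pairs, sites, de)
        twice = filter_pairs(once, sites, de)
        assert twice == once


class TestSpearman:
    def _pairs(self, x, y):
        return [make_pair(float(xi), y=float(yi), cpg=f"cg{i}", partner=f"P{i}")
                for i, (xi, yi) in enumerate(zip(x, y))]

    def test_monotone_increasing_rho_one(self):
        x = [0.2, 0.5, 1.0, 2.0, 3.3, 4.0, 5.5, 6.0, 7.1, 8.0, 9.0, 10.0]
        y = [v**3 + 1 for v in x]
        res = spearman_coupling(self._pairs(x, y))
        assert res.rho == pytest.approx(1.0)

    def test_antitone_rho_minus_one(self):
        x = list(range(1, 15))
        res = spearman_coupling(self._pairs(x, [-v for v in x]))
        assert res.rho == pytest.approx(-1.0)

    def test_invariant_under_monotone_transforms(self, rng):
        x = rng.normal(size=40)
        y = 0.5 * x + rng.normal(size=40)
        base = spearman_coupling(self._pairs(x, y))
        warped = spearman_coupling(self._pairs(np.exp(x), np.cbrt(y)))
        assert warped.rho == pytest.approx(base.rho, abs=1e-12)

    def test_matches_scipy_for_large_n(self, rng):
        x = rng.normal(size=60)
        y = rng.normal(size=60)
        res = spearman_coupling(self._pairs(x, y))
        ref = stats.spearmanr(x, y)
        assert res.rho == pytest.approx(float(ref.statistic), abs=1e-12)
        assert res.pvalue == pytest.approx(float(ref.pvalue), abs=1e-12)

    def test_exact_small_n_pvalue_is_valid_and_extreme_for_perfect_rank(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        res = spearman_coupling(self._pairs(x, x))
        # 2/6! pairings reach |rho| = 1 (identity and reversal)
        assert res.rho == pytest.approx(1.0)
        assert res.pvalue == pytest.approx(2 / math.factorial(6))

    def test_constant_input_flagged_undefined(self):
        res = spearman_coupling(self._pairs([1, 1, 1, 1], [1, 2, 3, 4]))
        assert not res.defined and math.isnan(res.rho)

    def test_uniqueness_counts(self):
        pairs = [make_pair(0.1 * i, y=float(i), cpg=f"cg{i % 3}",
                           partner=f"P{i % 2}") for i in range(6)]
        res = spearman_coupling(pairs)
        assert (res.n_pairs, res.n_unique_cpgs, res.n_unique_partners) == (6, 3, 2)


def normal_equation_fit(X, y):
    return np.linalg.solve(X.T @ X, X.T @ y)


class TestLocusModel:
    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(20, 200))
            pairs = [make_pair(float(rng.normal()), y=float(rng.normal()),
                               x2=int(rng.random() < 0.5), cpg=f"c{i}",
                               partner=f"P{i}") for i in range(n)]
            res = fit_locus_model(pairs)
            if not res.applicable:
                continue
            X = np.column_stack([
                np.ones(n),
                [p.X1 for p in pairs],
                [p.X2 for p in pairs],
                [p.X1 * p.X2 for p in pairs],
            ])
            y = np.array([p.Y for p in pairs])
            beta = normal_equation_fit(X, y)
            for j, term in enumerate(("const", "X1", "X2", "X1:X2")):
                assert res.estimate(term) == pytest.approx(beta[j], abs=1e-10)

    def test_noise_free_exact_recovery(self):
        cfg = SimulationConfig(
            seed=5, noise_sd=0.0,
            coupling_beta={"beta0": 2.0, "beta1": -0.5, "beta2": 0.3,
                           "beta3": 0.7})
        pairs = simulate_pairs(cfg, 200, kind="cpg_locus")
        res = fit_locus_model(pairs)
        assert res.applicable
        assert res.estimate("const") == pytest.approx(2.0, abs=1e-8)
        assert res.estimate("X1") == pytest.approx(-0.5, abs=1e-8)
        assert res.estimate("X2") == pytest.approx(0.3, abs=1e-8)
        assert res.estimate("X1:X2") == pytest.approx(0.7, abs=1e-8)

    def test_slope_recovered_within_three_se(self):
        cfg = SimulationConfig(
            seed=11, noise_sd=0.1,
            coupling_beta={"beta0": 2.0, "beta1": -0.5, "beta2": 0.0,
                           "beta3": 0.0})
        pairs = simulate_pairs(cfg, 200, kind="cpg_locus")
        res = fit_locus_model(pairs)
        assert abs(res.estimate("X1") - (-0.5)) < 3 * res.se("X1")

    def test_constant_strand_indicator_not_applicable(self):
        pairs = [make_pair(float(i) * 0.1, y=float(i), x2=1, cpg=f"c{i}",
                           partner=f"P{i}") for i in range(20)]
        res = fit_locus_model(pairs)
        assert not res.applicable
        assert "X2" in res.inapplicability_reason
        assert res.coefficients == {}

    def test_too_few_pairs_flagged(self):
        pairs = [make_pair(0.1, y=1.0, cpg=f"c{i}", partner=f"P{i}")
                 for i in range(3)]
        res = fit_locus_model(pairs)
        assert not res.applicable and "fewer than" in res.inapplicability_reason


class TestGeneModel:
    def test_promoter_interaction_sign_flip_detected(self):
        cfg = SimulationConfig(
            seed=7, noise_sd=0.2,
            gene_coupling_beta={"beta0": 0.0, "beta1": 0.4, "beta2": 0.0,
                                "beta3": 0.0, "beta4": 0.0, "beta5": -0.9})
        pairs = simulate_pairs(cfg, 400, kind="cpg_gene")
        res = fit_gene_model(pairs)
        assert res.applicable
        assert res.estimate("X1") > 0
        assert res.estimate("X1:X3") < 0
        assert abs(res.estimate("X1") - 0.4) < 3 * res.se("X1")
        assert abs(res.estimate("X1:X3") - (-0.9)) < 3 * res.se("X1:X3")
        assert res.promoter_sign_flip

    def test_no_promoter_sites_not_applicable(self):
        pairs = [make_pair(float(i) * 0.1, y=float(i),
                           x2=i % 2, x3=0, kind="cpg_gene",
                           cpg=f"c{i}", partner=f"P{i}") for i in range(20)]
        res = fit_gene_model(pairs)
        assert not res.applicable
        assert "X3" in res.inapplicability_reason

    def test_noise_free_exact_recovery(self):
        cfg = SimulationConfig(
            seed=13, noise_sd=0.0,
            gene_coupling_beta={"beta0": 1.0, "beta1": 0.4, "beta2": -0.2,
                                "beta3": 0.5, "beta4": 0.3, "beta5": -0.9})
        pairs = simulate_pairs(cfg, 300, kind="cpg_gene")
        res = fit_gene_model(pairs)
        expected = {"const": 1.0, "X1": 0.4, "X2": -0.2, "X3": 0.5,
                    "X1:X2": 0.3, "X1:X3": -0.9}
        for term, value in expected.items():
            assert res.estimate(term) == pytest.approx(value, abs=1e-8)

    def test_wrong_pair_kind_rejected(self):
        with pytest.raises(ValueError, match="cpg_gene"):
            fit_gene_model([make_pair(0.1, y=1.0)])


class TestParameterRecoverySweep:
    @pytest.mark.parametrize("beta1", [-1.0, -0.3, 0.0, 0.5])
    def test_mean_estimate_unbiased_over_replicates(self, beta1):
        n_reps, n = 50, 300
        estimates = []
        for rep in range(n_reps):
            cfg = SimulationConfig(
                seed=1000 + rep, noise_sd=0.3,
                coupling_beta={"beta0": 0.0, "beta1": beta1, "beta2": 0.0,
                               "beta3": 0.0})
            pairs = simulate_pairs(cfg, n, kind="cpg_locus")
            res = fit_locus_model(pairs)
            estimates.append(res.estimate("X1"))
        mean_est = float(np.mean(estimates))
        sem = float(np.std(estimates, ddof=1) / math.sqrt(n_reps))
        assert abs(mean_est - beta1) < 2 * sem + 1e-12
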