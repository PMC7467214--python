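import numpy as np
import pandas as pd
import pytest

import proberel as pr


def rel_table(icc, ids=None):
    ids = ids or [f"cg{i:06d}" for i in range(len(icc))]
    return pd.DataFrame({"icc": icc}, index=pd.Index(ids, name="probe_id"))


def stat_series(values, ids):
    return pd.Series(values, index=pd.Index(ids, name="probe_id"), name="stat")


class TestAssociateExternal:
    def test_stat_equal_to_icc_gives_r_one(self, rng):
        icc = rng.uniform(0, 1, 50)
        tab = rel_table(icc)
        stat = stat_series(icc, list(tab.index))
        for method in ("pearson", "spearman"):
            out = pr.associate_external(tab, stat, method=method)
            assert out["r"] == pytest.approx(1.0)

    def test_independent_stat_near_zero(self, rng):
        n = 2000
        icc = rng.uniform(0, 1, n)
        tab = rel_table(icc)
        stat = stat_series(rng.normal(size=n), list(tab.index))
        out = pr.associate_external(tab, stat)
        assert abs(out["r"]) < 3 / np.sqrt(n)

    def test_monotone_coupling_strengthens_with_less_noise(self, rng):
        n = 1000
        icc = rng.uniform(0, 1, n)
        tab = rel_table(icc)
        rs = []
        for noise in (0.5, 0.1):
            stat = stat_series(icc + rng.normal(0, noise, n), list(tab.index))
            rs.append(pr.associate_external(tab, stat, method="spearman")["r"])
        assert 0 < rs[0] < rs[1]

    def test_constant_stat_flagged(self):
        tab = rel_table([0.1, 0.5, 0.9])
        stat = stat_series([0.3, 0.3, 0.3], list(tab.index))
        out = pr.associate_external(tab, stat)
        assert out["flag"] == "zero_variance"

    def test_bins_partition_probes(self, rng):
        n = 500
        tab = rel_table(rng.uniform(0, 1, n))
        stat = stat_series(rng.uniform(0, 1, n), list(tab.index))
        out = pr.associate_external(tab, stat)
        total = sum(out["bins"][b]["n"] for b in ("low", "mid", "high"))
        assert total == n

    def test_boundary_values_fall_in_lower_bin(self):
        tab = rel_table([0.5, 0.5, 0.5])
        stat = stat_series([0.4, 0.75, 0.76], list(tab.index))
        bins = pr.concordance_bins(tab, stat)
        assert bins["low"]["n"] == 1   # exactly 0.4 -> low
        assert bins["mid"]["n"] == 1   # exactly 0.75 -> mid
        assert bins["high"]["n"] == 1


class TestMultiRegionIntersection:
    def test_identical_regions_match_single_region_bins(self, rng):
        n = 300
        icc = rng.uniform(0, 1, n)
        tab = rel_table(icc)
        s = stat_series(rng.uniform(0, 1, n), list(tab.index))
        out = pr.multi_region_intersection(tab, {"r1": s, "r2": s, "r3": s, "r4": s})
        bins = pr.concordance_bins(tab, s)
        assert out["all_high"]["n"] == bins["high"]["n"]

    def test_disjoint_highs_give_empty_intersection(self):
        tab = rel_table([0.5, 0.5])
        s1 = stat_series([0.9, 0.1], list(tab.index))
        s2 = stat_series([0.1, 0.9], list(tab.index))
        out = pr.multi_region_intersection(tab, {"a": s1, "b": s2})
        assert out["all_high"]["n"] == 0

    def test_shared_high_icc_core_concentrates_reliability(self, rng):
        n = 1000
        icc = np.concatenate([rng.uniform(0, 0.6, 900), rng.uniform(0.85, 0.99, 100)])
        ids = [f"cg{i:06d}" for i in range(n)]
        tab = rel_table(icc, ids)
        core = np.zeros(n, dtype=bool)
        core[900:] = True
        regions = {}
        for r in range(4):
            s = rng.uniform(0, 0.7, n)
            s[core] = rng.uniform(0.8, 1.0, core.sum())
            # each region also has private highs at random reliability
            extra = rng.choice(900, 50, replace=False)
            s[extra] = rng.uniform(0.8, 1.0, 50)
            regions[f"r{r}"] = stat_series(s, ids)
        out = pr.multi_region_intersection(tab, regions)
        single = pr.concordance_bins(tab, regions["r0"])
        assert out["all_high"]["median_icc"] > single["high"]["median_icc"]

    def test_needs_two_regions(self):
        tab = rel_table([0.5, 0.5, 0.5])
        s = stat_series([0.1, 0.5, 0.9], list(tab.index))
        with pytest.raises(ValueError, match="2 regions"):
            pr.multi_region_intersection(tab, {"only": s})


class TestMethylationExpression:
    def make_beta(self, rng, p=20, n=30):
        ids = [f"cg{i:06d}" for i in range(p)]
        samples = [f"s{i}" for i in range(n)]
        return pr.BetaMatrix(
            pd.DataFrame(rng.uniform(0.05, 0.95, (p, n)), index=ids, columns=samples)
        )

    def test_affine_expression_gives_perfect_correlation(self, rng):
        beta = self.make_beta(rng)
        links = pr.make_tss_links(beta.probe_ids)
        expr = pd.DataFrame(
            2.5 * beta.values.to_numpy() - 1.0,
            index=links["unit_id"].tolist(),
            columns=beta.sample_ids,
        )
        out = pr.methylation_expression_correlation(beta, expr, links, alpha=1e-7)
        assert np.allclose(np.abs(out["r"]), 1.0)
        assert out["significant"].all()

    def test_type_i_error_at_nominal_alpha(self, rng):
        """Independent β and expression: significant fraction at α=0.05
        within binomial 99% bounds."""
        beta = self.make_beta(rng, p=1000, n=50)
        links = pr.make_tss_links(beta.probe_ids)
        expr = pr.generate_expression(
            beta, links, effect_probes=[], effect_size=0.0, noise_sd=1.0, seed=11
        )
        out = pr.methylation_expression_correlation(beta, expr, links, alpha=0.05)
        frac = out["significant"].mean()
        half = 2.576 * np.sqrt(0.05 * 0.95 / 1000)
        assert 0.05 - half <= frac <= 0.05 + half

    def test_high_icc_effects_raise_significant_set_median(self):
        """Coupling expression only to high-ICC probes makes the
        significant set more reliable than background."""
        cfg = pr.GeneratorConfig(n_probes=600, n_samples=80, seed=21)
        paired, truth = pr.generate_paired(cfg)
        table = pr.reliability_table(paired)
        links = pr.make_tss_links(paired.probe_ids)
        high = truth.index[truth["true_icc"] > 0.7].tolist()
        expr = pr.generate_expression(
            paired.first, links, effect_probes=high, effect_size=8.0,
            noise_sd=0.5, seed=22,
        )
        out = pr.methylation_expression_correlation(
            paired.first, expr, links, alpha=1e-4
        )
        sig_probes = out.loc[out["significant"], "probe_id"]
        assert len(sig_probes) > 5
        sig_median = table.loc[sig_probes, "icc"].median()
        assert sig_median > table["icc"].median()

    def test_zero_variance_unit_skipped_with_flag(self, rng):
        beta = self.make_beta(rng, p=3, n=15)
        links = pr.make_tss_links(beta.probe_ids)
        expr = pd.DataFrame(
            np.zeros((3, 15)), index=links["unit_id"].tolist(), columns=beta.sample_ids
        )
        out = pr.methylation_expression_correlation(beta, expr, links)
        assert (out["flag"] == "zero_variance").all()
        assert not out["significant"].any()

    def test_too_few_shared_samples_rejected(self, rng):
        beta = self.make_beta(rng, p=3, n=5)
        links = pr.make_tss_links(beta.probe_ids)
        expr = pd.DataFrame(
            rng.normal(size=(3, 5)), index=links["unit_id"].tolist(), columns=beta.sample_ids
        )
        with pytest.raises(ValueError, match="10 shared samples"):
            pr.methylation_expression_correlation(beta, expr, links)
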