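"""Group selection, ECDFs, KS statistics and parameter ranking."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from integrinsim.ensemble import ParameterSpace
from integrinsim.groups import (
    ECDF,
    ecdf,
    group_mean_parameters,
    ks_statistic,
    ks_statistic_to_cdf,
    rank_parameters,
    select_groups,
)
from integrinsim.model import build_default_model


def _criteria_frame(n, rng):
    df = pd.DataFrame(
        {
            "c1": rng.random(n),
            "c2": rng.random(n),
            "valid": np.ones(n, dtype=bool),
        }
    )
    df.index.name = "sample_id"
    return df


class TestSelectGroups:
    def test_top_two_percent_of_1e5(self):
        rng = np.random.default_rng(0)
        sel = select_groups(_criteria_frame(100_000, rng), 0.02)
        assert len(sel.group1) == 2000
        assert len(sel.group2) == 2000

    def test_fraction_one_selects_everything(self):
        rng = np.random.default_rng(1)
        df = _criteria_frame(50, rng)
        sel = select_groups(df, 1.0)
        assert set(sel.group1) == set(df.index)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        df = _criteria_frame(500, rng)
        sel = select_groups(df, 0.02)
        shuffled = df.sample(frac=1.0, random_state=7)
        sel2 = select_groups(shuffled, 0.02)
        assert set(sel.group1) == set(sel2.group1)
        assert set(sel.group2) == set(sel2.group2)

    def test_invalid_rows_excluded(self):
        rng = np.random.default_rng(3)
        df = _criteria_frame(100, rng)
        df.loc[df.index[:50], "valid"] = False
        df.loc[df.index[0], "c1"] = 99.0  # invalid row must not be selected
        sel = select_groups(df, 0.02)
        assert df.index[0] not in sel.group2


class TestECDF:
    def test_basic_values(self):
        f = ecdf([1.0, 2.0, 3.0])
        assert f(2.0) == pytest.approx(2 / 3)
        assert f(-1e9) == 0.0
        assert f(1e9) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ecdf([])

    def test_matches_analytic_cdf_for_log_uniform(self):
        rng = np.random.default_rng(4)
        draws = np.exp(rng.uniform(np.log(0.1), np.log(10.0), 10_000))
        cdf = lambda x: (np.log(np.clip(x, 0.1, 10.0)) - np.log(0.1)) / np.log(100.0)
        assert ks_statistic_to_cdf(draws, cdf) < 0.02


class TestKSStatistic:
    def test_identical_samples_zero(self):
        x = np.arange(10.0)
        assert ks_statistic(x, x) == 0.0

    def test_disjoint_point_masses_one(self):
        assert ks_statistic([0.0, 0.0, 0.0], [1.0, 1.0, 1.0]) == 1.0

    def test_matches_dense_grid_oracle(self):
        """Agreement to machine precision with a brute-force sup over a
        dense grid, on 100 random sample pairs."""
        rng = np.random.default_rng(5)
        for _ in range(100):
            n1 = rng.integers(3, 40)
            n2 = rng.integers(3, 40)
            a = rng.normal(size=n1)
            b = rng.normal(loc=rng.uniform(-1, 1), size=n2)
            fa, fb = ECDF(a), ECDF(b)
            pts = np.unique(np.concatenate([a, b]))
            grid = np.sort(
                np.concatenate([pts - 1e-9, pts, pts + 1e-9,
                                np.linspace(pts.min() - 1, pts.max() + 1, 2001)])
            )
            oracle = np.abs(fa(grid) - fb(grid)).max()
            assert ks_statistic(a, b) == pytest.approx(oracle, abs=1e-12)

    def test_matches_scipy(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(size=80), rng.normal(0.4, size=60)
        assert ks_statistic(a, b) == pytest.approx(
            stats.ks_2samp(a, b).statistic, abs=1e-12
        )

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(7)
        a, b = rng.random(30), rng.random(50)
        d = ks_statistic(a, b)
        assert ks_statistic(np.exp(a), np.exp(b)) == pytest.approx(d, abs=1e-12)
        assert ks_statistic(b, a) == pytest.approx(d, abs=1e-12)


@pytest.fixture(scope="module")
def space():
    return ParameterSpace.from_model(build_default_model())


class TestRanking:
    def test_null_groups_below_ks_quantile(self, space):
        """Random subsamples deviate from the sampling law by less than the
        95% KS quantile for their size."""
        rng = np.random.default_rng(8)
        samples = space.sample(5000, seed=9)
        from integrinsim.groups import GroupSelection

        ids = rng.choice(samples.index.to_numpy(), size=300, replace=False)
        sel = GroupSelection(group1=ids[:150], group2=ids[150:], fraction=0.03)
        table = rank_parameters(samples, sel, space)
        threshold = 1.36 / np.sqrt(150)  # asymptotic 95% KS quantile
        # allow a small number of parameters at the boundary by chance
        assert (table["D_g1"] > threshold).sum() <= 4
        assert (table["D_g2"] > threshold).sum() <= 4

    def test_self_selected_group_attains_high_d(self, space):
        """Selecting the top 2% of one parameter makes that parameter's own
        KS distance approach 0.98."""
        samples = space.sample(5000, seed=10)
        sym = "DOK_tot"
        top = samples[sym].sort_values(ascending=False).index[:100].to_numpy()
        from integrinsim.groups import GroupSelection

        sel = GroupSelection(group1=top, group2=top, fraction=0.02)
        table = rank_parameters(samples, sel, space)
        assert table.loc[sym, "D_g1"] > 0.9
        assert table.loc[sym, "rank"] == 1

    def test_unit_scaling_invariance(self, space):
        """Scaling a parameter and its range leaves its KS distances fixed."""
        from dataclasses import replace
        from integrinsim.groups import GroupSelection

        samples = space.sample(2000, seed=11)
        top = samples["TAL_tot"].sort_values(ascending=False).index[:40].to_numpy()
        sel = GroupSelection(group1=top, group2=top, fraction=0.02)
        t1 = rank_parameters(samples, sel, space)

        scaled = samples.copy()
        scaled["TAL_tot"] *= 1000.0
        entries2 = [
            replace(e, base_value=e.base_value * 1000.0) if e.symbol == "TAL_tot" else e
            for e in space.entries
        ]
        t2 = rank_parameters(scaled, sel, ParameterSpace(entries2))
        assert t2.loc["TAL_tot", "D_g1"] == pytest.approx(t1.loc["TAL_tot", "D_g1"])


class TestGroupMeans:
    def test_singleton_group(self, space):
        samples = space.sample(10, seed=12)
        ps = group_mean_parameters(samples, np.array([3]))
        for sym in samples.columns:
            assert ps[sym] == pytest.approx(samples.loc[3, sym])

    def test_log_symmetric_pair_gives_base(self, space):
        samples = space.sample(2, seed=13)
        base = {e.symbol: e.base_value for e in space.entries}
        samples.loc[0] = {s: base[s] * 4.0 for s in samples.columns}
        samples.loc[1] = {s: base[s] / 4.0 for s in samples.columns}
        ps = group_mean_parameters(samples, np.array([0, 1]))
        for sym in samples.columns:
            assert ps[sym] == pytest.approx(base[sym])
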