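import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from shgmetrics.errors import ParameterError
from shgmetrics.stats import (CrosslinkQuant, collagen_from_hyp,
                              crosslink_density, one_way_anova, pooled_ttest,
                              posthoc_ttests, significance_stars)


def _table(groups: dict, metric="m") -> pd.DataFrame:
    rows = [{"sample_id": f"{g}{i}", "group": g, "metric": metric, "value": v}
            for g, vals in groups.items() for i, v in enumerate(vals)]
    return pd.DataFrame(rows)


class TestCrosslinkNormalization:
    def test_300_hyp_is_one_collagen(self):
        assert collagen_from_hyp(300.0) == (1.0, 300.0)

    def test_zero(self):
        assert collagen_from_hyp(0.0) == (0.0, 0.0)

    def test_negative_rejected(self):
        with pytest.raises(ParameterError):
            collagen_from_hyp(-1.0)

    def test_density_half_crosslink_per_collagen(self):
        q = CrosslinkQuant(pyd_dpd_nmol=0.5, hyp_nmol=300.0)
        assert crosslink_density(q) == pytest.approx(0.5)
        assert crosslink_density(CrosslinkQuant(0.0, 300.0)) == 0.0

    def test_zero_hyp_flagged_nan(self):
        with pytest.warns(UserWarning):
            assert np.isnan(crosslink_density(CrosslinkQuant(0.5, 0.0)))


class TestAnova:
    def test_identical_groups_f_zero_p_one(self):
        res = one_way_anova(_table({"A": [1, 2, 3], "B": [1, 2, 3],
                                    "C": [1, 2, 3]}), "m")
        assert res.f_stat == 0.0 and res.p_value == 1.0

    def test_textbook_two_group_value(self):
        res = one_way_anova(_table({"A": [1, 2, 3], "B": [4, 5, 6]}), "m")
        assert res.f_stat == pytest.approx(13.5, rel=1e-12)
        assert res.p_value == pytest.approx(0.0214, abs=5e-4)

    def test_matches_scipy_on_unequal_n(self, rng):
        groups = {g: rng.normal(i, 1.0, size=n).tolist()
                  for i, (g, n) in enumerate([("A", 4), ("B", 7), ("C", 5)])}
        res = one_way_anova(_table(groups), "m")
        ref = sps.f_oneway(*groups.values())
        assert res.f_stat == pytest.approx(ref.statistic, rel=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_f_equals_t_squared_for_two_groups(self, rng):
        for _ in range(5):
            x = rng.normal(0, 1, 6).tolist()
            y = rng.normal(0.5, 1, 9).tolist()
            res = one_way_anova(_table({"A": x, "B": y}), "m")
            t, p, df, _ = pooled_ttest(np.array(x), np.array(y))
            assert res.f_stat == pytest.approx(t ** 2, rel=1e-10)
            assert res.p_value == pytest.approx(p, rel=1e-10)

    def test_small_group_rejected(self):
        with pytest.raises(ParameterError):
            one_way_anova(_table({"A": [1.0], "B": [1, 2]}), "m")


class TestPosthoc:
    def test_textbook_pair(self):
        out = posthoc_ttests(_table({"A": [1, 2, 3], "B": [4, 5, 6]}), "m")
        row = out.iloc[0]
        assert row.t == pytest.approx(-3.674, abs=5e-4)
        assert row.df == 4
        assert row.p == pytest.approx(0.0214, abs=5e-4)
        assert row.significant

    def test_matches_scipy_ttest_ind(self, rng):
        x, y = rng.normal(0, 1, 8), rng.normal(1, 2, 5)
        t, p, _, _ = pooled_ttest(x, y)
        ref = sps.ttest_ind(x, y, equal_var=True)
        assert t == pytest.approx(ref.statistic, rel=1e-10)
        assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_swap_symmetry(self, rng):
        x, y = rng.normal(0, 1, 6), rng.normal(1, 1, 6)
        t1, p1, _, _ = pooled_ttest(x, y)
        t2, p2, _, _ = pooled_ttest(y, x)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_identical_groups_t_zero_p_one(self):
        out = posthoc_ttests(_table({"A": [2, 2, 2], "B": [2, 2, 2]}), "m")
        assert out.t[0] == 0.0 and out.p[0] == 1.0 and not out.degenerate[0]

    def test_zero_variance_unequal_means_flagged(self):
        out = posthoc_ttests(_table({"A": [1, 1, 1], "B": [2, 2, 2]}), "m")
        assert out.degenerate[0] and np.isinf(out.t[0]) and out.p[0] == 0.0

    def test_star_thresholds(self):
        assert significance_stars(0.03) == "*"
        assert significance_stars(0.009) == "**"
        assert significance_stars(0.0009) == "***"
        assert significance_stars(0.2) == "ns"

    def test_holm_adjustment_monotone(self):
        out = posthoc_ttests(_table({"A": [1, 2, 3], "B": [4, 5, 6],
                                     "C": [1.5, 2.5, 3.5]}), "m", holm=True)
        assert (out.p_adj >= out.p - 1e-15).all()
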