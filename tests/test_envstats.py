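"""Rank-based environmental association tests against enumeration and
permutation oracles."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sagtools.envstats import (
    eligible_samples,
    kruskal_wallis,
    parameter_association,
    posthoc_pairwise,
    split_by_similarity,
    wilcoxon_ranksum,
)
from sagtools.types import StationMeta


def _kw_statistic(groups):
    """Direct rank computation of H with tie correction (oracle)."""
    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)
    n = len(pooled)
    start, H = 0, 0.0
    for g in groups:
        r = ranks[start:start + len(g)]
        H += r.sum() ** 2 / len(g)
        start += len(g)
    H = 12 / (n * (n + 1)) * H - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1 - (counts ** 3 - counts).sum() / (n ** 3 - n)
    return H / tie


class TestKruskalWallis:
    def test_three_group_hand_example(self):
        H, p = kruskal_wallis([[1, 2, 3], [10, 11, 12], [20, 21, 22]])
        assert H == pytest.approx(7.2)
        assert p == pytest.approx(stats.chi2.sf(7.2, 2))

    def test_identical_groups_are_null(self):
        H, p = kruskal_wallis([[4, 4, 4], [4, 4, 4]])
        assert H == 0.0 and p == pytest.approx(1.0)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])

    def test_matches_direct_rank_oracle_with_ties(self, rng):
        for _ in range(20):
            groups = [list(rng.integers(0, 8, rng.integers(3, 7))) for _ in range(3)]
            H, _ = kruskal_wallis(groups)
            assert H == pytest.approx(_kw_statistic(groups))

    def test_p_value_agrees_with_permutation_oracle(self, rng):
        groups = [[3.1, 5.2, 1.0, 4.4], [6.5, 7.1, 2.2, 8.0], [9.3, 0.5, 10.1, 11.6]]
        H_obs, p = kruskal_wallis(groups)
        pooled = np.concatenate(groups)
        sizes = [len(g) for g in groups]
        count = 0
        n_perm = 10_000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            parts = np.split(perm, np.cumsum(sizes)[:-1])
            if _kw_statistic([list(x) for x in parts]) >= H_obs - 1e-12:
                count += 1
        p_perm = count / n_perm
        # chi-square approximation vs Monte-Carlo within 3 MC standard errors + approx slack
        se = (p_perm * (1 - p_perm) / n_perm) ** 0.5
        assert abs(p - p_perm) < 3 * se + 0.02


class TestPosthoc:
    GROUPS = [[1.0, 2, 3, 2.5], [1.5, 2.2, 3.1, 2.8], [40.0, 41, 42, 43]]

    def test_all_pairs_reported_symmetric(self):
        table = posthoc_pairwise(self.GROUPS, labels=list("abc"))
        assert table.shape == (3, 3)
        assert table.loc["a", "b"] == table.loc["b", "a"]
        assert np.isnan(table.loc["a", "a"])

    def test_separated_group_has_smallest_pairwise_p(self):
        table = posthoc_pairwise(self.GROUPS, labels=list("abc"))
        assert table.loc["a", "c"] < table.loc["a", "b"]
        assert table.loc["b", "c"] < table.loc["a", "b"]

    def test_group_permutation_permutes_table(self):
        t1 = posthoc_pairwise(self.GROUPS, labels=list("abc"))
        t2 = posthoc_pairwise([self.GROUPS[2], self.GROUPS[0], self.GROUPS[1]],
                              labels=list("cab"))
        assert t1.loc["a", "c"] == pytest.approx(t2.loc["a", "c"])

    def test_holm_corrected_wilcoxon_mode(self):
        table = posthoc_pairwise(self.GROUPS, labels=list("abc"),
                                 method="wilcoxon_holm")
        assert table.loc["a", "c"] <= 1.0
        assert table.loc["a", "b"] > table.loc["a", "c"]


class TestWilcoxon:
    def test_exact_enumeration_small_samples(self):
        U, p = wilcoxon_ranksum([1, 2, 3], [4, 5, 6])
        assert U == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_samples_p_one(self):
        _, p = wilcoxon_ranksum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_symmetry_under_swap(self, rng):
        x, y = rng.normal(size=12), rng.normal(1.0, 1.0, size=9)
        U1, p1 = wilcoxon_ranksum(x, y)
        U2, p2 = wilcoxon_ranksum(y, x)
        assert U1 == pytest.approx(U2)
        assert p1 == pytest.approx(p2)

    def test_matches_full_enumeration_oracle(self):
        import itertools
        x, y = [2.0, 7.0, 9.0], [1.0, 4.0, 12.0]
        U_obs, p = wilcoxon_ranksum(x, y)
        pooled = x + y
        n = len(x)
        us = []
        for combo in itertools.combinations(range(6), n):
            xs = [pooled[i] for i in combo]
            ys = [pooled[i] for i in range(6) if i not in combo]
            u = sum(1 for a in xs for b in ys if a > b) + \
                0.5 * sum(1 for a in xs for b in ys if a == b)
            us.append(min(u, n * n - u))
        p_exact = sum(1 for u in us if u <= U_obs + 1e-12) / len(us)
        assert p == pytest.approx(p_exact)


class TestSplitsAndEligibility:
    def test_split_by_threshold(self):
        ident = pd.Series({"a": 99.0, "b": 98.0, "c": 92.0, "d": 91.0})
        temps = pd.Series({"a": 20.0, "b": 22.0, "c": 10.0, "d": 12.0})
        near, far = split_by_similarity(ident, temps, threshold=95)
        assert sorted(near) == [20.0, 22.0]
        assert sorted(far) == [10.0, 12.0]

    def test_degenerate_split_warns(self, caplog):
        ident = pd.Series({"a": 99.0, "b": 98.0})
        temps = pd.Series({"a": 1.0, "b": 2.0})
        with caplog.at_level("WARNING"):
            near, far = split_by_similarity(ident, temps, threshold=90)
        assert len(far) == 0 and "degenerate" in caplog.text

    def test_divergent_lineage_at_colder_stations_detected(self, rng):
        # near-reference genotype occupies warm stations, divergent cold ones
        warm = rng.normal(24, 2, size=30)
        cold = rng.normal(15, 2, size=30)
        temps = pd.Series(np.concatenate([warm, cold]),
                          index=[f"s{i}" for i in range(60)])
        ident = pd.Series(np.concatenate([rng.uniform(97, 100, 30),
                                          rng.uniform(88, 94, 30)]),
                          index=temps.index)
        near, far = split_by_similarity(ident, temps)
        _, p = wilcoxon_ranksum(near, far)
        assert p < 0.05

    def test_lineage_below_station_minimum_excluded(self):
        stations = [
            StationMeta(f"ST{i}", "SRF", "Atlantic", float(10 + i), 100,
                        {"salinity_PSU": 35.0 + 0.01 * i})
            for i in range(12)
        ]
        keys = [s.sample for s in stations]
        eligible = {"deep": keys[:6], "wide": keys[6:], "sparse": keys[:3]}
        table = parameter_association(stations, eligible, min_eligible=5)
        assert (table["n_lineages"] == 2).all()

    def test_eligibility_threshold(self):
        frac = pd.Series({"a": 0.19, "b": 0.20, "c": 0.9})
        assert eligible_samples(frac) == ["b", "c"]
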