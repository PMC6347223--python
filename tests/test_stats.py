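"""Tests for cohort-level statistics."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from cryoactin.stats import (
    class_fractions,
    delta_summaries,
    direction_split,
    mann_whitney_u,
    summarize_cohort,
)


def brute_force_mw_p(a, b):
    """Exact two-sided p by enumerating every assignment of pooled ranks."""
    pooled = np.concatenate([a, b])
    n1, n = len(a), len(pooled)
    ranks = pooled.argsort().argsort() + 1.0
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    center = n1 * len(b) / 2
    obs_dev = abs(u_obs - center)
    all_ranks = np.arange(1, n + 1)
    hits = total = 0
    for comb in combinations(range(n), n1):
        u = all_ranks[list(comb)].sum() - n1 * (n1 + 1) / 2
        hits += abs(u - center) >= obs_dev - 1e-9
        total += 1
    return hits / total


class TestMannWhitney:
    def test_identical_samples_give_central_U(self):
        a = [1.0, 2.0, 3.0, 4.0]
        u, p = mann_whitney_u(a, a)
        assert u == pytest.approx(len(a) ** 2 / 2)

    def test_fully_separated_hand_case(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)   # 2 of C(6,3)=20 orderings

    def test_exact_branch_matches_enumeration(self, rng):
        for _ in range(60):
            n1, n2 = rng.integers(3, 8, size=2)
            a = rng.normal(size=int(n1))
            b = rng.normal(rng.uniform(-1, 1), 1, size=int(n2))
            _, p = mann_whitney_u(a, b)
            assert p == pytest.approx(brute_force_mw_p(a, b), abs=1e-9)

    def test_asymptotic_branch_near_exact_on_its_domain(self, rng):
        # the approximation serves min(n) > 8; there it tracks the exact
        # enumeration closely (and within 0.02 down to n = 5)
        for lo, hi in ((5, 8), (9, 13)):
            for _ in range(40):
                n1, n2 = rng.integers(lo, hi, size=2)
                a = rng.normal(size=int(n1))
                b = rng.normal(rng.uniform(-1, 1), 1, size=int(n2))
                pa = mannwhitneyu(a, b, method="asymptotic").pvalue
                pe = mannwhitneyu(a, b, method="exact").pvalue
                assert abs(pa - pe) < 0.02

    def test_ties_fall_back_to_corrected_normal(self):
        a = [1, 1, 2, 2, 3]
        b = [2, 2, 3, 3, 4]
        u, p = mann_whitney_u(a, b)
        assert 0 < p <= 1

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_power_on_planted_location_shift(self):
        # delta scores centred at 0 (control) vs +15, spread 10, n=15/group:
        # the test should flag the shift in >= 80% of repetitions
        gen = np.random.default_rng(42)
        hits = 0
        for _ in range(200):
            a = gen.normal(0, 10, 15)
            b = gen.normal(15, 10, 15)
            hits += mann_whitney_u(a, b)[1] < 0.05
        assert hits >= 0.80 * 200


def _records(rows):
    return pd.DataFrame(rows, columns=["replicate", "assigned_class", "delta_nu",
                                       "delta_F", "delta_L"])


class TestClassFractions:
    def test_single_replicate_all_class_I(self):
        rec = _records([("R1", "I", 0, 0, 0)] * 5)
        out = class_fractions(rec)
        assert out["mean_fraction"].tolist() == [1.0, 0.0, 0.0, 0.0]
        assert out["sd_fraction"].tolist() == [0.0, 0.0, 0.0, 0.0]

    def test_mean_and_sd_across_replicates(self):
        rows = []
        for rep, frac in (("R1", 0.8), ("R2", 0.9), ("R3", 1.0)):
            k = int(frac * 10)
            rows += [(rep, "I", 0, 0, 0)] * k + [(rep, "II", 0, 0, 0)] * (10 - k)
        out = class_fractions(_records(rows)).set_index("assigned_class")
        assert out.loc["I", "mean_fraction"] == pytest.approx(0.9)
        assert out.loc["I", "sd_fraction"] == pytest.approx(0.1)

    def test_fractions_partition_each_replicate(self, rng):
        classes = ["I", "II", "III", "detached"]
        rows = [(f"R{r}", classes[rng.integers(0, 4)], 0, 0, 0)
                for r in range(3) for _ in range(20)]
        out = class_fractions(_records(rows))
        assert out["mean_fraction"].sum() == pytest.approx(1.0, abs=1e-9)


class TestDeltaSummaries:
    def test_median_of_symmetric_triple(self):
        rec = _records([("R1", "II", d, d, d) for d in (-10, 0, 10)])
        assert delta_summaries(rec, "delta_nu")["median"] == 0.0

    def test_linear_interpolation_convention(self):
        rec = _records([("R1", "II", d, d, d) for d in (1, 2, 3, 4)])
        out = delta_summaries(rec, "delta_F")
        assert out["median"] == pytest.approx(2.5)
        assert out["q25"] == pytest.approx(1.75)
        assert out["q75"] == pytest.approx(3.25)

    def test_order_invariance_and_nan_dropping(self, rng):
        vals = list(rng.normal(size=21)) + [math.nan] * 3
        rec1 = _records([("R1", "II", v, v, v) for v in vals])
        rng.shuffle(vals)
        rec2 = _records([("R1", "II", v, v, v) for v in vals])
        s1, s2 = delta_summaries(rec1, "delta_L"), delta_summaries(rec2, "delta_L")
        assert s1["median"] == pytest.approx(s2["median"])
        assert s1["n_dropped"] == 3

    def test_empty_stratum_flagged(self):
        out = delta_summaries(_records([]), "delta_nu")
        assert out["empty"] and math.isnan(out["median"])


class TestDirectionSplit:
    def test_all_increased(self):
        rec = _records([("R1", "II", 5, 5, 5), ("R1", "III", 1, 1, 1)])
        assert direction_split(rec, "delta_nu") == (1.0, 0.0)

    def test_hand_counted_split(self):
        rec = _records([("R1", "II", d, d, d) for d in (5, -3, -7, 1)])
        assert direction_split(rec, "delta_F") == (0.5, 0.5)

    def test_class_I_cells_never_contribute(self):
        rec = _records([("R1", "I", 100, 100, 100), ("R1", "II", -5, -5, -5)])
        assert direction_split(rec, "delta_L") == (0.0, 1.0)


class TestSummarizeCohort:
    @staticmethod
    def _cohort_records(shift=0.0, seed=0):
        gen = np.random.default_rng(seed)
        rows = []
        for cond, mu in (("control", 0.0), ("vitrified", shift)):
            for rep in ("R1", "R2", "R3"):
                for i in range(15):
                    d = gen.normal(mu, 5, 3)
                    rows.append(dict(cell_id=f"{cond}{rep}{i}", replicate=rep,
                                     condition=cond, recovery_min=0,
                                     delta_nu=d[0], delta_F=d[1], delta_L=d[2],
                                     delta_T=float(np.abs(d).mean()),
                                     apoptotic=True, assigned_class="II",
                                     excluded_reason=""))
        return pd.DataFrame(rows)

    def test_planted_shift_flagged_significant(self):
        summary = summarize_cohort(self._cohort_records(shift=15.0, seed=1))
        assert summary.tests["significant"].all()

    def test_null_mostly_not_significant(self):
        summary = summarize_cohort(self._cohort_records(shift=0.0, seed=2))
        assert summary.tests["significant"].sum() <= 1

    def test_detached_excluded_from_deltas_but_in_fractions(self, default_cohort):
        from cryoactin.pipeline import alterations_from_tables

        alt = alterations_from_tables(default_cohort.filament_table,
                                      default_cohort.manifest)
        summary = summarize_cohort(alt)
        det = summary.fractions.query("assigned_class == 'detached'")
        assert (det["mean_fraction"] > 0).any()
        # delta summaries count dropped (detached/excluded) cells separately
        n_det = int(default_cohort.manifest["detached"].sum())
        dropped = summary.deltas.groupby(["condition", "recovery_min"])["n_dropped"].first().sum()
        assert dropped >= n_det
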