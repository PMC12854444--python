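"""Limit of blank, positivity calling, cohort summaries, rank tests."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from methplex import (
    DropletWell,
    LobTable,
    WellSimConfig,
    blank_counts_from_wells,
    call_sample,
    clopper_pearson_interval,
    duplex_multiplex_agreement,
    estimate_lob,
    group_difference_test,
    simulate_blank_cohort,
    simulate_well,
    summarize_cohort,
    validate_lob,
    wald_interval,
)
from methplex.panel import DEFAULT_PANEL
from methplex.simulate import DEFAULT_BLANK_FP_RATES


def _sample_wells(positives_by_marker, sample="s1", alb=2000, accepted=20000):
    wells = [
        DropletWell(f"{sample}_{m}", sample, m, p, accepted)
        for m, p in positives_by_marker.items()
    ]
    wells.append(DropletWell(f"{sample}_ALB", sample, "ALB", alb, accepted))
    return wells


class TestEstimateLob:
    def test_all_zero_blanks(self):
        table = estimate_lob({"EVX1": [0] * 40})
        assert table["EVX1"] == 0

    def test_sort_and_index_rule(self):
        counts = [0] * 38 + [1, 5]
        assert estimate_lob({"m": counts}, confidence=0.95)["m"] == 0
        assert estimate_lob({"m": counts}, confidence=0.99)["m"] == 5

    def test_constant_blanks_any_confidence(self):
        for conf in (0.5, 0.9, 0.95, 0.99):
            assert estimate_lob({"m": [3] * 25}, confidence=conf)["m"] == 3

    def test_monotone_in_confidence_and_permutation_invariant(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(1.0, size=40)
        prev = -1
        for conf in (0.5, 0.8, 0.9, 0.95, 0.99):
            val = estimate_lob({"m": counts}, confidence=conf)["m"]
            assert val >= prev
            prev = val
        shuffled = rng.permutation(counts)
        assert (
            estimate_lob({"m": counts})["m"] == estimate_lob({"m": shuffled})["m"]
        )

    def test_empty_blanks_rejected(self):
        with pytest.raises(ValueError, match="no blank"):
            estimate_lob({"m": []})

    def test_small_cohort_warns(self):
        with pytest.warns(UserWarning, match="unstable"):
            estimate_lob({"m": [0] * 5})

    def test_matches_sort_and_index_oracle_on_random_cohorts(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            n = int(rng.integers(20, 60))
            counts = rng.poisson(rng.uniform(0.05, 3.0), size=n)
            conf = float(rng.uniform(0.8, 0.99))
            oracle = int(np.sort(counts)[math.ceil(conf * n) - 1])
            assert estimate_lob({"m": counts}, confidence=conf)["m"] == oracle

    def test_clsi_variant_close_to_rank(self):
        counts = list(range(40))
        rank = estimate_lob({"m": counts}, method="rank")["m"]
        clsi = estimate_lob({"m": counts}, method="clsi")["m"]
        assert abs(rank - clsi) <= 1


class TestValidateLob:
    def test_no_exceedance_confirms(self):
        table = estimate_lob({"m": [0] * 40})
        assert validate_lob(table, {"m": [0] * 40}) == {"m": True}

    def test_boundary_five_percent_confirms(self):
        table = LobTable({"m": 1}, {"m": 40})
        counts = [0] * 38 + [2, 2]  # exactly 5% exceed
        assert validate_lob(table, {"m": counts})["m"]

    def test_seven_percent_exceedance_rejected(self):
        table = LobTable({"m": 1}, {"m": 40})
        counts = [0] * 37 + [2, 2, 2]  # 7.5% exceed
        assert not validate_lob(table, {"m": counts})["m"]


class TestCallSample:
    def test_all_equal_to_lob_is_negative(self, paper_lob):
        wells = _sample_wells(dict(paper_lob.lob))
        call = call_sample(wells, paper_lob)
        assert not call.overall_positive and call.n_positive_markers == 0

    def test_single_conserved_marker_pattern(self, paper_lob):
        # ACTRT2-only positivity: conserved-any true, specific-any false
        pos = dict(paper_lob.lob)
        pos["ACTRT2"] = paper_lob["ACTRT2"] + 10
        call = call_sample(_sample_wells(pos), paper_lob)
        assert call.overall_positive and call.n_positive_markers == 1
        assert call.positive_conserved and not call.positive_specific

    def test_mixed_type_pattern(self, paper_lob):
        # EVX1 + HAPLN3: both marker types represented
        pos = dict(paper_lob.lob)
        pos["EVX1"] += 5
        pos["HAPLN3"] += 5
        call = call_sample(_sample_wells(pos), paper_lob)
        assert call.positive_conserved and call.positive_specific
        assert call.n_positive_markers == 2

    def test_missing_marker_rejected(self, paper_lob):
        wells = _sample_wells({"ACTRT2": 0, "EVX1": 0})
        with pytest.raises(ValueError, match="missing marker"):
            call_sample(wells, paper_lob)

    def test_missing_alb_flags_fractions_undefined(self, paper_lob):
        pos = {m: paper_lob[m] + 3 for m in DEFAULT_PANEL.markers}
        wells = [
            DropletWell(f"w_{m}", "s1", m, p, 20000) for m, p in pos.items()
        ]
        call = call_sample(wells, paper_lob)
        assert call.overall_positive
        assert all(v is None for v in call.ctdna_fraction_pct.values())

    def test_zero_lob_reduces_to_any_droplet(self):
        zero = LobTable({m: 0 for m in DEFAULT_PANEL.markers},
                        {m: 40 for m in DEFAULT_PANEL.markers})
        pos = {m: 0 for m in DEFAULT_PANEL.markers}
        pos["DOCK2"] = 1
        call = call_sample(_sample_wells(pos), zero)
        assert call.overall_positive and call.n_positive_markers == 1


class TestSummarizeCohort:
    def _calls(self, patterns, paper_lob):
        calls = []
        for i, pat in enumerate(patterns):
            pos = {
                m: paper_lob[m] + (5 if m in pat else 0)
                for m in DEFAULT_PANEL.markers
            }
            calls.append(
                call_sample(_sample_wells(pos, sample=f"s{i}"), paper_lob)
            )
        return calls

    def test_19_of_20_wald(self, paper_lob):
        patterns = [set(DEFAULT_PANEL.markers)] * 19 + [set()]
        summary = summarize_cohort(self._calls(patterns, paper_lob))
        assert summary.sensitivity_pct == pytest.approx(95.0)
        assert summary.ci95_reported == (85, 100)

    def test_zero_of_n(self, paper_lob):
        summary = summarize_cohort(self._calls([set()] * 10, paper_lob))
        assert summary.sensitivity_pct == 0 and summary.ci95[0] == 0

    def test_all_positive_truncates_upper(self, paper_lob):
        patterns = [set(DEFAULT_PANEL.markers)] * 20
        summary = summarize_cohort(self._calls(patterns, paper_lob))
        assert summary.sensitivity_pct == 100 and summary.ci95[1] == 100

    def test_count_ordering_invariant(self, paper_lob):
        rng = np.random.default_rng(3)
        markers = list(DEFAULT_PANEL.markers)
        patterns = [
            set(rng.choice(markers, size=rng.integers(0, 6), replace=False))
            for _ in range(30)
        ]
        s = summarize_cohort(self._calls(patterns, paper_lob))
        assert (
            s.n_all_five
            <= min(s.n_conserved_any, s.n_specific_any)
            <= s.n_positive
            <= s.n
        )


class TestBinomialIntervals:
    def test_wald_19_of_20(self):
        lo, hi = wald_interval(19, 20)
        assert round(lo) == 85 and hi == 100.0

    def test_clopper_pearson_differs_from_wald(self):
        lo, hi = clopper_pearson_interval(19, 20)
        assert round(lo) == 75  # deliberately not the Wald bound
        assert hi > 99

    @given(st.integers(0, 30), st.integers(1, 30))
    def test_bounds_truncated_to_percent_scale(self, k, n):
        k = min(k, n)
        lo, hi = wald_interval(k, n)
        assert 0 <= lo <= hi <= 100


class TestGroupDifference:
    def test_identical_groups_p_one(self):
        res = group_difference_test([1, 2, 3], [1, 2, 3])
        assert res.p_value == pytest.approx(1.0) and res.method == "exact"

    def test_fully_separated_small_groups(self):
        res = group_difference_test([1, 2, 3], [10, 11, 12])
        assert res.u == 0 and res.p_value == pytest.approx(0.1)

    def test_exact_matches_brute_force_enumeration(self):
        # oracle: U from pairwise comparisons over every label assignment
        rng = np.random.default_rng(4)
        for n1 in range(2, 5):
            for n2 in range(n1, 5):
                a = rng.integers(0, 4, n1).astype(float)
                b = rng.integers(0, 4, n2).astype(float)
                res = group_difference_test(a, b)
                pooled = np.concatenate([a, b])
                mean_u = n1 * n2 / 2
                u_obs = sum(
                    1.0 if x > y else 0.5 if x == y else 0.0
                    for x in a for y in b
                )
                count = total = 0
                for combo in itertools.combinations(range(n1 + n2), n1):
                    ca = pooled[list(combo)]
                    cb = pooled[[i for i in range(n1 + n2) if i not in combo]]
                    u = sum(
                        1.0 if x > y else 0.5 if x == y else 0.0
                        for x in ca for y in cb
                    )
                    if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-9:
                        count += 1
                    total += 1
                assert res.p_value == pytest.approx(count / total)

    def test_exact_agrees_with_scipy_without_ties(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=6)
        b = rng.normal(1.0, size=7)
        res = group_difference_test(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_large_separated_groups_significant(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 1, 21)
        b = rng.normal(4, 1, 20)
        res = group_difference_test(a, b)
        assert res.method == "normal" and res.p_value < 1e-4

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_difference_test([], [1.0])


class TestDuplexMultiplexAgreement:
    def test_identical_pairs(self):
        fit = duplex_multiplex_agreement([1, 2, 3], [1, 2, 3])
        assert fit.slope == pytest.approx(1) and fit.r_squared == pytest.approx(1)

    def test_exact_attenuation(self):
        x = [10.0, 20.0, 30.0, 40.0]
        fit = duplex_multiplex_agreement(x, [0.9 * v for v in x])
        assert fit.slope == pytest.approx(0.9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_simulated_paired_wells_agree(self):
        cfg = WellSimConfig(seed=7)
        rng = np.random.default_rng(7)
        duplex, multiplex = [], []
        for copies in (50, 150, 450, 1350, 4050):
            for _ in range(2):
                w1 = simulate_well(copies, cfg, rng)
                w2 = simulate_well(copies, cfg, rng)
                from methplex import poisson_concentration

                duplex.append(poisson_concentration(w1.positives, w1.accepted).conc_per_ul)
                multiplex.append(poisson_concentration(w2.positives, w2.accepted).conc_per_ul)
        fit = duplex_multiplex_agreement(duplex, multiplex)
        assert fit.r_squared > 0.95


class TestSpecificityByConstruction:
    def test_fresh_blank_cohorts_rarely_exceed_lob(self):
        # light version of the specificity property: LOB from one cohort,
        # false-positive rate on 20 fresh cohorts stays near 1 - confidence
        train = simulate_blank_cohort(
            40, DEFAULT_BLANK_FP_RATES, WellSimConfig(seed=100)
        )
        table = estimate_lob(blank_counts_from_wells(train))
        exceed = {m: 0 for m in DEFAULT_PANEL.markers}
        total = 0
        for i in range(20):
            fresh = simulate_blank_cohort(
                40, DEFAULT_BLANK_FP_RATES, WellSimConfig(seed=200 + i)
            )
            counts = blank_counts_from_wells(fresh)
            for m in DEFAULT_PANEL.markers:
                exceed[m] += int((counts[m] > table[m]).sum())
            total += 40
        tol = 2.58 * math.sqrt(0.05 * 0.95 / total)
        for m, k in exceed.items():
            assert k / total <= 0.05 + tol
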