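"""Three-rule event classification (vs a brute-force window-enumeration
oracle), switching frequencies, and the rank-sum/Fisher tests (vs
enumeration oracles)."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from mtdynamics import DIParams, add_measurement_noise, simulate_length_trace
from mtdynamics._stats import ols_line
from mtdynamics.invivo import (
    classify_events,
    catastrophe_frequency,
    event_rate_invivo,
    fisher_exact_2x2,
    rank_sum_test,
    rescue_frequency,
    summarize_condition,
    summarize_microtubule,
)
from conftest import make_trace


def qualifying_windows(trace, min_points=3, min_delta_um=0.5, min_r2=0.80):
    """All windows satisfying the three rules, via brute force."""
    n = len(trace)
    out = []
    for i in range(n - min_points + 1):
        for j in range(i + min_points - 1, n):
            dl = trace.lengths_um[j] - trace.lengths_um[i]
            if abs(dl) < min_delta_um:
                continue
            slope, _, r2 = ols_line(
                trace.times_s[i : j + 1], trace.lengths_um[i : j + 1]
            )
            if r2 >= min_r2 and slope * dl > 0:
                out.append((i, j, "assembly" if dl > 0 else "disassembly"))
    return out


def oracle_single_switch(trace, **cfg):
    """Best two-event cover for a rise-fall (or fall-rise) trace: the pair
    of qualifying windows, sharing at most the turning point, that covers
    the most samples (ties: higher total R²)."""
    wins = qualifying_windows(trace, **cfg)
    best = None
    for a, b in itertools.combinations(wins, 2):
        if a[1] > b[0]:
            a, b = b, a
        if a[1] > b[0]:
            continue
        cover = (a[1] - a[0]) + (b[1] - b[0])
        r2 = sum(
            ols_line(trace.times_s[i : j + 1], trace.lengths_um[i : j + 1])[2]
            for i, j, _ in (a, b)
        )
        key = (cover, r2)
        if best is None or key > best[0]:
            best = (key, [a, b])
    return None if best is None else best[1]


class TestClassifyEvents:
    def test_exact_line_single_assembly_event(self):
        trace = make_trace([0.0, 0.3, 0.6, 0.9], dt_s=4.0)
        events = classify_events(trace)
        assert len(events) == 1
        e = events[0]
        assert e.kind == "assembly"
        assert e.delta_length_um == pytest.approx(0.9)
        assert e.r_squared == pytest.approx(1.0)
        assert e.rate_um_min == pytest.approx(4.5)

    def test_small_change_rejected(self):
        trace = make_trace([0.0, 0.2, 0.4], dt_s=4.0)
        assert classify_events(trace) == []

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            classify_events(make_trace([0.0, 1.0]))

    def test_every_event_satisfies_all_three_rules(self, wildtype_invivo_params):
        for seed in range(10):
            tr = add_measurement_noise(
                simulate_length_trace(wildtype_invivo_params, 400.0, 4.0, seed),
                0.05,
                50 + seed,
            )
            for e in classify_events(tr):
                assert e.n_points >= 3
                assert abs(e.delta_length_um) >= 0.5
                assert e.r_squared >= 0.80

    def test_tightening_thresholds_never_adds_events(self, wildtype_invivo_params):
        tr = add_measurement_noise(
            simulate_length_trace(wildtype_invivo_params, 600.0, 4.0, 3), 0.05, 4
        )
        base = len(classify_events(tr))
        assert len(classify_events(tr, min_delta_um=0.8)) <= base
        assert len(classify_events(tr, min_r2=0.9)) <= base
        assert len(classify_events(tr, min_points=5)) <= base

    def test_matches_enumeration_oracle_on_single_switch_traces(self):
        rng = np.random.default_rng(6)
        checked = 0
        for rep in range(30):
            k = int(rng.integers(6, 12))
            n = k + int(rng.integers(6, 12))
            t = np.arange(n) * 4.0
            up, dn = 0.03, 0.05  # μm per frame-second slopes scaled below
            y = np.where(
                np.arange(n) <= k,
                0.5 + 0.12 * np.arange(n),
                0.5 + 0.12 * k - 0.18 * (np.arange(n) - k),
            )
            y = np.maximum(y + rng.normal(0, 0.04, n), 0.0)
            trace = make_trace(y, dt_s=4.0)
            oracle = oracle_single_switch(trace)
            got = classify_events(trace)
            if oracle is None:
                continue
            checked += 1
            assert len(got) == 2, f"rep {rep}: expected 2 events, got {len(got)}"
            for ev, (oi, oj, okind) in zip(got, oracle):
                assert ev.kind == okind
                assert abs(ev.start_idx - oi) <= 2
                assert abs(ev.end_idx - oj) <= 2
        assert checked >= 20

    def test_events_time_ordered_with_disjoint_interiors(self, wildtype_invivo_params):
        tr = add_measurement_noise(
            simulate_length_trace(wildtype_invivo_params, 600.0, 4.0, 8), 0.05, 9
        )
        events = classify_events(tr)
        for a, b in zip(events, events[1:]):
            assert a.end_idx <= b.start_idx


class TestRatesAndFrequencies:
    def test_event_rate_arithmetic(self):
        trace = make_trace([0.0, 0.3, 0.6, 0.9], dt_s=4.0)
        e = classify_events(trace)[0]
        assert event_rate_invivo(e, 4.0) == pytest.approx(4.5)

    def test_catastrophe_frequency_formula(self):
        assert catastrophe_frequency(2, 300.0, 60.0) == pytest.approx(0.5)
        assert catastrophe_frequency(0, 300.0, 60.0) == 0.0
        with pytest.raises(ValueError):
            catastrophe_frequency(1, 60.0, 60.0)

    def test_rescue_frequency_formula(self):
        assert rescue_frequency(1, 240.0, 120.0) == pytest.approx(0.5)
        assert rescue_frequency(0, 240.0, 120.0) == 0.0

    def test_frequencies_recovered_in_detectable_regime(self):
        # velocities/hazards chosen so nearly all excursions exceed the
        # 0.5-μm rule; pooled recovery should then be within 10%
        p = DIParams(v_grow=4.0, v_shrink=10.0, f_cat=0.2, f_res=1.0, seed_length_um=0.0)
        n_cat = n_res = 0
        t_no_dis = t_no_as = 0.0
        for seed in range(120):
            tr = add_measurement_noise(
                simulate_length_trace(p, 1800.0, 4.0, 900 + seed), 0.05, 1900 + seed
            )
            s = summarize_microtubule(tr)
            n_cat += s.n_catastrophes
            n_res += s.n_rescues
            t_no_dis += (s.lifetime_s - s.time_in_disassembly_s) / 60.0
            t_no_as += (s.lifetime_s - s.time_in_assembly_s) / 60.0
        assert n_cat >= 500
        assert n_cat / t_no_dis == pytest.approx(0.2, rel=0.10)
        assert n_res / t_no_as == pytest.approx(1.0, rel=0.10)

    def test_frequency_invariant_to_frame_interval(self):
        p = DIParams(v_grow=4.0, v_shrink=10.0, f_cat=0.2, f_res=1.0, seed_length_um=0.0)
        est = {}
        for dt in (3.0, 5.0):
            n_cat, t_no_dis = 0, 0.0
            for seed in range(60):
                tr = add_measurement_noise(
                    simulate_length_trace(p, 600.0, dt, 300 + seed), 0.05, 400 + seed
                )
                s = summarize_microtubule(tr)
                n_cat += s.n_catastrophes
                t_no_dis += (s.lifetime_s - s.time_in_disassembly_s) / 60.0
            est[dt] = n_cat / t_no_dis
        assert est[3.0] == pytest.approx(est[5.0], rel=0.10)


class TestSummarizeCondition:
    def test_single_microtubule_degenerate(self):
        trace = make_trace([0.0, 0.3, 0.6, 0.9], dt_s=4.0)
        s = summarize_microtubule(trace)
        out = summarize_condition([s])
        assert out["median_poly_rate_um_min"] == pytest.approx(4.5)
        lo, hi = out["ci_poly_rate_um_min"]
        assert lo == hi == pytest.approx(4.5)

    def test_odd_n_median_is_middle_order_statistic(self):
        from mtdynamics._stats import median_ci

        med, _, _ = median_ci([3.0, 1.0, 2.0, 5.0, 4.0])
        assert med == 3.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_condition([])


class TestRankSum:
    def test_complete_separation_exact_p(self):
        u, p = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(2.0 / math.comb(6, 3))

    def test_identical_samples_p_one(self):
        u, p = rank_sum_test([1.0, 1.0, 2.0], [1.0, 1.0, 2.0])
        assert p == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])

    def test_matches_permutation_oracle_small_n(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            a = rng.integers(0, 6, rng.integers(3, 6)).astype(float)
            b = rng.integers(0, 6, rng.integers(3, 6)).astype(float)
            u, p = rank_sum_test(a, b)
            # oracle: full permutation distribution of U with midranks
            pooled = np.concatenate([a, b])
            ranks = stats.rankdata(pooled)
            m = len(a)
            const = m * (m + 1) / 2.0
            us = [
                sum(ranks[list(c)]) - const
                for c in itertools.combinations(range(len(pooled)), m)
            ]
            us = np.asarray(us)
            p_le = np.mean(us <= u + 1e-9)
            p_ge = np.mean(us >= u - 1e-9)
            p_oracle = min(1.0, 2.0 * min(p_le, p_ge))
            assert p == pytest.approx(p_oracle)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            a = rng.normal(0, 1, 6)
            b = rng.normal(0.5, 1, 7)
            _, p = rank_sum_test(a, b)
            ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert p == pytest.approx(ref.pvalue)

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.8, 1, 25)
        _, p = rank_sum_test(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert p == pytest.approx(ref.pvalue)


def hypergeom_fisher(table):
    """Independent two-sided Fisher oracle: sum hypergeometric
    probabilities of all tables (same margins) no more probable than the
    observed one."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = prob(a)
    return sum(
        prob(x)
        for x in range(max(0, c1 - r2), min(r1, c1) + 1)
        if prob(x) <= p_obs * (1 + 1e-9)
    )


class TestFisherExact:
    def test_perfect_association(self):
        assert fisher_exact_2x2([[0, 5], [5, 0]]) == pytest.approx(2.0 / 252.0)

    def test_symmetric_table_p_one(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -2], [3, 4]])
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1.5, 2], [3, 4]])

    def test_matches_enumeration_for_all_small_margins(self):
        for a in range(5):
            for b in range(5):
                for c in range(5):
                    for d in range(5):
                        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                            continue
                        table = [[a, b], [c, d]]
                        assert fisher_exact_2x2(table) == pytest.approx(
                            hypergeom_fisher(table)
                        ), table
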