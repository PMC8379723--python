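import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pairforage import (
    IndividualTimeline,
    PairSchedule,
    SimConfig,
    compute_stats,
    load_published_coordination,
    nest_attendance,
    partner_present_at_departure,
    randomisation_test,
    randomise_schedule,
    simulate_pair_schedule,
    summarise_population,
)
from pairforage.coordination import DegenerateScheduleError


def tl(trips, bouts, window=(0.0, 10.0)):
    return IndividualTimeline(np.asarray(trips, float), np.asarray(bouts, float), window)


class TestPartnerPresence:
    def test_partner_never_leaves(self):
        focal = tl([[2, 4], [6, 8]], [[0, 2], [4, 6], [8, 10]])
        partner = tl(np.empty((0, 2)), [[0, 10]])
        prop, n = partner_present_at_departure(focal, partner)
        assert prop == 1.0 and n == 2

    def test_hand_traced_half(self):
        focal = tl([[5, 6], [7, 10]], [[0, 5], [6, 7]])
        partner = tl([[0, 4], [6, 8]], [[4, 6], [8, 10]])
        prop, n = partner_present_at_departure(focal, partner)
        assert prop == 0.5 and n == 2

    def test_return_instant_counts_departure_does_not(self):
        focal = tl([[5, 10]], [[0, 5]])
        returning = tl([[0, 5]], [[5, 10]])   # partner returns exactly at t=5
        departing = tl([[5, 10]], [[0, 5]])   # partner departs exactly at t=5
        assert partner_present_at_departure(focal, returning)[0] == 1.0
        assert partner_present_at_departure(focal, departing)[0] == 0.0

    def test_censored_start_excluded(self):
        focal = IndividualTimeline(np.array([[0.0, 3.0], [5.0, 8.0]]),
                                   np.array([[3.0, 5.0], [8.0, 10.0]]), (0.0, 10.0))
        partner = tl(np.empty((0, 2)), [[0, 10]])
        assert focal.trip_censored_start[0]
        prop, n = partner_present_at_departure(focal, partner)
        assert n == 1

    def test_no_eligible_departures_flagged(self):
        focal = IndividualTimeline(np.array([[0.0, 10.0]]), np.empty((0, 2)), (0.0, 10.0))
        partner = tl(np.empty((0, 2)), [[0, 10]])
        prop, n = partner_present_at_departure(focal, partner)
        assert n == 0 and np.isnan(prop)


class TestAttendance:
    def test_full_cover(self):
        pair = PairSchedule("x", tl([[6, 10]], [[0, 6]]), tl([[0, 4]], [[4, 10]]))
        assert nest_attendance(pair) == pytest.approx(1.0)

    def test_partial_cover(self):
        pair = PairSchedule("x", tl([[4, 10]], [[0, 4]]), tl([[0, 6]], [[6, 10]]))
        assert nest_attendance(pair) == pytest.approx(0.8)

    def test_union_dominates_single_parent(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            cuts = np.sort(rng.uniform(0, 10, 4))
            m = tl([[cuts[0], cuts[1]], [cuts[2], cuts[3]]],
                   [[0, cuts[0]], [cuts[1], cuts[2]], [cuts[3], 10]])
            f = tl([[0, 5]], [[5, 10]])
            pair = PairSchedule("x", m, f)
            assert nest_attendance(pair) >= max(m.in_colony_fraction(),
                                                f.in_colony_fraction()) - 1e-12


class TestRandomiseSchedule:
    def test_single_trip_single_bout_identity(self):
        t = tl([[4, 10]], [[0, 4]])
        out = randomise_schedule(t, np.random.default_rng(0))
        np.testing.assert_allclose(out.trips, t.trips)
        np.testing.assert_allclose(out.bouts, t.bouts)

    def test_duration_multisets_preserved(self):
        t = tl([[1, 3], [4, 8], [9, 10]], [[0, 1], [3, 4], [8, 9]])
        rng = np.random.default_rng(1)
        for _ in range(50):
            out = randomise_schedule(t, rng, overrun="clip")
            np.testing.assert_allclose(
                np.sort(out.trips[:, 1] - out.trips[:, 0]),
                np.sort(t.trips[:, 1] - t.trips[:, 0]))
            np.testing.assert_allclose(
                np.sort(out.bouts[:, 1] - out.bouts[:, 0]),
                np.sort(t.bouts[:, 1] - t.bouts[:, 0]))
            out.check_tiling()

    def test_uniform_over_arrangements(self):
        # 3 distinct trips x 3 distinct bouts = 36 equally likely orders
        t = tl([[1, 2], [3.5, 6], [8, 15]], [[0, 1], [2, 3.5], [6, 8]], window=(0.0, 15.0))
        rng = np.random.default_rng(7)
        counts = {}
        n_draws = 10000
        for _ in range(n_draws):
            out = randomise_schedule(t, rng, overrun="clip")
            key = (tuple(np.round(out.trips[:, 1] - out.trips[:, 0], 9)),
                   tuple(np.round(out.bouts[:, 1] - out.bouts[:, 0], 9)))
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 36
        chi = stats.chisquare(list(counts.values()))
        assert chi.pvalue > 1e-3

    def test_pin_keeps_final_interval(self):
        t = tl([[1, 2], [3.5, 6], [8, 15]], [[0, 1], [2, 3.5], [6, 8]], window=(0.0, 15.0))
        rng = np.random.default_rng(3)
        final = t.trips[-1, 1] - t.trips[-1, 0]
        for _ in range(20):
            out = randomise_schedule(t, rng, overrun="pin")
            assert out.trips[-1, 1] - out.trips[-1, 0] == pytest.approx(final)


def oracle_pinned_null(pair):
    """Independent exhaustive enumeration of the pinned randomisation null."""
    def arrangements(t):
        seq = t.alternation()
        tdur = list(t.trips[:, 1] - t.trips[:, 0])
        bdur = list(t.bouts[:, 1] - t.bouts[:, 0])
        tmask, bmask = t.permutable_masks("pin")
        t_idx = [i for i in range(len(tdur)) if tmask[i]]
        b_idx = [i for i in range(len(bdur)) if bmask[i]]
        outs = []
        for tp in itertools.permutations(t_idx):
            for bp in itertools.permutations(b_idx):
                td = list(tdur)
                bd = list(bdur)
                for dst, src in zip(t_idx, tp):
                    td[dst] = tdur[src]
                for dst, src in zip(b_idx, bp):
                    bd[dst] = bdur[src]
                outs.append((seq, td, bd))
        return outs

    def rebuild(seq, td, bd, w0):
        trips, bouts = [], []
        ti = bi = 0
        cur = w0
        for c in seq:
            if c == "t":
                trips.append((cur, cur + td[ti])); cur += td[ti]; ti += 1
            else:
                bouts.append((cur, cur + bd[bi])); cur += bd[bi]; bi += 1
        return trips, bouts

    def four_stats(mt, mb, ft, fb, L, lead_m, lead_f):
        def pres(dep, bouts):
            return [any(s <= t < e for s, e in bouts) for t in dep]
        dep_m = [t[0] for t in mt][1 if lead_m else 0:]
        dep_f = [t[0] for t in ft][1 if lead_f else 0:]
        km, kf = sum(pres(dep_m, fb)), sum(pres(dep_f, mb))
        inter = sum(max(0.0, min(e1, e2) - max(s1, s2))
                    for s1, e1 in mb for s2, e2 in fb)
        att = (sum(e - s for s, e in mb) + sum(e - s for s, e in fb) - inter) / L
        return (km / len(dep_m), kf / len(dep_f),
                (km + kf) / (len(dep_m) + len(dep_f)), att)

    w0, w1 = pair.window
    L = w1 - w0
    null = []
    for seq_m, tdm, bdm in arrangements(pair.male):
        mt, mb = rebuild(seq_m, tdm, bdm, w0)
        for seq_f, tdf, bdf in arrangements(pair.female):
            ft, fb = rebuild(seq_f, tdf, bdf, w0)
            null.append(four_stats(mt, mb, ft, fb, L,
                                   seq_m[0] == "t", seq_f[0] == "t"))
    return np.asarray(null)


class TestRandomisationTest:
    def _random_small_pair(self, rng, n_trips=2):
        def one():
            cuts = np.sort(rng.uniform(0.5, 19.5, 2 * n_trips))
            trips, bouts = [], []
            prev = 0.0
            for k in range(n_trips):
                s, e = cuts[2 * k], cuts[2 * k + 1]
                bouts.append([prev, s])
                trips.append([s, e])
                prev = e
            bouts.append([prev, 20.0])
            return IndividualTimeline(np.array(trips), np.array(bouts), (0.0, 20.0))
        return PairSchedule("p", one(), one())

    def test_exact_path_matches_independent_oracle(self):
        rng = np.random.default_rng(5)
        for k in range(4):
            pair = self._random_small_pair(rng, n_trips=2 + k % 2)
            res = randomisation_test(pair, rng=np.random.default_rng(k))
            assert res.exact
            null = oracle_pinned_null(pair)
            obs = compute_stats(pair).as_array()
            p_oracle = (null >= obs[None, :] - 1e-12).mean(axis=0)
            np.testing.assert_allclose(res.p, p_oracle, atol=1e-12)
            np.testing.assert_allclose(res.expected.as_array(), null.mean(axis=0),
                                       atol=1e-12)

    def test_difference_identity_and_p_range(self):
        cfg = SimConfig(days=10.0, seed=2)
        pair = PairSchedule.from_simulation(simulate_pair_schedule(cfg, "P1"), cfg.window_h)
        res = randomisation_test(pair, n_rep=199, rng=np.random.default_rng(0))
        np.testing.assert_allclose(
            res.difference, res.observed.as_array() - res.expected.as_array(), atol=1e-12)
        assert np.all(res.p > 0) and np.all(res.p <= 1)

    def test_null_preserves_total_times(self):
        cfg = SimConfig(days=10.0, seed=8)
        pair = PairSchedule.from_simulation(simulate_pair_schedule(cfg, "P2"), cfg.window_h)
        rng = np.random.default_rng(1)
        for tl_ in (pair.male, pair.female):
            for _ in range(10):
                out = randomise_schedule(tl_, rng)
                assert np.sum(out.trips[:, 1] - out.trips[:, 0]) == pytest.approx(
                    np.sum(tl_.trips[:, 1] - tl_.trips[:, 0]), rel=1e-12)
                assert np.sum(out.bouts[:, 1] - out.bouts[:, 0]) == pytest.approx(
                    np.sum(tl_.bouts[:, 1] - tl_.bouts[:, 0]), rel=1e-12)

    def test_degenerate_schedule_untestable(self):
        pair = PairSchedule("p", tl([[4, 10]], [[0, 4]]), tl([[2, 6]], [[0, 2], [6, 10]]))
        res = randomisation_test(pair, rng=np.random.default_rng(0))
        assert res.untestable and np.all(np.isnan(res.p))

    def test_power_monotone_in_coordination(self):
        rates = []
        for w in (0.0, 0.5, 1.0):
            cfg = SimConfig(coordination_prob=w, seed=101)
            rng = np.random.default_rng(55)
            rej = n = 0
            for k in range(20):
                ps = PairSchedule.from_simulation(
                    simulate_pair_schedule(cfg, f"P{k:02d}"), cfg.window_h)
                r = randomisation_test(ps, n_rep=199, rng=rng)
                if not r.untestable:
                    n += 1
                    rej += r.p[2] < 0.05
            rates.append(rej / n)
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] >= 0.9


class TestPopulationSummary:
    def test_published_table_reproduces_printed_averages(self):
        df = load_published_coordination()
        s = summarise_population(df)
        assert round(s.loc["male", "mean_observed"], 3) == 0.815
        assert round(s.loc["female", "mean_observed"], 3) == 0.835
        assert round(s.loc["attendance", "mean_observed"], 4) == 0.9304
        assert round(s.loc["male", "mean_difference"], 3) == 0.341
        assert round(s.loc["female", "mean_difference"], 3) == 0.423
        assert round(s.loc["attendance", "mean_difference"], 3) == 0.135
        assert s.loc["male", "n_significant"] == 22
        assert s.loc["female", "n_significant"] == 23
        assert s.loc["male", "n_pairs"] == 25

    def test_identical_pairs_mean_is_common_value(self):
        row = {f"observed_{k}": 0.7 for k in ("male", "female", "partner", "attendance")}
        row.update({f"expected_{k}": 0.5 for k in ("male", "female", "partner", "attendance")})
        row.update({f"difference_{k}": 0.2 for k in ("male", "female", "partner", "attendance")})
        row.update({f"p_{k}": 0.01 for k in ("male", "female", "partner", "attendance")})
        df = pd.DataFrame([row] * 5)
        s = summarise_population(df)
        assert (s["mean_observed"] == 0.7).all()
        assert (s["n_significant"] == 5).all()


class TestAttendanceVsAge:
    def test_daily_attendance_partitions_window(self):
        cfg = SimConfig(days=5.0, seed=6)
        pair = PairSchedule.from_simulation(simulate_pair_schedule(cfg, "A"), cfg.window_h)
        from pairforage import daily_attendance
        df = daily_attendance(pair)
        assert len(df) == 5
        assert df["attendance"].between(0, 1).all()

    def test_declining_bouts_give_negative_attendance_slope(self):
        # w=0 so that attendance tracks the bout/trip balance directly;
        # departure gating would otherwise hold attendance high at all ages
        from pairforage import attendance_vs_age
        cfg = SimConfig(seed=14, coordination_prob=0.0)  # beta_age < 0 by default
        pairs = [PairSchedule.from_simulation(simulate_pair_schedule(cfg, f"A{k}"),
                                              cfg.window_h) for k in range(15)]
        fit = attendance_vs_age(pairs)
        assert fit.coef("age") < 0
        assert fit.coef("age") + 2 * fit.se("age") < 0  # clearly negative
        assert fit.fallback is not None  # random effects via clusters


class TestPairScheduleConstruction:
    def test_from_frames_round_trip(self):
        cfg = SimConfig(days=5.0, seed=3)
        sch = simulate_pair_schedule(cfg, "P9")
        from pairforage import schedule_to_frames
        trips, bouts = schedule_to_frames(sch, cfg)
        sex_of = {"P9m": "male", "P9f": "female"}
        pair = PairSchedule.from_frames(trips, bouts, "P9", sex_of)
        direct = PairSchedule.from_simulation(sch, cfg.window_h)
        np.testing.assert_allclose(pair.male.trips, direct.male.trips, atol=1e-9)
        np.testing.assert_allclose(pair.female.bouts, direct.female.bouts, atol=1e-9)

    def test_disjoint_windows_raise(self):
        t0 = pd.Timestamp("2016-06-01T00:00:00Z")
        def frame(ind, offset_h):
            return (pd.DataFrame(dict(individual_id=ind,
                                      start=[t0 + pd.Timedelta(hours=offset_h)],
                                      end=[t0 + pd.Timedelta(hours=offset_h + 5)],
                                      duration_h=[5.0])),
                    pd.DataFrame(dict(individual_id=ind,
                                      start=[t0 + pd.Timedelta(hours=offset_h + 5)],
                                      end=[t0 + pd.Timedelta(hours=offset_h + 10)],
                                      duration_h=[5.0])))
        t1, b1 = frame("a", 0)
        t2, b2 = frame("b", 100)
        with pytest.raises(DegenerateScheduleError):
            PairSchedule.from_frames(pd.concat([t1, t2]), pd.concat([b1, b2]),
                                     "p", {"a": "male", "b": "female"})
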