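import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from riskrank import hierarchy
from riskrank.hierarchy import (
    EloConfig,
    compute_elo,
    cop,
    elo_update,
    ordinal_rank,
)

# frozen oracle: sequential hand computation of the 5-event log in conftest
# (k=100, base-10/400 expectation, start 1000), carried out independently
FIVE_EVENT_FINAL = {"a": 966.075276, "b": 976.133583, "c": 1057.791141}
FIVE_EVENT_AFTER_2 = {"a": 1092.853688, "b": 950.0, "c": 957.146312}


class TestEloUpdate:
    def test_equal_ratings_split_k(self):
        assert elo_update(1000.0, 1000.0) == (1050.0, 950.0)

    def test_closed_form_update(self):
        e_w = 1.0 / (1.0 + 10 ** (-0.5))  # 1100 vs 900
        rw, rl = elo_update(1100.0, 900.0)
        assert rw == pytest.approx(1100 + 100 * (1 - e_w))
        assert rl == pytest.approx(900 - 100 * (1 - e_w))
        assert rw == pytest.approx(1124.025148)

    def test_upset_moves_more_than_expected_win(self):
        favourite_gain = elo_update(1100.0, 900.0)[0] - 1100.0
        underdog_gain = elo_update(900.0, 1100.0)[0] - 900.0
        assert underdog_gain > favourite_gain

    def test_points_conserved(self):
        for rw, rl in [(1000, 1000), (1234, 876), (800, 1500)]:
            nw, nl = elo_update(rw, rl, EloConfig(k=37.0))
            assert nw + nl == pytest.approx(rw + rl)


class TestComputeElo:
    def test_matches_hand_computation_exactly(self, events_5):
        traj = compute_elo(events_5, ["a", "b", "c"])
        final = traj.ratings.iloc[-1]
        for ind, expected in FIVE_EVENT_FINAL.items():
            assert final[ind] == pytest.approx(expected, abs=1e-6)
        after2 = traj.at("2020-03-02")
        for ind, expected in FIVE_EVENT_AFTER_2.items():
            assert after2[ind] == pytest.approx(expected, abs=1e-6)

    def test_empty_log_flat_at_start(self):
        traj = compute_elo(pd.DataFrame(columns=["timestamp", "winner_id", "loser_id"]),
                           ["x", "y"])
        assert (traj.ratings == 1000.0).all().all()

    def test_daily_sum_conserved(self, events_5):
        traj = compute_elo(events_5, ["a", "b", "c"])
        assert np.allclose(traj.ratings.sum(axis=1), 3000.0)

    def test_unknown_id_signalled(self, events_5):
        with pytest.raises(ValueError, match="outside roster"):
            compute_elo(events_5, ["a", "b"])

    def test_carry_forward_over_event_free_days(self):
        events = pd.DataFrame(
            {
                "timestamp": pd.to_datetime(["2020-01-01", "2020-01-10"]),
                "winner_id": ["a", "a"],
                "loser_id": ["b", "b"],
            }
        )
        traj = compute_elo(events, ["a", "b"])
        assert len(traj.ratings) == 10  # full daily range
        assert (traj.ratings.loc["2020-01-05"] == traj.ratings.loc["2020-01-01"]).all()

    def test_latent_order_recovered_under_strict_dominance(self):
        # higher latent strength always wins: the final Elo order must match
        # the latent order in nearly every replicate
        n, n_events = 6, 100
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            ids = [f"m{k}" for k in range(n)]
            i = rng.integers(0, n, size=n_events)
            j = (i + rng.integers(1, n, size=n_events)) % n
            winners = np.minimum(i, j)  # lower index = stronger
            losers = np.maximum(i, j)
            events = pd.DataFrame(
                {
                    "timestamp": pd.Timestamp("2021-01-01")
                    + pd.to_timedelta(np.arange(n_events), unit="h"),
                    "winner_id": [ids[k] for k in winners],
                    "loser_id": [ids[k] for k in losers],
                }
            )
            final = compute_elo(events, ids).ratings.iloc[-1]
            hits += list(final.sort_values(ascending=False).index) == ids
        assert hits >= 19


class TestOrdinalRank:
    def test_all_tied_share_rank_one(self, events_5):
        traj = compute_elo(events_5, ["a", "b", "c"])
        ranks = ordinal_rank(traj, "2020-02-01")  # before any event
        assert (ranks == 1).all()

    def test_distinct_ratings_ranked_densely(self, events_5):
        traj = compute_elo(events_5, ["a", "b", "c"])
        ranks = ordinal_rank(traj, "2020-03-05")
        assert ranks["c"] == 1 and ranks["b"] == 2 and ranks["a"] == 3

    def test_invariant_to_constant_shift(self, events_5):
        traj = compute_elo(events_5, ["a", "b", "c"])
        shifted = hierarchy.EloTrajectory(traj.ratings + 500.0, traj.config)
        pd.testing.assert_series_equal(
            ordinal_rank(traj, "2020-03-05"), ordinal_rank(shifted, "2020-03-05")
        )


class TestCOP:
    def _events(self, wins, losses):
        n = wins + losses
        return pd.DataFrame(
            {
                "timestamp": pd.Timestamp("2020-01-01")
                + pd.to_timedelta(np.arange(n), unit="D"),
                "winner_id": ["me"] * wins + ["other"] * losses,
                "loser_id": ["other"] * wins + ["me"] * losses,
            }
        )

    @pytest.mark.parametrize("wins, losses, score", [(10, 0, 1.0), (5, 5, 0.0), (7, 3, 0.4)])
    def test_hand_arithmetic(self, wins, losses, score):
        ev = self._events(wins, losses)
        c = cop(ev, "me", (ev["timestamp"].min(), ev["timestamp"].max()))
        assert c.score == pytest.approx(score)
        assert c.n_conflicts == wins + losses

    def test_label_swap_invariance(self):
        ev = self._events(7, 3)
        swapped = ev.rename(columns={"winner_id": "loser_id", "loser_id": "winner_id"})
        w = (ev["timestamp"].min(), ev["timestamp"].max())
        assert cop(ev, "me", w).score == cop(swapped, "me", w).score

    def test_zero_conflicts_is_missing_not_zero(self):
        ev = self._events(2, 2)
        c = cop(ev, "stranger", (ev["timestamp"].min(), ev["timestamp"].max()))
        assert c.n_conflicts == 0
        assert np.isnan(c.score)


class TestAlignment:
    def test_constant_trajectory_mean_is_constant(self, events_5):
        traj = compute_elo(
            pd.DataFrame(columns=["timestamp", "winner_id", "loser_id"]), ["a", "b"]
        )
        assert traj.mean_over("2019-01-01", "2019-02-01")["a"] == pytest.approx(1000.0)

    def test_linear_ramp_mean_is_midpoint(self):
        days = pd.date_range("2020-01-01", periods=101, freq="D")
        ramp = pd.DataFrame({"a": np.linspace(1000, 1100, 101)}, index=days)
        traj = hierarchy.EloTrajectory(ramp)
        assert traj.mean_over(days[0], days[-1])["a"] == pytest.approx(1050.0)

    def test_one_day_window_is_that_days_rating(self, events_5):
        traj = compute_elo(events_5, ["a", "b", "c"])
        m = traj.mean_over("2020-03-02", "2020-03-02")
        assert m["a"] == pytest.approx(FIVE_EVENT_AFTER_2["a"], abs=1e-6)

    def test_vectorized_spans_match_scalar_api(self, small_cohort):
        traj = small_cohort.elo
        rng = np.random.default_rng(4)
        rows = []
        for _ in range(25):
            d0 = traj.ratings.index[0] + pd.Timedelta(days=int(rng.integers(-10, 120)))
            d1 = d0 + pd.Timedelta(days=int(rng.integers(0, 60)))
            rows.append(
                dict(individual_id=rng.choice(traj.individuals), t_start=d0, t_end=d1)
            )
        spans = pd.DataFrame(rows)
        fast = hierarchy.mean_elo_over_spans(traj, spans)
        slow = [
            float(traj.mean_over(r.t_start, r.t_end)[r.individual_id])
            for r in spans.itertuples()
        ]
        assert np.allclose(fast, slow)

    def test_cop_u_shape_against_elo(self):
        # rating-proximity-dependent outcomes: extremes of the hierarchy have
        # predictable conflicts, the middle does not -> positive quadratic
        import statsmodels.formula.api as smf

        from riskrank import synthetic_cohort

        cohort = synthetic_cohort.generate_cohort(
            synthetic_cohort.CohortConfig(
                n_individuals=14, n_males=7, months=10,
                trials_per_individual=6000, seed=23,
            ),
            include_trials=False,
        )
        spans = cohort.truth[["individual_id", "chunk_index", "t_start", "t_end"]]
        hier = hierarchy.align_hierarchy_to_chunks(cohort.elo, cohort.events, spans)
        hier = hier[np.isfinite(hier["cop"])].copy()
        hier["z"] = (hier["elo_mean"] - hier["elo_mean"].mean()) / hier["elo_mean"].std()
        fit = smf.ols("cop ~ z + I(z**2)", data=hier).fit()
        assert fit.params["I(z ** 2)"] > 0
        assert fit.pvalues["I(z ** 2)"] < 0.01


class TestEventIO:
    def test_roundtrip(self, tmp_path, events_5):
        path = tmp_path / "events.csv"
        hierarchy.write_events(events_5, path)
        back = hierarchy.read_events(path)
        assert (back["winner_id"] == events_5["winner_id"]).all()
        assert (back["timestamp"] == events_5["timestamp"]).all()
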