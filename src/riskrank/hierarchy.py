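"""Elo-rating dominance hierarchy and conflict outcome predictability.

Displacement events at the testing devices (one animal supplanting another)
are treated as dyadic conflicts.  Each individual starts at an Elo rating of
1000; after every conflict the winner gains and the loser loses
``k * (1 - E_w)`` points, where ``E_w = 1/(1 + 10**((r_loser - r_winner)/400))``
is the winner's expected score — upsets move ratings more than expected
outcomes, and total points are conserved.

Conflict outcome predictability (COP) over a time window is
``|wins - losses| / n_conflicts`` for one individual: 1 means fully
predictable outcomes (all wins or all losses), 0 a 50/50 split.  Plotted
against Elo, COP is U-shaped: animals at either end of the hierarchy have
predictable conflicts while mid-ranking animals face balanced contests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "EloConfig",
    "EloTrajectory",
    "COPScore",
    "elo_update",
    "compute_elo",
    "ordinal_rank",
    "cop",
    "align_hierarchy_to_chunks",
    "read_events",
    "write_events",
]

EVENT_COLUMNS = ("timestamp", "winner_id", "loser_id")


@dataclass(frozen=True)
class EloConfig:
    start_rating: float = 1000.0
    k: float = 100.0
    scale: float = 400.0  # logistic base-10 expectation scale

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be positive")
        if self.scale <= 0:
            raise ValueError("scale must be positive")


@dataclass(frozen=True)
class COPScore:
    individual_id: str
    window: Tuple[pd.Timestamp, pd.Timestamp]
    n_conflicts: int
    score: float  # NaN when n_conflicts == 0 (undefined, not zero)


def elo_update(
    r_winner: float, r_loser: float, config: EloConfig = EloConfig()
) -> Tuple[float, float]:
    """One conflict's rating update; returns (r_winner', r_loser')."""
    e_w = 1.0 / (1.0 + 10.0 ** ((r_loser - r_winner) / config.scale))
    delta = config.k * (1.0 - e_w)
    return r_winner + delta, r_loser - delta


@dataclass
class EloTrajectory:
    """Daily Elo ratings, one column per individual.

    ``ratings`` is indexed by calendar day covering the full event span; the
    value for a day is the rating after that day's last event, carried
    forward over days without events.
    """

    ratings: pd.DataFrame
    config: EloConfig = field(default_factory=EloConfig)

    @property
    def individuals(self) -> list:
        return list(self.ratings.columns)

    def at(self, date) -> pd.Series:
        """Ratings on a given day (start rating before the first event day)."""
        day = pd.Timestamp(date).normalize()
        idx = self.ratings.index
        if day < idx[0]:
            return pd.Series(self.config.start_rating, index=self.ratings.columns)
        pos = idx.searchsorted(day, side="right") - 1
        return self.ratings.iloc[min(pos, len(idx) - 1)]

    def mean_over(self, start, end) -> pd.Series:
        """Mean of daily ratings over [start, end] (inclusive, calendar days)."""
        lo = pd.Timestamp(start).normalize()
        hi = pd.Timestamp(end).normalize()
        if hi < lo:
            raise ValueError("window end precedes start")
        idx = self.ratings.index
        n_days = (hi - lo).days + 1
        # days before the first event day sit at the start rating; days past
        # the last snapshot carry the final rating forward
        n_before = max(0, min((idx[0] - lo).days, n_days))
        n_after = max(0, min((hi - idx[-1]).days, n_days))
        inside = self.ratings.loc[max(lo, idx[0]) : min(hi, idx[-1])]
        total = (
            inside.sum()
            + n_before * self.config.start_rating
            + n_after * self.ratings.iloc[-1]
        )
        return total / (len(inside) + n_before + n_after)

    def to_long(self) -> pd.DataFrame:
        long = self.ratings.reset_index(names="date").melt(
            id_vars="date", var_name="individual_id", value_name="rating"
        )
        return long.sort_values(["date", "individual_id"]).reset_index(drop=True)


def compute_elo(
    events: pd.DataFrame,
    roster: Sequence[str],
    config: EloConfig = EloConfig(),
) -> EloTrajectory:
    """Sequential Elo over a displacement-event log, with daily snapshots.

    Every roster member starts at ``config.start_rating``; events naming an
    id outside the roster raise.  Events are applied in timestamp order.
    """
    roster = list(dict.fromkeys(roster))
    pos = {ind: i for i, ind in enumerate(roster)}
    ratings = np.full(len(roster), config.start_rating, dtype=float)

    if len(events) == 0:
        today = pd.Timestamp.now().normalize()
        frame = pd.DataFrame([ratings], index=[today], columns=roster)
        return EloTrajectory(frame, config)

    ev = events.sort_values("timestamp", kind="stable")
    ts = pd.to_datetime(ev["timestamp"])
    days = ts.dt.normalize().to_numpy()
    winners = ev["winner_id"].to_numpy()
    losers = ev["loser_id"].to_numpy()
    unknown = {w for w in winners if w not in pos} | {l for l in losers if l not in pos}
    if unknown:
        raise ValueError(f"events name ids outside roster: {sorted(map(str, unknown))}")

    snap_days: list = []
    snaps: list = []
    current_day = days[0]
    for i in range(len(ev)):
        if days[i] != current_day:
            snap_days.append(current_day)
            snaps.append(ratings.copy())
            current_day = days[i]
        wi, li = pos[winners[i]], pos[losers[i]]
        if wi == li:
            raise ValueError("winner and loser must differ")
        ratings[wi], ratings[li] = elo_update(ratings[wi], ratings[li], config)
    snap_days.append(current_day)
    snaps.append(ratings.copy())

    frame = pd.DataFrame(snaps, index=pd.DatetimeIndex(snap_days), columns=roster)
    # fill the full daily range, carrying ratings over event-free days
    full_range = pd.date_range(frame.index[0], frame.index[-1], freq="D")
    frame = frame.reindex(full_range).ffill()
    return EloTrajectory(frame, config)


def ordinal_rank(trajectory: EloTrajectory, date) -> pd.Series:
    """Dense ordinal ranks on a day (1 = highest rating; ties share a rank).

    The returned Series is ordered by individual id so tied individuals
    appear in a documented, reproducible order.
    """
    ratings = trajectory.at(date)
    ranks = ratings.rank(method="dense", ascending=False).astype(int)
    return ranks.sort_index()


def cop(
    events: pd.DataFrame,
    individual: str,
    window: Tuple[pd.Timestamp, pd.Timestamp],
) -> COPScore:
    """Conflict outcome predictability of one individual over a window."""
    lo, hi = (pd.Timestamp(window[0]), pd.Timestamp(window[1]))
    if hi < lo:
        raise ValueError("window end precedes start")
    ts = pd.to_datetime(events["timestamp"])
    inside = (ts >= lo) & (ts <= hi)
    wins = int(((events["winner_id"] == individual) & inside).sum())
    losses = int(((events["loser_id"] == individual) & inside).sum())
    n = wins + losses
    score = abs(wins - losses) / n if n > 0 else float("nan")
    return COPScore(str(individual), (lo, hi), n, score)


def mean_elo_over_spans(trajectory: EloTrajectory, spans: pd.DataFrame) -> np.ndarray:
    """Vectorized :meth:`EloTrajectory.mean_over` for many (individual, span) rows.

    ``spans`` needs columns ``individual_id, t_start, t_end``.  Uses a daily
    cumulative sum so the cost is independent of span length; returns NaN
    for individuals absent from the trajectory.
    """
    idx = trajectory.ratings.index
    vals = trajectory.ratings.to_numpy(dtype=float)
    csum = np.vstack([np.zeros(vals.shape[1]), np.cumsum(vals, axis=0)])
    day0, day_n = idx[0], idx[-1]
    col_of = {str(c): k for k, c in enumerate(trajectory.ratings.columns)}
    start_rating = trajectory.config.start_rating
    last = vals[-1]

    out = np.empty(len(spans))
    lo_days = pd.to_datetime(spans["t_start"]).dt.normalize()
    hi_days = pd.to_datetime(spans["t_end"]).dt.normalize()
    for i, (ind, lo, hi) in enumerate(
        zip(spans["individual_id"].astype(str), lo_days, hi_days)
    ):
        k = col_of.get(ind)
        if k is None:
            out[i] = np.nan
            continue
        n_days = (hi - lo).days + 1
        n_before = max(0, min((day0 - lo).days, n_days))
        n_after = max(0, min((hi - day_n).days, n_days))
        a = max(0, (lo - day0).days)
        b = min((hi - day0).days, len(vals) - 1) + 1
        n_in = max(0, b - a)
        s = csum[b, k] - csum[a, k] if n_in > 0 else 0.0
        out[i] = (s + n_before * start_rating + n_after * last[k]) / (
            n_in + n_before + n_after
        )
    return out


def align_hierarchy_to_chunks(
    trajectory: EloTrajectory,
    events: pd.DataFrame,
    chunk_spans: pd.DataFrame,
) -> pd.DataFrame:
    """Per-chunk mean Elo and COP over each chunk's time span.

    ``chunk_spans`` needs columns ``individual_id, chunk_index, t_start,
    t_end`` (as produced by the fitting stage).  Chunks whose span has no
    rating coverage get NaN and are flagged in the ``missing`` column.
    """
    elo_means = mean_elo_over_spans(trajectory, chunk_spans)

    ts = pd.to_datetime(events["timestamp"]).to_numpy(dtype="datetime64[ns]")
    order = np.argsort(ts, kind="stable")
    ts_sorted = ts[order]
    winners = events["winner_id"].astype(str).to_numpy()[order]
    losers = events["loser_id"].astype(str).to_numpy()[order]
    inds = chunk_spans["individual_id"].astype(str)
    cum_w = {
        ind: np.concatenate([[0], np.cumsum(winners == ind)]) for ind in set(inds)
    }
    cum_l = {
        ind: np.concatenate([[0], np.cumsum(losers == ind)]) for ind in set(inds)
    }
    i0 = np.searchsorted(
        ts_sorted, pd.to_datetime(chunk_spans["t_start"]).to_numpy("datetime64[ns]")
    )
    i1 = np.searchsorted(
        ts_sorted,
        pd.to_datetime(chunk_spans["t_end"]).to_numpy("datetime64[ns]"),
        side="right",
    )

    rows = []
    for i, r in enumerate(chunk_spans.itertuples(index=False)):
        ind = str(r.individual_id)
        wins = int(cum_w[ind][i1[i]] - cum_w[ind][i0[i]])
        losses = int(cum_l[ind][i1[i]] - cum_l[ind][i0[i]])
        n = wins + losses
        rows.append(
            {
                "individual_id": ind,
                "chunk_index": int(r.chunk_index),
                "elo_mean": elo_means[i],
                "cop": abs(wins - losses) / n if n > 0 else float("nan"),
                "n_conflicts": n,
                "missing": not np.isfinite(elo_means[i]),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# event-log I/O
# ---------------------------------------------------------------------------

def write_events(events: pd.DataFrame, path) -> None:
    out = events.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False, columns=list(EVENT_COLUMNS))


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df
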