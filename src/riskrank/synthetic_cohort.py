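"""Synthetic cohort generator: trial logs, conflicts, metadata, ground truth.

Emulates a group of ~18 macaques with months of free access to gambling
devices.  Each animal carries a latent dominance strength that drifts as a
slow random walk, so the hierarchy is dynamic: displacement conflicts are
drawn between random dyads and resolved with win probability increasing in
the strength gap (near-equal opponents produce near-coin-flip outcomes,
which is what makes conflict outcomes unpredictable for mid-ranking animals
and yields the U-shaped COP/Elo relationship).

Prospect-theory parameters are structured in three layers: a stable
individual baseline, an optional *rank link* adding quadratic-in-z-scored-Elo
terms to selected parameters (so longitudinal rank changes propagate to risk
attitudes), and chunk-level jitter.  Choices are then simulated through the
behavioural model, and the per-chunk ground truth is emitted alongside the
logs so every pipeline stage can be checked against known generative values.

Baseline means mirror the cohort-level parameter values reported for this
task (risk aversion in gains, risk seeking in losses, loss aversion near 3,
S-shaped gain weighting / inverted-S loss weighting); between-individual and
chunk-level spreads mirror the mixed models' random-intercept and residual
variances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit

from . import hierarchy, pipeline, task_model
from .pt_model import PTParams
from .task_model import BatteryConfig

__all__ = ["CohortConfig", "Cohort", "generate_cohort", "inject_pathologies",
           "truth_analysis_table"]

#: baseline distribution of the five PT parameters across individuals:
#: (mean, between-individual sd); log-scale for lam and the alphas
BASE_MEANS: Dict[str, float] = {
    "rho_plus": 0.182,
    "rho_minus": -0.508,
    "log_lam": math.log(2.987),
    "log_alpha_plus": math.log(1.208),
    "log_alpha_minus": math.log(0.655),
}
BASE_SDS: Dict[str, float] = {
    "rho_plus": 0.26,
    "rho_minus": 0.14,
    "log_lam": 0.62,
    "log_alpha_plus": 0.52,
    "log_alpha_minus": 0.35,
}
#: chunk-to-chunk jitter sd per parameter (residual-scale variation)
CHUNK_JITTER_SDS: Dict[str, float] = {
    "rho_plus": 0.24,
    "rho_minus": 0.14,
    "log_lam": 0.56,
    "log_alpha_plus": 0.39,
    "log_alpha_minus": 0.33,
}
#: quadratic rank link: coefficient on z-scored-Elo**2 per parameter.
#: Positive for gain-domain risk aversion (U-shape), negative for the gain
#: weighting exponent and loss aversion (inverted U), zero in the loss domain.
DEFAULT_RANK_LINK: Dict[str, float] = {
    "rho_plus": 0.08,
    "rho_minus": 0.0,
    "log_lam": -0.25,
    "log_alpha_plus": -0.10,
    "log_alpha_minus": 0.0,
}

_CLIP: Dict[str, Tuple[float, float]] = {
    "rho_plus": (-0.9, 0.9),
    "rho_minus": (-0.9, 0.9),
    "log_lam": (math.log(0.1), math.log(14.0)),
    "log_alpha_plus": (math.log(0.1), math.log(4.8)),
    "log_alpha_minus": (math.log(0.1), math.log(4.8)),
}


@dataclass(frozen=True)
class CohortConfig:
    n_individuals: int = 18
    n_males: int = 11
    months: float = 40.0
    trials_per_individual: int = 75_000
    chunk_size: int = 1500
    start_date: str = "2020-02-01"
    age_mean: float = 7.24  # years at study start
    age_sd: float = 4.56
    min_age: float = 1.0
    # hierarchy dynamics
    conflict_rate_per_day: float = 12.0
    strength_beta: float = 1.5  # logistic slope of win prob on strength gap
    strength_drift_sd: float = 0.03  # per-day latent-strength random walk
    # behavioural structure
    base_means: Dict[str, float] = field(default_factory=lambda: dict(BASE_MEANS))
    base_sds: Dict[str, float] = field(default_factory=lambda: dict(BASE_SDS))
    chunk_jitter_sds: Dict[str, float] = field(
        default_factory=lambda: dict(CHUNK_JITTER_SDS)
    )
    rank_link: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RANK_LINK))
    mu_mean: float = 5.0
    mu_sd: float = 1.0
    x0_sd: float = 0.3
    battery: BatteryConfig = field(default_factory=BatteryConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_males <= self.n_individuals:
            raise ValueError("n_males must lie in [0, n_individuals]")
        if self.trials_per_individual < self.chunk_size:
            raise ValueError("trials_per_individual must cover at least one chunk")
        if any(sd < 0 for sd in self.base_sds.values()):
            raise ValueError("base sds must be non-negative")
        if any(sd < 0 for sd in self.chunk_jitter_sds.values()):
            raise ValueError("jitter sds must be non-negative")
        if self.conflict_rate_per_day < 0:
            raise ValueError("conflict rate must be non-negative")

    @property
    def n_days(self) -> int:
        return max(1, int(round(self.months * 30.44)))


@dataclass
class Cohort:
    """A complete synthetic dataset with its generative ground truth."""

    trials: Optional[pd.DataFrame]
    events: pd.DataFrame
    metadata: pd.DataFrame
    truth: pd.DataFrame
    elo: hierarchy.EloTrajectory
    config: CohortConfig

    def write(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if self.trials is not None:
            task_model.write_trials(self.trials, out / "trials.csv")
        hierarchy.write_events(self.events, out / "events.csv")
        self.metadata.to_csv(out / "metadata.csv", index=False)
        self.truth.to_csv(out / "ground_truth.csv", index=False)


def _simulate_events(config: CohortConfig, rng: np.random.Generator, ids):
    """Dyadic displacement events over drifting latent strengths."""
    n, days = config.n_individuals, config.n_days
    start = pd.Timestamp(config.start_date)
    strengths = np.empty((days, n))
    strengths[0] = rng.normal(0.0, 1.0, size=n)
    steps = rng.normal(0.0, config.strength_drift_sd, size=(days - 1, n))
    strengths[1:] = strengths[0] + np.cumsum(steps, axis=0)

    counts = rng.poisson(config.conflict_rate_per_day, size=days)
    total = int(counts.sum())
    if total == 0:
        raise ValueError("conflict model produced zero events; raise the rate")
    day_idx = np.repeat(np.arange(days), counts)
    i = rng.integers(0, n, size=total)
    shift = rng.integers(1, n, size=total)
    j = (i + shift) % n  # uniform opponent distinct from i
    p_i_wins = expit(config.strength_beta * (strengths[day_idx, i] - strengths[day_idx, j]))
    i_wins = rng.random(total) < p_i_wins
    winners = np.where(i_wins, i, j)
    losers = np.where(i_wins, j, i)
    seconds = rng.integers(8 * 3600, 20 * 3600, size=total)
    ts = start + pd.to_timedelta(day_idx, unit="D") + pd.to_timedelta(seconds, unit="s")
    events = pd.DataFrame(
        {
            "timestamp": ts,
            "winner_id": np.array(ids)[winners],
            "loser_id": np.array(ids)[losers],
        }
    ).sort_values("timestamp", kind="stable", ignore_index=True)
    return events


_TRUTH_PARAMS = ("rho_plus", "rho_minus", "log_lam", "log_alpha_plus", "log_alpha_minus")


def generate_cohort(config: CohortConfig = CohortConfig(), include_trials: bool = True) -> Cohort:
    """Generate the full dataset (bitwise-reproducible under ``config.seed``).

    With ``include_trials=False`` only conflicts, metadata and the chunk-level
    ground truth are produced — enough to study the hierarchy and
    mixed-model stages without the cost of simulating choices.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    ids = [f"ind{i:02d}" for i in range(n)]
    sexes = np.array(["male"] * config.n_males + ["female"] * (n - config.n_males))
    rng.shuffle(sexes)
    ages = np.clip(
        rng.normal(config.age_mean, config.age_sd, size=n), config.min_age, None
    )
    start = pd.Timestamp(config.start_date)
    birth = start - pd.to_timedelta(ages * 365.25, unit="D")
    metadata = pd.DataFrame(
        {"individual_id": ids, "sex": sexes, "birth_date": birth.normalize()}
    )

    events = _simulate_events(config, rng, ids)
    traj = hierarchy.compute_elo(events, ids)

    # chunk spans: trials are spread evenly over the activity window
    n_chunks = config.trials_per_individual // config.chunk_size
    total_days = float(config.n_days)
    truth_rows = []
    for ind_i, ind in enumerate(ids):
        offset = rng.uniform(0, 1)  # small per-individual stagger (days)
        for ci in range(n_chunks):
            d0 = total_days * ci / n_chunks + offset
            d1 = total_days * (ci + 1) / n_chunks + offset
            t0 = start + pd.to_timedelta(d0, unit="D")
            t1 = start + pd.to_timedelta(d1, unit="D") - pd.Timedelta(seconds=1)
            truth_rows.append(
                {
                    "individual_id": ind,
                    "chunk_index": ci,
                    "t_start": t0,
                    "t_end": t1,
                }
            )
    truth = pd.DataFrame(truth_rows)
    truth["elo_mean"] = hierarchy.mean_elo_over_spans(traj, truth)
    elo_z = (truth["elo_mean"] - truth["elo_mean"].mean()) / truth["elo_mean"].std(ddof=1)
    truth["elo_z"] = elo_z

    # individual baselines, rank link, chunk jitter
    base = {
        p: rng.normal(config.base_means[p], config.base_sds[p], size=n)
        for p in _TRUTH_PARAMS
    }
    mu = np.clip(rng.normal(config.mu_mean, config.mu_sd, size=n), 1.0, None)
    x0 = rng.normal(0.0, config.x0_sd, size=n)
    ind_pos = truth["individual_id"].map({ind: i for i, ind in enumerate(ids)}).to_numpy()
    for p in _TRUTH_PARAMS:
        vals = (
            base[p][ind_pos]
            + config.rank_link.get(p, 0.0) * truth["elo_z"].to_numpy() ** 2
            + rng.normal(0.0, config.chunk_jitter_sds[p], size=len(truth))
        )
        lo, hi = _CLIP[p]
        truth[p] = np.clip(vals, lo, hi)
    truth["lam"] = np.exp(truth["log_lam"])
    truth["alpha_plus"] = np.exp(truth["log_alpha_plus"])
    truth["alpha_minus"] = np.exp(truth["log_alpha_minus"])
    truth["mu"] = mu[ind_pos]
    truth["x0"] = x0[ind_pos]

    trials = _simulate_trials(config, rng, truth) if include_trials else None
    return Cohort(trials, events, metadata, truth, traj, config)


def _simulate_trials(
    config: CohortConfig, rng: np.random.Generator, truth: pd.DataFrame
) -> pd.DataFrame:
    battery = task_model.generate_battery(config.battery, seed=config.seed)
    bf = task_model._battery_frame(battery)
    xl = bf["left_outcome"].to_numpy(float)
    pl = bf["left_prob"].to_numpy(float)
    xr = bf["right_outcome"].to_numpy(float)
    pr = bf["right_prob"].to_numpy(float)
    conds = bf["condition"].to_numpy()
    doms = bf["domain"].to_numpy()

    from . import pt_model

    size = config.chunk_size
    frames = []
    for ind, sub in truth.groupby("individual_id", sort=False):
        sub = sub.sort_values("chunk_index")
        n_tr = len(sub) * size
        pair_idx = np.empty(n_tr, dtype=int)
        chose_right = np.empty(n_tr, dtype=bool)
        t_all = np.empty(n_tr, dtype="datetime64[ns]")
        for k, row in enumerate(sub.itertuples(index=False)):
            params = PTParams(
                rho_plus=row.rho_plus,
                rho_minus=row.rho_minus,
                lam=row.lam,
                alpha_plus=row.alpha_plus,
                alpha_minus=row.alpha_minus,
                mu=row.mu,
                x0=row.x0,
            )
            vec = params.to_vector()
            delta = pt_model.sev_arrays(xr, pr, vec) - pt_model.sev_arrays(xl, pl, vec)
            p_right = expit(params.mu * delta + params.x0)
            sl = slice(k * size, (k + 1) * size)
            idx = rng.integers(0, len(bf), size=size)
            pair_idx[sl] = idx
            chose_right[sl] = rng.random(size) < p_right[idx]
            t0 = pd.Timestamp(row.t_start)
            t1 = pd.Timestamp(row.t_end)
            t_all[sl] = np.asarray(t0 + (t1 - t0) * ((np.arange(size) + 0.5) / size))
        frames.append(
            pd.DataFrame(
                {
                    "individual_id": ind,
                    "timestamp": t_all,
                    "trial_index": np.arange(n_tr),
                    "left_outcome": xl[pair_idx].astype(int),
                    "left_prob": pl[pair_idx],
                    "right_outcome": xr[pair_idx].astype(int),
                    "right_prob": pr[pair_idx],
                    "choice": np.where(chose_right, "right", "left"),
                    "condition": conds[pair_idx],
                    "domain": doms[pair_idx],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def inject_pathologies(
    trials: pd.DataFrame,
    individuals: Sequence[str],
    same_side_rate: float = 1.0,
    side: str = "right",
    seed: int = 0,
) -> pd.DataFrame:
    """Overwrite selected individuals' choices with one-sided responding.

    Each affected trial picks ``side`` with probability ``same_side_rate``
    (in [0.5, 1]) regardless of the lotteries shown — the degenerate
    behaviour the filtering stage must catch.  An empty ``individuals`` list
    returns the log unchanged.
    """
    if not 0.5 <= same_side_rate <= 1.0:
        raise ValueError("same_side_rate must lie in [0.5, 1]")
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    if len(individuals) == 0:
        return trials
    out = trials.copy()
    rng = np.random.default_rng(seed)
    mask = out["individual_id"].isin(list(individuals)).to_numpy()
    other = "left" if side == "right" else "right"
    draws = rng.random(int(mask.sum())) < same_side_rate
    out.loc[mask, "choice"] = np.where(draws, side, other)
    return out


def truth_analysis_table(cohort: Cohort) -> pd.DataFrame:
    """Analysis table built from the generative ground truth (no fitting).

    Same columns as the pipeline's assembled table, with each chunk's *true*
    parameters in place of fitted ones; used to study the statistical stage
    in isolation.
    """
    spans = cohort.truth[["individual_id", "chunk_index", "t_start", "t_end"]]
    hier = hierarchy.align_hierarchy_to_chunks(cohort.elo, cohort.events, spans)
    fits_like = cohort.truth.drop(columns=["elo_mean", "elo_z"])
    return pipeline.assemble_table(
        fits_like, hier, cohort.metadata, cohort.config.chunk_size
    )
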