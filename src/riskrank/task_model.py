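"""Lottery battery and forward simulation of the two-lottery gambling task.

The task presents two pie-chart lotteries side by side; the animal picks one
and receives its outcome (a token gain or loss between -3 and +3) with the
stated probability.  Pairs come in three conditions, each realized in both
the gain and the loss domain:

* ``quantity``   — same probability, different outcome magnitude;
* ``probability``— same outcome, different probability;
* ``tradeoff``   — both differ, with the larger-magnitude outcome carried by
  the *lower* probability (otherwise one side would dominate).

The published task never enumerates its full lottery set, so
:func:`generate_battery` enumerates every pair consistent with the condition
predicates over the outcome/probability grids.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import pt_model
from .pt_model import PTParams

__all__ = [
    "Lottery",
    "BatteryConfig",
    "expected_value",
    "classify_condition",
    "pair_domain",
    "generate_battery",
    "simulate_choices",
    "write_trials",
    "read_trials",
]

CONDITIONS = ("quantity", "probability", "tradeoff")

#: canonical column order of a trial log
TRIAL_COLUMNS = (
    "individual_id",
    "timestamp",
    "trial_index",
    "left_outcome",
    "left_prob",
    "right_outcome",
    "right_prob",
    "choice",
    "condition",
    "domain",
)


@dataclass(frozen=True)
class Lottery:
    """A single-outcome lottery: ``outcome`` tokens with ``probability``."""

    outcome: int
    probability: float

    def __post_init__(self) -> None:
        if self.outcome == 0:
            raise ValueError("lottery outcome must be non-zero")
        if not 0 < self.probability <= 1:
            raise ValueError("lottery probability must lie in (0, 1]")


def expected_value(lottery) -> float:
    """EV = p * x (the zero-token complement contributes nothing)."""
    x, p = pt_model._as_xp(lottery)
    return p * x


def pair_domain(left, right) -> str:
    xl, _ = pt_model._as_xp(left)
    xr, _ = pt_model._as_xp(right)
    if xl > 0 and xr > 0:
        return "gain"
    if xl < 0 and xr < 0:
        return "loss"
    return "mixed"


def classify_condition(left, right) -> Optional[str]:
    """Condition predicate for a pair; None if the pair fits no condition.

    Pairs where one side dominates (larger magnitude *and* higher
    probability) belong to no condition.  For mixed gain/loss pairs only the
    same-probability (quantity-like) and both-differ (tradeoff-like) labels
    are meaningful.
    """
    xl, plp = pt_model._as_xp(left)
    xr, prp = pt_model._as_xp(right)
    same_p = plp == prp
    same_x = xl == xr
    if same_p and same_x:
        return None
    domain = pair_domain(left, right)
    if domain == "mixed":
        return "quantity" if same_p else "tradeoff"
    if same_p:
        return "quantity"
    if same_x:
        return "probability"
    # both differ: tradeoff iff the bigger stake has the lower probability
    if (abs(xl) - abs(xr)) * (plp - prp) < 0:
        return "tradeoff"
    return None


@dataclass(frozen=True)
class BatteryConfig:
    """Which lotteries and pair conditions to enumerate."""

    allowed_outcomes: Tuple[int, ...] = (1, 2, 3)
    allowed_probabilities: Tuple[float, ...] = (0.25, 0.50, 0.75, 1.00)
    conditions: Tuple[str, ...] = CONDITIONS
    domains: Tuple[str, ...] = ("gain", "loss")
    include_mixed_domain: bool = False
    condition_weights: Optional[Mapping[str, float]] = None

    def __post_init__(self) -> None:
        if any(c not in CONDITIONS for c in self.conditions):
            raise ValueError(f"conditions must be among {CONDITIONS}")
        if any(x <= 0 for x in self.allowed_outcomes):
            raise ValueError("allowed_outcomes are magnitudes; must be positive")
        if self.condition_weights is not None:
            w = sum(self.condition_weights.values())
            if abs(w - 1.0) > 1e-9:
                raise ValueError("condition_weights must sum to 1")


def generate_battery(
    config: BatteryConfig = BatteryConfig(), seed: int = 0
) -> List[Tuple[Lottery, Lottery]]:
    """Enumerate all condition-consistent pairs; side order randomized by seed.

    Raises ``ValueError`` if the configuration excludes every pair.
    """
    lotteries: dict[str, list[Lottery]] = {"gain": [], "loss": []}
    for x in sorted(config.allowed_outcomes):
        for p in sorted(config.allowed_probabilities):
            if "gain" in config.domains:
                lotteries["gain"].append(Lottery(x, p))
            if "loss" in config.domains:
                lotteries["loss"].append(Lottery(-x, p))

    pairs: List[Tuple[Lottery, Lottery]] = []
    for domain in ("gain", "loss"):
        for a, b in itertools.combinations(lotteries[domain], 2):
            cond = classify_condition(a, b)
            if cond in config.conditions:
                pairs.append((a, b))
    if config.include_mixed_domain:
        for a in lotteries["gain"]:
            for b in lotteries["loss"]:
                cond = classify_condition(a, b)
                if cond in config.conditions:
                    pairs.append((a, b))

    if not pairs:
        raise ValueError("battery configuration excludes every pair")

    rng = np.random.default_rng(seed)
    flip = rng.random(len(pairs)) < 0.5
    return [(b, a) if f else (a, b) for (a, b), f in zip(pairs, flip)]


def _battery_frame(battery: Sequence[Tuple[Lottery, Lottery]]) -> pd.DataFrame:
    rows = []
    for left, right in battery:
        rows.append(
            dict(
                left_outcome=left.outcome,
                left_prob=left.probability,
                right_outcome=right.outcome,
                right_prob=right.probability,
                condition=classify_condition(left, right),
                domain=pair_domain(left, right),
            )
        )
    return pd.DataFrame(rows)


def simulate_choices(
    params: PTParams,
    battery: Sequence[Tuple[Lottery, Lottery]],
    n_trials: int,
    seed: int = 0,
    individual_id: str = "agent",
    start_time: Optional[pd.Timestamp] = None,
    mean_trials_per_day: float = 60.0,
    condition_weights: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """Simulate ``n_trials`` choices of one agent over the battery.

    Pairs are drawn uniformly (or per ``condition_weights``); the right side
    is chosen with probability :func:`riskrank.pt_model.choice_prob_right`.
    Returns a chronologically indexed trial log (see ``TRIAL_COLUMNS``).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not isinstance(params, PTParams):
        raise TypeError("params must be a PTParams instance")
    bf = _battery_frame(battery)
    rng = np.random.default_rng(seed)

    if condition_weights is None:
        idx = rng.integers(0, len(bf), size=n_trials)
    else:
        conds = list(condition_weights)
        probs = np.array([condition_weights[c] for c in conds], dtype=float)
        cond_draw = rng.choice(len(conds), size=n_trials, p=probs / probs.sum())
        idx = np.empty(n_trials, dtype=int)
        for ci, c in enumerate(conds):
            members = np.flatnonzero(bf["condition"].to_numpy() == c)
            if len(members) == 0:
                raise ValueError(f"no battery pairs in condition {c!r}")
            mask = cond_draw == ci
            idx[mask] = members[rng.integers(0, len(members), size=int(mask.sum()))]

    vec = params.to_vector()
    delta = pt_model.sev_arrays(
        bf["right_outcome"].to_numpy(float), bf["right_prob"].to_numpy(float), vec
    ) - pt_model.sev_arrays(
        bf["left_outcome"].to_numpy(float), bf["left_prob"].to_numpy(float), vec
    )
    from scipy.special import expit

    p_right = expit(params.mu * delta + params.x0)
    chose_right = rng.random(n_trials) < p_right[idx]

    if start_time is None:
        start_time = pd.Timestamp("2020-02-01")
    step = pd.Timedelta(days=1) / mean_trials_per_day
    timestamps = start_time + step * np.arange(n_trials)

    sub = bf.iloc[idx].reset_index(drop=True)
    return pd.DataFrame(
        {
            "individual_id": individual_id,
            "timestamp": timestamps,
            "trial_index": np.arange(n_trials),
            "left_outcome": sub["left_outcome"].to_numpy(),
            "left_prob": sub["left_prob"].to_numpy(),
            "right_outcome": sub["right_outcome"].to_numpy(),
            "right_prob": sub["right_prob"].to_numpy(),
            "choice": np.where(chose_right, "right", "left"),
            "condition": sub["condition"].to_numpy(),
            "domain": sub["domain"].to_numpy(),
        }
    )


# ---------------------------------------------------------------------------
# trial-log I/O
# ---------------------------------------------------------------------------

def write_trials(trials: pd.DataFrame, path) -> None:
    out = trials.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False, columns=[c for c in TRIAL_COLUMNS if c in out.columns])


def read_trials(path) -> pd.DataFrame:
    """Read a trial log; missing condition/domain columns are re-derived."""
    df = pd.read_csv(path)
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    if "condition" not in df.columns or "domain" not in df.columns:
        conds, doms = [], []
        for xl, plp, xr, prp in zip(
            df["left_outcome"], df["left_prob"], df["right_outcome"], df["right_prob"]
        ):
            left, right = (xl, plp), (xr, prp)
            conds.append(classify_condition(left, right))
            doms.append(pair_domain(left, right))
        df["condition"] = conds
        df["domain"] = doms
    return df
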