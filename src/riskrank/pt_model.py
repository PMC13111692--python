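"""Prospect-theory choice model for two-lottery gambles.

Each lottery delivers a single non-zero token outcome ``x`` (between -3 and
+3) with probability ``p``; with probability ``1 - p`` the animal gets
nothing.  Subjective value combines

* a power utility with domain-specific curvature: ``u(x) = x**(1 - rho_plus)``
  for gains and ``u(x) = -lam * (-x)**(1 + rho_minus)`` for losses, so that
  ``rho = 0`` is risk-neutral, ``rho_plus > 0`` risk-averse in gains,
  ``rho_minus < 0`` risk-seeking in losses, and ``lam > 1`` loss-averse;
* a Prelec-I probability weight ``w(p) = exp(-(-ln p)**alpha)`` with a
  separate exponent per domain (``alpha_plus``, ``alpha_minus``).

Choice between the two sides is a logistic function of the subjective
expected value difference ``delta = sev(right) - sev(left)``:

    P(right) = 1 / (1 + exp(-(mu * delta + x0)))

where ``mu >= 0`` is the steepness (higher for better-trained animals) and
``x0`` a side bias (``x0 > 0`` favours the right side).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, replace
from typing import Iterable, Mapping, Sequence, Tuple

import numpy as np
from scipy.special import expit

__all__ = [
    "PARAM_NAMES",
    "PTParams",
    "utility",
    "weight",
    "sev",
    "choice_prob_right",
    "negative_log_likelihood",
    "nll_arrays",
    "sev_arrays",
]

PARAM_NAMES: Tuple[str, ...] = (
    "rho_plus",
    "rho_minus",
    "lam",
    "alpha_plus",
    "alpha_minus",
    "mu",
    "x0",
)

#: probabilities are clamped into [PROB_CLIP, 1 - PROB_CLIP] inside the
#: likelihood so the NLL stays finite for arbitrarily steep sigmoids
PROB_CLIP = 1e-12
_LOG_CLIP = math.log(PROB_CLIP)


@dataclass(frozen=True)
class PTParams:
    """The seven-parameter behavioural model.

    Defaults are the *neutral* agent: linear utility, no loss aversion,
    undistorted probabilities, unit steepness, no side bias — under which
    subjective expected value reduces exactly to expected value.
    """

    rho_plus: float = 0.0
    rho_minus: float = 0.0
    lam: float = 1.0
    alpha_plus: float = 1.0
    alpha_minus: float = 1.0
    mu: float = 1.0
    x0: float = 0.0

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"PTParams.{name} must be finite, got {v!r}")
        if self.lam <= 0:
            raise ValueError("loss aversion lam must be positive")
        if self.alpha_plus <= 0 or self.alpha_minus <= 0:
            raise ValueError("Prelec exponents alpha_plus/alpha_minus must be positive")
        if not self.rho_plus < 1:
            raise ValueError("rho_plus must be < 1 (gain exponent 1 - rho_plus positive)")
        if not self.rho_minus > -1:
            raise ValueError("rho_minus must be > -1 (loss exponent 1 + rho_minus positive)")
        if self.mu < 0:
            raise ValueError("choice steepness mu must be non-negative")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "PTParams":
        return cls(**{k: float(d[k]) for k in PARAM_NAMES})

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_vector(cls, vec: Sequence[float]) -> "PTParams":
        if len(vec) != len(PARAM_NAMES):
            raise ValueError(f"expected {len(PARAM_NAMES)} values, got {len(vec)}")
        return cls(**dict(zip(PARAM_NAMES, map(float, vec))))

    @classmethod
    def neutral(cls, mu: float = 1.0, x0: float = 0.0) -> "PTParams":
        return cls(mu=mu, x0=x0)

    def replace(self, **kw) -> "PTParams":
        return replace(self, **kw)


def _as_xp(lottery) -> Tuple[float, float]:
    """Accept a task_model.Lottery or a plain ``(outcome, probability)`` pair."""
    if hasattr(lottery, "outcome"):
        return float(lottery.outcome), float(lottery.probability)
    x, p = lottery
    return float(x), float(p)


def utility(x, params: PTParams):
    """Subjective utility of a token quantity (u(0) = 0 by definition)."""
    xa = np.asarray(x, dtype=float)
    ax = np.abs(xa)
    gain = np.power(ax, 1.0 - params.rho_plus)
    loss = -params.lam * np.power(ax, 1.0 + params.rho_minus)
    out = np.where(xa > 0, gain, np.where(xa < 0, loss, 0.0))
    return float(out) if np.isscalar(x) else out


def weight(p, alpha: float):
    """Prelec-I probability weighting ``w(p) = exp(-(-ln p)**alpha)``.

    Strictly increasing on (0, 1] with fixed points at ``p = 1/e`` and
    ``p = 1`` for every ``alpha > 0``.
    """
    if alpha <= 0 or not np.isfinite(alpha):
        raise ValueError("alpha must be positive and finite")
    pa = np.asarray(p, dtype=float)
    if np.any(pa <= 0) or np.any(pa > 1):
        raise ValueError("probability must lie in (0, 1]")
    out = np.exp(-np.power(-np.log(pa), alpha))
    return float(out) if np.isscalar(p) else out


def sev(lottery, params: PTParams) -> float:
    """Subjective expected value ``w(p) * u(x)`` of one lottery.

    The Prelec exponent is selected by the sign of the lottery's non-zero
    outcome (``alpha_plus`` for gains, ``alpha_minus`` for losses).
    """
    x, p = _as_xp(lottery)
    if x == 0:
        return 0.0
    alpha = params.alpha_plus if x > 0 else params.alpha_minus
    return float(weight(p, alpha) * utility(x, params))


def choice_prob_right(pair, params: PTParams) -> float:
    """P(choose the right lottery) under the logistic choice rule."""
    left, right = pair
    delta = sev(right, params) - sev(left, params)
    return float(expit(params.mu * delta + params.x0))


# ---------------------------------------------------------------------------
# vectorized internals (shared with the fitting module)
# ---------------------------------------------------------------------------

def sev_arrays(x: np.ndarray, p: np.ndarray, vec: np.ndarray) -> np.ndarray:
    """Vectorized SEV for arrays of outcomes/probabilities.

    ``vec`` is the parameter vector in :data:`PARAM_NAMES` order.
    """
    rho_p, rho_m, lam, a_p, a_m = vec[0], vec[1], vec[2], vec[3], vec[4]
    ax = np.abs(x)
    pos = x > 0
    u = np.where(pos, np.power(ax, 1.0 - rho_p), -lam * np.power(ax, 1.0 + rho_m))
    u = np.where(x == 0, 0.0, u)
    w = np.exp(-np.power(-np.log(p), np.where(pos, a_p, a_m)))
    return w * u


def nll_arrays(
    vec: np.ndarray,
    xl: np.ndarray,
    pl: np.ndarray,
    xr: np.ndarray,
    pr: np.ndarray,
    chose_right: np.ndarray,
    counts: np.ndarray | None = None,
) -> float:
    """Negative log-likelihood over (possibly weighted) trial arrays."""
    delta = sev_arrays(xr, pr, vec) - sev_arrays(xl, pl, vec)
    z = vec[5] * delta + vec[6]
    # log P(right) = -log(1 + exp(-z)), computed overflow-safe
    log_pr = -np.logaddexp(0.0, -z)
    log_pl = -np.logaddexp(0.0, z)
    ll = np.where(chose_right, log_pr, log_pl)
    ll = np.maximum(ll, _LOG_CLIP)
    if counts is not None:
        ll = ll * counts
    return float(-np.sum(ll))


def nll_and_grad_arrays(
    vec: np.ndarray,
    xl: np.ndarray,
    pl: np.ndarray,
    xr: np.ndarray,
    pr: np.ndarray,
    chose_right: np.ndarray,
    counts: np.ndarray | None = None,
) -> Tuple[float, np.ndarray]:
    """NLL and its analytic gradient in :data:`PARAM_NAMES` order.

    The chain rule runs through z = mu*delta + x0 with
    d(nll)/dz = count * (sigmoid(z) - chose_right); per-side SEV derivatives:
    d(u)/d(rho+) = -ln|x| * u for gains, d(u)/d(rho-) = ln|x| * u for losses,
    d(u)/d(lam) = u / lam for losses, and
    d(w)/d(alpha) = -(-ln p)**alpha * ln(-ln p) * w (0 at p = 1).
    """
    rho_p, rho_m, lam, a_p, a_m, mu, x0 = vec
    grad = np.zeros(7)

    def side(x, p):
        ax = np.abs(x)
        pos = x > 0
        lax = np.log(ax)
        u = np.where(pos, np.power(ax, 1.0 - rho_p), -lam * np.power(ax, 1.0 + rho_m))
        t = -np.log(p)  # >= 0; == 0 at p = 1
        alpha = np.where(pos, a_p, a_m)
        ta = np.power(t, alpha)
        w = np.exp(-ta)
        s = w * u
        du_drho = np.where(pos, -lax * u, lax * u)  # rho+ for gains, rho- for losses
        du_dlam = np.where(pos, 0.0, u / lam)
        with np.errstate(divide="ignore"):
            logt = np.where(t > 0, np.log(np.maximum(t, 1e-300)), 0.0)
        dw_dalpha = -ta * logt * w
        ds = {
            "rho_plus": np.where(pos, w * du_drho, 0.0),
            "rho_minus": np.where(pos, 0.0, w * du_drho),
            "lam": w * du_dlam,
            "alpha_plus": np.where(pos, dw_dalpha * u, 0.0),
            "alpha_minus": np.where(pos, 0.0, dw_dalpha * u),
        }
        return s, ds

    s_r, ds_r = side(xr, pr)
    s_l, ds_l = side(xl, pl)
    delta = s_r - s_l
    z = mu * delta + x0
    log_pr = -np.logaddexp(0.0, -z)
    log_pl = -np.logaddexp(0.0, z)
    ll = np.where(chose_right, log_pr, log_pl)
    ll = np.maximum(ll, _LOG_CLIP)
    c = counts if counts is not None else 1.0
    nll = float(-np.sum(ll * c))

    dz = c * (expit(z) - chose_right)  # d(nll)/dz per row
    for i, name in enumerate(PARAM_NAMES[:5]):
        grad[i] = float(np.sum(dz * mu * (ds_r[name] - ds_l[name])))
    grad[5] = float(np.sum(dz * delta))
    grad[6] = float(np.sum(dz))
    return nll, grad


_TRIAL_COLS = ("left_outcome", "left_prob", "right_outcome", "right_prob")


def trials_to_arrays(trials) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Extract (xl, pl, xr, pr, chose_right) arrays from a trial table."""
    xl = np.asarray(trials["left_outcome"], dtype=float)
    pl = np.asarray(trials["left_prob"], dtype=float)
    xr = np.asarray(trials["right_outcome"], dtype=float)
    pr = np.asarray(trials["right_prob"], dtype=float)
    choice = np.asarray(trials["choice"])
    chose_right = choice == "right"
    if not np.all(chose_right | (choice == "left")):
        raise ValueError("choice column must contain only 'left'/'right'")
    return xl, pl, xr, pr, chose_right


def negative_log_likelihood(trials, params: PTParams) -> float:
    """-sum(log P(observed choice)) over a trial table.

    ``trials`` is any mapping of columns (typically a pandas DataFrame) with
    ``left_outcome, left_prob, right_outcome, right_prob, choice``.
    """
    if len(trials) == 0:
        raise ValueError("cannot compute likelihood of an empty trial list")
    xl, pl, xr, pr, cr = trials_to_arrays(trials)
    return nll_arrays(params.to_vector(), xl, pl, xr, pr, cr)
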