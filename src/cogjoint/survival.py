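"""Dropout outcomes, reverse Kaplan-Meier follow-up, and the
piecewise-exponential proportional-hazards machinery.

The dropout endpoint is composite: dementia diagnosis, or death within a
window (default 18 months) of the last study visit.  Deaths beyond the window
are treated as dropout for other reasons first, so those subjects are
censored at their last visit.  The baseline hazard is piecewise constant,
which keeps the cumulative hazard in closed form — that exactness is what
makes the joint likelihood in :mod:`cogjoint.joint` testable term by term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .coding import encode_baselines


@dataclass
class HazardSpec:
    """Piecewise-constant baseline hazard with log-linear covariates and
    shared-random-effect association coefficients."""

    knots: np.ndarray  # increasing, starting at 0; final piece extends to inf
    rates: np.ndarray  # one per piece, >= 0
    covariates: tuple = ()  # encoded covariate names entering gamma
    gamma: np.ndarray = field(default_factory=lambda: np.zeros(0))
    alpha: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.knots = np.asarray(self.knots, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.knots[0] != 0 or (np.diff(self.knots) <= 0).any():
            raise ValueError("knots must start at 0 and increase")
        if len(self.rates) != len(self.knots):
            raise ValueError("need one rate per piece")
        if (self.rates < 0).any():
            raise ValueError("rates must be >= 0")
        if len(self.gamma) != len(self.covariates):
            raise ValueError("gamma length must match covariate list")


def baseline_cumhaz(knots: np.ndarray, rates: np.ndarray, t) -> np.ndarray:
    """Integral of the piecewise-constant baseline hazard from 0 to t.

    The final rate extends beyond the last knot to infinity.  Exact closed
    form: sum over pieces of rate times the overlap of the piece with [0, t].
    """
    t = np.asarray(t, dtype=float)
    uppers = np.concatenate([knots[1:], [np.inf]])
    overlap = np.clip(t[..., None] - knots, 0.0, uppers - knots)
    return overlap @ rates


def piecewise_cumhaz(spec: HazardSpec, x: np.ndarray, b: np.ndarray, t) -> np.ndarray:
    """Subject-specific cumulative hazard
    Lambda(t) = exp(gamma' x + alpha' b) * H0(t)."""
    t = np.asarray(t, dtype=float)
    if (t < 0).any():
        raise ValueError("t must be >= 0")
    eta = float(np.dot(spec.gamma, x) + np.dot(spec.alpha, b))
    return np.exp(eta) * baseline_cumhaz(spec.knots, spec.rates, t)


# ---------------------------------------------------------------------------
# dropout endpoint definition
# ---------------------------------------------------------------------------

def define_dropout(
    events: pd.DataFrame,
    window: float = 1.5,
    admin_end: float = np.inf,
    alive_margin: float = 0.0,
) -> pd.DataFrame:
    """Derive one dropout outcome per subject from raw event dates.

    Rules, applied in order:

    1. dementia diagnosis -> event (cause ``dementia``) at the diagnosis time;
    2. death within ``window`` years of the last study visit -> event (cause
       ``death``) at the death time;
    3. otherwise censored at ``min(last_visit_time + alive_margin,
       admin_end)`` — a death beyond the window is treated as dropout for
       other reasons first, so the subject is censored at last known alive.

    Total and idempotent: exactly one outcome row per input subject.
    """
    for col in ("dementia_time", "death_time", "last_visit_time"):
        vals = events[col].to_numpy(float)
        if np.nanmin(vals, initial=np.inf) < 0:
            raise ValueError(f"negative times in {col}")
    dem = events["dementia_time"].to_numpy(float)
    death = events["death_time"].to_numpy(float)
    last = events["last_visit_time"].to_numpy(float)

    has_dem = ~np.isnan(dem)
    death_on_study = ~np.isnan(death) & ~has_dem & (death - last <= window)
    time = np.where(
        has_dem, dem, np.where(death_on_study, death, np.minimum(last + alive_margin, admin_end))
    )
    status = np.where(has_dem | death_on_study, "event", "censored")
    cause = np.where(has_dem, "dementia", np.where(death_on_study, "death", "none"))
    return pd.DataFrame(
        {
            "subject_id": events["subject_id"].to_numpy(),
            "time": time,
            "status": status,
            "cause": cause,
        }
    )


# ---------------------------------------------------------------------------
# reverse Kaplan-Meier follow-up
# ---------------------------------------------------------------------------

@dataclass
class FollowupSummary:
    median: float  # NaN when not reached
    q25: float
    q75: float
    n: int


def _km_quantile(times: np.ndarray, observed: np.ndarray, q: float) -> float:
    """Product-limit quantile: smallest t with S(t) <= 1 - q."""
    order = np.argsort(times, kind="stable")
    times, observed = times[order], observed[order]
    uniq = np.unique(times)
    at_risk = len(times)
    S = 1.0
    for t in uniq:
        here = times == t
        d = int((observed & here).sum())
        if d and at_risk:
            S *= 1.0 - d / at_risk
        at_risk -= int(here.sum())
        if S <= 1.0 - q + 1e-12:
            return float(t)
    return np.nan


def reverse_km_median(outcomes: pd.DataFrame) -> FollowupSummary:
    """Median and quartiles of follow-up by the reverse Kaplan-Meier method.

    The censoring indicator is flipped: censorings are the 'events' and
    dropout events are censored, so the estimand is the follow-up (censoring)
    distribution free of the dropout process.  With no censored subjects the
    median is not reached and reported as NaN.
    """
    if len(outcomes) == 0:
        raise ValueError("need at least one subject")
    times = outcomes["time"].to_numpy(float)
    flipped = (outcomes["status"].to_numpy() == "censored")
    return FollowupSummary(
        median=_km_quantile(times, flipped, 0.5),
        q25=_km_quantile(times, flipped, 0.25),
        q75=_km_quantile(times, flipped, 0.75),
        n=len(outcomes),
    )


# ---------------------------------------------------------------------------
# piecewise-exponential PH fit (association fixed at zero)
# ---------------------------------------------------------------------------

def event_time_knots(outcomes: pd.DataFrame, n_pieces: int = 5) -> np.ndarray:
    """Default knots at event-time quantiles (0 plus interior quantiles)."""
    ev = outcomes.loc[outcomes["status"] == "event", "time"].to_numpy(float)
    if len(ev) == 0:
        raise ValueError("need at least one event to place knots")
    qs = np.linspace(0, 1, n_pieces + 1)[1:-1]
    interior = np.unique(np.quantile(ev, qs))
    interior = interior[interior > 0]
    return np.concatenate([[0.0], interior])


@dataclass
class PHFit:
    covariates: tuple
    gamma: pd.Series
    knots: np.ndarray
    rates: np.ndarray
    loglik: float
    n_events: int


def _piece_exposure(knots: np.ndarray, times: np.ndarray) -> np.ndarray:
    """n x K matrix of time at risk within each hazard piece."""
    uppers = np.concatenate([knots[1:], [np.inf]])
    return np.clip(times[:, None] - knots, 0.0, uppers - knots)


def fit_ph_baseline(
    outcomes: pd.DataFrame,
    baselines: pd.DataFrame,
    knots: np.ndarray,
    covariates: tuple = (),
) -> PHFit:
    """ML fit of the piecewise-exponential PH model in (gamma, rates).

    The rates have closed-form optima given gamma (events over weighted
    person-time per piece), so only gamma is optimized numerically.  Used to
    initialize the joint model; with dense knots gamma agrees closely with a
    Cox partial-likelihood fit.
    """
    knots = np.asarray(knots, dtype=float)
    merged = outcomes.merge(baselines, on="subject_id", how="left", validate="1:1")
    times = merged["time"].to_numpy(float)
    delta = (merged["status"].to_numpy() == "event").astype(float)
    if delta.sum() < 1:
        raise ValueError("need at least one event")
    X = (
        encode_baselines(merged, covariates).to_numpy()
        if covariates
        else np.zeros((len(merged), 0))
    )
    E = _piece_exposure(knots, times)  # n x K person-time
    piece_of_event = np.clip(np.searchsorted(knots, times, side="right") - 1, 0, len(knots) - 1)
    d_k = np.bincount(piece_of_event[delta == 1].astype(int), minlength=len(knots)).astype(float)

    def negloglik(gamma):
        eta = X @ gamma
        w = np.exp(eta)
        Ek = E.T @ w  # weighted person-time per piece
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(d_k > 0, d_k * (np.log(d_k) - np.log(Ek)), 0.0)
        return -(term.sum() + float(delta @ eta) - d_k.sum())

    if X.shape[1]:
        res = optimize.minimize(negloglik, np.zeros(X.shape[1]), method="BFGS",
                                options={"gtol": 1e-9})
        gamma = res.x
    else:
        gamma = np.zeros(0)
    w = np.exp(X @ gamma)
    Ek = E.T @ w
    with np.errstate(divide="ignore", invalid="ignore"):
        rates = np.where(Ek > 0, d_k / Ek, 0.0)
    if (d_k == 0).any():
        empty = [k for k in range(len(knots)) if d_k[k] == 0]
        warnings.warn(f"no events in hazard piece(s) {empty}; rate estimated at boundary 0")
    return PHFit(
        covariates=tuple(covariates),
        gamma=pd.Series(gamma, index=list(covariates)),
        knots=knots,
        rates=rates,
        loglik=-negloglik(gamma),
        n_events=int(delta.sum()),
    )
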