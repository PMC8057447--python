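"""Synthetic cohort generation.

Generates complete cohorts with the structure the analysis assumes: baseline
covariates drawn from configured marginals, irregular gamma-distributed visit
times, a first post-enrollment surgical exposure from an exponential clock,
cognitive z-score trajectories from the linear mixed model

    y_ij = beta0 + beta_x' x_i + (beta_t + beta_tx' x_i) t_ij
           + beta_e u_ij + b0_i + b1_i t_ij + b2_i u_ij + eps_ij,

with u_ij = max(0, t_ij - s_i) the years since first exposure, and dropout
(dementia or death) from a proportional-hazards process

    h_i(t) = h0(t) exp(gamma' x_i + alpha0 b0_i + alpha1 b1_i + alpha2 b2_i)

with piecewise-constant baseline h0.  The missingness regime is controlled by
``config.regime``: under MNAR the hazard depends on the random effects
(informative dropout); under MAR ``alpha`` is forced to zero; under MCAR the
covariate effects ``gamma`` are zeroed as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .coding import (
    BASELINE_COLUMNS,
    EDUCATION_LEVELS,
    MARITAL_LEVELS,
    SMOKING_LEVELS,
    encode_baselines,
)
from .config import SimulationConfig, stage_rng


@dataclass
class Cohort:
    """One assembled synthetic cohort (four tables plus provenance)."""

    baselines: pd.DataFrame  # one row per subject, BASELINE_COLUMNS
    visits: pd.DataFrame  # subject_id, t, z
    exposures: pd.DataFrame  # subject_id, s (first post-enrollment surgery)
    events: pd.DataFrame  # subject_id, dementia_time, death_time, last_visit_time
    config: SimulationConfig
    meta: dict = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return len(self.baselines)

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_cohort_tables(self, outdir)

    @classmethod
    def load(cls, indir) -> "Cohort":
        return read_cohort_tables(Path(indir))


# ---------------------------------------------------------------------------
# component draws
# ---------------------------------------------------------------------------

def draw_covariates(config: SimulationConfig, n: int, rng=None) -> pd.DataFrame:
    """Draw ``n`` baseline covariate rows from the configured marginals.

    Covariates are drawn independently of each other (the configured values
    are marginals; dependence can be injected by editing the returned table).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    m = config.covariates
    m.validate()
    if rng is None:
        rng = stage_rng(config.seed, "covariates")

    def bern(name: str) -> np.ndarray:
        return (rng.random(n) < m.binary.get(name, 0.0)).astype(int)

    def categ(levels, probs) -> np.ndarray:
        p = np.array([probs.get(lv, 0.0) for lv in levels], dtype=float)
        p = p / p.sum()
        return rng.choice(np.array(levels, dtype=object), size=n, p=p)

    age = 70.0 + rng.gamma(m.age_excess_shape, m.age_excess_scale, size=n)
    df = pd.DataFrame(
        {
            "subject_id": np.arange(1, n + 1),
            "age_at_enrollment": np.round(age, 2),
            "sex": np.where(rng.random(n) < m.binary.get("female", 0.0), "F", "M"),
            "education_level": categ(EDUCATION_LEVELS, m.education),
            "apoe4": bern("apoe4"),
            "mci_at_enrollment": bern("mci"),
            "midlife_diabetes": bern("diabetes"),
            "midlife_hypertension": bern("hypertension"),
            "midlife_dyslipidemia": bern("dyslipidemia"),
            "atrial_fibrillation": bern("afib"),
            "chf": bern("chf"),
            "stroke": bern("stroke"),
            "cad": bern("cad"),
            "charlson_index": rng.poisson(m.charlson_mean, size=n),
            "marital_status": categ(MARITAL_LEVELS, m.marital),
            "smoking_status": categ(SMOKING_LEVELS, m.smoking),
            "alcohol_problem": bern("alcohol"),
            "prior_20yr_exposure": bern("prior_exposure"),
        }
    )
    return df[list(BASELINE_COLUMNS)]


def draw_random_effects(G, n: int, rng) -> np.ndarray:
    """Draw ``n`` random-effect triples b_i ~ N(0, G).

    Accepts any positive semidefinite (possibly singular) 3x3 covariance.
    """
    G = np.asarray(G, dtype=float)
    if G.shape != (3, 3) or not np.allclose(G, G.T, atol=1e-10):
        raise ValueError("G must be a symmetric 3x3 matrix")
    w, V = np.linalg.eigh(G)
    if w.min() < -1e-10:
        raise ValueError("G must be positive semidefinite")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    root = V * np.sqrt(np.clip(w, 0.0, None))
    return rng.standard_normal((n, 3)) @ root.T


def simulate_visits(config: SimulationConfig, n: int, rng=None) -> list[np.ndarray]:
    """Per-subject visit times: 0 then cumulative gamma gaps, truncated at
    the administrative censoring time."""
    if config.admin_censor_time <= 0:
        raise ValueError("admin_censor_time must be > 0")
    if config.visit_gap_shape <= 0 or config.visit_gap_scale <= 0:
        raise ValueError("visit gap distribution must have positive support")
    if rng is None:
        rng = stage_rng(config.seed, "visits")
    horizon = config.admin_censor_time
    mean_gap = config.visit_gap_shape * config.visit_gap_scale
    # draw a comfortable surplus of gaps, top up in the rare shortfall
    n_gap = int(np.ceil(horizon / mean_gap * 2.5)) + 6
    out = []
    for _ in range(n):
        gaps = rng.gamma(config.visit_gap_shape, config.visit_gap_scale, size=n_gap)
        t = np.concatenate([[0.0], np.cumsum(gaps)])
        while t[-1] <= horizon:  # pragma: no cover - essentially never at defaults
            more = rng.gamma(config.visit_gap_shape, config.visit_gap_scale, size=n_gap)
            t = np.concatenate([t, t[-1] + np.cumsum(more)])
        out.append(t[t <= horizon])
    return out


def simulate_exposure(
    config: SimulationConfig, n: int, rng=None, end_of_followup=None
) -> pd.DataFrame:
    """First post-enrollment surgery times from an exponential clock.

    The raw exposure time is recorded only if it precedes the subject's end of
    follow-up (``end_of_followup`` per subject; defaults to the administrative
    censoring time).  Returns a table with columns ``subject_id, s`` holding
    only the exposed subjects.
    """
    if config.exposure_rate < 0:
        raise ValueError("exposure_rate must be >= 0")
    if rng is None:
        rng = stage_rng(config.seed, "exposure")
    if end_of_followup is None:
        end_of_followup = np.full(n, config.admin_censor_time)
    end_of_followup = np.asarray(end_of_followup, dtype=float)
    if config.exposure_rate == 0:
        s = np.full(n, np.inf)
    else:
        s = rng.exponential(1.0 / config.exposure_rate, size=n)
    exposed = s < end_of_followup
    return pd.DataFrame(
        {"subject_id": np.arange(1, n + 1)[exposed], "s": s[exposed]}
    ).reset_index(drop=True)


def _linear_predictor(
    config: SimulationConfig, X: pd.DataFrame, t: np.ndarray, u: np.ndarray, idx: np.ndarray
) -> np.ndarray:
    """Fixed-effect mean of the z-score at (t, u) for subjects ``idx``."""
    mu = np.full(len(t), config.beta_intercept)
    slope = np.full(len(t), config.beta_time)
    for name, coef in config.beta_cov.items():
        mu += coef * X[name].to_numpy()[idx]
    for name, coef in config.beta_cov_time.items():
        slope += coef * X[name].to_numpy()[idx]
    return mu + slope * t + config.beta_exposure * u


def simulate_outcomes(
    baselines: pd.DataFrame,
    visits: list[np.ndarray],
    exposures: pd.DataFrame,
    effects: np.ndarray,
    config: SimulationConfig,
    rng=None,
) -> pd.DataFrame:
    """Cognitive z-scores at every visit: fixed linear predictor plus random
    effects plus Gaussian residual noise."""
    if len(visits) != len(baselines):
        raise ValueError("every visited subject needs a covariate row")
    if rng is None:
        rng = stage_rng(config.seed, "outcomes")
    needed = set(config.beta_cov) | set(config.beta_cov_time)
    X = encode_baselines(baselines, sorted(needed)) if needed else pd.DataFrame(index=baselines.index)
    s_by_subj = np.full(len(baselines), np.inf)
    if len(exposures):
        pos = {sid: i for i, sid in enumerate(baselines["subject_id"])}
        for sid, s in zip(exposures["subject_id"], exposures["s"]):
            if sid not in pos:
                raise ValueError(f"exposure for unknown subject {sid}")
            s_by_subj[pos[sid]] = s

    idx = np.repeat(np.arange(len(visits)), [len(v) for v in visits])
    t = np.concatenate(visits) if visits else np.empty(0)
    u = np.maximum(0.0, t - s_by_subj[idx])
    mu = _linear_predictor(config, X, t, u, idx)
    b = effects[idx]
    z = mu + b[:, 0] + b[:, 1] * t + b[:, 2] * u + rng.normal(0.0, config.sigma, size=len(t))
    return pd.DataFrame(
        {"subject_id": baselines["subject_id"].to_numpy()[idx], "t": t, "z": z}
    )


def simulate_dropout(
    baselines: pd.DataFrame,
    effects: np.ndarray,
    config: SimulationConfig,
    rng=None,
    censor_times=None,
) -> pd.DataFrame:
    """Dropout (dementia or death) times by inverse transform of the
    piecewise-constant cumulative hazard.

    Returns a table ``subject_id, event_time, cause`` where ``cause`` is
    ``dementia``/``death`` for events before the administrative censoring time
    and ``censored`` (with ``event_time`` equal to the censoring time)
    otherwise.
    """
    if rng is None:
        rng = stage_rng(config.seed, "dropout")
    n = len(baselines)
    knots = np.asarray(config.hazard_knots, dtype=float)
    rates = np.asarray(config.hazard_rates, dtype=float)
    alpha = config.effective_alpha
    gamma = config.effective_gamma
    if config.regime == "MNAR" and np.any(alpha != 0) and rates.max() == 0:
        raise ValueError("all-zero baseline hazard under MNAR: no events possible")

    eta = np.zeros(n)
    if gamma:
        Xs = encode_baselines(baselines, sorted(gamma))
        for name, coef in gamma.items():
            eta += coef * Xs[name].to_numpy()
    eta += effects @ alpha
    mult = np.exp(eta)

    # cumulative baseline hazard at the knots; final piece extends to infinity
    widths = np.diff(knots)
    cum = np.concatenate([[0.0], np.cumsum(rates[:-1] * widths)])
    target = rng.exponential(1.0, size=n) / mult  # required baseline cum. hazard
    # zero-rate pieces have zero-width cumulative intervals, so searchsorted
    # with side='right' lands on a positive-rate piece for interior targets
    k = np.searchsorted(cum, target, side="right") - 1
    k = np.clip(k, 0, len(rates) - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        T = knots[k] + (target - cum[k]) / rates[k]
    T = np.where(np.isfinite(T), T, np.inf)

    if censor_times is None:
        censor_times = np.full(n, config.admin_censor_time)
    censor_times = np.asarray(censor_times, dtype=float)
    censor = T > censor_times
    cause = np.where(
        censor,
        "censored",
        np.where(rng.random(n) < config.p_dementia, "dementia", "death"),
    )
    event_time = np.where(censor, censor_times, T)
    return pd.DataFrame(
        {
            "subject_id": baselines["subject_id"].to_numpy(),
            "event_time": event_time,
            "cause": cause,
        }
    )


# ---------------------------------------------------------------------------
# full cohort assembly
# ---------------------------------------------------------------------------

def assemble_cohort(config: SimulationConfig) -> Cohort:
    """Generate one full cohort under ``config``.

    Visits after the dropout event are deleted (dropout means no further
    observations); optionally a configured fraction of post-dementia visits is
    retained so the downstream exclusion filter has work to do.  Deterministic
    under ``config.seed``.
    """
    config.validate()
    n = config.n_subjects
    baselines = draw_covariates(config, n, stage_rng(config.seed, "covariates"))
    effects = draw_random_effects(config.G, n, stage_rng(config.seed, "effects"))
    schedule = simulate_visits(config, n, stage_rng(config.seed, "visits"))
    censor_times = np.full(n, config.admin_censor_time)
    if config.entry_window > 0:
        censor_times -= stage_rng(config.seed, "entry").uniform(0, config.entry_window, size=n)
    dropout = simulate_dropout(
        baselines, effects, config, stage_rng(config.seed, "dropout"), censor_times
    )

    T = dropout["event_time"].to_numpy()
    cause = dropout["cause"].to_numpy()
    end_fu = np.minimum(T, censor_times)
    exposures = simulate_exposure(config, n, stage_rng(config.seed, "exposure"), end_fu)

    keep_rng = stage_rng(config.seed, "retention")
    kept: list[np.ndarray] = []
    for i, t in enumerate(schedule):
        mask = t <= T[i]
        if cause[i] == "dementia" and config.post_dementia_retention > 0:
            post = (t > T[i]) & (keep_rng.random(len(t)) < config.post_dementia_retention)
            mask = mask | post
        kept.append(t[mask])
    visits = simulate_outcomes(
        baselines, kept, exposures, effects, config, stage_rng(config.seed, "outcomes")
    )

    last_visit = np.array([t.max() if len(t) else 0.0 for t in kept])
    dementia_time = np.where(cause == "dementia", T, np.nan)
    death_time = np.where(cause == "death", T, np.nan)
    if config.death_after_dementia:
        lag = stage_rng(config.seed, "death-lag").exponential(2.0, size=n)
        later = np.minimum(T + lag, np.inf)
        death_time = np.where(cause == "dementia", later, death_time)
    events = pd.DataFrame(
        {
            "subject_id": baselines["subject_id"].to_numpy(),
            "dementia_time": dementia_time,
            "death_time": death_time,
            "last_visit_time": last_visit,
        }
    )

    meta = {"config_hash": config.config_hash(), "seed": int(config.seed)}
    if config.missing_rates:
        baselines, injected = _inject_missing(
            baselines, config.missing_rates, stage_rng(config.seed, "missing")
        )
        meta["injected_missing"] = injected
    return Cohort(baselines, visits, exposures, events, config, meta)


def _inject_missing(baselines: pd.DataFrame, rates: dict, rng) -> tuple[pd.DataFrame, dict]:
    """Blank out raw covariate values at the configured per-column rates."""
    df = baselines.copy()
    injected = {}
    for col, rate in rates.items():
        if col not in df.columns:
            raise KeyError(f"unknown baseline column {col!r}")
        hit = rng.random(len(df)) < rate
        if hit.any():
            df[col] = df[col].astype(object)
            df.loc[hit, col] = np.nan
            injected[col] = int(hit.sum())
    return df, injected


# ---------------------------------------------------------------------------
# delimited-text round trip
# ---------------------------------------------------------------------------

def write_cohort_tables(cohort: Cohort, outdir: Path) -> None:
    """Write subjects/visits/exposures/events CSVs plus a provenance block."""
    cohort.baselines.to_csv(outdir / "subjects.csv", index=False)
    cohort.visits.to_csv(outdir / "visits.csv", index=False, float_format="%.10g")
    cohort.exposures.to_csv(outdir / "exposures.csv", index=False, float_format="%.10g")
    cohort.events.to_csv(outdir / "events.csv", index=False, float_format="%.10g")
    prov = {
        "config": cohort.config.to_dict(),
        "provenance": dict(cohort.meta),
    }
    with open(outdir / "provenance.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(prov, fh, sort_keys=True)


def read_cohort_tables(indir: Path) -> Cohort:
    baselines = pd.read_csv(indir / "subjects.csv")
    visits = pd.read_csv(indir / "visits.csv")
    exposures = pd.read_csv(indir / "exposures.csv")
    events = pd.read_csv(indir / "events.csv")
    with open(indir / "provenance.yaml", encoding="utf-8") as fh:
        prov = yaml.safe_load(fh)
    config = SimulationConfig.from_dict(prov["config"])
    return Cohort(baselines, visits, exposures, events, config, prov.get("provenance", {}))
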