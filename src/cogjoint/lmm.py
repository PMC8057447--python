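"""Linear mixed effects model with a time-dependent exposure term.

The mean model couples baseline covariates, time since enrollment, their
interactions, and years since a post-enrollment surgical exposure,

    E[y_ij] = beta0 + beta_x' x_i + (beta_t + beta_tx' x_i) t_ij + beta_e u_ij,

with u_ij = max(0, t_ij - s_i) zero for never-exposed subjects and before
exposure.  Random effects (a subset of intercept, slope, exposure-slope) are
Gaussian with unstructured covariance G; fitting is maximum likelihood (not
REML) on the profiled Gaussian marginal likelihood, with G parameterized by a
scaled log-Cholesky factor so positive semidefiniteness never binds.

Under a missing-at-random dropout process ML estimates here are consistent;
under informative (MNAR) dropout they are biased toward zero in the exposure
term, which is what the shared parameter model in :mod:`cogjoint.joint`
corrects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .coding import DEFAULT_MODEL_COVARIATES, encode_baselines

RANDOM_TERMS = ("intercept", "slope", "exposure_slope")


@dataclass(frozen=True)
class LMMSpec:
    """Model specification: fixed covariate set and random-effect structure."""

    covariates: tuple = DEFAULT_MODEL_COVARIATES
    interactions: tuple | None = None  # covariates with x-by-time terms; None = all
    random: tuple = RANDOM_TERMS

    def __post_init__(self):
        if self.interactions is None:
            object.__setattr__(self, "interactions", tuple(self.covariates))
        object.__setattr__(self, "covariates", tuple(self.covariates))
        object.__setattr__(self, "interactions", tuple(self.interactions))
        object.__setattr__(self, "random", tuple(self.random))
        bad = set(self.random) - set(RANDOM_TERMS)
        if bad:
            raise ValueError(f"unknown random terms {sorted(bad)}")
        if "intercept" not in self.random:
            raise ValueError("random structure must include the intercept")

    @property
    def fixed_columns(self) -> list[str]:
        cols = ["intercept", *self.covariates, "time"]
        cols += [f"{c}:time" for c in self.interactions]
        cols.append("time_since_exposure")
        return cols

    @property
    def random_columns(self) -> list[str]:
        return list(self.random)


@dataclass
class DesignData:
    """Stacked long-format design: fixed X, random Z, response y, group index."""

    X: np.ndarray
    Z: np.ndarray
    y: np.ndarray
    groups: np.ndarray  # 0..m-1 per row
    subject_ids: np.ndarray  # id per group index
    columns: list[str]
    random_columns: list[str]

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)


def exposure_time_on_study(t: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Years since first exposure: u = max(0, t - s); 0 when never exposed
    (s = +inf) and at the exposure instant itself."""
    return np.maximum(0.0, t - s)


def build_design(
    records: pd.DataFrame,
    baselines: pd.DataFrame,
    exposures: pd.DataFrame,
    spec: LMMSpec,
) -> DesignData:
    """Assemble fixed/random design matrices from the long table.

    Column order is ``intercept, <covariates>, time, <covariate:time>,
    time_since_exposure`` and is stable across calls.
    """
    ids = baselines["subject_id"].to_numpy()
    pos = {sid: i for i, sid in enumerate(ids)}
    rec_ids = records["subject_id"].to_numpy()
    unknown = set(rec_ids) - set(pos)
    if unknown:
        raise KeyError(f"records reference unknown subject ids: {sorted(unknown)[:5]}")

    needed = sorted(set(spec.covariates) | set(spec.interactions))
    Xcov = encode_baselines(baselines, needed) if needed else pd.DataFrame(index=baselines.index)
    if Xcov.isna().any().any():
        bad = [c for c in Xcov.columns if Xcov[c].isna().any()]
        raise ValueError(f"missing covariate values in {bad}; run the complete-case filter first")

    s = np.full(len(ids), np.inf)
    for sid, sv in zip(exposures["subject_id"], exposures["s"]):
        if sid in pos:
            s[pos[sid]] = sv

    gidx = np.array([pos[sid] for sid in rec_ids])
    # re-index groups densely over subjects that actually appear
    present = np.unique(gidx)
    remap = {g: j for j, g in enumerate(present)}
    groups = np.array([remap[g] for g in gidx])
    subject_ids = ids[present]

    t = records["t"].to_numpy(float)
    u = exposure_time_on_study(t, s[gidx])
    cols = [np.ones(len(t))]
    for c in spec.covariates:
        cols.append(Xcov[c].to_numpy()[gidx])
    cols.append(t)
    for c in spec.interactions:
        cols.append(Xcov[c].to_numpy()[gidx] * t)
    cols.append(u)
    X = np.column_stack(cols)

    zmap = {"intercept": np.ones(len(t)), "slope": t, "exposure_slope": u}
    Z = np.column_stack([zmap[r] for r in spec.random])
    y = records["z"].to_numpy(float)
    return DesignData(X, Z, y, groups, subject_ids, spec.fixed_columns, spec.random_columns)


# ---------------------------------------------------------------------------
# preparation filters
# ---------------------------------------------------------------------------

def exclude_post_dementia(
    records: pd.DataFrame, events: pd.DataFrame
) -> tuple[pd.DataFrame, int]:
    """Drop observations strictly after a subject's dementia diagnosis.

    Records at exactly the diagnosis time are retained (the diagnosis visit
    itself contributes).  Subjects without a dementia time are untouched.
    """
    dem = events.set_index("subject_id")["dementia_time"]
    cutoff = records["subject_id"].map(dem).to_numpy(float)
    keep = ~(records["t"].to_numpy(float) > cutoff)  # NaN cutoff -> keep
    keep |= np.isnan(cutoff)
    removed = int((~keep).sum())
    return records.loc[keep].reset_index(drop=True), removed


def complete_case_filter(
    baselines: pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """Remove subjects with any missing baseline covariate.

    Returns the filtered table and a report with the per-covariate missingness
    tally and the number of excluded subjects.
    """
    covcols = [c for c in baselines.columns if c != "subject_id"]
    isna = baselines[covcols].isna()
    tally = {c: int(isna[c].sum()) for c in covcols if isna[c].any()}
    keep = ~isna.any(axis=1)
    report = {"n_excluded": int((~keep).sum()), "missing_by_covariate": tally}
    return baselines.loc[keep].reset_index(drop=True), report


# ---------------------------------------------------------------------------
# maximum likelihood fit
# ---------------------------------------------------------------------------

@dataclass
class LMMFit:
    """ML fit: fixed effects with covariance, variance components, and AIC."""

    spec: LMMSpec
    beta: pd.Series
    cov_beta: pd.DataFrame
    G: np.ndarray
    sigma: float
    loglik: float
    n_obs: int
    n_subjects: int
    n_params: int
    converged: bool
    theta: np.ndarray = field(default=None, repr=False)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    def summary_frame(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.cov_beta.to_numpy()))
        est = self.beta.to_numpy()
        zval = np.divide(est, se, out=np.zeros_like(est), where=se > 0)
        p = 2.0 * stats.norm.sf(np.abs(zval))
        return pd.DataFrame(
            {
                "estimate": est,
                "se": se,
                "ci_low": est - 1.959963984540054 * se,
                "ci_high": est + 1.959963984540054 * se,
                "p": p,
            },
            index=self.beta.index,
        )


def _chol_from_theta(theta: np.ndarray, q: int) -> np.ndarray:
    L = np.zeros((q, q))
    L[np.diag_indices(q)] = np.exp(theta[:q])
    if q > 1:
        L[np.tril_indices(q, -1)] = theta[q:]
    return L


def _n_theta(q: int) -> int:
    return q * (q + 1) // 2


class _ProfiledLoglik:
    """Profiled ML deviance over the relative Cholesky factor of G/sigma^2.

    Subjects are batched by visit count so each evaluation is a handful of
    batched 3x3-ish Cholesky factorizations instead of a Python loop over
    subjects.
    """

    def __init__(self, data: DesignData, reml: bool = False):
        self.reml = reml
        self.N, self.p = data.X.shape
        self.q = data.Z.shape[1]
        order = np.argsort(data.groups, kind="stable")
        Xo, Zo, yo, go = data.X[order], data.Z[order], data.y[order], data.groups[order]
        counts = np.bincount(go, minlength=data.n_subjects)
        if (counts == 0).any():
            raise ValueError("every included subject needs at least one observation")
        self.batches = []
        starts = np.concatenate([[0], np.cumsum(counts)])
        by_ni: dict[int, list[int]] = {}
        for g, ni in enumerate(counts):
            by_ni.setdefault(int(ni), []).append(g)
        for ni, gs in sorted(by_ni.items()):
            idx = np.concatenate([np.arange(starts[g], starts[g] + ni) for g in gs])
            m = len(gs)
            self.batches.append(
                (
                    Xo[idx].reshape(m, ni, self.p),
                    Zo[idx].reshape(m, ni, self.q),
                    yo[idx].reshape(m, ni),
                )
            )

    def profile(self, theta: np.ndarray):
        """Return (nll, beta, sigma2, XtVX) at the profiled optimum."""
        L = _chol_from_theta(theta, self.q)
        A = L @ L.T
        XtVX = np.zeros((self.p, self.p))
        XtVy = np.zeros(self.p)
        ytVy = 0.0
        logdet = 0.0
        for Xb, Zb, yb in self.batches:
            ni = Xb.shape[1]
            V = Zb @ A @ np.swapaxes(Zb, 1, 2) + np.eye(ni)
            C = np.linalg.cholesky(V)
            logdet += 2.0 * np.sum(np.log(np.diagonal(C, axis1=1, axis2=2)))
            # batched solve against the Cholesky factor (np.linalg.solve
            # broadcasts over the leading batch axis)
            Xs = np.linalg.solve(C, Xb)
            ys = np.linalg.solve(C, yb[..., None])[..., 0]
            XtVX += np.einsum("mij,mik->jk", Xs, Xs)
            XtVy += np.einsum("mij,mi->j", Xs, ys)
            ytVy += float(np.einsum("mi,mi->", ys, ys))
        beta = np.linalg.solve(XtVX, XtVy)
        qform = max(ytVy - beta @ XtVy, 1e-12)
        if self.reml:
            dof = self.N - self.p
            sigma2 = qform / dof
            sign, ld_xtvx = np.linalg.slogdet(XtVX / sigma2)
            nll = 0.5 * (dof * np.log(2.0 * np.pi * sigma2) + logdet + dof + ld_xtvx)
        else:
            sigma2 = qform / self.N
            nll = 0.5 * (self.N * np.log(2.0 * np.pi * sigma2) + logdet + self.N)
        return nll, beta, sigma2, XtVX

    def __call__(self, theta: np.ndarray) -> float:
        if np.abs(theta).max() > 40:  # keep exp() finite
            return 1e12
        try:
            nll = self.profile(theta)[0]
        except np.linalg.LinAlgError:
            return 1e12
        return nll if np.isfinite(nll) else 1e12


def _check_rank(X: np.ndarray, columns: list[str]) -> None:
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        bad = [columns[j] for j in piv[rank:]]
        raise ValueError(f"fixed-effect design is rank deficient; collinear columns: {bad}")


def fit_lmm_ml(data: DesignData, spec: LMMSpec | None = None, reml: bool = False) -> LMMFit:
    """Maximize the Gaussian marginal likelihood over (beta, G, sigma).

    Deterministic: a fixed set of starting values for the variance components
    is tried and the best optimum kept.  beta and sigma^2 are profiled out,
    so the optimizer works in the ``q(q+1)/2``-dimensional Cholesky space of
    the relative covariance G / sigma^2.  ``reml=True`` switches to the
    restricted-likelihood criterion for variance components (sensitivity
    option; maximum likelihood is the default and the basis of all AIC
    comparisons).
    """
    _check_rank(data.X, data.columns)
    prof = _ProfiledLoglik(data, reml=reml)
    q = prof.q
    nth = _n_theta(q)

    starts = []
    for rel_sd in ([1.0, 0.3, 0.3], [0.2, 0.05, 0.05]):
        th = np.zeros(nth)
        th[:q] = np.log(rel_sd[:q])
        starts.append(th)

    best = None
    for th0 in starts:
        res = optimize.minimize(
            prof, th0, method="BFGS", options={"gtol": 1e-10, "maxiter": 300}
        )
        res = optimize.minimize(
            prof, res.x, method="Nelder-Mead",
            options={"maxiter": 800, "xatol": 1e-9, "fatol": 1e-12},
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    converged = bool(np.isfinite(best.fun) and best.fun < 1e11)
    if not converged:
        raise RuntimeError("LMM optimizer failed to converge")
    nll, beta, sigma2, XtVX = prof.profile(best.x)
    L = _chol_from_theta(best.x, q)
    G = sigma2 * (L @ L.T)
    cov_beta = sigma2 * np.linalg.inv(XtVX)
    n_params = data.X.shape[1] + nth + 1
    spec = spec or LMMSpec()
    return LMMFit(
        spec=spec,
        beta=pd.Series(beta, index=data.columns),
        cov_beta=pd.DataFrame(cov_beta, index=data.columns, columns=data.columns),
        G=G,
        sigma=float(np.sqrt(sigma2)),
        loglik=-nll,
        n_obs=data.n_obs,
        n_subjects=data.n_subjects,
        n_params=n_params,
        converged=converged,
        theta=best.x,
    )


def select_random_structure(
    candidates: list[LMMSpec],
    records: pd.DataFrame,
    baselines: pd.DataFrame,
    exposures: pd.DataFrame,
) -> tuple[LMMSpec, pd.DataFrame]:
    """Fit each candidate random structure and pick the one minimizing AIC.

    Ties break toward the structure with fewer parameters.  Candidates that
    fail to converge are excluded with a warning and flagged in the table.
    """
    if len(candidates) < 2:
        raise ValueError("need at least two candidate specifications")
    rows = []
    fits = {}
    for i, spec in enumerate(candidates):
        label = "+".join(spec.random)
        try:
            fit = fit_lmm_ml(build_design(records, baselines, exposures, spec), spec)
            fits[i] = fit
            rows.append(
                {"structure": label, "n_params": fit.n_params, "aic": fit.aic,
                 "loglik": fit.loglik, "converged": True}
            )
        except (RuntimeError, np.linalg.LinAlgError) as exc:
            warnings.warn(f"candidate {label!r} failed to converge: {exc}")
            rows.append(
                {"structure": label, "n_params": np.nan, "aic": np.nan,
                 "loglik": np.nan, "converged": False}
            )
    table = pd.DataFrame(rows)
    ok = table[table["converged"]]
    if ok.empty:
        raise RuntimeError("no candidate converged")
    order = ok.sort_values(["aic", "n_params"], kind="stable")
    best_idx = int(order.index[0])
    return candidates[best_idx], table


def marginal_slope(fit: LMMFit, baselines: pd.DataFrame) -> tuple[float, float]:
    """Average pre-exposure annual slope over the sample's covariate mix.

    Averages the subject-specific fixed-effect slopes beta_t + beta_tx' x_i
    over subjects, assuming no post-enrollment exposure; the standard error
    follows from the delta method on the fixed-effect covariance.
    """
    cols = list(fit.beta.index)
    c = np.zeros(len(cols))
    c[cols.index("time")] = 1.0
    inter = [col for col in cols if col.endswith(":time")]
    if inter:
        X = encode_baselines(baselines, [col[: -len(":time")] for col in inter])
        for col in inter:
            c[cols.index(col)] = float(X[col[: -len(":time")]].mean())
    est = float(c @ fit.beta.to_numpy())
    se = float(np.sqrt(c @ fit.cov_beta.to_numpy() @ c))
    return est, se
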