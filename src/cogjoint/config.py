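"""Configuration objects for cohort simulation and experiments.

The simulation truth lives in :class:`SimulationConfig`: the fixed effects of
the longitudinal mean model, the random-effects covariance ``G``, the residual
SD, a piecewise-constant baseline hazard with covariate log-hazard effects and
random-effect association coefficients ``alpha``, and the visit/exposure
process parameters.  The default values are stored in
``cogjoint/data/default_config.yaml`` and emulate a community cohort of
non-demented adults aged 70+ followed at roughly 15-month intervals.
"""

from __future__ import annotations

import dataclasses
import hashlib
import importlib.resources
import zlib
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import yaml

REGIMES = ("MCAR", "MAR", "MNAR")

#: encoded design-column vocabulary used by both the generator and the fitters
ENCODED_COVARIATES = (
    "age_c",
    "female",
    "educ_hs12",
    "educ_coll13_15",
    "educ_ge16",
    "apoe4",
    "mci",
    "diabetes",
    "hypertension",
    "dyslipidemia",
    "afib",
    "chf",
    "stroke",
    "cad",
    "charlson",
    "marital_single",
    "marital_widowed_divorced",
    "smoking_former",
    "smoking_current",
    "alcohol",
    "prior_exposure",
)


def _as_matrix(G: Any) -> np.ndarray:
    G = np.asarray(G, dtype=float)
    if G.shape != (3, 3):
        raise ValueError(f"G must be 3x3, got shape {G.shape}")
    return G


@dataclass
class CovariateMarginals:
    """Marginal distributions of the baseline covariates.

    Binary covariates carry a Bernoulli probability; categorical covariates a
    probability vector; age at enrollment is 70 plus a gamma excess; the
    Charlson comorbidity index is Poisson.
    """

    binary: dict[str, float] = field(default_factory=dict)
    education: dict[str, float] = field(default_factory=dict)
    marital: dict[str, float] = field(default_factory=dict)
    smoking: dict[str, float] = field(default_factory=dict)
    age_excess_shape: float = 1.9056
    age_excess_scale: float = 5.1643
    charlson_mean: float = 2.0

    def validate(self) -> None:
        for name, p in self.binary.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"invalid probability for covariate {name!r}: {p}")
        for label, probs in (
            ("education", self.education),
            ("marital", self.marital),
            ("smoking", self.smoking),
        ):
            vals = np.array(list(probs.values()), dtype=float)
            if (vals < 0).any() or (vals > 1).any():
                raise ValueError(f"invalid probability in {label} levels: {probs}")
            if vals.size and abs(vals.sum() - 1.0) > 1e-8:
                raise ValueError(f"{label} level probabilities must sum to 1, got {vals.sum()}")
        if self.age_excess_shape <= 0 or self.age_excess_scale <= 0:
            raise ValueError("age excess gamma parameters must be positive")
        if self.charlson_mean < 0:
            raise ValueError("charlson_mean must be non-negative")


@dataclass
class SimulationConfig:
    """Full generative truth for one synthetic cohort."""

    n_subjects: int = 1948
    # longitudinal mean model (z-score units; time in years)
    beta_intercept: float = 0.3
    beta_cov: dict[str, float] = field(default_factory=dict)
    beta_time: float = -0.03
    beta_cov_time: dict[str, float] = field(default_factory=dict)
    beta_exposure: float = -0.081
    # random effects (intercept, slope, post-exposure slope change) and noise
    G: np.ndarray = field(default_factory=lambda: np.diag([0.55, 0.006, 0.004]))
    sigma: float = 0.30
    # dropout hazard: piecewise-constant baseline, log-linear covariates,
    # shared-random-effect association alpha = (alpha0, alpha1, alpha2)
    hazard_knots: list[float] = field(default_factory=lambda: [0.0])
    hazard_rates: list[float] = field(default_factory=lambda: [0.03])
    gamma_cov: dict[str, float] = field(default_factory=dict)
    alpha: tuple[float, float, float] = (0.0, 0.0, 0.0)
    p_dementia: float = 0.389
    # observation processes
    visit_gap_shape: float = 8.1723
    visit_gap_scale: float = 0.16578
    exposure_rate: float = 0.055
    admin_censor_time: float = 8.5
    #: staggered enrollment: each subject's administrative censoring time is
    #: admin_censor_time minus U(0, entry_window) years
    entry_window: float = 0.0
    regime: str = "MNAR"
    seed: int = 0
    covariates: CovariateMarginals = field(default_factory=CovariateMarginals)
    # emulation knobs for the preparation-stage filters
    post_dementia_retention: float = 0.0
    death_after_dementia: bool = False
    missing_rates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.G = _as_matrix(self.G)
        self.alpha = tuple(float(a) for a in self.alpha)

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}, got {self.regime!r}")
        G = self.G
        if not np.allclose(G, G.T, atol=1e-10):
            raise ValueError("G must be symmetric")
        eig = np.linalg.eigvalsh(G)
        if eig.min() < -1e-10:
            raise ValueError("G must be positive semidefinite")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        knots = np.asarray(self.hazard_knots, dtype=float)
        rates = np.asarray(self.hazard_rates, dtype=float)
        if knots[0] != 0.0 or (np.diff(knots) <= 0).any():
            raise ValueError("hazard_knots must be increasing and start at 0")
        if len(rates) != len(knots):
            raise ValueError("need one hazard rate per knot interval")
        if (rates < 0).any():
            raise ValueError("hazard rates must be >= 0")
        if not 0.0 <= self.p_dementia <= 1.0:
            raise ValueError("p_dementia must be in [0, 1]")
        if self.visit_gap_shape <= 0 or self.visit_gap_scale <= 0:
            raise ValueError("visit gap distribution parameters must be positive")
        if self.exposure_rate < 0:
            raise ValueError("exposure_rate must be >= 0")
        if self.admin_censor_time <= 0:
            raise ValueError("admin_censor_time must be > 0")
        if not 0.0 <= self.entry_window < self.admin_censor_time:
            raise ValueError("entry_window must be in [0, admin_censor_time)")
        if not 0.0 <= self.post_dementia_retention <= 1.0:
            raise ValueError("post_dementia_retention must be in [0, 1]")
        for name, r in self.missing_rates.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"invalid missing rate for covariate {name!r}: {r}")
        if self.regime == "MNAR" and np.any(np.asarray(self.alpha) != 0) and rates.max() == 0:
            raise ValueError("MNAR regime with all-zero baseline hazard produces no events")
        unknown = (set(self.beta_cov) | set(self.beta_cov_time) | set(self.gamma_cov)) - set(
            ENCODED_COVARIATES
        )
        if unknown:
            raise ValueError(f"unknown covariate effect names: {sorted(unknown)}")
        self.covariates.validate()

    # -- regime-effective parameters -------------------------------------
    @property
    def effective_alpha(self) -> np.ndarray:
        """Association used in generation: forced to zero unless MNAR."""
        if self.regime == "MNAR":
            return np.asarray(self.alpha, dtype=float)
        return np.zeros(3)

    @property
    def effective_gamma(self) -> dict[str, float]:
        """Covariate log-hazard effects: forced to zero under MCAR."""
        if self.regime == "MCAR":
            return {}
        return dict(self.gamma_cov)

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["G"] = np.asarray(self.G).tolist()
        d["alpha"] = list(self.alpha)
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "SimulationConfig":
        d = dict(d)
        if "covariates" in d and isinstance(d["covariates"], Mapping):
            d["covariates"] = CovariateMarginals(**d["covariates"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        payload = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


def default_config(**overrides) -> SimulationConfig:
    """Load the packaged default simulation truth, with optional overrides."""
    ref = importlib.resources.files("cogjoint").joinpath("data/default_config.yaml")
    cfg = SimulationConfig.from_dict(yaml.safe_load(ref.read_text(encoding="utf-8")))
    if overrides:
        cfg = cfg.replace(**overrides)
    cfg.validate()
    return cfg


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    """Derive an independent generator for a named pipeline stage.

    A counter-based scheme: the stage name is hashed (CRC-32) and combined with
    the master seed in a :class:`numpy.random.SeedSequence`, so stages can be
    rerun independently and adding a stage never perturbs the others.
    """
    entropy = [int(master_seed) & 0x7FFFFFFF, zlib.crc32(stage.encode())]
    return np.random.default_rng(np.random.SeedSequence(entropy))
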