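"""Competing-risk data-generating process for the Monte Carlo studies.

Data are generated by the indirect method: the event *type* is drawn first,
then the event time conditional on the type.  With a standard-normal
covariate x, primary-event linear predictor lp1 and competing-event linear
predictor lp2:

* the event-type indicator Z is Bernoulli with parameter
  phi = 1 - (1 - p)^exp(lp1), where p is the proportion of subjects with
  covariate 0 who ever experience the primary event;
* given Z = 1, the primary-event time T1 is drawn by inverse transform from
  the conditional subdistribution, F1(t | x) / phi with
  F1(t | x) = 1 - (1 - p (1 - e^-t))^exp(lp1);
* given Z = 0, the competing-event time T2 is exponential with rate
  exp(lp2).

The cause-1 subdistribution is then exactly a Fine-Gray model with
coefficient beta1 (cumulative subdistribution hazard
-log(1 - p(1 - e^-t)) * exp(lp1)), which makes the closed-form
:func:`true_cif` an exact oracle for fitted models.  Optional exponential
censoring is calibrated to a target censored proportion by bisection on a
super-population.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

import numpy as np

from .data import CompetingRiskDataset
import pandas as pd


@dataclass
class DGPConfig:
    """Configuration of the competing-risk data-generating process.

    Parameters
    ----------
    n : sample size.
    p : proportion of subjects with covariate 0 who experience the primary
        event as t -> infinity.
    beta1, beta2 : subdistribution log-hazard ratios of the covariate for
        the primary and the competing event.
    censor_proportion : target proportion of censored subjects (0 = none).
    quadratic : the primary linear predictor becomes
        beta1 * x + 0.25 * beta1 * x^2 (the fitted model in the matching
        study deliberately omits the quadratic term).
    two_covariate : dict with key ``rho`` (correlation) and optionally
        ``beta2_second`` (primary-event coefficient of x2, default 0.25);
        primary linear predictor 0.50 x1 + beta2_second x2, competing
        0.25 x1 + 0.25 x2.  Mutually exclusive with ``quadratic``.
    p_validation : generate outcomes with this value of p instead of ``p``
        (covariate distribution unchanged), emulating a validation
        population with shifted incidence.
    censor_rate : exponential censoring rate; when None and
        censor_proportion > 0 it is calibrated by bisection at generation
        time.
    seed : integer seed; generation is bit-reproducible.
    """

    n: int
    p: float = 0.5
    beta1: float = 1.0
    beta2: float = 0.25
    censor_proportion: float = 0.0
    quadratic: bool = False
    two_covariate: dict | None = None
    p_validation: float | None = None
    censor_rate: float | None = None
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.p <= 1.0:
            raise ValueError("p must be in (0, 1]")
        if self.p_validation is not None and not 0.0 < self.p_validation <= 1.0:
            raise ValueError("p_validation must be in (0, 1]")
        if not 0.0 <= self.censor_proportion < 1.0:
            raise ValueError("censor_proportion must be in [0, 1)")
        if self.quadratic and self.two_covariate is not None:
            raise ValueError("quadratic and two_covariate are mutually exclusive")
        if self.two_covariate is not None and not -1.0 <= self.two_covariate.get("rho", 0.0) <= 1.0:
            raise ValueError("rho must be in [-1, 1]")

    @property
    def effective_p(self) -> float:
        return self.p if self.p_validation is None else self.p_validation

    @classmethod
    def from_file(cls, path) -> "DGPConfig":
        """Load a configuration from a YAML or JSON file.

        Keys mirror the field names; unknown keys are rejected.
        """
        import json

        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
        doc = (
            json.loads(text)
            if str(path).endswith(".json")
            else yaml.safe_load(text)
        )
        if not isinstance(doc, dict):
            raise ValueError(f"{path} does not hold a mapping of config fields")
        valid = {f.name for f in fields(cls)}
        unknown = set(doc) - valid
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**doc)


def _linear_predictors(cfg: DGPConfig, rng: np.random.Generator):
    """Draw covariates and return (covariate frame, lp1, lp2)."""
    if cfg.two_covariate is not None:
        rho = float(cfg.two_covariate.get("rho", 0.0))
        b2s = float(cfg.two_covariate.get("beta2_second", 0.25))
        cov = np.array([[1.0, rho], [rho, 1.0]])
        xs = rng.multivariate_normal([0.0, 0.0], cov, size=cfg.n)
        x1, x2 = xs[:, 0], xs[:, 1]
        lp1 = 0.50 * x1 + b2s * x2
        lp2 = 0.25 * x1 + 0.25 * x2
        frame = pd.DataFrame({"x1": x1, "x2": x2})
    else:
        x = rng.standard_normal(cfg.n)
        lp1 = cfg.beta1 * x + (0.25 * cfg.beta1 * x**2 if cfg.quadratic else 0.0)
        lp2 = cfg.beta2 * x
        frame = pd.DataFrame({"x": x})
    return frame, lp1, lp2


def _event_times(cfg: DGPConfig, rng: np.random.Generator, lp1, lp2):
    """Draw (event time, Z) by the indirect method."""
    p = cfg.effective_p
    elp1 = np.exp(lp1)
    phi = 1.0 - (1.0 - p) ** elp1
    z = rng.uniform(size=cfg.n) < phi
    t2 = rng.exponential(scale=np.exp(-lp2))
    u = rng.uniform(size=cfg.n)
    # u exactly 0 or 1 would be degenerate for the inverse transform
    u = np.clip(u, np.finfo(float).tiny, 1.0 - np.finfo(float).eps)
    # T1 = -log(1 - (1 - (1 - u*phi)^{1/exp(lp1)}) / p), stable arrangement
    inner = np.exp(np.log1p(-u * phi) / elp1)  # (1 - u phi)^(1/e^lp1)
    t1 = -np.log1p(-(1.0 - inner) / p)
    return np.where(z, t1, t2), z


def generate(config: DGPConfig) -> CompetingRiskDataset:
    """Generate a competing-risk sample from the configured process."""
    rng = np.random.default_rng(config.seed)
    frame, lp1, lp2 = _linear_predictors(config, rng)
    t, z = _event_times(config, rng, lp1, lp2)
    status = np.where(z, 1, 2)
    if config.censor_proportion > 0:
        rate = config.censor_rate
        if rate is None:
            rate = calibrate_censoring_rate(config, config.censor_proportion)
        c = rng.exponential(scale=1.0 / rate, size=config.n)
        censored = c < t
        t = np.minimum(t, c)
        status = np.where(censored, 0, status)
    return CompetingRiskDataset(np.arange(config.n), t, status, frame)


def true_cif(x, t, p: float, beta1: float):
    """Closed-form cause-1 cumulative incidence of the default process.

    F1(t | x) = 1 - (1 - p (1 - e^-t))^exp(beta1 * x); at x = 0 this tends
    to p as t -> infinity.  Serves as the oracle for fitted models and for
    the nonparametric estimators.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be nonnegative")
    out = 1.0 - (1.0 - p * (1.0 - np.exp(-t))) ** np.exp(beta1 * x)
    return float(out) if out.ndim == 0 else out


_CAL_SEED_OFFSET = 202_201  # internal seed offset for the calibration super-population


def calibrate_censoring_rate(
    config: DGPConfig,
    target: float,
    superpop_n: int = 200_000,
    tol: float = 0.001,
    bracket: tuple[float, float] = (1e-6, 100.0),
) -> float:
    """Exponential censoring rate achieving a target censored proportion.

    Bisection on the rate: a super-population of event times is generated
    once (fixed internal seed derived from ``config.seed``), a unit
    exponential draw E gives censoring times E / rate, and the rate is
    bisected until the censored proportion is within ``tol`` of ``target``.
    """
    if not 0.0 <= target < 1.0:
        raise ValueError("target must be in [0, 1)")
    if target == 0.0:
        return 0.0
    rng = np.random.default_rng(config.seed + _CAL_SEED_OFFSET)
    cfg = replace(config, n=superpop_n, censor_proportion=0.0, censor_rate=None)
    _, lp1, lp2 = _linear_predictors(cfg, rng)
    t, _ = _event_times(cfg, rng, lp1, lp2)
    e = rng.exponential(size=superpop_n)

    def censored_prop(rate):
        return float(np.mean(e / rate < t))

    lo, hi = bracket
    if censored_prop(lo) > target or censored_prop(hi) < target:
        raise ValueError(f"bracket {bracket} does not contain the target rate")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        prop = censored_prop(mid)
        if abs(prop - target) <= tol:
            return mid
        if prop < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def evaluation_times(
    config: DGPConfig,
    superpop_n: int = 1_000_000,
    percentiles=(10.0, 25.0, 50.0, 75.0, 90.0),
) -> np.ndarray:
    """Percentiles of event time (or observed time under censoring).

    A super-population of ``superpop_n`` subjects is generated from
    ``config`` (seeded, so reproducible); the returned times are the
    requested percentiles of the all-cause event times, or of the observed
    min(event, censoring) times when the process censors.
    """
    cfg = replace(config, n=superpop_n)
    data = generate(cfg)
    times = np.percentile(data.time, percentiles, method="linear")
    if np.any(np.diff(times) <= 0):
        raise ValueError("evaluation times are not strictly increasing")
    return times
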