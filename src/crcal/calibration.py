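"""Smoothed calibration curves and calibration metrics for competing risks.

Observed risk is estimated by regressing the subdistribution hazard of the
primary event on the complementary log-log of the predicted risk, via a
Fine-Gray model with a restricted cubic spline.  Evaluating the fitted model
at each subject's predicted risk yields a smoothed "observed" risk, from
which the calibration curve and the numerical metrics are computed:

* ICI  — mean |observed - predicted| over subjects,
* E50  — median of the absolute differences,
* E90  — 90th percentile of the absolute differences,
* Emax — maximum absolute difference.

Metrics are always computed from per-subject values, never from the display
grid.  A decile-binned comparator (mean predicted vs Aalen-Johansen observed
risk within prediction-quantile strata) is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import CompetingRiskDataset, RiskPredictionSet
from .errors import BinDegeneracyError, ConvergenceError
from .finegray import (
    WeightedCountingRows,
    expand_weighted,
    fit_weighted_cox,
    predict_cif,
)
from .nonparametric import aalen_johansen
from .splines import RCSBasisSpec, rcs_design

CLOGLOG_CLIP = 1e-10
DEFAULT_GRID_SIZE = 100


def cloglog(p) -> np.ndarray:
    """Complementary log-log transform log(-log(1 - p)).

    Input must lie in [0, 1]; values are clipped to
    [1e-10, 1 - 1e-10] so the transform is finite at the boundaries.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("probabilities must lie in [0, 1]")
    p = np.clip(p, CLOGLOG_CLIP, 1.0 - CLOGLOG_CLIP)
    return np.log(-np.log1p(-p))


@dataclass
class CalibrationMetrics:
    ici: float
    e50: float
    e90: float
    emax: float

    def as_tuple(self):
        return (self.ici, self.e50, self.e90, self.emax)

    def as_dict(self):
        return {"ICI": self.ici, "E50": self.e50, "E90": self.e90, "Emax": self.emax}


def calibration_metrics(predicted, observed) -> CalibrationMetrics:
    """ICI / E50 / E90 / Emax from per-subject predicted and observed risk.

    E90 uses the linear-interpolation ("type 7") percentile convention.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError("predicted and observed must have equal length")
    if predicted.size == 0:
        raise ValueError("need at least one subject")
    for name, v in (("predicted", predicted), ("observed", observed)):
        if np.any((v < 0) | (v > 1)):
            raise ValueError(f"{name} values must lie in [0, 1]")
    diff = np.abs(observed - predicted)
    return CalibrationMetrics(
        ici=float(diff.mean()),
        e50=float(np.median(diff)),
        e90=float(np.percentile(diff, 90.0, method="linear")),
        emax=float(diff.max()),
    )


@dataclass
class CalibrationResult:
    """Smoothed calibration assessment at one prediction horizon."""

    horizon_t0: float
    predicted: np.ndarray  # per-subject predicted risk
    observed_smoothed: np.ndarray  # per-subject smoothed observed risk
    curve_predicted: np.ndarray  # display grid (1st-99th pct of predicted)
    curve_observed: np.ndarray
    n_knots: int
    metrics: CalibrationMetrics
    fit: object = None  # the secondary FineGrayFit, kept for diagnostics

    def curve_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"predicted": self.curve_predicted, "observed": self.curve_observed}
        )


def calibration_curve(
    dataset: CompetingRiskDataset,
    predictions: RiskPredictionSet,
    n_knots: int = 3,
    administrative_censor_at_t0: bool = False,
    grid_size: int = DEFAULT_GRID_SIZE,
    expansion: WeightedCountingRows | None = None,
) -> CalibrationResult:
    """Smoothed calibration curve and metrics at ``predictions.horizon_t0``.

    The secondary model regresses the subdistribution hazard of the primary
    event on a restricted cubic spline (default 3 knots, at Harrell's
    percentiles of the transformed values) in cloglog(predicted risk).  The
    smoothed observed risk for each subject is the secondary model's
    predicted cumulative incidence at t0, and the display curve spans the
    1st-99th percentile of the predicted risks.

    ``administrative_censor_at_t0`` recodes follow-up beyond t0 as censoring
    at t0 before fitting, which protects the assessment against
    non-proportional subdistribution hazards in the secondary model.

    ``expansion`` may carry a precomputed weighted expansion of ``dataset``
    (ignored when administrative censoring is requested, since that changes
    the data).
    """
    if len(predictions) != len(dataset):
        raise ValueError("predictions must align with the dataset")
    t0 = predictions.horizon_t0
    if t0 > dataset.time.max():
        raise ValueError("t0 lies beyond the observed follow-up")
    data = dataset
    if administrative_censor_at_t0:
        data = dataset.administratively_censored(t0)
        expansion = None

    z = cloglog(predictions.predicted)
    spec = RCSBasisSpec.from_data(z, n_knots)  # KnotDegeneracyError if constant
    design = rcs_design(z, spec)
    names = ["cll"] + [f"cll_rcs{j}" for j in range(1, n_knots - 1)]

    if expansion is None:
        expansion = expand_weighted(data)
    rows = expansion.replace_covariates(design, names)
    fit = fit_weighted_cox(rows, names)
    if not fit.converged:
        raise ConvergenceError(
            "secondary calibration model did not converge "
            f"(iterations={fit.iterations}, log PL={fit.log_partial_likelihood})",
            fit=fit,
        )

    observed = predict_cif(fit, design, t0).predicted
    lo, hi = np.percentile(predictions.predicted, [1.0, 99.0], method="linear")
    grid = np.linspace(lo, hi, grid_size)
    grid_obs = predict_cif(fit, rcs_design(cloglog(grid), spec), t0).predicted
    return CalibrationResult(
        horizon_t0=t0,
        predicted=predictions.predicted.copy(),
        observed_smoothed=observed,
        curve_predicted=grid,
        curve_observed=grid_obs,
        n_knots=n_knots,
        metrics=calibration_metrics(predictions.predicted, observed),
        fit=fit,
    )


@dataclass
class BinnedCalibration:
    """Decile-style comparator: observed vs mean predicted risk by stratum."""

    horizon_t0: float
    n_bins: int
    mean_predicted: np.ndarray
    observed: np.ndarray  # Aalen-Johansen CIF at t0 within each stratum
    counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mean_predicted": self.mean_predicted,
                "observed": self.observed,
                "count": self.counts,
            }
        )


def binned_calibration(
    dataset: CompetingRiskDataset,
    predictions: RiskPredictionSet,
    n_bins: int = 10,
) -> BinnedCalibration:
    """Bin subjects by prediction quantiles; compare mean predicted risk with
    the Aalen-Johansen cause-1 cumulative incidence at t0 within each bin.

    Tied prediction values are never split across bins (quantile bins are
    formed on the values, so equal predictions share a bin).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    if len(predictions) != len(dataset):
        raise ValueError("predictions must align with the dataset")
    pred = predictions.predicted
    try:
        bins = pd.qcut(pred, n_bins, labels=False, duplicates="raise")
    except ValueError as exc:
        raise BinDegeneracyError(
            f"cannot form {n_bins} non-empty prediction-quantile bins: {exc}"
        ) from exc
    t0 = predictions.horizon_t0
    mean_pred, observed, counts = [], [], []
    for b in range(n_bins):
        mask = bins == b
        if not np.any(mask):
            raise BinDegeneracyError(f"bin {b} is empty after tie handling")
        mean_pred.append(pred[mask].mean())
        cif = aalen_johansen(dataset.subset(mask), cause=1)
        observed.append(cif(t0))
        counts.append(int(mask.sum()))
    return BinnedCalibration(
        horizon_t0=t0,
        n_bins=n_bins,
        mean_predicted=np.asarray(mean_pred),
        observed=np.asarray(observed),
        counts=np.asarray(counts),
    )
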