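"""Fine-Gray subdistribution hazard model.

The model is fit by the weighted-data route: subjects who experience the
competing event remain in the risk set after their event time, with a
time-dependent inverse-probability-of-censoring weight
G(s-)/G(T_i-), where G is the reverse Kaplan-Meier estimate of the
censoring survival function.  The expanded start-stop rows are then fed to
a weighted Cox partial likelihood (Breslow tie handling), maximized by
Newton-Raphson with step-halving.  For right-censored data this coincides
with the original estimating-equation formulation of the model.

The cumulative incidence implied by a fit is
``F1(t | x) = 1 - exp(-Lambda0(t) * exp(x beta))`` with ``Lambda0`` the
Breslow baseline cumulative subdistribution hazard.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CompetingRiskDataset, RiskPredictionSet, StepFunction
from .errors import DegenerateWeightError
from .nonparametric import km_survival

MAX_ITER = 50
MAX_HALVINGS = 20
GRAD_TOL = 1e-8
LL_RTOL = 1e-10


@dataclass
class WeightedCountingRows:
    """Start-stop counting-process rows realizing the Fine-Gray risk set.

    Subjects with status 0 or 1 contribute a single row with weight 1.
    Subjects with a competing event contribute their own follow-up with
    weight 1 and then remain at risk, with intervals whose weight is
    G(s-)/G(T_i-) for primary-event times s inside the interval.
    """

    subject_index: np.ndarray  # row -> position in the source dataset
    subject_id: np.ndarray
    start: np.ndarray
    stop: np.ndarray
    event: np.ndarray  # 1 iff primary event at stop
    weight: np.ndarray
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __len__(self) -> int:
        return len(self.start)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "start": self.start,
                "stop": self.stop,
                "event": self.event,
                "weight": self.weight,
            }
        )
        for c in self.covariates.columns:
            df[c] = self.covariates[c].to_numpy()
        return df

    def replace_covariates(self, values, names: list[str]) -> "WeightedCountingRows":
        """Same expansion with different subject-level covariates.

        ``values`` has one row per subject of the source dataset; rows are
        gathered through ``subject_index``.  Lets a single expansion back
        several fits (the expansion depends only on times and status).
        """
        values = np.atleast_2d(np.asarray(values, dtype=float))
        if values.shape[0] == 1 and len(names) == 1:
            values = values.T
        cov = pd.DataFrame(values[self.subject_index], columns=names)
        return WeightedCountingRows(
            self.subject_index, self.subject_id, self.start, self.stop,
            self.event, self.weight, cov,
        )


def expand_weighted(
    dataset: CompetingRiskDataset,
    G: StepFunction | None = None,
    granularity: str = "censoring",
) -> WeightedCountingRows:
    """IPCW weighted-data expansion realizing the Fine-Gray risk set.

    Parameters
    ----------
    G : StepFunction, optional
        Censoring survival function; computed by reverse Kaplan-Meier from
        ``dataset`` when omitted.
    granularity : {"censoring", "event"}
        How finely the post-event follow-up of competing-event subjects is
        partitioned.  ``"censoring"`` (default) breaks intervals where the
        weight actually changes, i.e. at censoring times; ``"event"`` emits
        one row per distinct primary-event time.  The two partitions carry
        identical weights at every primary-event time and give identical
        fits; the default is far more compact.
    """
    if granularity not in ("censoring", "event"):
        raise ValueError("granularity must be 'censoring' or 'event'")
    if G is None:
        G = km_survival(dataset, "censoring")
    time, status = dataset.time, dataset.status
    n = len(dataset)

    primary_times = np.unique(time[status == 1])
    base = WeightedCountingRows(
        subject_index=np.arange(n),
        subject_id=dataset.subject_id.copy(),
        start=np.zeros(n),
        stop=time.copy(),
        event=(status == 1).astype(int),
        weight=np.ones(n),
        covariates=dataset.covariates.copy(),
    )
    competing = np.nonzero(status == 2)[0]
    if competing.size == 0 or primary_times.size == 0:
        return base

    # Risk-set extension stops at the last primary-event time, or earlier
    # if G hits zero (weights would be zero from there on).
    s_max = primary_times[-1]
    if G.jump_times.size and np.any(G.values <= 0):
        g_zero = G.jump_times[np.nonzero(G.values <= 0)[0][0]]
        s_max = min(s_max, g_zero)  # event at g_zero still has G(s-) > 0

    g_left_T = G(time[competing], side="left")
    if np.any(g_left_T <= 0):
        bad = dataset.subject_id[competing[np.nonzero(g_left_T <= 0)[0][0]]]
        raise DegenerateWeightError(
            f"censoring survival is 0 just before the competing event of "
            f"subject {bad!r}; IPCW weight undefined"
        )

    if granularity == "censoring":
        interior = G.jump_times[(G.jump_times < s_max)]
        breaks = np.unique(np.concatenate([interior, [s_max]]))
    else:
        breaks = primary_times[primary_times <= s_max]

    pos = np.searchsorted(breaks, time[competing], side="right")
    counts = len(breaks) - pos
    keep = counts > 0
    comp = competing[keep]
    pos = pos[keep]
    counts = counts[keep]
    if comp.size == 0:
        return base

    # Row r of subject i covers (b[pos_i + r - 1], b[pos_i + r]], with the
    # first interval starting at the subject's own event time.
    row_subj = np.repeat(np.arange(comp.size), counts)
    offsets = np.arange(counts.sum()) - np.repeat(
        np.concatenate(([0], np.cumsum(counts)[:-1])), counts
    )
    stop = breaks[pos[row_subj] + offsets]
    start = np.where(
        offsets == 0, time[comp][row_subj], breaks[pos[row_subj] + offsets - 1]
    )
    if granularity == "censoring":
        # G(s-) is constant on each interval and equals G at its left end.
        g_num = G(start, side="right")
    else:
        g_num = G(stop, side="left")
    weight = g_num / g_left_T[keep][row_subj]
    ext_index = comp[row_subj]

    subject_index = np.concatenate([np.arange(n), ext_index])
    cov = (
        pd.concat(
            [dataset.covariates, dataset.covariates.iloc[ext_index]],
            ignore_index=True,
        )
        if len(dataset.covariates.columns)
        else pd.DataFrame()
    )
    return WeightedCountingRows(
        subject_index=subject_index,
        subject_id=dataset.subject_id[subject_index],
        start=np.concatenate([base.start, start]),
        stop=np.concatenate([base.stop, stop]),
        event=np.concatenate([base.event, np.zeros(len(start), dtype=int)]),
        weight=np.concatenate([base.weight, weight]),
        covariates=cov,
    )


@dataclass
class FineGrayFit:
    """A fitted Fine-Gray model.

    ``baseline_cum_hazard`` is the Breslow baseline cumulative
    subdistribution hazard, jumping only at observed primary-event times.
    ``info_diagonal`` is the diagonal of the observed information at the
    optimum, reported only as a convergence diagnostic.
    """

    coefficients: np.ndarray
    covariate_names: list[str]
    baseline_cum_hazard: StepFunction
    log_partial_likelihood: float
    iterations: int
    converged: bool
    info_diagonal: np.ndarray | None = None

    def linear_predictor(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.covariate_names].to_numpy(dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X @ self.coefficients

    def to_json(self) -> str:
        return json.dumps(
            {
                "coefficients": self.coefficients.tolist(),
                "covariate_names": self.covariate_names,
                "baseline": {
                    "jump_times": self.baseline_cum_hazard.jump_times.tolist(),
                    "values": self.baseline_cum_hazard.values.tolist(),
                    "initial_value": self.baseline_cum_hazard.initial_value,
                },
                "convergence": {
                    "log_partial_likelihood": self.log_partial_likelihood,
                    "iterations": self.iterations,
                    "converged": self.converged,
                    "info_diagonal": (
                        None if self.info_diagonal is None else self.info_diagonal.tolist()
                    ),
                },
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "FineGrayFit":
        doc = json.loads(text)
        conv = doc["convergence"]
        return cls(
            coefficients=np.asarray(doc["coefficients"], dtype=float),
            covariate_names=list(doc["covariate_names"]),
            baseline_cum_hazard=StepFunction(
                np.asarray(doc["baseline"]["jump_times"], dtype=float),
                np.asarray(doc["baseline"]["values"], dtype=float),
                doc["baseline"]["initial_value"],
            ),
            log_partial_likelihood=conv["log_partial_likelihood"],
            iterations=conv["iterations"],
            converged=conv["converged"],
            info_diagonal=(
                None
                if conv["info_diagonal"] is None
                else np.asarray(conv["info_diagonal"], dtype=float)
            ),
        )


def _risk_set_sums(lo, hi, contrib, m):
    """Sum `contrib` over rows at risk at each of m event times.

    Row j is at risk at event-time indices [lo[j], hi[j]); accumulate by
    difference array + cumulative sum.
    """
    diff = np.bincount(lo, weights=contrib, minlength=m + 1)
    diff -= np.bincount(hi, weights=contrib, minlength=m + 1)
    return np.cumsum(diff)[:m]


def fit_weighted_cox(
    rows: WeightedCountingRows, covariate_names: list[str] | None = None
) -> FineGrayFit:
    """Maximize the weighted Cox partial likelihood on start-stop rows.

    Newton-Raphson from beta = 0 with step-halving; Breslow handling of
    ties; converged when the gradient max-norm drops below 1e-8 or the
    relative log-likelihood change below 1e-10.  Non-convergence (including
    monotone-likelihood divergence) is flagged on the returned fit, never
    silent.
    """
    if covariate_names is None:
        covariate_names = list(rows.covariates.columns)
    if not covariate_names:
        raise ValueError("at least one covariate is required")
    X = rows.covariates[covariate_names].to_numpy(dtype=float)
    w = np.asarray(rows.weight, dtype=float)
    event = np.asarray(rows.event, dtype=int)

    ev = event == 1
    if not np.any(ev):
        raise ValueError("no primary-event rows; cannot fit")
    ets, ev_group = np.unique(rows.stop[ev], return_inverse=True)
    m = ets.size
    p = X.shape[1]

    dw = np.bincount(ev_group, weights=w[ev], minlength=m)

    lo = np.searchsorted(ets, rows.start, side="right")
    hi = np.searchsorted(ets, rows.stop, side="right")
    at_risk = lo < hi
    Xk, wk, lok, hik = X[at_risk], w[at_risk], lo[at_risk], hi[at_risk]

    xbar = Xk.mean(axis=0)
    Xc = Xk - xbar
    sx = np.empty((m, p))
    Xev_c = X[ev] - xbar
    for q in range(p):
        sx[:, q] = np.bincount(ev_group, weights=w[ev] * Xev_c[:, q], minlength=m)
    sx_total = sx.sum(axis=0)

    def loglik(beta):
        eta = np.clip(Xc @ beta, -700, 700)
        r = wk * np.exp(eta)
        D = _risk_set_sums(lok, hik, r, m)
        if np.any(D <= 0):
            return -np.inf, None, None
        return float(sx_total @ beta - dw @ np.log(D)), r, D

    beta = np.zeros(p)
    ll, r, D = loglik(beta)
    converged = False
    it = 0
    info = None
    for it in range(1, MAX_ITER + 1):
        # risk-set sums of r*x and r*x*x'
        N1 = np.empty((m, p))
        for q in range(p):
            N1[:, q] = _risk_set_sums(lok, hik, r * Xc[:, q], m)
        N2 = np.empty((m, p, p))
        for q in range(p):
            for s in range(q, p):
                val = _risk_set_sums(lok, hik, r * Xc[:, q] * Xc[:, s], m)
                N2[:, q, s] = val
                N2[:, s, q] = val
        mu = N1 / D[:, None]
        grad = sx_total - dw @ mu
        info = np.einsum("i,ijk->jk", dw / D, N2) - np.einsum(
            "i,ij,ik->jk", dw, mu, mu
        )
        if np.max(np.abs(grad)) < GRAD_TOL:
            converged = True
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            break
        # noise floor for the improvement check (float resolution at |ll|)
        tol = 1e-9 * (abs(ll) + 1.0)
        new_ll, new_r, new_D = -np.inf, None, None
        for _ in range(MAX_HALVINGS + 1):
            cand = beta + step
            new_ll, new_r, new_D = loglik(cand)
            if new_ll >= ll - tol:
                break
            step = step / 2.0
        if new_ll < ll - tol:  # could not improve even after halving
            break
        rel_change = abs(new_ll - ll) / (abs(ll) + 1.0)
        beta, ll, r, D = cand, new_ll, new_r, new_D
        if np.max(np.abs(beta)) > 200:  # monotone-likelihood divergence
            break
        if rel_change < LL_RTOL:
            converged = True
            break

    # Breslow baseline on the original (uncentered) covariate scale.
    offset = float(np.exp(np.clip(xbar @ beta, -700, 700)))
    jumps = dw / (D * offset)
    baseline = StepFunction(ets, np.cumsum(jumps), initial_value=0.0)
    return FineGrayFit(
        coefficients=beta,
        covariate_names=list(covariate_names),
        baseline_cum_hazard=baseline,
        log_partial_likelihood=ll,
        iterations=it,
        converged=converged,
        info_diagonal=None if info is None else np.diag(info).copy(),
    )


def predict_cif(fit: FineGrayFit, X, t0: float) -> RiskPredictionSet:
    """Predicted cumulative incidence 1 - exp(-Lambda0(t0) e^{X beta})."""
    if t0 <= 0:
        raise ValueError("t0 must be positive")
    lam0 = fit.baseline_cum_hazard(t0)
    eta = np.clip(fit.linear_predictor(X), -700, 700)
    return RiskPredictionSet(t0, 1.0 - np.exp(-lam0 * np.exp(eta)))


def fine_gray(
    dataset: CompetingRiskDataset,
    covariate_names: list[str] | None = None,
    expansion: WeightedCountingRows | None = None,
) -> FineGrayFit:
    """Fit a Fine-Gray model to a dataset (expansion + weighted Cox)."""
    if expansion is None:
        expansion = expand_weighted(dataset)
    return fit_weighted_cox(expansion, covariate_names)
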