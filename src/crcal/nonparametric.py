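"""Kaplan-Meier and Aalen-Johansen estimators.

These back two pieces of machinery: the reverse Kaplan-Meier estimate G of
the censoring survival function (used for inverse-probability-of-censoring
weights, always evaluated left-continuously as G(t-)) and the
Aalen-Johansen cumulative incidence estimator (the nonparametric observed
risk in the decile-binned comparator).

Tie convention: at a tied time the risk set for either estimator is every
subject with follow-up time >= t.  For the event-time KM this means
subjects censored at t remain at risk for events at t; for the reverse KM
the roles swap symmetrically.
"""

from __future__ import annotations

import numpy as np

from .data import CompetingRiskDataset, StepFunction


def _product_limit(times: np.ndarray, is_event: np.ndarray) -> StepFunction:
    """Product-limit survival estimate S(t) = prod_{t_j <= t} (1 - d_j/n_j)."""
    order = np.argsort(times, kind="stable")
    t = times[order]
    d = is_event[order].astype(float)
    uniq, start = np.unique(t, return_index=True)
    # events at each distinct time, risk set = everyone with time >= t
    d_at = np.add.reduceat(d, start)
    n_total = len(t)
    n_at = n_total - start  # sorted, so #(time >= uniq[i]) = n - first index
    keep = d_at > 0
    jump_t = uniq[keep]
    frac = 1.0 - d_at[keep] / n_at[keep]
    values = np.cumprod(frac)
    return StepFunction(jump_t, values, initial_value=1.0)


def km_survival(dataset: CompetingRiskDataset, event_definition: str = "any_event") -> StepFunction:
    """Kaplan-Meier survival function.

    ``event_definition="any_event"`` treats status 1 and 2 as events and
    returns the all-cause event-time survival S.  ``"censoring"`` treats
    status 0 as the event (reverse KM) and returns the censoring survival G.
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    if event_definition == "any_event":
        is_event = dataset.status != 0
    elif event_definition == "censoring":
        is_event = dataset.status == 0
    else:
        raise ValueError("event_definition must be 'any_event' or 'censoring'")
    return _product_limit(dataset.time, is_event)


def aalen_johansen(dataset: CompetingRiskDataset, cause: int = 1) -> StepFunction:
    """Aalen-Johansen cumulative incidence function for one cause.

    CIF_cause(t) = sum_{t_j <= t} S(t_j-) d_{cause,j} / n_j, with S the
    all-cause Kaplan-Meier survival.  Nondecreasing, starts at 0.
    """
    if cause not in (1, 2):
        raise ValueError("cause must be 1 or 2")
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    order = np.argsort(dataset.time, kind="stable")
    t = dataset.time[order]
    status = dataset.status[order]
    uniq, start = np.unique(t, return_index=True)
    n_at = len(t) - start
    d_any = np.add.reduceat((status != 0).astype(float), start)
    d_cause = np.add.reduceat((status == cause).astype(float), start)
    # S(t-) at each distinct time: survival just before, i.e. product over
    # earlier distinct times only.
    frac = 1.0 - d_any / n_at
    s_left = np.concatenate(([1.0], np.cumprod(frac)[:-1]))
    jumps = s_left * d_cause / n_at
    keep = d_cause > 0
    return StepFunction(uniq[keep], np.cumsum(jumps)[keep], initial_value=0.0)
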