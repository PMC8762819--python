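"""Restricted cubic spline basis with percentile-based knot placement.

The restricted ("natural") cubic spline is piecewise cubic, continuous in its
second derivative, and constrained to be linear below the first knot and
above the last.  With k knots t_1 < ... < t_k the basis has k-1 columns: the
identity, plus k-2 truncated-cubic combinations.  Knots are placed at fixed
percentiles of the data following Harrell's convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import KnotDegeneracyError

# Harrell's recommended knot percentiles by number of knots.
KNOT_PERCENTILES = {
    3: (10.0, 50.0, 90.0),
    4: (5.0, 35.0, 65.0, 95.0),
    5: (5.0, 27.5, 50.0, 72.5, 95.0),
}


def place_knots(values, k: int) -> np.ndarray:
    """Place ``k`` knots at percentiles of ``values``.

    Percentiles follow the linear-interpolation ("type 7") convention.
    Raises :class:`KnotDegeneracyError` when there are fewer than ``k``
    distinct values or the computed knots are not strictly increasing.
    """
    if k not in KNOT_PERCENTILES:
        raise ValueError(f"number of knots must be one of {sorted(KNOT_PERCENTILES)}")
    values = np.asarray(values, dtype=float)
    if np.unique(values).size < k:
        raise KnotDegeneracyError(
            f"need at least {k} distinct values to place {k} knots"
        )
    knots = np.percentile(values, KNOT_PERCENTILES[k], method="linear")
    if np.any(np.diff(knots) <= 0):
        raise KnotDegeneracyError(
            f"computed knots are not strictly increasing: {knots.tolist()}"
        )
    return knots


@dataclass
class RCSBasisSpec:
    """A fixed restricted-cubic-spline basis: knots plus normalization.

    ``normalization_constant`` divides the nonlinear columns; it rescales
    coefficients but leaves every fitted spline function unchanged.  The
    default (t_k - t_1)^2 keeps the nonlinear columns on roughly the scale
    of the linear one.
    """

    knots: np.ndarray
    normalization_constant: float | None = None

    def __post_init__(self):
        self.knots = np.asarray(self.knots, dtype=float)
        k = self.knots.size
        if k not in KNOT_PERCENTILES:
            raise ValueError(f"number of knots must be one of {sorted(KNOT_PERCENTILES)}")
        if np.any(np.diff(self.knots) <= 0):
            raise KnotDegeneracyError("knots must be strictly increasing")
        if self.normalization_constant is None:
            self.normalization_constant = float((self.knots[-1] - self.knots[0]) ** 2)
        if self.normalization_constant <= 0:
            raise ValueError("normalization_constant must be positive")

    @property
    def n_knots(self) -> int:
        return self.knots.size

    @property
    def n_columns(self) -> int:
        return self.knots.size - 1

    @classmethod
    def from_data(cls, values, k: int, normalization_constant: float | None = None):
        return cls(place_knots(values, k), normalization_constant)


def rcs_design(values, spec: RCSBasisSpec) -> np.ndarray:
    """Evaluate the restricted-cubic-spline design matrix at ``values``.

    Column 0 is x itself; column j (j = 1..k-2) is

        [(x - t_j)+^3 - (x - t_{k-1})+^3 (t_k - t_j)/(t_k - t_{k-1})
                      + (x - t_k)+^3 (t_{k-1} - t_j)/(t_k - t_{k-1})] / c

    with c the normalization constant.  The restriction makes any linear
    combination exactly linear outside [t_1, t_k].
    """
    x = np.asarray(values, dtype=float)
    t = spec.knots
    k = t.size
    cols = [x]
    tk, tk1 = t[-1], t[-2]
    for j in range(k - 2):
        tj = t[j]
        term = (
            np.clip(x - tj, 0, None) ** 3
            - np.clip(x - tk1, 0, None) ** 3 * (tk - tj) / (tk - tk1)
            + np.clip(x - tk, 0, None) ** 3 * (tk1 - tj) / (tk - tk1)
        )
        cols.append(term / spec.normalization_constant)
    return np.column_stack(cols)
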