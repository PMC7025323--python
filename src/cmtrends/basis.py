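"""Bases for the non-linear time and age components.

Time: a second-order random walk (RW2) deviation per country, constrained
to sum to zero and to carry no linear trend so it is orthogonal to the
hierarchical intercept and slope.  The constrained space is parameterised
by an orthonormal basis Z (T x (T-2)) spanning the null space of the two
constraints; any weight vector w yields a valid deviation u = Z @ w, and
the RW2 smoothness penalty acts on the second differences D2 @ u.

Age: cubic B-splines over the adult age range with configurable interior
knots, pinned to zero at a reference age so the age curve is identified
against the intercept.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import null_space


def second_difference_matrix(n: int) -> np.ndarray:
    """(n-2) x n matrix mapping a series to its second differences."""
    if n < 3:
        raise ValueError("need at least 3 points for second differences")
    d2 = np.zeros((n - 2, n))
    for t in range(n - 2):
        d2[t, t:t + 3] = (1.0, -2.0, 1.0)
    return d2


class RW2Basis:
    """Orthonormal basis of the doubly-constrained RW2 deviation space."""

    def __init__(self, n_years: int):
        if n_years < 3:
            raise ValueError("RW2 deviation needs at least 3 years")
        t = np.arange(n_years, dtype=float)
        constraints = np.vstack([np.ones(n_years), t - t.mean()])
        self.n_years = n_years
        self.Z = null_space(constraints)                     # T x (T-2)
        self.D2 = second_difference_matrix(n_years)          # (T-2) x T
        self.D2Z = self.D2 @ self.Z                          # (T-2) x (T-2)

    @property
    def n_free(self) -> int:
        return self.Z.shape[1]

    def to_series(self, w: np.ndarray) -> np.ndarray:
        """Weights -> constrained deviation series over years."""
        return self.Z @ w

    def project(self, u: np.ndarray) -> np.ndarray:
        """Least-squares projection of an arbitrary series onto the space."""
        return self.Z.T @ u


class AgeBasis:
    """Cubic B-spline age basis pinned to zero at a reference age.

    The pinned basis b(a) = B(a) - B(ref_age) makes every spanned curve
    vanish at the reference age, for any coefficient vector.
    """

    def __init__(self, knots: tuple[float, ...] = (35.0, 50.0, 65.0),
                 ref_age: float = 45.0,
                 age_range: tuple[float, float] = (15.0, 90.0),
                 degree: int = 3):
        lo, hi = age_range
        knots = tuple(float(k) for k in knots)
        if any(b <= a for a, b in zip(knots, knots[1:])):
            raise ValueError("knots must be strictly increasing")
        if knots and (knots[0] <= lo or knots[-1] >= hi):
            raise ValueError("interior knots must lie inside the age range")
        if not (lo <= ref_age <= hi):
            raise ValueError("reference age outside the age range")
        self.knots = knots
        self.ref_age = ref_age
        self.age_range = (lo, hi)
        self.degree = degree
        self._t = np.concatenate([[lo] * (degree + 1), knots, [hi] * (degree + 1)])
        self.n_basis = len(knots) + degree + 1
        self._ref_row = self._raw(np.array([ref_age]))[0]

    def _raw(self, ages: np.ndarray) -> np.ndarray:
        lo, hi = self.age_range
        if ages.size == 0:
            return np.zeros((0, self.n_basis))
        if np.any(ages < lo) or np.any(ages > hi):
            raise ValueError(f"age outside the modelled range [{lo}, {hi}]")
        # clip the right endpoint into the half-open support of the last basis
        a = np.minimum(np.asarray(ages, dtype=float), hi - 1e-9)
        return BSpline.design_matrix(a, self._t, self.degree).toarray()

    def design(self, ages: np.ndarray) -> np.ndarray:
        """Pinned basis rows for the given ages (zero at the reference age)."""
        return self._raw(np.atleast_1d(np.asarray(ages, dtype=float))) - self._ref_row
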