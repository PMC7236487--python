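"""Spline bases used throughout the package.

Two bases appear in the models:

* a **natural cubic spline** basis over age for the longitudinal mean
  trajectories (cubic between knots, linear beyond the boundary knots), and
* a **cubic B-spline** basis for the log baseline hazard of the event
  submodel, which is held constant beyond its boundary knots.

The natural basis follows the classical truncated-power construction: with
knots xi_1 < ... < xi_K (boundary knots included), the df = K - 1 basis
functions are x and d_k(x) - d_{K-2}(x) for k = 1..K-2, where

    d_k(x) = [ (x - xi_k)_+^3 - (x - xi_K)_+^3 ] / (xi_K - xi_k).

Every basis function is exactly linear outside [xi_1, xi_K], and ages are
rescaled to [0, 1] over the boundary span before the powers are taken so the
columns are well conditioned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

from .errors import KnotError, ParameterError

__all__ = ["SplineBasisSpec", "build_spline_basis", "LogHazardBasis"]


@dataclass(frozen=True)
class SplineBasisSpec:
    """Recipe for a natural cubic spline basis over age.

    Parameters
    ----------
    degrees_of_freedom
        Number of basis columns (>= 1). ``df = 1`` is a plain linear term.
    boundary_knots
        Ages delimiting the cubic region; the basis is linear outside.
    interior_knots
        Optional explicit interior knots. When ``None`` they are placed at
        equally spaced quantiles of the ages supplied to :func:`resolve`.
    """

    degrees_of_freedom: int
    boundary_knots: tuple[float, float] = (6.0, 20.0)
    interior_knots: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.degrees_of_freedom < 1:
            raise ParameterError("degrees_of_freedom must be >= 1")
        lo, hi = self.boundary_knots
        if not lo < hi:
            raise ParameterError("boundary knots must be increasing")

    @property
    def n_interior(self) -> int:
        return self.degrees_of_freedom - 1

    def resolve(self, ages: np.ndarray | None = None) -> "SplineBasisSpec":
        """Return a spec with interior knots made explicit.

        Quantile placement needs at least ``df + 1`` distinct ages; with
        fewer a :class:`KnotError` is raised.
        """
        if self.interior_knots is not None:
            return self
        if self.n_interior == 0:
            return SplineBasisSpec(self.degrees_of_freedom, self.boundary_knots, ())
        if ages is None:
            raise KnotError("interior knots unspecified and no ages supplied")
        ages = np.asarray(ages, dtype=float)
        lo, hi = self.boundary_knots
        inside = ages[(ages >= lo) & (ages <= hi)]
        if np.unique(inside).size < self.degrees_of_freedom + 1:
            raise KnotError(
                f"need at least {self.degrees_of_freedom + 1} distinct ages in "
                f"[{lo}, {hi}] to place {self.n_interior} interior knot(s)"
            )
        probs = np.arange(1, self.n_interior + 1) / (self.n_interior + 1)
        knots = np.quantile(inside, probs)
        if np.unique(knots).size < knots.size or knots[0] <= lo or knots[-1] >= hi:
            # quantiles collided (heavily tied ages): spread them evenly instead
            knots = lo + (hi - lo) * probs
        return SplineBasisSpec(self.degrees_of_freedom, self.boundary_knots, tuple(knots))


def build_spline_basis(ages: np.ndarray, spec: SplineBasisSpec) -> np.ndarray:
    """Evaluate the natural cubic spline basis at ``ages``.

    Returns an ``(len(ages), df)`` matrix. The basis does not include an
    intercept column. Evaluation is defined for all finite ages;
    extrapolation beyond the boundary knots is exactly linear.
    """
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    if not np.all(np.isfinite(ages)):
        raise ParameterError("ages must be finite")
    spec = spec.resolve(ages)
    lo, hi = spec.boundary_knots
    span = hi - lo
    x = (ages - lo) / span
    knots = np.concatenate([[0.0], (np.asarray(spec.interior_knots) - lo) / span, [1.0]])
    cols = [x]
    if knots.size > 2:
        xiK, xiK1 = knots[-1], knots[-2]

        def d(k: int) -> np.ndarray:
            return (
                np.clip(x - knots[k], 0.0, None) ** 3
                - np.clip(x - xiK, 0.0, None) ** 3
            ) / (xiK - knots[k])

        dlast = d(knots.size - 2)
        for k in range(knots.size - 2):
            cols.append(d(k) - dlast)
    out = np.column_stack(cols)
    assert out.shape[1] == spec.degrees_of_freedom
    return out


@dataclass(frozen=True)
class LogHazardBasis:
    """Cubic B-spline basis for the log baseline hazard ``log h0(t)``.

    ``n_basis`` functions on ``boundary`` with ``n_basis - 4`` interior
    knots; evaluation outside the boundary clamps to the boundary value, so
    the log hazard is continued as a constant there.
    """

    n_basis: int = 5
    boundary: tuple[float, float] = (6.0, 20.0)
    interior_knots: tuple[float, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.n_basis < 4:
            raise ParameterError("need at least 4 B-spline basis functions (cubic)")
        lo, hi = self.boundary
        if not lo < hi:
            raise ParameterError("boundary must be increasing")
        if self.interior_knots is None:
            n_int = self.n_basis - 4
            knots = tuple(lo + (hi - lo) * np.arange(1, n_int + 1) / (n_int + 1))
            object.__setattr__(self, "interior_knots", knots)
        elif len(self.interior_knots) != self.n_basis - 4:
            raise ParameterError("interior knot count must equal n_basis - 4")

    @classmethod
    def from_times(cls, times: np.ndarray, n_basis: int = 5,
                   boundary: tuple[float, float] = (6.0, 20.0)) -> "LogHazardBasis":
        """Place interior knots at quantiles of observed exit times."""
        n_int = n_basis - 4
        if n_int == 0:
            return cls(n_basis, boundary)
        lo, hi = boundary
        t = np.asarray(times, dtype=float)
        t = t[(t > lo) & (t < hi)]
        if t.size < n_int + 1:
            return cls(n_basis, boundary)
        probs = np.arange(1, n_int + 1) / (n_int + 1)
        knots = np.quantile(t, probs)
        eps = 1e-6 * (hi - lo)
        knots = np.clip(knots, lo + eps, hi - eps)
        if np.unique(knots).size < knots.size:
            return cls(n_basis, boundary)
        return cls(n_basis, boundary, tuple(knots))

    @property
    def full_knots(self) -> np.ndarray:
        lo, hi = self.boundary
        return np.concatenate([[lo] * 4, self.interior_knots, [hi] * 4])

    def design(self, t: np.ndarray) -> np.ndarray:
        """Evaluate the basis at times ``t`` -> ``(len(t), n_basis)``."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        lo, hi = self.boundary
        eps = 1e-9 * (hi - lo)
        tc = np.clip(t, lo, hi - eps)
        dm = BSpline.design_matrix(tc, self.full_knots, 3)
        return np.asarray(dm.todense())
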