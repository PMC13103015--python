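"""Natural cubic spline basis for visit time.

Both the fixed and random parts of the trajectory models use a natural
cubic spline of time with two degrees of freedom: boundary knots at the
minimum and maximum observed measurement times of the variable and a
single interior knot at the median observed time (with multiplicity).
A natural cubic spline is piecewise cubic, C² inside the boundary
knots, and constrained to be *linear* beyond them — the sensible
behaviour when extrapolating a clinical trajectory slightly outside
the visit window.

The basis is built with the classical truncated-power construction
with the natural (zero second/third derivative beyond the boundary)
constraint absorbed:

    d_k(t) = [ (t − ξ_k)₊³ − (t − ξ_K)₊³ ] / (ξ_K − ξ_k)

    basis columns = { t,  d_1(t) − d_{K−1}(t), …, d_{K−2}(t) − d_{K−1}(t) }

for knots ξ_1 < … < ξ_K (boundary knots included).  With one interior
knot this yields exactly two columns.  Any other standard natural-spline
basis (e.g. R's ``splines::ns``) spans the same function space and
differs only by an invertible linear map, to which the mixed-model fits
are invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import IdentifiabilityError


@dataclass(frozen=True)
class SplineBasisSpec:
    """Knot layout of a natural cubic spline basis for time.

    ``df`` basis columns; the intercept is never part of the basis
    (it is a separate design column in every model).
    """

    df: int
    boundary_knots: tuple[float, float]
    interior_knots: tuple[float, ...]

    def __post_init__(self):
        lo, hi = self.boundary_knots
        if not lo < hi:
            raise IdentifiabilityError(f"boundary knots must be ordered, got ({lo}, {hi})")
        for k in self.interior_knots:
            if not lo < k < hi:
                raise IdentifiabilityError(
                    f"interior knot {k} not strictly inside boundary ({lo}, {hi})"
                )
        if len(self.interior_knots) != self.df - 1:
            raise IdentifiabilityError(
                f"df={self.df} requires {self.df - 1} interior knot(s), "
                f"got {len(self.interior_knots)}"
            )

    @property
    def all_knots(self) -> np.ndarray:
        return np.asarray([self.boundary_knots[0], *self.interior_knots, self.boundary_knots[1]])


def make_spline_spec(times, df: int = 2) -> SplineBasisSpec:
    """Build the spec from observed times: boundary at (min, max), interior at quantiles.

    For ``df = 2`` (the default trajectory configuration) the single
    interior knot sits at the median of the supplied times, counted
    with multiplicity.  Raises :class:`IdentifiabilityError` when fewer
    than 3 distinct times are available or an interior knot collides
    with a boundary knot — callers fall back to slope/intercept-only
    structures in that case.
    """
    t = np.asarray(times, dtype=float)
    if t.size == 0 or not np.isfinite(t).all():
        raise IdentifiabilityError("times must be non-empty and finite")
    distinct = np.unique(t)
    if distinct.size < 3:
        raise IdentifiabilityError(
            f"natural spline needs >= 3 distinct times, got {distinct.size}"
        )
    if df < 2:
        raise IdentifiabilityError("natural spline basis requires df >= 2")
    lo, hi = float(distinct[0]), float(distinct[-1])
    probs = np.arange(1, df) / df
    interior = tuple(float(q) for q in np.quantile(t, probs))
    for k in interior:
        if not lo < k < hi:
            raise IdentifiabilityError(
                f"interior knot {k} coincides with a boundary knot ({lo}, {hi}); "
                "too little spread in observation times"
            )
    if len(set(interior)) != len(interior):
        raise IdentifiabilityError(f"tied interior knots {interior}")
    return SplineBasisSpec(df=df, boundary_knots=(lo, hi), interior_knots=interior)


def evaluate_basis(spec: SplineBasisSpec, t) -> np.ndarray:
    """Evaluate the ``df`` natural-spline basis columns at times ``t``.

    Returns an array of shape ``(len(t), df)`` (or ``(df,)`` for scalar
    input).  Extrapolation beyond the boundary knots is exactly linear.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    knots = spec.all_knots
    K = len(knots)
    xi_K = knots[-1]

    def d(k_idx: int) -> np.ndarray:
        xk = knots[k_idx]
        num = np.maximum(t_arr - xk, 0.0) ** 3 - np.maximum(t_arr - xi_K, 0.0) ** 3
        return num / (xi_K - xk)

    cols = [t_arr]
    d_last = d(K - 2)
    for k_idx in range(K - 2):
        cols.append(d(k_idx) - d_last)
    out = np.column_stack(cols)
    if np.isscalar(t) or np.ndim(t) == 0:
        return out[0]
    return out
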